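"""Mutation kernel, lineage scoring, hybrid simulation, and ensemble summaries."""

import numpy as np
import pytest

from metaniche import (CellType, MutationParams, TumorState, classify_fate,
                       published_defaults, invasion_success, mutation_kernel,
                       records_to_frame, resident_community, run_ensemble,
                       simulate_tumor, summarize)
from metaniche.ensemble import EnsembleRecord, MutationEvent


class TestMutationKernel:
    def test_empty_tumor_yields_no_events(self, mutation_defaults):
        rng = np.random.default_rng(0)
        assert mutation_kernel(np.zeros(4), 1.0, mutation_defaults, rng) == []

    def test_event_rates_scale_with_population_and_class(self):
        # amplify the population so the Poisson means are testable in one
        # draw: n00 = 1e12 gives mean 400 for each 1/500 transition from
        # (0,0) and mean 200 for the (0,0)->(1,1) double transition
        mp = MutationParams()
        rng = np.random.default_rng(1234)
        counts = {}
        n = np.array([1e12, 0, 0, 0])
        for ev in mutation_kernel(n, 1.0, mp, rng):
            counts[(ev.source, ev.target)] = ev.seeded_cells
        single = counts[(CellType.CHEATER, CellType.SECONDARY)]
        double = counts[(CellType.CHEATER, CellType.GLOBAL)]
        assert 300 < single < 500     # Poisson(400) within ~5 sigma
        assert 130 < double < 270     # Poisson(200)
        assert (CellType.LOCAL, CellType.GLOBAL) not in counts  # no source cells

    def test_expected_arrival_rate_at_tumor_scale(self, mutation_defaults):
        # n00 = 1e5: mean (0,0)->(0,1) events per day is 1e5*2e-7/500 = 4e-5
        mp = mutation_defaults
        lam = 1e5 * mp.rate_per_cell_per_day * mp.p_major
        assert lam == pytest.approx(4e-5)

    def test_fixed_seed_replays_identically(self, mutation_defaults):
        n = np.array([1e10, 1e9, 1e10, 1e8])
        a = mutation_kernel(n, 1.0, mutation_defaults,
                            np.random.default_rng(7))
        b = mutation_kernel(n, 1.0, mutation_defaults,
                            np.random.default_rng(7))
        assert [(e.source, e.target, e.seeded_cells) for e in a] == \
            [(e.source, e.target, e.seeded_cells) for e in b]

    def test_rejects_nonpositive_interval(self, mutation_defaults):
        with pytest.raises(ValueError):
            mutation_kernel(np.zeros(4), 0.0, mutation_defaults,
                            np.random.default_rng(0))


class TestInvasionSuccess:
    def test_extinct_lineage_failed(self):
        assert invasion_success(0.0, 1e5, -0.1) == "failed"
        assert invasion_success(0.5, 1e5, 0.2) == "failed"

    def test_threshold_crossing_with_growth_established(self):
        assert invasion_success(150.0, 1e5, 0.004) == "established"
        # larger tumors demand a larger absolute foothold (0.1% of N)
        assert invasion_success(150.0, 1e9, 0.004) == "pending"
        assert invasion_success(1.1e6, 1e9, 0.004) == "established"

    def test_crossing_while_declining_stays_pending(self):
        assert invasion_success(150.0, 1e5, -0.01) == "pending"


class TestResidentCommunity:
    def test_composition_labels(self):
        assert resident_community(np.array([1e5, 0, 0, 0])) == "cheater_only"
        assert resident_community(np.array([10.0, 0, 1e6, 0])) == "producer_only"
        assert resident_community(np.array([5e4, 0, 5e4, 0])) == "coexistence"
        assert resident_community(np.array([5e4, 5e4, 5e4, 0])) == "metastatic"
        assert resident_community(np.zeros(4)) == "empty"

    def test_one_percent_threshold(self):
        n = np.array([1e5, 0, 999.0, 0])
        assert resident_community(n) == "cheater_only"
        n[2] = 1.2e3
        assert resident_community(n) == "coexistence"


class TestSimulateTumor:
    def test_zero_mutation_rate_is_deterministic_plateau(self, published,
                                                         cheater_start):
        mp = MutationParams(rate_per_cell_per_day=0.0)
        traj, rec = simulate_tumor(published, mp, 1500, 3, initial=cheater_start)
        assert rec.events == []
        assert rec.fate == "cheater_only"
        assert rec.final_state.N == pytest.approx(published.k, rel=1e-2)

    def test_fixed_seed_reproducibility(self, published, mutation_defaults,
                                        cheater_start):
        out = []
        for _ in range(2):
            traj, rec = simulate_tumor(published, mutation_defaults, 3000, 11,
                                       initial=cheater_start)
            out.append((tuple((e.t, e.source, e.target, e.outcome)
                              for e in rec.events),
                        rec.final_state.n.tobytes(), rec.final_state.R))
        assert out[0] == out[1]

    def test_seeded_lineage_deducted_from_source(self, published, cheater_start):
        # force an immediate, certain mutation: rate 1, all mass to (0,0)->(1,0)
        mp = MutationParams(rate_per_cell_per_day=1.0, p_major=1.0 / 6,
                            p_double=1.0 / 6)
        traj, rec = simulate_tumor(published, mp, 3, 5, initial=cheater_start)
        assert rec.events, "with rate 1 and n=1e3, events are certain"
        first = rec.events[0]
        assert first.seeded_cells >= 1
        assert first.resident_community == "cheater_only"


class TestClassifyFate:
    def test_established_prometastatic_lineage_dominates(self):
        rec = EnsembleRecord(0, 0)
        rec.events.append(MutationEvent(40.0, CellType.CHEATER,
                                        CellType.SECONDARY,
                                        outcome="established",
                                        resolution_time=60.0))
        fate, t = classify_fate(rec, TumorState([1e5, 5e3, 0, 0], 10.0))
        assert fate == "metastasis_competent"
        assert t == 60.0

    def test_producer_takeover_without_metastatic_lineage(self):
        rec = EnsembleRecord(0, 0)
        rec.events.append(MutationEvent(10.0, CellType.CHEATER, CellType.LOCAL,
                                        outcome="established"))
        fate, _ = classify_fate(rec, TumorState([0, 0, 5e6, 0], 4e6, t=3650))
        assert fate == "producer_only"

    def test_quiet_tumor_stays_cheater_only(self):
        fate, _ = classify_fate(EnsembleRecord(0, 0),
                                TumorState([1e5, 0, 0, 0], 0.0))
        assert fate == "cheater_only"


class TestRunEnsemble:
    def test_requires_at_least_one_tumor(self, published, mutation_defaults):
        with pytest.raises(ValueError):
            run_ensemble(0, published, mutation_defaults, 100, 1)

    def test_master_seed_reproducibility(self, published, mutation_defaults):
        frames = []
        for _ in range(2):
            records, summary, _ = run_ensemble(4, published, mutation_defaults,
                                               1200, 99)
            frames.append(records_to_frame(records))
        assert frames[0].equals(frames[1])

    def test_single_tumor_matches_direct_simulation(self, published,
                                                    mutation_defaults):
        records, summary, _ = run_ensemble(1, published, mutation_defaults, 800, 21)
        child = np.random.SeedSequence(21).spawn(1)[0]
        _, direct = simulate_tumor(published, mutation_defaults, 800, child,
                                   tumor_id=0, keep_trajectory=True)
        assert records_to_frame(records).equals(records_to_frame([direct]))

    def test_zero_rate_ensemble_all_cheater_only(self, published):
        mp = MutationParams(rate_per_cell_per_day=0.0)
        records, summary, _ = run_ensemble(3, published, mp, 400, 2)
        assert summary.fate_counts == {"cheater_only": 3}
        assert (summary.tradeoff["arrivals"] == 0).all()

    def test_summary_counts_are_consistent(self, published, mutation_defaults):
        records, summary, _ = run_ensemble(4, published, mutation_defaults, 1200, 99)
        total = sum(len(r.metastatic_events) for r in records)
        assert summary.tradeoff["arrivals"].sum() == total
        assert sum(summary.fate_counts.values()) == 4
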