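"""Hybrid deterministic-stochastic tumor simulation and the mutation ensemble.

Between-mutation dynamics are deterministic (the clone sizes involved,
1e5-1e7 cells, make demographic noise negligible); mutation arrivals are
stochastic.  Each day, for each allowed phenotype transition, the number of
mutation events is Poisson with mean n_source * rate * p(transition); each
event moves one cell (or the drawn count) from the source clone into the
target clone, seeding a rare lineage whose fate is then scored against
establishment and extinction thresholds.

The headline experiment runs an ensemble of tumors that all start cheater-
only and tallies arrivals and establishments of pre-metastatic producer
lineages, stratified by the resident community at arrival time: the
arrival-vs-invasion trade-off (small cheater tumors see few mutants but are
invadable; large producer tumors see many mutants that all fail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Trajectory, _solve_chunk
from .model import competition_matrix, rhs_cells
from .params import ModelParams, MutationParams, DEFAULT_INITIAL
from .types import CANONICAL_ORDER, METASTATIC_TYPES, CellType, TumorState

__all__ = [
    "MutationEvent", "EnsembleRecord", "EnsembleSummary",
    "mutation_kernel", "invasion_success", "simulate_tumor",
    "run_ensemble", "classify_fate", "resident_community", "summarize",
]

#: A clone counts as part of the resident community when it holds at least
#: this fraction of the total population.
RESIDENT_FRACTION = 0.01

#: Establishment threshold constants: the lineage must exceed
#: max(ESTABLISH_FOLD * seeded cells, ESTABLISH_FRACTION * N).
ESTABLISH_FOLD = 100.0
ESTABLISH_FRACTION = 1e-3


@dataclass
class MutationEvent:
    """One phenotype-changing mutation arrival."""

    t: float
    source: CellType
    target: CellType
    seeded_cells: float = 1.0
    outcome: str = "pending"      # pending | established | failed
    resident_community: str = ""  # community label at arrival time
    resolution_time: float | None = None


@dataclass
class EnsembleRecord:
    """Per-tumor history of mutation events, outcomes and final fate."""

    tumor_id: int
    seed: int
    events: list[MutationEvent] = field(default_factory=list)
    fate: str = "cheater_only"
    fate_time: float | None = None
    final_state: TumorState | None = None

    @property
    def metastatic_events(self) -> list[MutationEvent]:
        return [e for e in self.events if e.target in METASTATIC_TYPES]


def resident_community(n: np.ndarray, fraction: float = RESIDENT_FRACTION) -> str:
    """Label the resident community by which clones hold >= ``fraction`` of N.

    Returns ``cheater_only``, ``producer_only``, ``coexistence`` (cheaters
    and local producers), ``metastatic`` (a pre-metastatic clone is
    resident) or ``empty``.
    """
    N = float(np.sum(n))
    if N <= 0:
        return "empty"
    residents = {ct for ct in CANONICAL_ORDER if n[ct.index] >= fraction * N}
    if residents & set(METASTATIC_TYPES):
        return "metastatic"
    if residents == {CellType.CHEATER}:
        return "cheater_only"
    if residents == {CellType.LOCAL}:
        return "producer_only"
    if residents == {CellType.CHEATER, CellType.LOCAL}:
        return "coexistence"
    return "empty"


def mutation_kernel(n: np.ndarray, dt: float, mp: MutationParams,
                    rng: np.random.Generator) -> list[MutationEvent]:
    """Draw the phenotype-changing mutation events over an interval ``dt``.

    One vectorised Poisson draw per call, over the allowed transitions in
    their fixed canonical order, with mean n_source * rate * dt * p; the
    residual mutation mass is phenotypically silent and not tracked.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam = np.array([
        max(float(n[s.index]), 0.0) * mp.rate_per_cell_per_day * dt
        * (mp.p_major if cls == "major" else mp.p_double)
        for s, t, cls in mp.transitions
    ])
    counts = rng.poisson(lam)
    events = []
    for (s, t, _cls), c in zip(mp.transitions, counts):
        if c > 0:
            events.append(MutationEvent(t=np.nan, source=s, target=t,
                                        seeded_cells=float(c)))
    return events


def invasion_success(size: float, N: float, percap_growth: float,
                     seeded: float = 1.0,
                     extinction_threshold: float = 1.0) -> str:
    """Score a seeded lineage from one observation of its state.

    ``established`` once the lineage exceeds max(100 x seeded cells, 0.1%
    of the tumor) while its per-capita growth is nonnegative; ``failed``
    once it drops below the pseudo-extinction threshold; ``pending``
    otherwise.
    """
    if size < extinction_threshold:
        return "failed"
    if (size >= max(ESTABLISH_FOLD * seeded, ESTABLISH_FRACTION * N)
            and percap_growth >= 0):
        return "established"
    return "pending"


def _percap_growth(n: np.ndarray, R: float, params: ModelParams,
                   C: np.ndarray, i: int) -> float:
    if n[i] <= 0:
        return 0.0
    return float(rhs_cells(n, R, params, C=C)[i] / n[i])


def simulate_tumor(params: ModelParams, mp: MutationParams, horizon: float,
                   seed, initial: TumorState | None = None,
                   max_chunk_days: float = 365.0,
                   extinction_threshold: float = 1.0,
                   rtol: float = 1e-8, atol: float = 1e-6,
                   tumor_id: int = 0,
                   keep_trajectory: bool = True
                   ) -> tuple[Trajectory | None, EnsembleRecord]:
    """Simulate one tumor: deterministic dynamics plus daily mutation draws.

    The ODE is integrated in multi-day chunks with daily dense-output
    samples; the daily Poisson mutation draws are made from the sampled
    states in chronological order, and the chunk is truncated and the state
    modified at the first day carrying an event (mutation arrival or
    pseudo-extinction), so the event stream is identical to strict daily
    stepping of the same scheme.  ``seed`` may be an int or a
    ``numpy.random.SeedSequence``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if initial is None:
        d = DEFAULT_INITIAL
        initial = TumorState(n=[d["n00"], d["n01"], d["n10"], d["n11"]],
                             R=d["R"], t=0.0)
    seedseq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seedseq)
    C = competition_matrix(params)

    record = EnsembleRecord(tumor_id=tumor_id,
                            seed=int(seedseq.entropy) if seedseq.spawn_key == ()
                            else int(seedseq.spawn_key[-1]))
    pending: list[MutationEvent] = []

    t = initial.t
    t_end = initial.t + horizon
    n = initial.n.copy()
    R = initial.R
    times = [t]
    ns = [n.copy()]
    Rs = [R]
    traj_events: list[tuple[float, str]] = []

    def update_pending(t_now: float, n_now: np.ndarray, R_now: float,
                       zeroed: set[int]) -> None:
        for ev in pending:
            i = ev.target.index
            if i in zeroed or n_now[i] <= 0:
                ev.outcome = "failed"
                ev.resolution_time = t_now
                continue
            growth = _percap_growth(n_now, R_now, params, C, i)
            verdict = invasion_success(n_now[i], float(n_now.sum()), growth,
                                       seeded=ev.seeded_cells,
                                       extinction_threshold=extinction_threshold)
            if verdict != "pending":
                ev.outcome = verdict
                ev.resolution_time = t_now
        pending[:] = [ev for ev in pending if ev.outcome == "pending"]

    while t < t_end - 1e-9:
        chunk_end = min(t + max_chunk_days, t_end)
        t_eval = np.arange(np.floor(t) + 1.0, chunk_end + 1e-9, 1.0)
        if t_eval.size == 0 or t_eval[-1] < chunk_end - 1e-9:
            t_eval = np.append(t_eval, chunk_end)
        t_eval = t_eval[t_eval > t + 1e-9]
        sol = _solve_chunk(params, np.append(n, R), t, chunk_end, t_eval, C,
                           rtol, atol, "LSODA")
        interrupted = False
        for j in range(sol.y.shape[1]):
            t_j = float(sol.t[j])
            n_j = np.clip(sol.y[:4, j], 0.0, None)
            R_j = max(float(sol.y[4, j]), 0.0)

            # pseudo-extinction of declining trace clones
            zeroed: set[int] = set()
            if extinction_threshold > 0:
                dn = rhs_cells(n_j, R_j, params, C=C)
                for ct in CANONICAL_ORDER:
                    i = ct.index
                    if 0 < n_j[i] < extinction_threshold and dn[i] < 0:
                        n_j[i] = 0.0
                        zeroed.add(i)
                        traj_events.append((t_j, f"extinct:{ct.label}"))

            # daily mutation draw from the sampled state
            events = mutation_kernel(n_j, 1.0, mp, rng)
            for ev in events:
                ev.t = t_j
                ev.resident_community = resident_community(n_j)
                moved = min(ev.seeded_cells, n_j[ev.source.index])
                if moved <= 0:
                    continue
                ev.seeded_cells = moved
                n_j[ev.source.index] -= moved
                n_j[ev.target.index] += moved
                zeroed.discard(ev.target.index)
                record.events.append(ev)
                pending.append(ev)
                traj_events.append(
                    (t_j, f"mutation:{ev.source.label}->{ev.target.label}"))

            update_pending(t_j, n_j, R_j, zeroed)
            if keep_trajectory or t_j >= t_end - 1e-9:
                times.append(t_j)
                ns.append(n_j.copy())
                Rs.append(R_j)
            if events or zeroed:
                n, R, t = n_j, R_j, t_j
                interrupted = True
                break
        if not interrupted:
            t = float(sol.t[-1])
            n = np.clip(sol.y[:4, -1], 0.0, None)
            R = max(float(sol.y[4, -1]), 0.0)

    final = TumorState(n=n.copy(), R=R, t=t)
    # horizon-end pending lineages resolve by the sign of their current
    # per-capita growth rate
    for ev in pending:
        growth = _percap_growth(n, R, params, C, ev.target.index)
        ev.outcome = "established" if growth > 0 else "failed"
        ev.resolution_time = t
    pending.clear()

    record.final_state = final
    record.fate, record.fate_time = classify_fate(record, final)
    traj = None
    if keep_trajectory:
        traj = Trajectory(np.array(times), np.vstack(ns), np.array(Rs),
                          sorted(traj_events))
    return traj, record


def classify_fate(record: EnsembleRecord,
                  final: TumorState) -> tuple[str, float | None]:
    """Fate label and the time at which it was sealed.

    ``metastasis_competent`` dominates: some pre-metastatic producer
    lineage established (the model's necessary condition for metastasis).
    Otherwise the final resident composition decides between
    ``cheater_only``, ``producer_only`` and ``coexistence``.
    """
    established_meta = [e for e in record.metastatic_events
                        if e.outcome == "established"]
    if established_meta:
        first = min(established_meta, key=lambda e: e.resolution_time or np.inf)
        return "metastasis_competent", first.resolution_time
    label = resident_community(final.n)
    if label in ("metastatic", "empty"):
        label = "cheater_only" if final.n[CellType.CHEATER.index] > 0 \
            else "producer_only"
    return label, final.t


def run_ensemble(n_tumors: int, params: ModelParams, mp: MutationParams,
                 horizon: float, master_seed: int,
                 initial: TumorState | None = None,
                 keep_trajectories: bool = False,
                 **sim_kwargs) -> tuple[list[EnsembleRecord], "EnsembleSummary",
                                        list[Trajectory | None]]:
    """Simulate ``n_tumors`` independent tumors from per-tumor substreams.

    Substream seeds derive from ``master_seed`` via SeedSequence spawning,
    so the whole ensemble is reproducible bit-for-bit from one integer.
    """
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n_tumors)
    records, trajs = [], []
    for i, child in enumerate(children):
        traj, rec = simulate_tumor(params, mp, horizon, child, initial=initial,
                                   tumor_id=i, keep_trajectory=keep_trajectories,
                                   **sim_kwargs)
        records.append(rec)
        trajs.append(traj)
    return records, summarize(records), trajs


@dataclass
class EnsembleSummary:
    """Fate counts and the arrival/establishment trade-off table."""

    n_tumors: int
    fate_counts: dict[str, int]
    tradeoff: pd.DataFrame  # rows: resident community at arrival

    def establishment_probability(self, community: str) -> float:
        row = self.tradeoff.loc[self.tradeoff["community"] == community]
        if row.empty or int(row["arrivals"].iloc[0]) == 0:
            return float("nan")
        return float(row["establishments"].iloc[0] / row["arrivals"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return self.tradeoff.copy()


def summarize(records: list[EnsembleRecord]) -> EnsembleSummary:
    """Tally fates and stratify pre-metastatic arrivals by community."""
    fate_counts: dict[str, int] = {}
    for rec in records:
        fate_counts[rec.fate] = fate_counts.get(rec.fate, 0) + 1
    communities = ("cheater_only", "coexistence", "producer_only", "metastatic")
    rows = []
    for community in communities:
        arrivals = establishments = 0
        for rec in records:
            for ev in rec.metastatic_events:
                if ev.resident_community == community:
                    arrivals += 1
                    establishments += ev.outcome == "established"
        rows.append({"community": community, "arrivals": arrivals,
                     "establishments": establishments})
    return EnsembleSummary(len(records), fate_counts, pd.DataFrame(rows))


def records_to_frame(records: list[EnsembleRecord]) -> pd.DataFrame:
    """Flat per-tumor table (one row per tumor) for CSV export."""
    rows = []
    for rec in records:
        meta = rec.metastatic_events
        est = [e for e in meta if e.outcome == "established"]
        rows.append({
            "tumor_id": rec.tumor_id,
            "fate": rec.fate,
            "fate_time": rec.fate_time,
            "n_arrivals_01_11": len(meta),
            "n_establishments": len(est),
            "first_establishment_day": min(
                (e.resolution_time for e in est), default=np.nan),
            "final_N": rec.final_state.N if rec.final_state else np.nan,
            "final_R": rec.final_state.R if rec.final_state else np.nan,
        })
    return pd.DataFrame(rows)


__all__.append("records_to_frame")
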