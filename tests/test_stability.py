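"""Invasion growth rates, Jacobians, stability verdicts, and analytic cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaniche import (CellType, NotApplicable, agreement_summary,
                       analytic_condition_limit, analytic_invasion_exact,
                       analytic_invasion_margin, coexistence_equilibrium,
                       consistency_report, published_defaults, invasion_growth_rate,
                       is_stable, jacobian_fast, limit_condition_margin,
                       rhs_cells, sample_params, single_type_equilibrium)


def _central_difference_jacobian(n, R, params, h=1e-3):
    J = np.zeros((4, 4))
    for j in range(4):
        up, dn = n.copy(), n.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (rhs_cells(up, R, params) - rhs_cells(dn, R, params)) / (2 * h)
    return J


class TestInvasionGrowthRate:
    def test_cheater_tumor_invadable_by_local_producers(self, no_dispersal):
        # lambda = r10 (1 - theta) > 0 whenever theta < 1
        eq = single_type_equilibrium(CellType.CHEATER, 0.0, no_dispersal)
        lam = invasion_growth_rate(CellType.LOCAL, eq, no_dispersal)
        assert lam == pytest.approx(no_dispersal.r10 * (1 - no_dispersal.theta))
        assert lam > 0

    def test_growthless_invader_only_disperses(self, published):
        p = published.replace(r11=1e-15)
        eq = single_type_equilibrium(CellType.CHEATER, 0.0, p)
        lam = invasion_growth_rate(CellType.GLOBAL, eq, p)
        m = p.alpha * eq.N / (p.k + p.beta1 * eq.R)
        assert lam == pytest.approx(-m, rel=1e-6)
        assert lam <= 0

    def test_weakly_coupled_secondary_producers_invade_specific_niche(self):
        # omega=0.7 < beta0/beta1 = 0.833: invasion succeeds at large R
        p = published_defaults(alpha=0.0, omega=0.7)
        eq = single_type_equilibrium(CellType.LOCAL, 1e9, p)
        assert invasion_growth_rate(CellType.SECONDARY, eq, p) > 0
        # omega=0.9 > 0.833: invasion fails
        p2 = published_defaults(alpha=0.0, omega=0.9)
        eq2 = single_type_equilibrium(CellType.LOCAL, 1e9, p2)
        assert invasion_growth_rate(CellType.SECONDARY, eq2, p2) < 0

    def test_resident_invader_rejected(self, published):
        eq = single_type_equilibrium(CellType.CHEATER, 0.0, published)
        with pytest.raises(ValueError, match="resident"):
            invasion_growth_rate(CellType.CHEATER, eq, published)


class TestJacobian:
    def test_empty_tumor_decouples_to_growth_rates(self, published):
        J = jacobian_fast(np.zeros(4), 1e4, published)
        assert np.allclose(J, np.diag(published.growth_rates))

    def test_single_type_equilibrium_restoring_force(self, no_dispersal):
        # at the logistic fixed point the focal diagonal entry is -r
        eq = single_type_equilibrium(CellType.CHEATER, 0.0, no_dispersal)
        J = jacobian_fast(eq.n_star, 0.0, no_dispersal)
        i = CellType.CHEATER.index
        assert J[i, i] == pytest.approx(-no_dispersal.r00, rel=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        p = sample_params(rng, str(rng.choice(["I", "II", "III"])))
        n = rng.uniform(0, 2 * p.k, size=4)
        R = float(rng.uniform(0, 10 * p.k))
        J = jacobian_fast(n, R, p)
        Jfd = _central_difference_jacobian(n, R, p)
        assert np.allclose(J, Jfd, rtol=1e-6, atol=1e-6 * np.abs(J).max())


class TestStability:
    def test_specific_niche_construction_protects_producers(self):
        # theta = 0.9 > beta0/beta1 = 0.833: producer-only resists cheaters
        p = published_defaults(alpha=0.0)
        eq = single_type_equilibrium(CellType.LOCAL, 1e9 * p.k, p)
        assert is_stable(eq, p).stable

    def test_weak_competition_lets_cheaters_back_in(self):
        p = published_defaults(alpha=0.0, theta=0.5)
        eq = single_type_equilibrium(CellType.LOCAL, 1e9 * p.k, p)
        rep = is_stable(eq, p)
        assert not rep.stable
        assert rep.external_growth_rates[CellType.CHEATER] > 0

    def test_cheater_only_tumor_always_unstable(self, rng):
        for structure in ("I", "II", "III"):
            p = sample_params(rng, structure, alpha_max=0.0)
            eq = single_type_equilibrium(CellType.CHEATER, 0.0, p)
            assert not is_stable(eq, p).stable


class TestAnalyticExact:
    def test_reduces_to_pairwise_condition_for_cheater_resident(self):
        # with n10 = 0 the secondary-producer condition is phi n00 < k + beta0 R
        p = published_defaults(alpha=0.0, phi=0.4)
        eq = single_type_equilibrium(CellType.CHEATER, 0.0, p)
        margin = analytic_invasion_margin(CellType.SECONDARY, eq, p)
        n00 = eq.abundance(CellType.CHEATER)
        assert margin == pytest.approx((p.k - p.phi * n00) / p.k, rel=1e-12)
        assert analytic_invasion_exact(CellType.SECONDARY, eq, p)

    def test_structure_three_producer_tumor_blocks_global_producers(self):
        # n10* equals the invader's carrying capacity exactly at alpha=0, so
        # the strict inequality fails: global producers cannot invade
        p = published_defaults(structure="III", alpha=0.0)
        eq = single_type_equilibrium(CellType.LOCAL, 1e8, p)
        assert not analytic_invasion_exact(CellType.GLOBAL, eq, p)
        assert abs(analytic_invasion_margin(CellType.GLOBAL, eq, p)) < 1e-10

    def test_not_applicable_outside_scope(self, published):
        eq = single_type_equilibrium(CellType.SECONDARY, 0.0, published)
        with pytest.raises(NotApplicable):
            analytic_invasion_exact(CellType.GLOBAL, eq, published)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sign_equivalence_with_numeric_rate(self, seed):
        # the exact inequality is algebraically identical to lambda > 0
        rng = np.random.default_rng(seed)
        p = sample_params(rng, str(rng.choice(["I", "II", "III"])))
        R = float(rng.choice([0.0, p.k, 1e3 * p.k]))
        eq = coexistence_equilibrium(R, p) if rng.random() < 0.5 else \
            single_type_equilibrium(rng.choice(
                [CellType.CHEATER, CellType.LOCAL]), R, p)
        if eq is None:
            return
        for invader in (CellType.SECONDARY, CellType.GLOBAL):
            lam = invasion_growth_rate(invader, eq, p)
            if abs(lam) / p.growth_rates[invader.index] < 1e-3:
                continue  # knife edge: sign not meaningful
            assert (lam > 0) == analytic_invasion_exact(invader, eq, p)


class TestInvasionVerdict:
    def test_routes_agree_and_limit_is_attached(self):
        from metaniche import invasion_verdict
        p = published_defaults(alpha=0.0)
        eq = single_type_equilibrium(CellType.LOCAL, 1e6 * p.k, p)
        v = invasion_verdict(CellType.SECONDARY, eq, p)
        # omega = 0.9 > beta0/beta1: blocked by every route
        assert v.lambda_num < 0
        assert v.analytic_exact is False and v.analytic_limit is False
        assert v.agree and not v.boundary
        w = invasion_verdict(CellType.GLOBAL, eq, p)  # mu = 0.9 < 1: open
        assert w.lambda_num > 0 and w.analytic_exact and w.analytic_limit


class TestLimitConditions:
    @pytest.mark.parametrize("structure,resident,question,expected", [
        ("I", "producer_only", "stability", True),     # theta > beta0/beta1
        ("I", "producer_only", "invade_01", False),    # omega=0.9 > 0.833
        ("I", "producer_only", "invade_11", True),     # mu < 1
        ("II", "producer_only", "invade_01", False),   # beta0 < beta1
        ("II", "producer_only", "invade_11", False),   # unconditional
        ("III", "producer_only", "invade_01", False),  # theta > beta0/beta1
        ("I", "cheater_only", "stability", False),
        ("I", "cheater_only", "invade_01", True),      # phi < 1
        ("III", "cheater_only", "invade_01", False),   # r01 < r10 by default
        ("III", "cheater_only", "invade_11", True),    # phi < 1
        ("III", "coexistence", "invade_01", False),    # unconditional
    ])
    def test_published_default_grid(self, structure, resident, question, expected):
        p = published_defaults(structure=structure)
        assert analytic_condition_limit(resident, question, p) is expected

    def test_coexistence_stability_not_tabulated(self, published):
        with pytest.raises(NotApplicable):
            analytic_condition_limit("coexistence", "stability", published)

    def test_structure_three_mutual_exclusivity(self, rng):
        # producer-only stability and secondary-producer invasion are mutually
        # exclusive away from theta = beta0/beta1, and flip together
        for _ in range(100):
            p = sample_params(rng, "III", alpha_max=0.0)
            if abs(p.theta - p.beta0 / p.beta1) < 1e-3:
                continue
            stab = analytic_condition_limit("producer_only", "stability", p)
            inv = analytic_condition_limit("producer_only", "invade_01", p)
            assert stab != inv

    def test_window_of_specificity(self, rng):
        # omega < beta0/beta1 < theta: stable against cheaters yet open to
        # secondary producers
        found = 0
        while found < 20:
            p = sample_params(rng, "I", alpha_max=0.0)
            ratio = p.beta0 / p.beta1
            if not (p.omega < ratio - 0.02 and ratio + 0.02 < p.theta):
                continue
            found += 1
            eq = single_type_equilibrium(CellType.LOCAL, 1e6 * p.k, p)
            assert is_stable(eq, p).stable
            assert invasion_growth_rate(CellType.SECONDARY, eq, p) > 0


class TestConsistencyReport:
    def test_empty_for_zero_draws(self):
        rep = consistency_report(0, 1, regime="limit")
        assert rep.empty

    def test_limit_regime_agreement_on_small_sample(self):
        rep = consistency_report(40, 11, regime="limit")
        summary = agreement_summary(rep)
        informative = summary[summary.n_effective > 0]
        assert (informative.agreement == 1.0).all()
        # the knife-edge cells (invader growth rate identically zero in the
        # limit) are flagged as all-boundary rather than scored
        degenerate = set(map(tuple, summary[summary.n_effective == 0]
                             [["structure", "resident", "question"]].values))
        assert degenerate <= {
            ("II", "producer_only", "invade_11"),
            ("III", "producer_only", "invade_11"),
            ("III", "cheater_only", "invade_01"),
            ("III", "coexistence", "invade_01"),
            ("III", "coexistence", "invade_11"),
        }

    def test_exact_regime_sign_agreement(self):
        rep = consistency_report(40, 5, regime="exact",
                                 R_values=(0.0, 1e5, 1e8))
        nb = rep[~rep.boundary]
        assert len(nb) > 100
        assert (nb.numeric == nb.exact).all()
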