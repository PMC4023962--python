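"""State-dependent speciation-extinction likelihoods and model fits."""

import math

import numpy as np
import pytest

from divergrass.bisse import (
    BisseFit,
    BisseLikelihood,
    BisseParams,
    ModelSpec,
    branch_integrate,
    compare_models,
    fit_model,
    lrt,
    replicate_analysis,
    tip_init,
    tree_loglik,
    unresolved_clade_init,
)
from divergrass.medusa import BDRegime, backbone_loglik
from divergrass.phylo_core import TimeTree, TipData
from divergrass.synthetic_data import (
    DEFAULT_BISSE_PARAMS,
    SimulationConfig,
    perturb_tree_set,
    simulate_bisse_tree,
)

from .oracles import rk4_branch, rk4_tree_loglik


class TestBranchIntegrate:
    def test_pure_birth_analytic(self):
        """With lambda0=1 and no extinction/transitions, D0(t) = e^-t."""
        p = BisseParams(1, 0, 0, 0, 0, 0)
        out = branch_integrate(tip_init(0, 1.0), p, 1.0)
        assert out.d[0] == pytest.approx(math.exp(-1.0), rel=1e-6)
        assert out.d[1] == 0.0
        assert out.e[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_duration_is_identity(self, random_params):
        st = tip_init(1, 0.5)
        out = branch_integrate(st, random_params, 0.0)
        np.testing.assert_allclose(out.as_vector(), st.as_vector())

    def test_matches_fixed_step_rk4(self, random_params):
        st = tip_init(0, 0.8)
        out = branch_integrate(st, random_params, 2.0)
        ref = rk4_branch(st.as_vector(), random_params, 2.0, h=1e-4)
        np.testing.assert_allclose(out.as_vector(), ref, rtol=1e-6, atol=1e-12)

    def test_linearity_in_d(self, random_params):
        """D components scale linearly; E is unaffected by D magnitude."""
        st = tip_init(0, 1.0)
        scaled = tip_init(0, 1.0)
        scaled.d *= 1e-30
        a = branch_integrate(st, random_params, 3.0)
        b = branch_integrate(scaled, random_params, 3.0)
        np.testing.assert_allclose(b.d, a.d * 1e-30, rtol=1e-6)
        np.testing.assert_allclose(b.e, a.e, rtol=1e-7)

    def test_extinction_monotone_and_limits(self):
        p = BisseParams(0.3, 0.3, 0.2, 0.2, 0.02, 0.02)
        st = tip_init(0, 1.0)
        es = []
        for t in [1.0, 5.0, 20.0, 100.0, 400.0]:
            out = branch_integrate(st, p, t)
            es.append(out.e[0])
        assert all(b >= a - 1e-12 for a, b in zip(es, es[1:]))
        # with mu > 0 and f = 1, E approaches mu/lambda at long times
        assert es[-1] == pytest.approx(0.2 / 0.3, rel=1e-3)


class TestTipInit:
    def test_complete_sampling(self):
        st = tip_init(0, 1.0)
        np.testing.assert_allclose(st.d, [1.0, 0.0])
        np.testing.assert_allclose(st.e, [0.0, 0.0])

    def test_pacmad_sampling_fraction(self):
        st = tip_init(1, 0.2966)
        np.testing.assert_allclose(st.d, [0.0, 0.2966])
        np.testing.assert_allclose(st.e, [0.7034, 0.7034])

    def test_unknown_state_marginalizes(self):
        st = tip_init(None, 1.0)
        np.testing.assert_allclose(st.d, [1.0, 1.0])

    def test_invalid_f(self):
        with pytest.raises(ValueError):
            tip_init(0, 0.0)


class TestUnresolvedClade:
    def test_reduces_to_resolved_tip_when_richness_one(self):
        p = BisseParams(0.4, 0.2, 0.1, 0.05, 0.0, 0.0)
        u = unresolved_clade_init(1, (1, 0), 2.0, p)
        r = branch_integrate(tip_init(0, 1.0), p, 2.0)
        np.testing.assert_allclose(u.d, r.d, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(u.e, r.e, rtol=1e-6)

    @pytest.mark.parametrize("n,lam,t", [(1, 0.3, 2.0), (3, 0.3, 2.0), (8, 0.2, 5.0)])
    def test_yule_geometric_closed_form(self, n, lam, t):
        p = BisseParams(lam, lam, 0, 0, 0, 0)
        u = unresolved_clade_init(n, None, t, p)
        expect = math.exp(-lam * t) * (1 - math.exp(-lam * t)) ** (n - 1)
        assert u.d[0] == pytest.approx(expect, rel=1e-6)
        assert u.d[1] == pytest.approx(expect, rel=1e-6)

    def test_zero_duration_identity(self):
        p = BisseParams(0.3, 0.3, 0.1, 0.1, 0.01, 0.01)
        u = unresolved_clade_init(1, (0, 1), 0.0, p)
        np.testing.assert_allclose(u.d, [0.0, 1.0])
        np.testing.assert_allclose(u.e, [0.0, 0.0])

    def test_cap_exceeded_raises(self):
        p = BisseParams(0.5, 0.5, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(FloatingPointError, match="cap"):
            unresolved_clade_init(2, None, 30.0, p, cap=10)


class TestTreeLoglik:
    def test_cherry_analytic(self, cherry):
        tree, tips = cherry
        p = BisseParams(1, 0, 0, 0, 0, 0)
        lnl = tree_loglik(tree, tips, p, root_mode="given0")
        assert lnl == pytest.approx(-2.0, abs=1e-6)

    def test_matches_rk4_oracle_on_ten_tip_tree(self):
        tree, tips = simulate_bisse_tree(
            SimulationConfig(seed=81, params=DEFAULT_BISSE_PARAMS, target_tips=10)
        )
        states = {
            r.tip_label: int(r.state) for r in tips.table.itertuples()
        }
        p = BisseParams(0.35, 0.5, 0.1, 0.2, 0.06, 0.03)
        mine = tree_loglik(tree, tips, p)
        ref = rk4_tree_loglik(tree, states, p, f=1.0, h=1e-4)
        assert mine == pytest.approx(ref, rel=1e-6)

    def test_state_relabeling_symmetry(self, sim_tree_100, random_params):
        tree, tips = sim_tree_100
        swapped_states = {
            r.tip_label: 1 - int(r.state) for r in tips.table.itertuples()
        }
        tips_sw = TipData.from_dict(swapped_states, f=tips.f)
        a = tree_loglik(tree, tips, random_params)
        b = tree_loglik(tree, tips_sw, random_params.swapped())
        assert b == pytest.approx(a, abs=1e-8)

    def test_equal_rates_reduce_to_constant_rate_birth_death(self, sim_tree_50):
        """With both states sharing lambda and mu and the character
        ignored, the state-dependent likelihood equals the plain
        birth-death pruning density."""
        tree, _ = sim_tree_50
        tips = TipData.from_dict({l: None for l in tree.tip_labels})
        lam, mu = 0.3, 0.12
        p = BisseParams(lam, lam, mu, mu, 0.05, 0.02)
        lnl = tree_loglik(tree, tips, p)
        bd = backbone_loglik(
            tree, BDRegime(r=lam - mu, eps=mu / lam), condition_on_survival=False
        )
        assert lnl == pytest.approx(bd, rel=1e-6)

    def test_unresolved_mode_end_to_end(self, sim_tree_50):
        tree, tips = sim_tree_50
        t = tips.table.copy()
        td = TipData(t, sampling_mode="unresolved", f=1.0)
        p = DEFAULT_BISSE_PARAMS
        a = tree_loglik(tree, td, p, cap_extra=100, mass_tol=0.05)
        b = tree_loglik(tree, tips, p)
        # all richness 1: unresolved initialization reduces to resolved tips
        assert a == pytest.approx(b, rel=1e-5)

    def test_polytomy_rejected(self):
        tree = TimeTree.from_newick("((A:1,B:1,C:1):1,D:2);")
        tips = TipData.from_dict({l: 0 for l in tree.tip_labels})
        with pytest.raises(Exception, match="bifurcating"):
            tree_loglik(tree, tips, DEFAULT_BISSE_PARAMS)


class TestFitAndCompare:
    def test_full_model_never_below_nested(self, sim_tree_100):
        tree, tips = sim_tree_100
        lik = BisseLikelihood(tree, tips)
        f_eq = fit_model(tree, tips, "equal_diversification",
                         likelihood=lik, n_starts=2, seed=0)
        f_full = fit_model(tree, tips, "full", likelihood=lik, n_starts=2, seed=0)
        assert f_full.lnL >= f_eq.lnL - 1e-6
        assert f_eq.k == 4 and f_full.k == 6

    def test_lrt_arithmetic_from_published_likelihoods(self):
        """2 * (lnL_full - lnL_constrained) with df = 2 for the 4-vs-6
        parameter comparison; chi-squared tail gives the p-value."""
        spec4 = ModelSpec.preset("equal_diversification")
        spec6 = ModelSpec.preset("full")
        p = BisseParams(0.6, 0.6, 0.4, 0.4, 0.01, 0.0001)
        fa = BisseFit(spec4, p, lnL=-4803.4520, converged=True, n_starts=1, seed=0)
        fb = BisseFit(spec6, p, lnL=-4790.4060, converged=True, n_starts=1, seed=0)
        stat, df, pval = lrt(fa, fb)
        assert stat == pytest.approx(26.092, abs=1e-9)
        assert df == 2
        assert pval < 1e-5

    def test_identical_fits_give_stat_zero_p_one(self):
        spec4 = ModelSpec.preset("equal_diversification")
        spec6 = ModelSpec.preset("full")
        p = BisseParams(0.3, 0.3, 0.1, 0.1, 0.01, 0.01)
        fa = BisseFit(spec4, p, lnL=-100.0, converged=True, n_starts=1, seed=0)
        fb = BisseFit(spec6, p, lnL=-100.0, converged=True, n_starts=1, seed=0)
        stat, df, pval = lrt(fa, fb)
        assert stat == 0.0 and pval == 1.0

    def test_non_nested_pair_rejected(self):
        fa = BisseFit(ModelSpec.preset("equal_speciation"),
                      DEFAULT_BISSE_PARAMS, -10, True, 1, 0)
        fb = BisseFit(ModelSpec.preset("equal_extinction"),
                      DEFAULT_BISSE_PARAMS, -9, True, 1, 0)
        with pytest.raises(ValueError, match="nested"):
            lrt(fa, fb)

    def test_comparison_table_structure(self, sim_tree_100):
        tree, tips = sim_tree_100
        lik = BisseLikelihood(tree, tips)
        fits = [
            fit_model(tree, tips, name, likelihood=lik, n_starts=1, seed=0)
            for name in ("equal_diversification", "full")
        ]
        tab = compare_models(fits, n_obs=tree.n_tips)
        models = tab[tab.kind == "model"]
        lrts = tab[tab.kind == "lrt"]
        assert len(models) == 2 and len(lrts) == 1
        assert models.preferred.sum() == 1
        assert lrts.iloc[0]["df"] == 2

    def test_preset_nesting_relations(self):
        eqd = ModelSpec.preset("equal_diversification")
        eqs = ModelSpec.preset("equal_speciation")
        eqe = ModelSpec.preset("equal_extinction")
        full = ModelSpec.preset("full")
        assert eqd.nested_in(full) and eqs.nested_in(full) and eqe.nested_in(full)
        assert eqd.nested_in(eqs) and eqd.nested_in(eqe)
        assert not eqs.nested_in(eqe) and not eqe.nested_in(eqs)


class TestReplicates:
    def test_jittered_copies_give_clustered_rates(self, sim_tree_100):
        tree, tips = sim_tree_100
        trees = perturb_tree_set(tree, 5, 0.05, seed=3)
        res = replicate_analysis(
            trees, tips, specs=("equal_diversification", "full"),
            seed=0, n_starts=1,
        )
        assert len(res.fits) == 10  # 5 trees x 2 models
        full = res.fits[res.fits.model == "full"]
        assert full["r1"].std() < 0.1
        assert not res.failures
        hist = res.net_rate_histogram(bins=5)
        assert set(hist) == {"C3", "C4"}
        lh = res.lrt_histogram()
        assert set(lh["reference_lines"]) == {0.05, 0.01, 0.005}

    def test_single_tree_warns(self, sim_tree_50):
        tree, tips = sim_tree_50
        with pytest.warns(UserWarning, match="degenerate"):
            replicate_analysis([tree], tips, specs=("full",), n_starts=1)
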