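"""Penalized function-on-scalar regression: recovery, inference, prediction."""

import numpy as np
import pandas as pd
import pytest

from artikin.errors import ConfigurationError, ModelError
from artikin.fosr import FosrSpec, bspline_basis, difference_penalty, fit_fosr, predict_curves
from artikin.fosr import test_group_effect as group_effect_test
from artikin.prep import TrajectorySet

T, K = 40, 10
B = bspline_basis(T, K)


def _tset(curves):
    rows = []
    for (subj, grp, rep), y in curves.items():
        rows.append(
            pd.DataFrame({"subject": subj, "group": grp, "repetition": rep, "site": "LA",
                          "frame": np.arange(len(y)), "width_px": y})
        )
    return TrajectorySet(data=pd.concat(rows, ignore_index=True), t_star=T)


def _simulate(rng, effect=0.0, n_sub=4, n_rep=3, subj_sd=0.6, noise_sd=0.5):
    beta0 = 3.0 + 2.0 * np.sin(np.linspace(0, np.pi, T))
    bump = effect * np.exp(-0.5 * ((np.arange(T) - T / 2) / 3.0) ** 2)
    curves = {}
    for grp, x in (("FS", 0.0), ("AWS", 1.0)):
        for i in range(n_sub):
            b_i = B @ rng.normal(0, subj_sd, K)
            for rep in range(n_rep):
                curves[(f"{grp}{i}", grp, rep)] = (
                    beta0 + x * bump + b_i + rng.normal(0, noise_sd, T)
                )
    return _tset(curves)


@pytest.fixture(scope="module")
def strong_effect_fit():
    rng = np.random.default_rng(10)
    ts = _simulate(rng, effect=3.0, n_sub=8)
    return fit_fosr(ts, "LA", FosrSpec(n_basis=K))


class TestFitFosr:
    def test_noise_free_recovery_in_small_penalty_limit(self):
        """Exact data representable in the basis is recovered to float noise
        when the curve penalties vanish (and speaker curves are truly zero)."""
        rng = np.random.default_rng(0)
        beta0 = B @ rng.normal(0, 2, K)
        beta1 = B @ rng.normal(0, 1, K)
        curves = {}
        for grp, x in (("FS", 0.0), ("AWS", 1.0)):
            for i in range(3):
                for rep in range(2):
                    curves[(f"{grp}{i}", grp, rep)] = beta0 + x * beta1
        ts = _tset(curves)
        fit = fit_fosr(ts, "LA", FosrSpec(n_basis=K, fixed_lambdas=(1e-8, 1e-8, 1.0)))
        assert np.sqrt(np.mean((fit.basis @ fit.beta0 - beta0) ** 2)) < 1e-6
        assert np.sqrt(np.mean((fit.basis @ fit.beta1 - beta1) ** 2)) < 1e-6
        assert np.abs(fit.b).max() < 1e-6

    def test_bump_peak_location_recovered(self):
        """The fitted group-difference curve peaks within +-2 frames of the
        true bump over 20 replicates."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            ts = _simulate(rng, effect=3.0, n_sub=5)
            fit = fit_fosr(ts, "LA", FosrSpec(n_basis=K))
            peak = int(np.argmax(fit.basis @ fit.beta1))
            hits += abs(peak - T // 2) <= 2
        assert hits == 20

    def test_reference_swap_flips_group_curve_sign(self):
        """In the small-curve-penalty limit the fit is invariant to the choice
        of reference group up to the sign of the group-difference curve (with
        a finite difference penalty the invariance is only approximate, since
        the penalty is not preserved by the reparametrization beta0 + beta1)."""
        rng = np.random.default_rng(3)
        ts = _simulate(rng, effect=2.0)
        lam = (1e-8, 1e-8, 1.0)
        f1 = fit_fosr(ts, "LA", FosrSpec(n_basis=K, reference_group="FS",
                                         fixed_lambdas=lam))
        f2 = fit_fosr(ts, "LA", FosrSpec(n_basis=K, reference_group="AWS",
                                         fixed_lambdas=lam))
        assert np.allclose(f1.basis @ f1.beta1, -(f2.basis @ f2.beta1), atol=1e-6)
        assert np.allclose(
            f1.basis @ f1.beta0, f2.basis @ (f2.beta0 + f2.beta1), atol=1e-6
        )

    def test_huge_penalty_drives_group_coefficients_to_null_space(self):
        """lambda -> inf forces the group-curve coefficients into the
        second-difference null space (linear in coefficient index)."""
        rng = np.random.default_rng(4)
        ts = _simulate(rng, effect=3.0)
        fit = fit_fosr(ts, "LA", FosrSpec(n_basis=K, fixed_lambdas=(1.0, 1e9, 1.0)))
        d2 = np.diff(fit.beta1, n=2)
        assert np.abs(d2).max() < 1e-6 * max(np.abs(fit.beta1).max(), 1e-12)

    def test_edf_increases_with_true_effect_roughness(self):
        """REML assigns more effective degrees of freedom to rougher true
        group-difference curves."""
        edfs = []
        for n_bumps in (0, 1, 3):
            rng = np.random.default_rng(50)
            t = np.arange(T)
            shape = sum(
                np.exp(-0.5 * ((t - c) / 2.5) ** 2)
                for c in np.linspace(8, T - 8, n_bumps)
            ) if n_bumps else np.zeros(T)
            curves = {}
            for grp, x in (("FS", 0.0), ("AWS", 1.0)):
                for i in range(5):
                    b_i = B @ rng.normal(0, 0.3, K)
                    for rep in range(3):
                        curves[(f"{grp}{i}", grp, rep)] = (
                            3.0 + x * 3.0 * shape + b_i + rng.normal(0, 0.3, T)
                        )
            fit = fit_fosr(_tset(curves), "LA", FosrSpec(n_basis=K))
            edfs.append(fit.edf["beta1"])
        assert edfs[0] < edfs[1] < edfs[2]

    def test_single_group_rejected(self):
        curves = {(f"s{i}", "FS", r): np.ones(T) for i in range(4) for r in range(2)}
        with pytest.raises(ModelError):
            fit_fosr(_tset(curves), "LA", FosrSpec(n_basis=K))

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(5)
        ts = _simulate(rng)
        f1 = fit_fosr(ts, "LA", FosrSpec(n_basis=K))
        f2 = fit_fosr(ts, "LA", FosrSpec(n_basis=K))
        assert np.array_equal(f1.beta1, f2.beta1)
        assert f1.lambdas == f2.lambdas


class TestGroupEffectTest:
    def test_permutation_needs_enough_permutations(self, strong_effect_fit):
        with pytest.raises(ConfigurationError):
            group_effect_test(strong_effect_fit, "permutation", n_perm=10)

    def test_unknown_method_rejected(self, strong_effect_fit):
        with pytest.raises(ConfigurationError):
            group_effect_test(strong_effect_fit, "bootstrap")

    def test_strong_effect_detected_by_both_methods(self, strong_effect_fit):
        _, _, p_wald = group_effect_test(strong_effect_fit, "wald")
        _, _, p_perm = group_effect_test(strong_effect_fit, "permutation",
                                         n_perm=199, seed=1)
        assert p_wald < 0.01
        assert p_perm < 0.01

    def test_wald_and_permutation_agree_on_moderate_effect(self):
        """Order-of-magnitude agreement on a moderate-effect fixture where the
        permutation p is not floored."""
        rng = np.random.default_rng(21)
        ts = _simulate(rng, effect=0.6, n_sub=8)
        fit = fit_fosr(ts, "LA", FosrSpec(n_basis=K))
        _, _, p_wald = group_effect_test(fit, "wald")
        _, _, p_perm = group_effect_test(fit, "permutation", n_perm=999, seed=2)
        assert p_wald > 1e-4 and p_perm > 1e-3  # in the comparable regime
        assert abs(np.log10(p_wald) - np.log10(p_perm)) < 1.5

    def test_null_gives_unremarkable_p(self):
        rng = np.random.default_rng(30)
        ts = _simulate(rng, effect=0.0)
        fit = fit_fosr(ts, "LA", FosrSpec(n_basis=K))
        _, _, p = group_effect_test(fit, "permutation", n_perm=99, seed=3)
        assert p > 0.05


class TestPredictCurves:
    def test_zero_random_effects_make_subject_equal_group_predictions(self):
        rng = np.random.default_rng(6)
        beta0 = B @ rng.normal(0, 1, K)
        curves = {}
        for grp, x in (("FS", 0.0), ("AWS", 1.0)):
            for i in range(3):
                for rep in range(2):
                    curves[(f"{grp}{i}", grp, rep)] = beta0 + x * 2.0
        ts = _tset(curves)
        fit = fit_fosr(ts, "LA", FosrSpec(n_basis=K, fixed_lambdas=(1e-6, 1e-6, 1.0)))
        subj = predict_curves(fit, "subject")
        grp_tab = predict_curves(fit, "group")
        for grp in ("FS", "AWS"):
            g_curve = grp_tab[grp_tab.unit == grp].value.to_numpy()
            for unit in subj.unit.unique():
                if unit.startswith(grp):
                    s_curve = subj[subj.unit == unit].value.to_numpy()
                    assert np.allclose(s_curve, g_curve, atol=1e-5)

    def test_group_prediction_difference_is_group_curve(self, strong_effect_fit):
        tab = predict_curves(strong_effect_fit, "group")
        fs = tab[tab.unit == "FS"].value.to_numpy()
        aws = tab[tab.unit == "AWS"].value.to_numpy()
        assert np.allclose(aws - fs, strong_effect_fit.basis @ strong_effect_fit.beta1)

    def test_predictions_match_direct_basis_expansion(self, strong_effect_fit):
        fit = strong_effect_fit
        subj = predict_curves(fit, "subject")
        i = 2
        expected = fit.basis @ (
            fit.beta0
            + (fit.subject_groups[i] != "FS") * fit.beta1
            + fit.b[i]
        )
        got = subj[subj.unit == fit.subjects[i]].value.to_numpy()
        assert np.allclose(got, expected)

    def test_unknown_level_rejected(self, strong_effect_fit):
        with pytest.raises(ConfigurationError):
            predict_curves(strong_effect_fit, "cohort")


class TestBasisAndPenalty:
    def test_basis_partition_of_unity(self):
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_penalty_annihilates_linear_coefficients(self):
        P = difference_penalty(K, 2)
        lin = np.arange(K, dtype=float)
        assert np.allclose(P @ lin, 0.0)
        assert np.linalg.matrix_rank(P) == K - 2

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            FosrSpec(n_basis=4).resolve_n_basis(40)
        with pytest.raises(ConfigurationError):
            FosrSpec(n_basis=8, penalty_order=9).resolve_n_basis(40)
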