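"""Beta MLE, semiparametric mixture, skew classification and concordance."""

import numpy as np
import pytest
from scipy import stats

from xcisight.datamodel import AllelicObservation, Phase, VariantSite
from xcisight.estimators import (
    SkewClass,
    classify_skew,
    clamp_boundary,
    evaluate_concordance,
    fit_beta,
    sp_mixture_fit,
    xci_from_phased,
    xci_from_unphased,
)
from xcisight.simulator import run_ratio_panel, simulate_counts


def _obs(ratio, depth=50, pos=5_000_000, phase=Phase.UNPHASED):
    site = VariantSite(chrom="X", pos=pos, ref="A", alt="G", id="rs1")
    return AllelicObservation(site=site, ratio=ratio, depth=depth, phase=phase)


class TestClampBoundary:
    def test_interior_values_untouched(self):
        out = clamp_boundary([0.3, 0.7], [20, 20])
        assert list(out) == [0.3, 0.7]

    def test_boundaries_shrunk_by_half_read(self):
        out = clamp_boundary([0.0, 1.0], [10, 50])
        assert out[0] == pytest.approx(1 / 20)
        assert out[1] == pytest.approx(1 - 1 / 100)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            clamp_boundary([0.5], [0])


class TestFitBeta:
    @pytest.mark.parametrize("a,b", [(2.0, 2.0), (8.0, 2.0)])
    def test_parameter_recovery(self, a, b):
        rng = np.random.default_rng(42)
        x = rng.beta(a, b, size=2000)
        fit = fit_beta(x)
        assert fit.mean == pytest.approx(a / (a + b), abs=0.02)
        # shape parameters within a generous sampling envelope
        assert fit.alpha == pytest.approx(a, rel=0.2)
        assert fit.beta_param == pytest.approx(b, rel=0.2)

    def test_three_point_fit(self):
        fit = fit_beta([0.49, 0.50, 0.51])
        assert fit.mean == pytest.approx(0.50, abs=0.01)

    def test_matches_scipy_mle(self):
        # independent route: scipy's own constrained beta MLE
        rng = np.random.default_rng(7)
        x = rng.beta(5.0, 3.0, size=500)
        fit = fit_beta(x)
        a_sp, b_sp, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        assert fit.alpha == pytest.approx(a_sp, rel=1e-3)
        assert fit.beta_param == pytest.approx(b_sp, rel=1e-3)

    def test_identical_values_fall_back_with_warning(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_beta([0.4] * 10)
        assert fit.degenerate and fit.mean == pytest.approx(0.4)

    def test_boundary_values_rejected(self):
        with pytest.raises(ValueError, match="clamp"):
            fit_beta([0.0, 0.5, 0.9])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_beta([0.4, 0.6])


class TestXciFromPhased:
    def test_worked_sixty_five_thirty_five(self):
        rng = np.random.default_rng(0)
        mat = [_obs(r, phase=Phase.MATERNAL) for r in rng.beta(65, 35, 400)]
        pat = [_obs(r, phase=Phase.PATERNAL) for r in rng.beta(35, 65, 400)]
        est = xci_from_phased(mat, pat)
        assert est.maternal_pct == pytest.approx(65, abs=1.5)
        assert est.paternal_pct == pytest.approx(35, abs=1.5)
        assert est.method == "beta_phased"

    def test_complete_skew_with_clean_counts(self):
        obs = simulate_counts(800, 1.0, seed=0, ref_bias=0.0, cross_map_rate=0.0)
        mat = [o for o in obs if o.phase is Phase.MATERNAL]
        pat = [o for o in obs if o.phase is Phase.PATERNAL]
        est = xci_from_phased(mat, pat)
        assert est.maternal_pct == pytest.approx(100.0, abs=0.1)
        assert est.paternal_pct == pytest.approx(0.0, abs=0.1)

    def test_moderate_skew_within_sampling_error(self):
        obs = [o for o in simulate_counts(
            1600, 0.85, seed=1, ref_bias=0.0, cross_map_rate=0.0,
            depth_sampler=lambda rng, n: np.full(n, 50),
        )]
        mat = [o for o in obs if o.phase is Phase.MATERNAL]
        est = xci_from_phased(mat, [o for o in obs if o.phase is Phase.PATERNAL])
        se = 100 * np.std([o.ratio for o in mat]) / len(mat) ** 0.5
        assert abs(est.maternal_pct - 85.0) < 3 * se

    def test_swapping_groups_swaps_estimate(self):
        rng = np.random.default_rng(3)
        mat = [_obs(r, phase=Phase.MATERNAL) for r in rng.beta(8, 2, 200)]
        pat = [_obs(r, phase=Phase.PATERNAL) for r in rng.beta(2, 8, 200)]
        a = xci_from_phased(mat, pat)
        b = xci_from_phased(pat, mat)
        assert a.maternal_pct == pytest.approx(b.paternal_pct)
        assert a.paternal_pct == pytest.approx(b.maternal_pct)

    def test_one_sided_estimate_warns(self):
        mat = [_obs(0.8, phase=Phase.MATERNAL) for _ in range(5)]
        with pytest.warns(RuntimeWarning, match="one-sided"):
            est = xci_from_phased(mat, [])
        assert est.paternal_pct is None


class TestSpMixture:
    def test_gaussian_mixture_recovery(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.2, 0.05, 250), rng.normal(0.8, 0.05, 250)])
        fit = sp_mixture_fit(x, seed=3)
        assert fit.component_means[0] == pytest.approx(0.8, abs=0.02)
        assert fit.component_means[1] == pytest.approx(0.2, abs=0.02)
        assert fit.mixing_prop == pytest.approx(0.5, abs=0.05)

    def test_unimodal_data_collapses_components(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 0.03, 400)
        fit = sp_mixture_fit(x, seed=4)
        assert fit.component_means[0] == pytest.approx(0.5, abs=0.03)
        assert fit.component_means[1] == pytest.approx(0.5, abs=0.03)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0.3, 0.05, 100), rng.normal(0.7, 0.05, 100)])
        assert sp_mixture_fit(x, seed=11) == sp_mixture_fit(x, seed=11)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sp_mixture_fit([0.4, 0.5, 0.6])

    def test_estimated_mixing_recovers_unbalanced_weight(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0.25, 0.04, 300), rng.normal(0.75, 0.04, 100)])
        fit = sp_mixture_fit(x, seed=9, estimate_mixing=True)
        assert fit.component_means[0] == pytest.approx(0.75, abs=0.03)
        assert fit.mixing_prop == pytest.approx(0.25, abs=0.08)

    def test_agrees_with_phased_beta_on_same_data(self):
        obs = [o for o in simulate_counts(4000, 0.85, seed=6) if o.depth >= 20]
        est_beta = xci_from_phased(
            [o for o in obs if o.phase is Phase.MATERNAL],
            [o for o in obs if o.phase is Phase.PATERNAL],
        )
        est_sp = xci_from_unphased([o.ratio for o in obs], seed=7)
        assert est_sp.maternal_pct == pytest.approx(
            max(est_beta.maternal_pct, est_beta.paternal_pct), abs=2.0
        )


class TestClassifySkew:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (100.0, SkewClass.COMPLETE),
            (97.5, SkewClass.COMPLETE),
            (90.0, SkewClass.EXTREME),
            (87.5, SkewClass.EXTREME),
            (82.7, SkewClass.MODERATE),
            (77.5, SkewClass.MODERATE),
            (70.0, SkewClass.RANDOM),
            (50.0, SkewClass.RANDOM),
            (17.3, SkewClass.MODERATE),  # minor-percentage input folds over
        ],
    )
    def test_category_boundaries(self, pct, expected):
        assert classify_skew(pct) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_skew(120.0)


class TestConcordance:
    def test_perfect_recovery_has_unit_correlation(self):
        panel = run_ratio_panel(ratios=[0.9, 0.7, 0.5], n_snps=2500, seed=0,
                                ref_bias=0.0, cross_map_rate=0.0)
        table = evaluate_concordance(panel, min_depths=(20,))
        assert (table["r"] > 0.999).all()

    def test_shuffled_estimate_breaks_correlation(self):
        panel = run_ratio_panel(n_snps=1500, seed=1)
        # corrupt one dataset by relabeling it with the wrong expected ratio
        panel[0.95], panel[0.55] = panel[0.55], panel[0.95]
        table = evaluate_concordance(panel, min_depths=(20,))
        assert (table["r"] < 0.99).all()

    def test_too_few_datasets_rejected(self):
        panel = run_ratio_panel(ratios=[0.5, 0.9], n_snps=200, seed=0)
        with pytest.raises(ValueError):
            evaluate_concordance(panel)

    def test_major_estimate_monotone_in_truth(self):
        panel = run_ratio_panel(n_snps=3000, seed=2)
        majors = []
        for expected in sorted(panel):
            obs = [o for o in panel[expected] if o.depth >= 20]
            est = xci_from_phased(
                [o for o in obs if o.phase is Phase.MATERNAL],
                [o for o in obs if o.phase is Phase.PATERNAL],
            )
            majors.append(est.maternal_pct)
        assert majors == sorted(majors)
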