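"""Reference grids, BCL calls, rankings and dynamics classification."""

import numpy as np
import pandas as pd
import pytest

from mbdynamics.contrasts import (
    BCL_LEVELS,
    CONTRASTS,
    ContrastResult,
    bcl_significant,
    build_reference_grid,
    classify_dynamics,
    contrast_posterior,
    credible_interval,
    differential_ranking,
)
from mbdynamics.design_matrix import DesignSpec


def spec_with_freqs(records):
    return DesignSpec(
        term_names=[f"t{i}" for i in range(16)],
        focal_terms=[f"t{i}" for i in range(16)],
        focal_freqs=records,
        n_samples=100,
    )


FULL_FREQS = [
    {"pfs12": z, "combo": w1, "colitis": w2, "ppi": w3, "weight": 1 / 16}
    for z in (0, 1)
    for w1 in (0, 1)
    for w2 in (0, 1)
    for w3 in (0, 1)
]


class TestReferenceGrid:
    def test_fully_conditioned_contrast_picks_out_z_terms(self):
        """With every moderator fixed at 0, the case-minus-control weight
        difference isolates the PFS12 intercept and slope coefficients."""
        spec = spec_with_freqs(FULL_FREQS)
        case, ctrl = build_reference_grid(spec, "pfs12_mono")
        wi_case, ws_case = case.weight_vectors()
        wi_ctrl, _ = ctrl.weight_vectors()
        np.testing.assert_allclose(wi_case, [1, 1, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(wi_ctrl, [1, 0, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(ws_case, wi_case)

    def test_degenerate_weights_reduce_overall_to_conditioned(self):
        """When no sample has combo/colitis/PPI, the overall comparison
        equals the fully conditioned one."""
        degenerate = [
            {"pfs12": 0, "combo": 0, "colitis": 0, "ppi": 0, "weight": 0.5},
            {"pfs12": 1, "combo": 0, "colitis": 0, "ppi": 0, "weight": 0.5},
        ]
        spec = spec_with_freqs(degenerate)
        g_all = build_reference_grid(spec, "pfs12")
        g_cond = build_reference_grid(spec, "pfs12_mono")
        for a, b in zip(g_all, g_cond):
            np.testing.assert_allclose(a.weight_vectors()[0], b.weight_vectors()[0])

    def test_weights_sum_to_one(self):
        spec = spec_with_freqs(FULL_FREQS)
        for name in CONTRASTS:
            for grid in build_reference_grid(spec, name):
                assert grid.rows["weight"].sum() == pytest.approx(1.0)

    def test_empty_stratum_errors(self):
        no_colitis = [r for r in FULL_FREQS if r["colitis"] == 0]
        spec = spec_with_freqs(no_colitis)
        with pytest.raises(ValueError, match="stratum"):
            build_reference_grid(spec, "colitis")

    def test_unknown_contrast_errors(self):
        with pytest.raises(KeyError):
            build_reference_grid(spec_with_freqs(FULL_FREQS), "nope")


class TestBclSignificance:
    def test_quantile_rule_96_of_100_positive(self):
        draws = np.concatenate([np.linspace(0.1, 2, 96), [-0.5, -0.4, -0.3, -0.2]])
        assert bcl_significant(draws, 0.9)

    def test_both_signs_never_significant_at_100(self):
        draws = np.array([-1.0, 1.0, 2.0, 3.0])
        assert not bcl_significant(draws, 1.0)

    def test_all_positive_significant_at_100(self):
        assert bcl_significant(np.linspace(0.1, 1, 50), 1.0)

    def test_symmetric_not_significant_at_50(self):
        draws = np.concatenate([np.linspace(-1, -0.1, 50), np.linspace(0.1, 1, 50)])
        assert not bcl_significant(draws, 0.5)

    def test_intervals_nested(self, rng):
        draws = rng.normal(0.3, 1.0, 500)
        prev = (np.inf, -np.inf)
        for lv in BCL_LEVELS:
            lo, hi = credible_interval(draws, lv)
            assert lo <= prev[0] + 1e-12 and hi >= prev[1] - 1e-12
            prev = (lo, hi)


def _draws_clr_like(rng, S=200, D=6):
    """Synthetic clr-system coefficient draws with known focal effects."""
    from mbdynamics.bayes_lnm import PosteriorDraws

    lam = rng.normal(0, 0.02, size=(S, D, 16))
    lam -= lam.mean(axis=1, keepdims=True)
    return PosteriorDraws(Lambda=lam, Sigma=np.tile(np.eye(D - 1), (S, 1, 1)), system="clr")


class TestContrastPosterior:
    def test_requires_clr(self, rng):
        draws = _draws_clr_like(rng)
        draws.system = "alr"
        spec = spec_with_freqs(FULL_FREQS)
        grids = build_reference_grid(spec, "pfs12")
        with pytest.raises(ValueError, match="clr"):
            contrast_posterior(draws, grids, [f"f{i}" for i in range(6)])

    def test_delta_zero_is_intercept_difference(self, rng):
        draws = _draws_clr_like(rng)
        spec = spec_with_freqs(FULL_FREQS)
        grids = build_reference_grid(spec, "pfs12_mono")
        ct = contrast_posterior(draws, grids, [f"f{i}" for i in range(6)])
        np.testing.assert_array_equal(ct.delta_at(0), ct.delta_int)
        np.testing.assert_allclose(ct.delta_at(2), ct.delta_int + 2 * ct.delta_slope)

    def test_self_contrast_exactly_zero(self, rng):
        draws = _draws_clr_like(rng)
        spec = spec_with_freqs(FULL_FREQS)
        case, _ = build_reference_grid(spec, "pfs12")
        ct = contrast_posterior(draws, (case, case), [f"f{i}" for i in range(6)])
        np.testing.assert_array_equal(ct.delta_at(3), 0.0)

    def test_planted_positive_effect_significant_everywhere(self, rng):
        draws = _draws_clr_like(rng)
        draws.Lambda[:, 0, 2] += 1.0  # strong PFS12 intercept effect, feature 0
        spec = spec_with_freqs(FULL_FREQS)
        grids = build_reference_grid(spec, "pfs12_mono")
        ct = contrast_posterior(draws, grids, [f"f{i}" for i in range(6)])
        res = ct.result("f0")
        assert all(res.significant(t, lv) for t in range(4) for lv in BCL_LEVELS)


class TestDifferentialRanking:
    def test_order_and_tiebreak(self, rng):
        draws = _draws_clr_like(rng, D=4)
        draws.Lambda[:, 0, 2] += 0.5
        draws.Lambda[:, 1, 2] -= 0.2
        spec = spec_with_freqs(FULL_FREQS)
        grids = build_reference_grid(spec, "pfs12_mono")
        ct = contrast_posterior(draws, grids, ["a", "b", "c", "d"])
        ranked = differential_ranking(ct, visit=0)
        assert ranked.loc[0, "feature_id"] == "a"
        assert ranked.loc[3, "feature_id"] == "b"

    def test_shift_invariance(self, rng):
        """Adding a constant to all clr rows (a change of reference) leaves
        the contrast-based ranking untouched."""
        draws = _draws_clr_like(rng, D=5)
        draws.Lambda[:, 2, 2] += 0.4
        spec = spec_with_freqs(FULL_FREQS)
        grids = build_reference_grid(spec, "pfs12")
        fids = [f"f{i}" for i in range(5)]
        r1 = differential_ranking(contrast_posterior(draws, grids, fids), visit=3)
        shifted = _draws_clr_like(rng, D=5)
        shifted.Lambda = draws.Lambda + 0.7  # constant across features
        r2 = differential_ranking(contrast_posterior(shifted, grids, fids), visit=3)
        assert list(r1["feature_id"]) == list(r2["feature_id"])
        # the shift moves every feature's difference by the same constant
        gaps = r2["mean"].to_numpy() - r1["mean"].to_numpy()
        np.testing.assert_allclose(gaps, gaps[0], atol=1e-9)

    def test_monotone_flag_counts(self, small_fit):
        """Flagged-feature counts never increase with the BCL level."""
        ct = small_fit.contrast_tables["pfs12"]
        for visit in range(4):
            ranked = differential_ranking(ct, visit=visit)
            counts = [ranked[f"sig{lv:g}"].sum() for lv in BCL_LEVELS]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


def _result(delta_by_visit, slope_case=1.0, slope_ctrl=-1.0, spread=0.01):
    """ContrastResult with tight draws centered at the requested values."""
    rng = np.random.default_rng(0)
    S = 400
    delta = np.stack([v + spread * rng.standard_normal(S) for v in delta_by_visit])
    return ContrastResult(
        feature_id="f",
        delta_draws=delta,
        slope_diff_draws=delta[3] - delta[0],
        slope_case_draws=slope_case + spread * rng.standard_normal(S),
        slope_ctrl_draws=slope_ctrl + spread * rng.standard_normal(S),
    )


class TestClassifyDynamics:
    def test_stable_difference(self):
        assert classify_dynamics(_result([1, 1, 1, 1])).category == "stable-difference"

    def test_baseline_only(self):
        assert classify_dynamics(_result([1, 0, 0, 0])).category == "baseline-only"

    def test_emergent(self):
        assert classify_dynamics(_result([0, 0.5, 1, 1.5])).category == "emergent"

    def test_crossing(self):
        assert classify_dynamics(_result([-1, -0.3, 0.3, 1])).category == "crossing"

    def test_case_flat(self):
        res = _result([0, 0, 0, 0], slope_case=0.0, slope_ctrl=-1.0)
        assert classify_dynamics(res).category == "case-flat"

    def test_none_when_nothing_excludes_zero(self):
        res = _result([0, 0, 0, 0], slope_case=0.0, slope_ctrl=0.0, spread=1.0)
        assert classify_dynamics(res).category == "none"
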