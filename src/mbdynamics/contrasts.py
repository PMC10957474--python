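"""Post hoc contrasts, Bayesian-confidence-level calls and dynamics labels.

A contrast compares the expected clr abundance between two focal settings
("arms"), e.g. PFS >= 12 vs PFS < 12 months.  Each arm is a reference
grid: some of (Z, W1, W2, W3) are fixed while the remaining ones are
averaged over with their observed joint frequencies, yielding a marginal
mean.  Because peripheral covariates are mean-centered / weighted-sum
coded, arm differences involve only the 16 focal coefficients; per
posterior draw the difference at visit t is

    delta(t) = delta_intercept + t * delta_slope,   t in {0, 1, 2, 3}.

A feature is called differentially abundant at Bayesian confidence level
(BCL) p when the equal-tailed p-credible interval of delta(t) excludes
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes_lnm import PosteriorDraws
from .design_matrix import DesignSpec

__all__ = [
    "CONTRASTS",
    "BCL_LEVELS",
    "VISITS",
    "ReferenceGrid",
    "ContrastResult",
    "ContrastTable",
    "DynamicsLabel",
    "build_reference_grid",
    "contrast_posterior",
    "bcl_significant",
    "credible_interval",
    "differential_ranking",
    "classify_dynamics",
]

VISITS = (0, 1, 2, 3)
BCL_LEVELS = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0)

_FOCAL_VARS = ("pfs12", "combo", "colitis", "ppi")
# focal-block coefficient indices: intercept terms pair with slope terms
# (same covariate pattern, multiplied by visit)
_INT_IDX = [0, 2, 4, 6, 8, 10, 12, 14]
_SLOPE_IDX = [1, 3, 5, 7, 9, 11, 13, 15]

#: the seven case/control comparisons: fixed focal settings per arm;
#: variables not fixed are averaged with observed joint frequencies
CONTRASTS: dict[str, tuple[dict, dict]] = {
    "pfs12": ({"pfs12": 1}, {"pfs12": 0}),
    "colitis": ({"colitis": 1}, {"colitis": 0}),
    "pfs12_colitis_vs_not": ({"pfs12": 1, "colitis": 1}, {"pfs12": 1, "colitis": 0}),
    "combo_vs_mono_colitis": ({"combo": 1, "colitis": 1}, {"combo": 0, "colitis": 1}),
    "pfs12_mono": (
        {"pfs12": 1, "combo": 0, "colitis": 0, "ppi": 0},
        {"pfs12": 0, "combo": 0, "colitis": 0, "ppi": 0},
    ),
    "pfs12_combo": (
        {"pfs12": 1, "combo": 1, "colitis": 0, "ppi": 0},
        {"pfs12": 0, "combo": 1, "colitis": 0, "ppi": 0},
    ),
    "pfs12_ppi": (
        {"pfs12": 1, "combo": 0, "colitis": 0, "ppi": 1},
        {"pfs12": 0, "combo": 0, "colitis": 0, "ppi": 1},
    ),
}


@dataclass
class ReferenceGrid:
    """One contrast arm: fixed focal settings plus weighted rows for the
    averaged-over settings."""

    fixed: dict[str, int]
    rows: pd.DataFrame  # columns pfs12, combo, colitis, ppi, weight

    def weight_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(intercept, slope) 8-weight vectors over the focal coefficients,
        ordered [1, Z, W1, ZW1, W2, ZW2, W3, ZW3]."""
        z = self.rows["pfs12"].to_numpy(float)
        w1 = self.rows["combo"].to_numpy(float)
        w2 = self.rows["colitis"].to_numpy(float)
        w3 = self.rows["ppi"].to_numpy(float)
        wt = self.rows["weight"].to_numpy(float)
        design = np.column_stack([np.ones_like(z), z, w1, z * w1, w2, z * w2, w3, z * w3])
        w = wt @ design
        return w, w.copy()


def _focal_freq_frame(spec: DesignSpec) -> pd.DataFrame:
    return pd.DataFrame(spec.focal_freqs)


def build_reference_grid(spec: DesignSpec, contrast_name: str) -> tuple[ReferenceGrid, ReferenceGrid]:
    """Case and control reference grids for one of the named contrasts.

    Averaged-over variables receive their observed joint frequencies,
    marginalized over the fixed variables; both arms use the same weights.
    Raises if a fixed stratum has no observed samples.
    """
    if contrast_name not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast_name!r}; choose from {sorted(CONTRASTS)}")
    freqs = _focal_freq_frame(spec)
    case_fixed, ctrl_fixed = CONTRASTS[contrast_name]
    averaged = [v for v in _FOCAL_VARS if v not in case_fixed]

    grids = []
    for fixed in (case_fixed, ctrl_fixed):
        mask = np.ones(len(freqs), dtype=bool)
        for var, val in fixed.items():
            mask &= freqs[var] == val
        if not mask.any():
            raise ValueError(f"empty stratum: no samples with {fixed}")
        if averaged:
            marg = freqs.groupby(averaged, as_index=False)["weight"].sum()
        else:
            marg = pd.DataFrame({"weight": [1.0]})
        rows = marg.copy()
        for var, val in fixed.items():
            rows[var] = val
        rows["weight"] = rows["weight"] / rows["weight"].sum()
        grids.append(ReferenceGrid(fixed=dict(fixed), rows=rows[["pfs12", "combo", "colitis", "ppi", "weight"]]))
    return grids[0], grids[1]


def credible_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval by linear interpolation of order
    statistics; level 1.0 gives the full range of the draws."""
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    lo = (1 - level) / 2
    return (
        float(np.quantile(draws, lo, method="linear")),
        float(np.quantile(draws, 1 - lo, method="linear")),
    )


def bcl_significant(draws: np.ndarray, level: float) -> bool:
    """True when the equal-tailed ``level`` interval excludes zero."""
    lo, hi = credible_interval(draws, level)
    return bool(lo > 0 or hi < 0)


@dataclass
class ContrastResult:
    """Posterior of one feature's case-control difference across visits."""

    feature_id: str
    delta_draws: np.ndarray  # 4 x S, rows are visits 0..3
    slope_diff_draws: np.ndarray  # S
    slope_case_draws: np.ndarray  # S
    slope_ctrl_draws: np.ndarray  # S
    levels: tuple[float, ...] = BCL_LEVELS

    @property
    def mean(self) -> np.ndarray:
        return self.delta_draws.mean(axis=1)

    def interval(self, visit: int, level: float) -> tuple[float, float]:
        return credible_interval(self.delta_draws[visit], level)

    def significant(self, visit: int, level: float = 0.9) -> bool:
        return bcl_significant(self.delta_draws[visit], level)

    def bcl_flags(self, visit: int) -> dict[float, bool]:
        return {lv: self.significant(visit, lv) for lv in self.levels}


class ContrastTable:
    """All features' contrast posteriors for one case/control comparison."""

    def __init__(
        self,
        feature_ids: list[str],
        delta_int: np.ndarray,  # S x D
        delta_slope: np.ndarray,  # S x D
        slope_case: np.ndarray,  # S x D
        slope_ctrl: np.ndarray,  # S x D
        name: str = "",
    ) -> None:
        self.feature_ids = list(feature_ids)
        self.delta_int = delta_int
        self.delta_slope = delta_slope
        self.slope_case = slope_case
        self.slope_ctrl = slope_ctrl
        self.name = name

    def delta_at(self, t: int) -> np.ndarray:
        """S x D draws of the case-control difference at visit t."""
        return self.delta_int + t * self.delta_slope

    def result(self, feature_id: str) -> ContrastResult:
        try:
            j = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in contrast table") from None
        delta = np.stack([self.delta_at(t)[:, j] for t in VISITS])
        return ContrastResult(
            feature_id=feature_id,
            delta_draws=delta,
            slope_diff_draws=self.delta_slope[:, j],
            slope_case_draws=self.slope_case[:, j],
            slope_ctrl_draws=self.slope_ctrl[:, j],
        )

    def summarize(self, levels: tuple[float, ...] = BCL_LEVELS) -> pd.DataFrame:
        """Long-format per-feature, per-visit posterior summary with CI
        bounds and BCL flags at every level."""
        records = []
        for t in VISITS:
            d = self.delta_at(t)
            rec = {
                "feature_id": self.feature_ids,
                "visit": t,
                "mean": d.mean(axis=0),
                "slope_diff_mean": self.delta_slope.mean(axis=0),
            }
            for lv in levels:
                lo = np.quantile(d, (1 - lv) / 2, axis=0, method="linear")
                hi = np.quantile(d, 1 - (1 - lv) / 2, axis=0, method="linear")
                tag = f"{lv:g}"
                rec[f"ci{tag}_low"] = lo
                rec[f"ci{tag}_high"] = hi
                rec[f"sig{tag}"] = (lo > 0) | (hi < 0)
            records.append(pd.DataFrame(rec))
        return pd.concat(records, ignore_index=True)


def contrast_posterior(
    draws: PosteriorDraws,
    grid_pair: tuple[ReferenceGrid, ReferenceGrid],
    feature_ids: list[str],
    name: str = "",
) -> ContrastTable:
    """Project clr coefficient draws onto a case-control contrast.

    Requires clr-system draws so that the result is invariant to the alr
    reference used during fitting.
    """
    if draws.system != "clr":
        raise ValueError("contrast_posterior requires clr-system draws (use draws_to_clr)")
    D = draws.Lambda.shape[1]
    if len(feature_ids) != D:
        raise ValueError(f"{len(feature_ids)} feature IDs for {D} coefficient rows")
    case, ctrl = grid_pair
    wi_case, ws_case = case.weight_vectors()
    wi_ctrl, ws_ctrl = ctrl.weight_vectors()
    L_int = draws.Lambda[:, :, _INT_IDX]  # S x D x 8
    L_slope = draws.Lambda[:, :, _SLOPE_IDX]
    delta_int = L_int @ (wi_case - wi_ctrl)
    slope_case = L_slope @ ws_case
    slope_ctrl = L_slope @ ws_ctrl
    return ContrastTable(
        feature_ids=feature_ids,
        delta_int=delta_int,
        delta_slope=slope_case - slope_ctrl,
        slope_case=slope_case,
        slope_ctrl=slope_ctrl,
        name=name,
    )


def differential_ranking(table: ContrastTable, visit: int, levels=BCL_LEVELS) -> pd.DataFrame:
    """Features ranked by posterior mean difference at ``visit`` (descending;
    ties broken by feature ID), with BCL flags at every level.

    The ranking is invariant to the compositional reference: adding any
    constant to all clr coordinates cancels in case-control differences.
    """
    if visit not in VISITS:
        raise ValueError(f"visit must be one of {VISITS}")
    d = table.delta_at(visit)
    df = pd.DataFrame({"feature_id": table.feature_ids, "mean": d.mean(axis=0)})
    for lv in levels:
        lo = np.quantile(d, (1 - lv) / 2, axis=0, method="linear")
        hi = np.quantile(d, 1 - (1 - lv) / 2, axis=0, method="linear")
        df[f"sig{lv:g}"] = (lo > 0) | (hi < 0)
    df = df.sort_values(["mean", "feature_id"], ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


@dataclass
class DynamicsLabel:
    feature_id: str
    category: str
    significant_visits: tuple[int, ...]
    signs: tuple[int, ...]


def classify_dynamics(res: ContrastResult, level: float = 0.9) -> DynamicsLabel:
    """Qualitative trajectory class of a case-control difference.

    Rules, applied in order of precedence:

    - ``stable-difference``: significant with one sign at every visit;
    - ``baseline-only``: significant at visit 0 only;
    - ``emergent``: not significant at baseline, significant with a
      constant sign at one or more later visits;
    - ``crossing``: significant with opposite signs at visits 0 and 3;
    - ``case-flat`` / ``control-flat``: that arm's slope interval covers
      zero while the other arm's does not;
    - ``none`` otherwise.
    """
    sig = [res.significant(t, level) for t in VISITS]
    means = res.mean
    signs = tuple(int(np.sign(means[t])) for t in VISITS)
    sig_visits = tuple(t for t in VISITS if sig[t])

    def label(cat: str) -> DynamicsLabel:
        return DynamicsLabel(res.feature_id, cat, sig_visits, signs)

    if all(sig) and len({signs[t] for t in VISITS}) == 1:
        return label("stable-difference")
    if sig[0] and not any(sig[1:]):
        return label("baseline-only")
    later_signs = {signs[t] for t in VISITS[1:] if sig[t]}
    if not sig[0] and later_signs and len(later_signs) == 1:
        return label("emergent")
    if sig[0] and sig[3] and signs[0] != signs[3]:
        return label("crossing")
    case_flat = not bcl_significant(res.slope_case_draws, level)
    ctrl_flat = not bcl_significant(res.slope_ctrl_draws, level)
    if case_flat and not ctrl_flat:
        return label("case-flat")
    if ctrl_flat and not case_flat:
        return label("control-flat")
    return label("none")
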