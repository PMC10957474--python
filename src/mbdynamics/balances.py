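"""Log-ratio balances as per-sample biomarker scores.

A balance between two disjoint feature sets I+ and I- is the log ratio of
their geometric means,

    B = (1/k+) sum_{i in I+} log x_i  -  (1/k-) sum_{j in I-} log x_j,

(the 1/k normalization constant of the original definition is omitted, as
it only rescales the score).  B is invariant to sample renormalization and
to subsetting the table to any superset of I+ u I-, so it transfers to
cohorts profiled with different pipelines.  Discrimination of a binary
outcome is evaluated with a univariate logistic model and rank AUC, either
in-sample or by repeated stratified cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .classical_stats import auc_rank
from .io_profiles import AbundanceTable

__all__ = [
    "BalanceDef",
    "balance_score",
    "median_stratify",
    "cv_auc",
    "external_eval",
]


@dataclass
class BalanceDef:
    """Named pair of disjoint feature-ID sets."""

    plus_set: list[str]
    minus_set: list[str]
    name: str = "balance"

    def __post_init__(self) -> None:
        if not self.plus_set or not self.minus_set:
            raise ValueError("both balance sets must be non-empty")
        overlap = set(self.plus_set) & set(self.minus_set)
        if overlap:
            raise ValueError(f"balance sets overlap: {sorted(overlap)}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "plus_set": list(self.plus_set), "minus_set": list(self.minus_set)},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "BalanceDef":
        with open(path) as fh:
            d = json.load(fh)
        return cls(plus_set=d["plus_set"], minus_set=d["minus_set"], name=d.get("name", "balance"))


def balance_score(tab: AbundanceTable, bdef: BalanceDef, on_missing: str = "error") -> pd.Series:
    """Per-sample balance values (log units).

    ``on_missing='error'`` (strict) raises listing absent member features;
    ``'drop'`` removes them from the respective geometric mean with a
    warning, mirroring how balances are transferred to external cohorts
    where some member taxa were not detected.
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    present = set(tab.feature_ids)
    missing = [f for f in list(bdef.plus_set) + list(bdef.minus_set) if f not in present]
    plus = [f for f in bdef.plus_set if f in present]
    minus = [f for f in bdef.minus_set if f in present]
    if missing:
        if on_missing == "error":
            raise ValueError(f"balance features absent from table: {missing}")
        warnings.warn(
            f"balance {bdef.name!r}: dropping absent features {missing}", stacklevel=2
        )
    if not plus or not minus:
        raise ValueError("a balance side has no features present in the table")
    vals = tab.df
    if (vals.loc[plus + minus] <= 0).any().any():
        raise ValueError("balance members must have strictly positive (zero-replaced) abundances")
    logv = np.log(vals.loc[plus + minus])
    b = logv.loc[plus].mean(axis=0) - logv.loc[minus].mean(axis=0)
    b.name = bdef.name
    return b


def median_stratify(scores: pd.Series) -> pd.Series:
    """High/Low labels by the median: strictly above goes High, ties at
    the median go Low."""
    med = scores.median()
    return pd.Series(np.where(scores > med, "High", "Low"), index=scores.index, name="stratum")


def _one_repeat(scores, labels, folds, rng, max_redraws=20):
    """Pooled held-out probabilities for one CV repeat; re-draws the fold
    split (within the repeat) if a training fold lacks a class."""
    x = scores.reshape(-1, 1)
    for _ in range(max_redraws):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        pooled = np.empty_like(scores)
        ok = True
        for train, test in skf.split(x, labels):
            if len(np.unique(labels[train])) < 2:
                ok = False
                break
            model = LogisticRegression()
            model.fit(x[train], labels[train])
            pooled[test] = model.predict_proba(x[test])[:, 1]
        if ok:
            return pooled
    raise RuntimeError("could not draw a class-complete fold split")


def cv_auc(
    scores: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    repeats: int = 100,
    folds: int = 5,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Repeated stratified k-fold CV-AUC of a univariate logistic model.

    Per repeat: stratified ``folds``-fold split; the fold model is a
    logistic regression of the label on the balance score fit on the
    training folds; held-out probabilities are pooled across folds and one
    AUC computed per repeat.  Returns ``(mean, sd, per-repeat AUCs)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(repeats)
    for r in range(repeats):
        pooled = _one_repeat(scores, labels, folds, rng)
        aucs[r] = auc_rank(pooled, labels)
    return float(aucs.mean()), float(aucs.std(ddof=1)), aucs


def external_eval(
    tab: AbundanceTable,
    bdef: BalanceDef,
    labels: pd.Series,
    on_missing: str = "drop",
) -> tuple[float, pd.Series]:
    """Training AUC of the balance in an independent cohort.

    Fits the univariate logistic model on all samples and evaluates the
    AUC on those same samples (no held-out data); member features missing
    from the cohort are dropped from the geometric means by default.
    Returns ``(auc, per-sample scores)``.
    """
    scores = balance_score(tab, bdef, on_missing=on_missing)
    labels = pd.Series(labels).loc[scores.index].astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    model = LogisticRegression()
    model.fit(scores.to_numpy().reshape(-1, 1), labels.to_numpy())
    prob = model.predict_proba(scores.to_numpy().reshape(-1, 1))[:, 1]
    return auc_rank(prob, labels.to_numpy()), scores
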