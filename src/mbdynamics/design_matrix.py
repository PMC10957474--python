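"""Model-matrix construction for the longitudinal interaction model.

The focal block encodes expected log-ratio abundance as a linear function
of study visit X (0-3), the clinical outcome Z (PFS >= 12 months vs < 12),
and three binary treatment-context moderators W1 (combination therapy),
W2 (ICB-induced colitis) and W3 (concomitant PPI use):

    Y = b0 + b1 X + b2 Z + b3 XZ
      + b4 W1 + b5 XW1 + b6 ZW1 + b7 XZW1
      + b8 W2 + b9 XW2 + b10 ZW2 + b11 XZW2
      + b12 W3 + b13 XW3 + b14 ZW3 + b15 XZW3

Z and W1-3 are dummy coded (0 = reference: PFS < 12, monotherapy, no
colitis, no PPI).  Peripheral adjustment variables are appended below the
focal block: categorical ones (previous targeted therapy, center, other
irAEs, antibiotics, sex, patient identifier) use *weighted sum* contrasts,
whose columns have observation-weighted mean zero, and continuous ones
(age, BMI, days since first infusion) are mean-centered.  As a result the
intercept is the observation-weighted grand mean and post hoc contrasts
between focal settings involve only the 16 focal coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FOCAL_TERMS",
    "DesignSpec",
    "DesignMatrix",
    "encode_weighted_sum",
    "build_design",
    "term_index",
]

#: the 16 focal terms, in coefficient order b0..b15
FOCAL_TERMS = [
    "intercept",
    "visit",
    "pfs12",
    "visit:pfs12",
    "combo",
    "visit:combo",
    "pfs12:combo",
    "visit:pfs12:combo",
    "colitis",
    "visit:colitis",
    "pfs12:colitis",
    "visit:pfs12:colitis",
    "ppi",
    "visit:ppi",
    "pfs12:ppi",
    "visit:pfs12:ppi",
]

_BINARY_ONE = {
    "pfs12": {"1", ">=12", "≥12", "pfs>=12", "yes", "true"},
    "therapy": {"1", "combo", "combination", "yes", "true"},
    "colitis": {"1", "yes", "true"},
    "other_irae": {"1", "yes", "true"},
    "ppi": {"1", "yes", "true"},
    "antibiotics": {"1", "yes", "true"},
    "prior_targeted": {"1", "yes", "true"},
}

PERIPHERAL_CATEGORICAL = ["prior_targeted", "center", "other_irae", "antibiotics", "sex"]
PERIPHERAL_CONTINUOUS = ["age", "bmi", "days_since_first_infusion"]


def binary01(series: pd.Series, fieldname: str) -> np.ndarray:
    """Map a yes/no-style metadata column to 0/1."""
    ones = _BINARY_ONE[fieldname]
    vals = series.astype(str).str.strip().str.lower()
    return vals.isin(ones).to_numpy(dtype=float)


@dataclass
class DesignSpec:
    """Everything needed to rebuild contrasts from a fitted model on disk."""

    term_names: list[str]
    focal_terms: list[str]
    #: joint observed frequencies of the focal settings, one record per
    #: observed (pfs12, combo, colitis, ppi) combination with its weight
    focal_freqs: list[dict]
    n_samples: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "term_names": self.term_names,
                    "focal_terms": self.focal_terms,
                    "focal_freqs": self.focal_freqs,
                    "n_samples": self.n_samples,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "DesignSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["term_names"], d["focal_terms"], d["focal_freqs"], d["n_samples"])


@dataclass
class DesignMatrix:
    X: np.ndarray  # Q x N
    term_names: list[str]
    sample_ids: list[str]
    spec: DesignSpec

    @property
    def Q(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]


def encode_weighted_sum(levels, reference=None) -> tuple[np.ndarray, list[str], object]:
    """Weighted-sum contrast coding of a categorical vector.

    With k observed levels the coding has k-1 columns: level j (non
    reference) is coded 1 in its own column and 0 elsewhere; the reference
    level is coded ``-n_j / n_ref`` in column j.  Each column therefore has
    observation mean exactly zero, so the model intercept remains the
    observation-weighted grand mean.

    Returns ``(matrix of shape (n, k-1), column level names, reference)``.
    """
    levels = pd.Series(levels).astype(str)
    counts = levels.value_counts()
    uniq = sorted(counts.index)
    if len(uniq) < 2:
        raise ValueError("weighted-sum coding needs a factor with >= 2 observed levels")
    if reference is None:
        reference = uniq[-1]
    elif str(reference) not in uniq:
        raise ValueError(f"reference level {reference!r} not observed")
    reference = str(reference)
    others = [u for u in uniq if u != reference]
    n_ref = counts[reference]
    mat = np.zeros((len(levels), len(others)))
    for j, lev in enumerate(others):
        mat[:, j] = np.where(
            levels == lev, 1.0, np.where(levels == reference, -counts[lev] / n_ref, 0.0)
        )
    return mat, others, reference


def _focal_block(meta: pd.DataFrame) -> np.ndarray:
    x = meta["visit"].to_numpy(dtype=float)
    z = binary01(meta["pfs12"], "pfs12")
    w1 = binary01(meta["therapy"], "therapy")
    w2 = binary01(meta["colitis"], "colitis")
    w3 = binary01(meta["ppi"], "ppi")
    rows = [np.ones_like(x), x, z, x * z]
    for w in (w1, w2, w3):
        rows += [w, x * w, z * w, x * z * w]
    return np.vstack(rows)


def build_design(
    meta: pd.DataFrame,
    include_patient: bool = True,
    peripheral_categorical: list[str] | None = None,
    peripheral_continuous: list[str] | None = None,
) -> DesignMatrix:
    """Build the Q x N design matrix from per-sample metadata.

    Raises a ``ValueError`` naming the sample and field if any required
    value is missing.  A numerical rank below Q is tolerated (the model
    prior regularizes) but logged as a warning.
    """
    cats = PERIPHERAL_CATEGORICAL if peripheral_categorical is None else peripheral_categorical
    conts = PERIPHERAL_CONTINUOUS if peripheral_continuous is None else peripheral_continuous
    required = ["sample_id", "patient_id", "visit", "pfs12", "therapy", "colitis", "ppi"]
    required += cats + conts
    for col in required:
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
        isna = meta[col].isna()
        if isna.any():
            sid = meta.loc[isna, "sample_id"].iloc[0] if "sample_id" in meta else "?"
            raise ValueError(f"missing value for field {col!r} in sample {sid!r}")

    meta = meta.reset_index(drop=True)
    blocks = [_focal_block(meta)]
    names = list(FOCAL_TERMS)

    for col in cats:
        mat, levels, _ref = encode_weighted_sum(meta[col])
        blocks.append(mat.T)
        names += [f"{col}[{lev}]" for lev in levels]
    if include_patient:
        mat, levels, _ref = encode_weighted_sum(meta["patient_id"])
        blocks.append(mat.T)
        names += [f"patient_id[{lev}]" for lev in levels]
    for col in conts:
        v = meta[col].to_numpy(dtype=float)
        blocks.append((v - v.mean())[None, :])
        names.append(col)

    X = np.vstack(blocks)
    if len(set(names)) != len(names):
        raise ValueError("duplicate term names in design")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[0]:
        warnings.warn(
            f"design matrix numerically rank-deficient (rank {rank} < Q {X.shape[0]}); "
            "the coefficient prior regularizes",
            stacklevel=2,
        )

    combos = (
        pd.DataFrame(
            {
                "pfs12": binary01(meta["pfs12"], "pfs12").astype(int),
                "combo": binary01(meta["therapy"], "therapy").astype(int),
                "colitis": binary01(meta["colitis"], "colitis").astype(int),
                "ppi": binary01(meta["ppi"], "ppi").astype(int),
            }
        )
        .value_counts(normalize=True)
        .reset_index(name="weight")
    )
    spec = DesignSpec(
        term_names=names,
        focal_terms=list(FOCAL_TERMS),
        focal_freqs=combos.to_dict(orient="records"),
        n_samples=len(meta),
    )
    return DesignMatrix(X=X, term_names=names, sample_ids=list(meta["sample_id"].astype(str)), spec=spec)


def term_index(spec: DesignSpec | DesignMatrix, name: str) -> int:
    """Row index of a term; accepts ``beta0``..``beta15`` aliases for the
    focal block."""
    names = spec.term_names
    if name.startswith("beta"):
        k = int(name[4:])
        if not 0 <= k <= 15:
            raise KeyError(f"unknown focal alias {name!r}")
        name = FOCAL_TERMS[k]
    try:
        return names.index(name)
    except ValueError:
        raise KeyError(f"unknown term {name!r}") from None
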