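"""Synthetic longitudinal cohorts with planted ground truth.

The generator emulates the statistical structure of a multicenter
ICB-melanoma microbiome study: ~175 patients sampled at up to four visits
(baseline plus three on-treatment visits, 3-4 week cycles) with dropout
calibrated to the per-visit sample counts of the study design, covariate
frequencies matching the cohort table (33% combination therapy, 19%
colitis, 27% PPI use, 14% antibiotics, 47% reaching PFS >= 12 months),
and relative abundances drawn from the same logistic-normal regression
the pipeline fits, under a known (planted) focal coefficient matrix.

Effects are planted on the clr scale — which is reference-free — and
mapped into the alr system used for generation, so recovered clr
coefficients can be scored against the truth regardless of the fitting
reference.  Planted features fall into named trajectory categories
(stable difference, baseline-only, emergent, crossing) via their PFS12
main effect (b2) and PFS12-by-visit slope (b3).

An optional multinomial count layer and structural zeros are available;
both default to off, so the default generator matches the proportion-only
logistic-normal model exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comp_transforms import alr_inv, closure
from .design_matrix import build_design
from .io_profiles import AbundanceTable

__all__ = ["SimConfig", "SimOutput", "simulate_metadata", "simulate_abundances", "simulate_survival", "simulate_cohort", "write_fixture"]

#: per-visit sample counts the retention probabilities are calibrated to
#: (PFS>=12: 62/77/38/30, PFS<12: 74/69/34/24 out of 175 patients)
_VISIT_COUNTS = (136, 146, 72, 54)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_patients: int = 175
    visit_presence: tuple[float, ...] = tuple(c / 175 for c in _VISIT_COUNTS)
    # covariate frequencies (cohort-table values)
    p_pfs12: float = 83 / 175
    p_combo: float = 58 / 175
    p_colitis: float = 33 / 175
    p_ppi: float = 48 / 175
    p_antibiotics: float = 25 / 175
    p_prior_targeted: float = 41 / 175
    p_other_irae: float = 74 / 175
    p_female: float = 75 / 175
    center_counts: dict = field(
        default_factory=lambda: {"PRIMM-UK": 54, "PRIMM-NL": 74, "Manchester": 17, "Leeds": 19, "Barcelona": 11}
    )
    # feature space and planted effects (clr units)
    D: int = 60
    delta: float = 0.8
    n_stable_plus: int = 5
    n_stable_minus: int = 4
    n_baseline_only: int = 4
    n_emergent: int = 4
    n_crossing: int = 4
    # noise structure
    sigma_resid: float = 0.5
    resid_corr: float = 0.05
    patient_sd: float = 0.3
    peripheral_sd: float = 0.1
    # optional observation layers
    zero_rate: float = 0.0
    seq_depth: int | None = None
    # survival
    base_median: float = 34.1
    log_hr: float = 0.5
    censor_range: tuple[float, float] = (24.0, 88.0)
    seed: int = 0

    @classmethod
    def small(cls, **kwargs) -> "SimConfig":
        """Desk-scale config: fewer planted features, suitable for D >= 8."""
        defaults = dict(
            n_patients=60, D=20, n_stable_plus=2, n_stable_minus=2,
            n_baseline_only=1, n_emergent=1, n_crossing=1,
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class SimOutput:
    table: AbundanceTable
    meta: pd.DataFrame
    patients: pd.DataFrame
    survival: pd.DataFrame
    truth: dict


def _feature_ids(D: int) -> list[str]:
    phyla = ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria", "Verrucomicrobia"]
    ids = []
    for i in range(D):
        p = phyla[i % len(phyla)]
        ids.append(
            f"k__Bacteria|p__{p}|c__C{i % 7}|o__O{i % 11}|f__F{i % 13}"
            f"|g__G{i:04d}|s__Species_{i:04d}|t__SGB{i:05d}"
        )
    return ids


def simulate_metadata(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level covariates and the per-sample visit structure.

    Visit inclusion is independent per visit with probabilities calibrated
    to the study's per-visit sample counts; patients with no retained
    sample are dropped.  Days since first infusion follow 3-4 week cycles.
    """
    n = cfg.n_patients
    centers = list(cfg.center_counts)
    center_p = np.array(list(cfg.center_counts.values()), dtype=float)
    center_p /= center_p.sum()
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "pfs12": np.where(rng.random(n) < cfg.p_pfs12, ">=12", "<12"),
            "therapy": np.where(rng.random(n) < cfg.p_combo, "combo", "mono"),
            "colitis": np.where(rng.random(n) < cfg.p_colitis, "yes", "no"),
            "ppi": np.where(rng.random(n) < cfg.p_ppi, "yes", "no"),
            "antibiotics": np.where(rng.random(n) < cfg.p_antibiotics, "yes", "no"),
            "prior_targeted": np.where(rng.random(n) < cfg.p_prior_targeted, "yes", "no"),
            "other_irae": np.where(rng.random(n) < cfg.p_other_irae, "yes", "no"),
            "sex": np.where(rng.random(n) < cfg.p_female, "F", "M"),
            "center": rng.choice(centers, size=n, p=center_p),
            "age": np.clip(np.round(rng.normal(62, 13, n)), 19, 94),
            "bmi": np.clip(np.round(rng.normal(27.6, 4.5, n), 1), 15.4, 47.7),
        }
    )
    rows = []
    for _, pat in patients.iterrows():
        for v, p_v in enumerate(cfg.visit_presence):
            if rng.random() < p_v:
                days = 0 if v == 0 else int(21 * v + rng.integers(-3, 4))
                rows.append({"sample_id": f"{pat.patient_id}_T{v}", "visit": v, "days_since_first_infusion": days, **pat.to_dict()})
    meta = pd.DataFrame(rows)
    kept = meta["patient_id"].unique()
    patients = patients[patients["patient_id"].isin(kept)].reset_index(drop=True)
    cols = ["sample_id", "patient_id", "visit", "days_since_first_infusion"] + [
        c for c in patients.columns if c != "patient_id"
    ]
    return meta[cols].reset_index(drop=True), patients


def planted_lambda_clr(cfg: SimConfig) -> tuple[np.ndarray, dict[str, list[int]]]:
    """D x 16 focal coefficient matrix (clr scale) with planted categories.

    Categories use the PFS12 main effect (column 2) and the
    visit-by-PFS12 slope (column 3); the matrix is column-centered so the
    truth lies in the identifiable clr subspace.
    """
    D, d = cfg.D, cfg.delta
    lam = np.zeros((D, 16))
    idx = 0
    cats: dict[str, list[int]] = {}

    def take(k):
        nonlocal idx
        out = list(range(idx, idx + k))
        idx += k
        return out

    cats["stable_plus"] = take(cfg.n_stable_plus)
    cats["stable_minus"] = take(cfg.n_stable_minus)
    cats["baseline_only"] = take(cfg.n_baseline_only)
    cats["emergent"] = take(cfg.n_emergent)
    cats["crossing"] = take(cfg.n_crossing)
    if idx > D:
        raise ValueError("more planted features than D")
    lam[cats["stable_plus"], 2] = d
    lam[cats["stable_minus"], 2] = -d
    for j, f in enumerate(cats["baseline_only"]):
        s = 1 if j % 2 == 0 else -1
        lam[f, 2] = s * d
        lam[f, 3] = -s * d / 3  # difference closes by the last visit
    for j, f in enumerate(cats["emergent"]):
        s = 1 if j % 2 == 0 else -1
        lam[f, 3] = s * d / 3  # grows to +/- delta at visit 3
    for j, f in enumerate(cats["crossing"]):
        s = 1 if j % 2 == 0 else -1
        lam[f, 2] = -s * d
        lam[f, 3] = s * 2 * d / 3  # -delta at baseline, +delta at visit 3
    lam -= lam.mean(axis=0, keepdims=True)
    return lam, cats


def simulate_abundances(
    meta: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> tuple[AbundanceTable, dict]:
    """Logistic-normal abundance generation under the planted coefficients.

    eta ~ N(Lambda X, Sigma*) in the alr system with the last feature as
    reference; proportions are the inverse-alr (softmax) image.
    """
    design = build_design(meta)
    D = cfg.D
    lam_clr, cats = planted_lambda_clr(cfg)
    lam_alr_focal = lam_clr[:-1] - lam_clr[-1]  # clr -> alr (ref = last feature)

    Q = design.Q
    lam_alr = np.zeros((D - 1, Q))
    lam_alr[:, :16] = lam_alr_focal
    for q, name in enumerate(design.term_names):
        if q < 16:
            continue
        sd = cfg.patient_sd if name.startswith("patient_id[") else cfg.peripheral_sd
        lam_alr[:, q] = rng.normal(0.0, sd, D - 1)

    corr = (1 - cfg.resid_corr) * np.eye(D - 1) + cfg.resid_corr * np.ones((D - 1, D - 1))
    sigma = cfg.sigma_resid**2 * corr
    chol = np.linalg.cholesky(sigma)
    eta = lam_alr @ design.X + chol @ rng.standard_normal((D - 1, design.N))
    pi = alr_inv(eta, ref=-1)

    if cfg.seq_depth:
        counts = np.column_stack([rng.multinomial(cfg.seq_depth, pi[:, j]) for j in range(pi.shape[1])])
        pi = counts.astype(float)
    if cfg.zero_rate > 0:
        drop = rng.random(pi.shape) < cfg.zero_rate
        keep_top = pi.argmax(axis=0)  # never zero out a sample's dominant feature
        drop[keep_top, np.arange(pi.shape[1])] = False
        pi = np.where(drop, 0.0, pi)
    pi = closure(pi)

    fids = _feature_ids(D)
    tab = AbundanceTable(pd.DataFrame(pi, index=fids, columns=design.sample_ids), level="SGB")
    truth = {
        "Lambda_clr_focal": lam_clr,
        "Sigma_alr": sigma,
        "categories": {k: [fids[i] for i in v] for k, v in cats.items()},
        "balance_plus": [fids[i] for i in cats["stable_plus"]],
        "balance_minus": [fids[i] for i in cats["stable_minus"]],
        "term_names": design.term_names,
    }
    return tab, truth


def simulate_survival(
    patients: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    stratum: pd.Series | None = None,
) -> pd.DataFrame:
    """Exponential event times with hazard tied to a per-patient stratum.

    ``stratum`` is 0/1 per patient (1 = higher hazard, scaled by
    exp(log_hr)); omitted means no planted survival effect.  Times are
    administratively censored at a uniform per-patient horizon.
    """
    pids = patients["patient_id"].to_numpy()
    if stratum is None:
        s = np.zeros(len(pids))
    else:
        s = pd.Series(stratum).reindex(pids).to_numpy(dtype=float)
        if np.any(np.isnan(s)):
            raise ValueError("stratum missing for some patients")
    base_rate = np.log(2) / cfg.base_median
    rate = base_rate * np.exp(cfg.log_hr * s)
    t_event = rng.exponential(1.0 / rate)
    horizon = rng.uniform(*cfg.censor_range, size=len(pids))
    time = np.minimum(t_event, horizon)
    event = (t_event <= horizon).astype(int)
    return pd.DataFrame({"patient_id": pids, "time": np.round(time, 2), "event": event, "stratum": s.astype(int)})


def simulate_cohort(cfg: SimConfig | None = None) -> SimOutput:
    """End-to-end synthetic cohort; all randomness flows from cfg.seed."""
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_meta, rng_ab, rng_surv = (np.random.default_rng(s) for s in ss.spawn(3))
    meta, patients = simulate_metadata(cfg, rng_meta)
    tab, truth = simulate_abundances(meta, cfg, rng_ab)

    # survival stratum from the planted balance at baseline: patients below
    # the median balance get the higher hazard
    from .balances import BalanceDef, balance_score, median_stratify
    from .comp_transforms import zero_replace

    base_samples = meta.loc[meta["visit"] == 0, "sample_id"]
    if len(base_samples) >= 2 and truth["balance_plus"] and truth["balance_minus"]:
        bdef = BalanceDef(truth["balance_plus"], truth["balance_minus"], name="planted")
        base_vals = zero_replace(tab.df[base_samples].to_numpy(), 1e-6)
        base_tab = AbundanceTable(
            pd.DataFrame(base_vals, index=tab.feature_ids, columns=base_samples), tab.level
        )
        scores = balance_score(base_tab, bdef)
        strat = median_stratify(scores)
        pid_of = meta.set_index("sample_id")["patient_id"]
        stratum = pd.Series(
            (strat == "Low").astype(int).to_numpy(), index=pid_of.loc[strat.index]
        )
        stratum = stratum.reindex(patients["patient_id"]).fillna(0)
    else:
        stratum = None
    survival = simulate_survival(patients, cfg, rng_surv, stratum=stratum)
    return SimOutput(table=tab, meta=meta, patients=patients, survival=survival, truth=truth)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fixture(out: SimOutput, directory) -> dict[str, Path]:
    """Write the cohort as plain-text files: a MetaPhlAn-style merged
    profile TSV, metadata TSV, survival TSV and a truth-bundle JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "profile": directory / "profile_sgb.tsv",
        "metadata": directory / "metadata.tsv",
        "survival": directory / "survival.tsv",
        "truth": directory / "truth.json",
    }
    with open(paths["profile"], "w") as fh:
        fh.write("#mbdynamics synthetic merged profile\n")
        fh.write("clade_name\t" + "\t".join(out.table.sample_ids) + "\n")
        for fid, row in zip(out.table.feature_ids, out.table.values):
            fh.write(fid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
    out.meta.to_csv(paths["metadata"], sep="\t", index=False)
    out.survival.to_csv(paths["survival"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(_jsonable(out.truth), fh)
    return paths
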