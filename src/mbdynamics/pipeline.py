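"""End-to-end orchestration of the longitudinal analysis stages.

``run_longitudinal`` chains: prevalence filter -> renormalize -> zero
replacement -> alr transform -> design matrix -> conjugate fit ->
posterior draws (clr) -> post hoc contrasts, and writes rankings,
dynamics labels and a provenance manifest.  ``run_balance`` scores a
balance per visit, tests discrimination (Wilcoxon), evaluates repeated
cross-validated AUC and runs the balance-stratified and
continuous-score survival analyses.  All randomness flows from a single
seed recorded in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balances import BalanceDef, balance_score, cv_auc, median_stratify
from .bayes_lnm import (
    PosteriorDraws,
    PosteriorModel,
    default_prior,
    draws_to_clr,
    fit_conjugate,
    sample_posterior,
    save_draws,
)
from .classical_stats import wilcoxon_rank_sum
from .comp_transforms import alr, zero_replace
from .contrasts import (
    BCL_LEVELS,
    VISITS,
    ContrastTable,
    build_reference_grid,
    classify_dynamics,
    contrast_posterior,
    differential_ranking,
)
from .design_matrix import DesignMatrix, build_design
from .io_profiles import AbundanceTable, prevalence_filter, renormalize, write_results
from .survival import cox_fit, km_estimate, schoenfeld_trend

__all__ = ["LongitudinalResult", "run_longitudinal", "run_balance", "run_simulate"]

_SURV_ADJUST = ["age", "sex01", "bmi", "prior_targeted01", "ppi01", "antibiotics01", "colitis01", "other_irae01"]


@dataclass
class LongitudinalResult:
    table: AbundanceTable
    meta: pd.DataFrame
    design: DesignMatrix
    post: PosteriorModel
    draws_clr: PosteriorDraws
    feature_ids: list[str]
    contrast_tables: dict[str, ContrastTable]
    manifest: dict
    out_dir: Path | None = None


def _prepare_eta(tab: AbundanceTable, epsilon: float) -> tuple[np.ndarray, list[str]]:
    """Zero-replace, order features by mean abundance (most abundant last,
    the alr reference) and alr-transform."""
    order = tab.df.mean(axis=1).sort_values(kind="mergesort").index
    df = tab.df.loc[order]
    pos = zero_replace(df.to_numpy(), epsilon)
    return alr(pos, ref=-1), list(df.index)


def run_longitudinal(
    tab: AbundanceTable,
    meta: pd.DataFrame,
    S: int = 2000,
    seed: int = 0,
    epsilon: float = 1e-6,
    contrast_names: tuple[str, ...] = ("pfs12",),
    bcl_level: float = 0.9,
    prior=None,
    filter_first: bool = True,
    out_dir=None,
) -> LongitudinalResult:
    """Fit the longitudinal model and compute the requested contrasts.

    Samples missing from the metadata are excluded before modeling.  When
    ``out_dir`` is given, per-contrast summaries, last-visit rankings,
    dynamics labels, posterior draws, the design spec and a manifest are
    written there.
    """
    meta = meta[meta["sample_id"].isin(tab.sample_ids)].reset_index(drop=True)
    tab = AbundanceTable(tab.df[list(meta["sample_id"])], tab.level)
    n_raw = len(tab.feature_ids)
    if filter_first:
        tab = prevalence_filter(tab, meta)
    tab = renormalize(tab)

    eta, feature_ids = _prepare_eta(tab, epsilon)
    design = build_design(meta)
    D = len(feature_ids)
    if prior is None:
        prior = default_prior(D, design.Q)
    post = fit_conjugate(eta, design.X, prior, term_names=design.term_names)
    draws = sample_posterior(post, S=S, seed=seed)
    draws_clr = draws_to_clr(draws)

    tables: dict[str, ContrastTable] = {}
    for name in contrast_names:
        grids = build_reference_grid(design.spec, name)
        tables[name] = contrast_posterior(draws_clr, grids, feature_ids, name=name)

    manifest = {
        "version": __version__,
        "seed": seed,
        "S": S,
        "epsilon": epsilon,
        "n_samples": design.N,
        "n_features_input": n_raw,
        "n_features_retained": D,
        "Q": design.Q,
        "prior": {"nu": prior.nu, "gamma": "identity", "theta": "zero", "xi_scale": float(prior.Xi[0, 0])},
        "contrasts": list(contrast_names),
        "bcl_level": bcl_level,
    }

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        save_draws(draws_clr, out_path / "posterior_clr")
        design.spec.to_json(out_path / "design_spec.json")
        with open(out_path / "feature_ids.json", "w") as fh:
            json.dump(feature_ids, fh)
        for name, ct in tables.items():
            write_results(ct.summarize(), out_path / f"contrast_{name}.tsv")
            write_results(differential_ranking(ct, visit=3), out_path / f"ranking_{name}_T3.tsv")
            labels = [classify_dynamics(ct.result(f), level=bcl_level) for f in feature_ids]
            write_results(
                pd.DataFrame(
                    {
                        "feature_id": [l.feature_id for l in labels],
                        "category": [l.category for l in labels],
                        "significant_visits": [",".join(map(str, l.significant_visits)) for l in labels],
                    }
                ),
                out_path / f"dynamics_{name}.tsv",
            )
        with open(out_path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    return LongitudinalResult(
        table=tab,
        meta=meta,
        design=design,
        post=post,
        draws_clr=draws_clr,
        feature_ids=feature_ids,
        contrast_tables=tables,
        manifest=manifest,
        out_dir=out_path,
    )


def _surv_frame(meta: pd.DataFrame, survival: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Patient-level survival frame with baseline balance score and the
    standard adjustment covariates (binary ones recoded 0/1)."""
    from .design_matrix import binary01

    base = meta[meta["visit"] == 0].set_index("sample_id")
    pat = base.reset_index().set_index("patient_id")
    df = survival.set_index("patient_id").join(pat, how="inner", rsuffix="_m")
    score_by_patient = pd.Series(
        scores.reindex(base.index).to_numpy(), index=base["patient_id"].to_numpy()
    )
    df["balance"] = score_by_patient.reindex(df.index).to_numpy()
    df["sex01"] = (df["sex"].astype(str).str.upper() == "F").astype(float)
    for name in ("prior_targeted", "ppi", "antibiotics", "colitis", "other_irae"):
        df[f"{name}01"] = binary01(df[name], name)
    return df.dropna(subset=["balance", "time", "event"])


def run_balance(
    tab: AbundanceTable,
    meta: pd.DataFrame,
    bdef: BalanceDef,
    survival: pd.DataFrame | None = None,
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    epsilon: float = 1e-6,
    out_dir=None,
) -> dict:
    """Per-visit balance scores, Wilcoxon discrimination, CV-AUC and
    (optionally) balance-stratified and continuous-score Cox analyses."""
    from .design_matrix import binary01

    meta = meta[meta["sample_id"].isin(tab.sample_ids)].reset_index(drop=True)
    tab = renormalize(AbundanceTable(tab.df[list(meta["sample_id"])], tab.level))
    pos = AbundanceTable(
        pd.DataFrame(zero_replace(tab.values, epsilon), index=tab.feature_ids, columns=tab.sample_ids),
        tab.level,
    )
    scores = balance_score(pos, bdef, on_missing="drop")
    z = pd.Series(binary01(meta.set_index("sample_id")["pfs12"], "pfs12"), index=meta["sample_id"])

    per_visit = []
    rng = np.random.default_rng(seed)
    for t in VISITS:
        sids = meta.loc[meta["visit"] == t, "sample_id"]
        sc, lab = scores.loc[sids], z.loc[sids].astype(int)
        if lab.nunique() < 2:
            continue
        _, p = wilcoxon_rank_sum(sc[lab == 1], sc[lab == 0])
        mean_auc, sd_auc, _ = cv_auc(sc, lab, repeats=repeats, folds=folds, seed=int(rng.integers(2**31)))
        per_visit.append(
            {"visit": t, "n": len(sc), "wilcoxon_p": p, "cv_auc_mean": mean_auc, "cv_auc_sd": sd_auc}
        )
    metrics: dict = {"per_visit": pd.DataFrame(per_visit), "scores": scores}

    if survival is not None:
        base_meta = meta[meta["visit"] == 0]
        df = _surv_frame(meta, survival, scores)
        strat = median_stratify(df["balance"])
        df["low_balance"] = (strat == "Low").astype(float)
        covs = [c for c in _SURV_ADJUST if df[c].nunique() > 1]
        strat_fit, cph = cox_fit(df, ["low_balance"] + covs)
        cont_fit, _ = cox_fit(df, ["balance"] + covs)
        metrics["km"] = {
            "High": km_estimate(df.loc[df["low_balance"] == 0, "time"], df.loc[df["low_balance"] == 0, "event"]),
            "Low": km_estimate(df.loc[df["low_balance"] == 1, "time"], df.loc[df["low_balance"] == 1, "event"]),
        }
        metrics["cox_stratified"] = strat_fit
        metrics["cox_continuous"] = cont_fit
        metrics["schoenfeld"] = schoenfeld_trend(cph, df[["time", "event", "low_balance"] + covs])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(metrics["per_visit"], out / f"balance_{bdef.name}_metrics.tsv")
        scores.rename("balance").to_frame().reset_index(names="sample_id").to_csv(
            out / f"balance_{bdef.name}_scores.tsv", sep="\t", index=False
        )
        if survival is not None:
            write_results(metrics["cox_stratified"], out / f"balance_{bdef.name}_cox_stratified.tsv")
            write_results(metrics["cox_continuous"], out / f"balance_{bdef.name}_cox_continuous.tsv")
    return metrics


def run_simulate(cfg=None, out_dir=None):
    """Generate a synthetic cohort and (optionally) write it as a fixture."""
    from .simulate import SimConfig, simulate_cohort, write_fixture

    out = simulate_cohort(cfg or SimConfig())
    if out_dir is not None:
        write_fixture(out, out_dir)
    return out
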