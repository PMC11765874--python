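"""End-to-end orchestration of the explanatory-IRT analysis sequence.

Stage order: classical item statistics -> pooled Rasch calibration with the
full diagnostic battery (Andersen LR test, residual PCA, residual
correlations, variance explained) -> misfit flagging and, when configured,
a single-pass removal of flagged items followed by one re-fit -> item-level
DIF across groups (when a group variable is present) -> Q-matrix
construction -> LLTM feature decomposition -> Rasch/LLTM model comparison ->
group-wise LLTM -> feature-level DCF.  Misfit removal is deliberately one
pass (flag, remove, re-fit once); iterative purification is not performed.

Every stage's inputs are the declared outputs of the previous stage, and the
report records excluded items per stage, the stage timings, and provenance
(config hash, seed, package version).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ctt import cronbach_alpha, item_summaries
from .data_io import (
    AnalysisConfig,
    ItemFeatureTable,
    QMatrix,
    ResponseMatrix,
    build_qmatrix,
    write_result_table,
)
from .group_invariance import dcf_wald_test, dif_standardized_difference, groupwise_calibration
from .lltm import LLTMFit, compare_models, fit_lltm_cml
from .rasch import (
    RaschFit,
    andersen_lr_test,
    fit_rasch_cml,
    flag_misfit_items,
    residual_correlation_summary,
    residual_pca,
    variance_explained,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    """All result tables of a full analysis run, plus provenance."""

    ctt_table: pd.DataFrame
    cronbach_alpha: float
    rasch_fit: RaschFit
    rasch_table: pd.DataFrame
    person_table: pd.DataFrame
    global_fit: dict
    misfit_items: list
    removed_items: list
    refit: RaschFit | None
    dif_table: pd.DataFrame | None
    qmatrix: QMatrix
    lltm_fit: LLTMFit
    feature_table: pd.DataFrame
    difficulty_table: pd.DataFrame
    model_comparison: dict
    group_lltm: dict | None
    dcf_table: pd.DataFrame | None
    provenance: dict
    timings: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def df(d):
            return None if d is None else json.loads(d.to_json(orient="records"))

        return {
            "provenance": self.provenance,
            "timings": self.timings,
            "cronbach_alpha": self.cronbach_alpha,
            "ctt": df(self.ctt_table),
            "rasch_items": df(self.rasch_table),
            "global_fit": self.global_fit,
            "misfit_items": list(self.misfit_items),
            "removed_items": list(self.removed_items),
            "dif": df(self.dif_table),
            "qmatrix": df(self.qmatrix.to_dataframe()),
            "lltm_features": df(self.feature_table),
            "lltm_difficulties": df(self.difficulty_table),
            "model_comparison": self.model_comparison,
            "dcf": df(self.dcf_table),
        }

    def write(self, outdir: str | Path) -> None:
        """Write the CSV set plus one machine-readable JSON report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_result_table(self.ctt_table, outdir / "ctt.csv")
        write_result_table(self.rasch_table, outdir / "rasch_items.csv")
        write_result_table(self.person_table, outdir / "rasch_persons.csv")
        write_result_table(self.feature_table, outdir / "lltm_features.csv")
        write_result_table(self.difficulty_table, outdir / "lltm_difficulties.csv")
        if self.dif_table is not None:
            write_result_table(self.dif_table, outdir / "dif.csv")
        if self.dcf_table is not None:
            write_result_table(self.dcf_table, outdir / "dcf.csv")
        self.qmatrix.to_dataframe().to_csv(outdir / "qmatrix.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full_analysis(
    responses: ResponseMatrix,
    features: ItemFeatureTable,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Execute the complete analysis sequence and assemble the report."""
    config = config or AnalysisConfig()
    features.check_matches(responses)
    timings: dict = {}

    def stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage: %s", name)

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 4)

    # -- classical item statistics -----------------------------------------
    stage("ctt")
    try:
        ctt_table = item_summaries(responses)
        alpha = cronbach_alpha(responses)
    except ValueError as exc:
        raise RuntimeError(
            f"stage 'ctt' failed: {exc}; check that the matrix has >=2 persons/items with variance"
        ) from exc
    done("ctt")

    # -- pooled Rasch calibration and diagnostics ---------------------------
    stage("rasch")
    try:
        pooled = fit_rasch_cml(responses)
        lr = andersen_lr_test(responses)
        eig, unidim = residual_pca(pooled, config)
        rescorr = residual_correlation_summary(pooled)
        var_exp = variance_explained(pooled, responses)
    except (ValueError, RuntimeError) as exc:
        raise RuntimeError(
            f"stage 'rasch' failed: {exc}; check item variance and sample size"
        ) from exc
    global_fit = {
        "andersen_lr": {"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value},
        "pca_eigenvalues": eig.tolist(),
        "unidimensional": unidim,
        "residual_correlation": rescorr,
        "variance_explained": var_exp,
        "minus2ll": pooled.minus2ll,
        "excluded_items": list(pooled.excluded_items),
    }
    done("rasch")

    # -- misfit flagging and one-pass removal -------------------------------
    stage("misfit")
    misfit = sorted(flag_misfit_items(pooled, config))
    removed: list = []
    refit = None
    working = responses
    if misfit and config.remove_misfit_items:
        removed = misfit
        logger.info("removing misfit item(s) %s and re-fitting once", removed)
        working = responses.drop_items(removed)
        refit = fit_rasch_cml(working)
    analysis_fit = refit if refit is not None else pooled
    done("misfit")

    # -- DIF across groups ---------------------------------------------------
    dif_table = None
    if responses.group is not None:
        stage("dif")
        group_rasch = groupwise_calibration(working, model="rasch", config=config)
        (ref_label, ref_fit), (focal_label, focal_fit) = group_rasch.items()
        dif_table = dif_standardized_difference(ref_fit, focal_fit, config)
        dif_table.attrs["reference"] = ref_label
        dif_table.attrs["focal"] = focal_label
        done("dif")

    # -- Q-matrix and LLTM ---------------------------------------------------
    stage("lltm")
    retained_features = features.subset_items(working.item_ids)
    q = build_qmatrix(retained_features, config)
    try:
        lltm_fit = fit_lltm_cml(working, q)
    except (ValueError, RuntimeError) as exc:
        raise RuntimeError(
            f"stage 'lltm' failed: {exc}; check the Q-matrix column rank on the retained items"
        ) from exc
    comparison_fit = analysis_fit
    if lltm_fit.item_ids != comparison_fit.item_ids:
        # degenerate items dropped by either fit: align on the intersection
        shared = [i for i in comparison_fit.item_ids if i in lltm_fit.item_ids]
        comparison_fit = fit_rasch_cml(working.subset_items(shared))
        lltm_fit = fit_lltm_cml(working.subset_items(shared), q.subset_items(shared))
    comparison = compare_models(comparison_fit, lltm_fit)
    model_comparison = {
        "lr_statistic": comparison.lr_statistic,
        "df": comparison.df,
        "p_value": comparison.p_value,
        "pearson_r": comparison.pearson_r,
        "r_squared": comparison.r_squared,
        "concordant": comparison.concordant,
        "minus2ll_rasch": comparison_fit.minus2ll,
        "minus2ll_lltm": lltm_fit.minus2ll,
    }
    done("lltm")

    # -- group-wise LLTM and DCF --------------------------------------------
    group_lltm = None
    dcf_table = None
    if responses.group is not None:
        stage("dcf")
        group_lltm = groupwise_calibration(working, model="lltm", q=q, config=config)
        (ref_label, ref_lltm), (focal_label, focal_lltm) = group_lltm.items()
        dcf_table = dcf_wald_test(ref_lltm, focal_lltm, config)
        dcf_table.attrs["reference"] = ref_label
        dcf_table.attrs["focal"] = focal_label
        done("dcf")

    provenance = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_persons": responses.n_persons,
        "n_items": responses.n_items,
        "group_levels": responses.group_levels(),
    }
    return AnalysisReport(
        ctt_table=ctt_table,
        cronbach_alpha=alpha,
        rasch_fit=pooled,
        rasch_table=analysis_fit.item_table(),
        person_table=analysis_fit.person_table(),
        global_fit=global_fit,
        misfit_items=misfit,
        removed_items=removed,
        refit=refit,
        dif_table=dif_table,
        qmatrix=q,
        lltm_fit=lltm_fit,
        feature_table=lltm_fit.feature_table(),
        difficulty_table=lltm_fit.difficulty_table(),
        model_comparison=model_comparison,
        group_lltm=group_lltm,
        dcf_table=dcf_table,
        provenance=provenance,
        timings=timings,
    )
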