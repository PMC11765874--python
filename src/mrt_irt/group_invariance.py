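"""Measurement invariance across two groups: item-level DIF and feature-level DCF.

**Differential item functioning (DIF).**  The Rasch model is calibrated
independently in a reference and a focal group (each with its own sum-zero
normalization, so the scale alignment is approximate) and each item's
difficulty difference is standardized:

    z_i = (delta_ref,i - delta_focal,i) / sqrt(SE_ref,i^2 + SE_focal,i^2),

compared against the standard normal.  Positive z means the item is harder
for the reference group.  The raw logit difference is reported alongside;
differences beyond a configurable magnitude (default 0.5 logits) are
annotated as practically meaningful.

**Differential component functioning (DCF).**  The LLTM is calibrated per
group and each feature effect is compared with a Wald chi-square statistic,

    W_j = (eta_ref,j - eta_focal,j)^2 / (SE_ref,j^2 + SE_focal,j^2) ~ chi2(1),

judged at the Bonferroni-adjusted level alpha* = alpha / J for J simultaneous
feature comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AnalysisConfig, QMatrix, ResponseMatrix
from .lltm import LLTMFit, fit_lltm_cml
from .rasch import RaschFit, andersen_lr_test, fit_rasch_cml

logger = logging.getLogger(__name__)


def groupwise_calibration(
    responses: ResponseMatrix,
    model: str = "rasch",
    q: QMatrix | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Independent per-group calibrations on the shared estimable item set.

    Items that are degenerate (all correct / all wrong) in either group are
    excluded from both groups' comparison, with logging.  For ``model="lltm"``
    each group's Rasch fit is first checked with the Andersen LR test; a
    rejection is logged as a warning (the feature decomposition is then
    interpretable only with caution) but does not abort the analysis.
    """
    config = config or AnalysisConfig()
    if model not in ("rasch", "lltm"):
        raise ValueError("model must be 'rasch' or 'lltm'")
    if model == "lltm" and q is None:
        raise ValueError("LLTM calibration needs a Q-matrix")
    groups = responses.split_by_group(config.reference_group, config.focal_group)
    for label, sub in groups.items():
        if sub.n_persons < 10:
            logger.warning("group %r has only %d persons", label, sub.n_persons)
    # shared estimable item set: drop items degenerate in either group
    shared = list(responses.item_ids)
    for label, sub in groups.items():
        probe = fit_rasch_cml(sub)
        if probe.excluded_items:
            logger.info("group %r degenerate items: %s", label, probe.excluded_items)
        shared = [i for i in shared if i in probe.item_ids]
    if len(shared) < 2:
        raise ValueError("fewer than 2 items estimable in both groups")
    dropped = [i for i in responses.item_ids if i not in shared]
    if dropped:
        logger.warning("items excluded from group comparison: %s", dropped)
    fits = {}
    for label, sub in groups.items():
        sub_shared = sub.subset_items(shared)
        try:
            if model == "rasch":
                fits[label] = fit_rasch_cml(sub_shared)
            else:
                lr = andersen_lr_test(sub_shared)
                if lr.p_value < config.alpha:
                    logger.warning(
                        "group %r fails the Andersen LR test "
                        "(chi2(%d) = %.2f, p = %.3f); LLTM effects may be distorted",
                        label, lr.df, lr.statistic, lr.p_value,
                    )
                fits[label] = fit_lltm_cml(sub_shared, q.subset_items(shared))
        except Exception as exc:
            raise RuntimeError(f"estimation failed in group {label!r}: {exc}") from exc
    return fits


def standardized_difference(
    d_ref: float, se_ref: float, d_focal: float, se_focal: float
):
    """Standardized between-group difference and its two-sided normal p-value."""
    z = (d_ref - d_focal) / np.sqrt(se_ref**2 + se_focal**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def dif_standardized_difference(
    ref_fit: RaschFit,
    focal_fit: RaschFit,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-item DIF records from two group-wise Rasch calibrations.

    Returns one row per shared item with the group difficulties and SEs, the
    standardized difference z (reference minus focal) with its two-sided
    p-value, the raw logit difference, a significance flag at the configured
    alpha, a practical-magnitude annotation, and a "harder for" label
    resolving the sign convention.
    """
    config = config or AnalysisConfig()
    if ref_fit.item_ids != focal_fit.item_ids:
        raise ValueError("group fits do not share an item set")
    crit = stats.norm.ppf(1 - config.alpha / 2)
    rows = []
    for j, item in enumerate(ref_fit.item_ids):
        z, p = standardized_difference(
            ref_fit.delta[j], ref_fit.se_delta[j],
            focal_fit.delta[j], focal_fit.se_delta[j],
        )
        diff = float(ref_fit.delta[j] - focal_fit.delta[j])
        rows.append(
            {
                "item": item,
                "delta_ref": float(ref_fit.delta[j]),
                "se_ref": float(ref_fit.se_delta[j]),
                "delta_focal": float(focal_fit.delta[j]),
                "se_focal": float(focal_fit.se_delta[j]),
                "z": z,
                "p_value": p,
                "logit_diff": diff,
                "flagged": bool(abs(z) > crit),
                "meaningful_magnitude": bool(abs(diff) > config.logit_diff_flag),
                "harder_for": "reference" if diff > 0 else ("focal" if diff < 0 else "equal"),
            }
        )
    return pd.DataFrame(rows)


def wald_component_test(
    eta_ref: float, se_ref: float, eta_focal: float, se_focal: float
):
    """DCF Wald statistic for one feature: deviance, W ~ chi2(1) and p-value."""
    dev = eta_ref - eta_focal
    w = dev**2 / (se_ref**2 + se_focal**2)
    return float(dev), float(w), float(stats.chi2.sf(w, 1))


def dcf_wald_test(
    ref_lltm: LLTMFit,
    focal_lltm: LLTMFit,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-feature DCF records from two group-wise LLTM calibrations.

    The deviance in effect is reference minus focal; significance is judged
    at the Bonferroni-adjusted level alpha* = alpha / J.
    """
    config = config or AnalysisConfig()
    if ref_lltm.feature_names != focal_lltm.feature_names:
        raise ValueError("group LLTM fits use different Q-matrix columns")
    n_feat = len(ref_lltm.feature_names)
    alpha_star = config.alpha / n_feat
    rows = []
    for j, feat in enumerate(ref_lltm.feature_names):
        dev, w, p = wald_component_test(
            ref_lltm.eta[j], ref_lltm.se_eta[j],
            focal_lltm.eta[j], focal_lltm.se_eta[j],
        )
        rows.append(
            {
                "feature": feat,
                "eta_ref": float(ref_lltm.eta[j]),
                "se_ref": float(ref_lltm.se_eta[j]),
                "eta_focal": float(focal_lltm.eta[j]),
                "se_focal": float(focal_lltm.se_eta[j]),
                "deviance": dev,
                "wald_w": w,
                "p_value": p,
                "significant_bonferroni": bool(p < alpha_star),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha_star"] = alpha_star
    return out
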