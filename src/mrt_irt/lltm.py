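"""Linear logistic test model (LLTM): item difficulty decomposed into feature effects.

The LLTM keeps the Rasch response function but constrains each item's
difficulty to a linear combination of basic parameters,

    delta'_i = sum_j q_ij * eta_j,

where ``q_ij`` is the Q-matrix weight of feature ``j`` for item ``i`` and
``eta_j`` is that feature's difficulty contribution in logits.  There is no
intercept and no extra normalization: identification comes from the
structure itself (the model is estimable whenever the all-ones vector is not
in the Q-matrix column space).  Estimation re-uses the conditional-likelihood
engine of the Rasch module, with the chain rule through Q (the gradient in
eta-space is Q' times the gradient in difficulty space).

Because the LLTM is nested in the Rasch model, minus twice its conditional
log-likelihood can only be larger; the difference is a chi-square likelihood
ratio statistic on (k - 1) - J degrees of freedom, and the Pearson
correlation between unstructured and implied difficulties summarizes how
much of the difficulty variance the features capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import QMatrix, ResponseMatrix
from .rasch import RaschFit, _fit_cml, _screen_items

logger = logging.getLogger(__name__)

#: concordance threshold for the Rasch/LLTM difficulty R-squared
RSQUARED_CONCORDANCE = 0.76


@dataclass
class LLTMFit:
    """Feature effects eta with covariance and the implied item difficulties."""

    feature_names: list[str]
    eta: np.ndarray
    se_eta: np.ndarray
    cov_eta: np.ndarray
    item_ids: list[str]
    delta_lltm: np.ndarray
    se_delta: np.ndarray
    minus2ll: float
    n_iter: int
    n_persons_used: int
    excluded_items: list[str]

    def feature_table(self) -> pd.DataFrame:
        """Feature-effect calibration: eta, SE and 95% Wald interval."""
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "eta": self.eta,
                "se": self.se_eta,
                "ci_lower": self.eta - 1.96 * self.se_eta,
                "ci_upper": self.eta + 1.96 * self.se_eta,
            }
        )

    def difficulty_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.item_ids,
                "delta_lltm": self.delta_lltm,
                "se": self.se_delta,
                "ci_lower": self.delta_lltm - 1.96 * self.se_delta,
                "ci_upper": self.delta_lltm + 1.96 * self.se_delta,
            }
        )


@dataclass
class ModelComparison:
    """Likelihood-ratio and concordance comparison of Rasch vs LLTM."""

    lr_statistic: float
    df: int
    p_value: float
    pearson_r: float
    r_squared: float
    concordant: bool


def fit_lltm_cml(responses: ResponseMatrix, q: QMatrix) -> LLTMFit:
    """Estimate the feature effects eta by CML with delta = Q @ eta.

    The Q-matrix must have full column rank on the retained (non-degenerate)
    items; the covariance of eta is the inverse observed information and the
    implied difficulties carry delta-method standard errors
    SE(delta'_i) = sqrt(q_i' Cov(eta) q_i).
    """
    if q.item_ids != responses.item_ids:
        raise ValueError("Q-matrix items do not match response matrix items")
    keep, _ = _screen_items(responses.values)
    excluded = [i for i, kk in zip(responses.item_ids, keep) if not kk]
    if excluded:
        logger.warning("LLTM excluding degenerate item(s): %s", excluded)
    values = responses.values[:, keep]
    item_ids = [i for i, kk in zip(responses.item_ids, keep) if kk]
    qsub = q.subset_items(item_ids)
    w = qsub.weights.astype(float)
    rank = np.linalg.matrix_rank(w)
    if rank < w.shape[1]:
        raise ValueError(
            f"Q-matrix is rank-deficient on the retained items "
            f"(rank {rank} < {w.shape[1]} columns: {qsub.feature_names})"
        )
    res = _fit_cml(values, w)
    eta = res["x"]
    cov_eta = res["cov_x"]
    delta = w @ eta
    se_delta = np.sqrt(np.einsum("ij,jk,ik->i", w, cov_eta, w))
    return LLTMFit(
        feature_names=list(qsub.feature_names),
        eta=eta,
        se_eta=np.sqrt(np.diag(cov_eta)),
        cov_eta=cov_eta,
        item_ids=item_ids,
        delta_lltm=delta,
        se_delta=se_delta,
        minus2ll=-2.0 * res["ll"],
        n_iter=res["n_iter"],
        n_persons_used=res["n_persons_used"],
        excluded_items=excluded,
    )


def implied_difficulties(
    q: QMatrix, eta: np.ndarray, cov_eta: np.ndarray | None = None
) -> pd.DataFrame:
    """Item difficulties implied by feature effects: delta'_i = sum_j q_ij eta_j.

    With a covariance matrix the delta-method SE and 95% CI are attached.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (q.n_features,):
        raise ValueError("eta length does not match the Q-matrix columns")
    w = q.weights.astype(float)
    delta = w @ eta
    out = pd.DataFrame({"item": q.item_ids, "delta_lltm": delta})
    if cov_eta is not None:
        se = np.sqrt(np.einsum("ij,jk,ik->i", w, np.asarray(cov_eta, float), w))
        out["se"] = se
        out["ci_lower"] = delta - 1.96 * se
        out["ci_upper"] = delta + 1.96 * se
    return out


def implied_item_difficulties(fit: LLTMFit, q: QMatrix) -> pd.DataFrame:
    """Implied difficulties with SEs and CIs for the items of a fitted LLTM."""
    return implied_difficulties(q.subset_items(fit.item_ids), fit.eta, fit.cov_eta)


def likelihood_ratio_test(
    minus2ll_rasch: float, minus2ll_lltm: float, n_items: int, n_features: int
):
    """Nested LR test of the LLTM restriction against the unstructured Rasch model.

    Returns ``(statistic, df, p)`` with statistic = difference of the -2
    conditional log-likelihoods and df = (k - 1) - J.
    """
    lr = minus2ll_lltm - minus2ll_rasch
    df = (n_items - 1) - n_features
    p = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else np.nan
    return float(lr), int(df), p


def compare_models(rasch: RaschFit, lltm: LLTMFit) -> ModelComparison:
    """LR test plus the Rasch/LLTM difficulty concordance (Pearson r, R-squared)."""
    if rasch.item_ids != lltm.item_ids:
        raise ValueError(
            "Rasch and LLTM fits cover different item sets: "
            f"{rasch.item_ids} vs {lltm.item_ids}"
        )
    lr, df, p = likelihood_ratio_test(
        rasch.minus2ll, lltm.minus2ll, len(rasch.item_ids), len(lltm.feature_names)
    )
    if lr < -1e-6:
        raise RuntimeError(
            f"LLTM likelihood exceeds the Rasch likelihood (LR = {lr:.3g}); "
            "the fits are inconsistent"
        )
    r = float(np.corrcoef(rasch.delta, lltm.delta_lltm)[0, 1])
    return ModelComparison(
        lr_statistic=lr,
        df=df,
        p_value=p,
        pearson_r=r,
        r_squared=r * r,
        concordant=bool(r * r >= RSQUARED_CONCORDANCE),
    )
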