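"""Dichotomous Rasch calibration by conditional maximum likelihood (CML).

The Rasch model gives person ``n`` probability

    P(X_ni = 1) = exp(theta_n - delta_i) / (1 + exp(theta_n - delta_i))

of solving item ``i``.  CML estimates the item difficulties ``delta`` by
conditioning on each person's raw score, which eliminates the person
parameters: a person with raw score ``r`` over administered items has
conditional pattern probability

    prod_i eps_i^{x_i} / gamma_r(eps),    eps_i = exp(-delta_i),

where ``gamma_r`` is the elementary symmetric function (ESF) of order ``r``
of the item easiness values — the sum over all score-``r`` patterns of the
product of the solved items' easiness.  ESFs and their leave-one-out /
leave-two-out companions are computed by the summation recursion in log
space, which is stable for test lengths well beyond 50 items.

Estimation is Newton-Raphson with step-halving on the observed information,
under the sum-zero identification ``sum_i delta_i = 0``.  Persons with
extreme raw scores (0 or all correct) carry no conditional information and
are excluded from estimation but retained in the data; items answered all
correctly or all incorrectly by the remaining persons cannot be located on
the logit scale and are excluded with a logged warning.

The module also houses the fit-diagnostic suite: infit/outfit mean squares
with Wilson-Hilferty standardization, the Andersen likelihood-ratio test of
subgroup invariance, principal components of standardized residuals,
inter-item residual correlations, and an R-squared style variance-explained
summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AnalysisConfig, ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EsfTable",
    "RaschFit",
    "AndersenResult",
    "ConvergenceError",
    "esf",
    "fit_rasch_cml",
    "estimate_abilities",
    "fit_statistics",
    "andersen_lr_test",
    "residual_pca",
    "residual_correlation_summary",
    "variance_explained",
    "flag_misfit_items",
]


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails to reach the gradient tolerance."""


# ---------------------------------------------------------------------------
# elementary symmetric functions
# ---------------------------------------------------------------------------


@dataclass
class EsfTable:
    """ESF values gamma_r, r = 0..k, of a vector of item easiness parameters."""

    gamma: np.ndarray
    log_gamma: np.ndarray


def esf(epsilon: np.ndarray) -> EsfTable:
    """Elementary symmetric functions of positive easiness values.

    ``gamma[r]`` equals the sum over all response patterns with raw score
    ``r`` of the product of the easiness values of the solved items;
    ``gamma[0] = 1`` and ``gamma[k]`` is the product of all easiness values.
    """
    epsilon = np.asarray(epsilon, dtype=float)
    if epsilon.ndim != 1 or epsilon.size == 0:
        raise ValueError("epsilon must be a non-empty 1-D array")
    if (epsilon <= 0).any():
        raise ValueError("all easiness values must be strictly positive")
    lg = _log_esf(np.log(epsilon))
    return EsfTable(gamma=np.exp(lg), log_gamma=lg)


def _log_esf(beta: np.ndarray) -> np.ndarray:
    """log gamma_r for r = 0..m from log-easiness ``beta`` (summation recursion)."""
    m = beta.size
    lg = np.full(m + 1, -np.inf)
    lg[0] = 0.0
    for t in range(m):
        lg[1 : t + 2] = np.logaddexp(lg[1 : t + 2], lg[0 : t + 1] + beta[t])
    return lg


def _log_esf_loo(beta: np.ndarray) -> np.ndarray:
    """Leave-one-out log ESFs: row i holds orders 0..m-1 with item i removed."""
    m = beta.size
    lg = np.full((m, m), -np.inf)
    lg[:, 0] = 0.0
    idx = np.arange(m)
    for t in range(m):
        upd = np.logaddexp(lg[:, 1:], lg[:, :-1] + beta[t])
        rows = idx != t
        lg[rows, 1:] = upd[rows]
    return lg


def _log_esf_loo2(beta: np.ndarray) -> np.ndarray:
    """Leave-two-out log ESFs: entry (i, j) holds orders 0..m-2 without items i, j."""
    m = beta.size
    width = max(m - 1, 1)
    lg = np.full((m, m, width), -np.inf)
    lg[:, :, 0] = 0.0
    for t in range(m):
        upd = np.logaddexp(lg[:, :, 1:], lg[:, :, :-1] + beta[t])
        mask = np.ones((m, m), dtype=bool)
        mask[t, :] = False
        mask[:, t] = False
        lg[mask, 1:] = upd[mask]
    return lg


# ---------------------------------------------------------------------------
# conditional likelihood engine (shared with the LLTM module)
# ---------------------------------------------------------------------------


@dataclass
class _Pattern:
    cols: np.ndarray  # indices of administered items
    counts: np.ndarray  # person counts per raw score r = 0..m


@dataclass
class _CmlData:
    item_totals: np.ndarray  # correct counts per item over non-extreme persons
    patterns: list
    nonextreme: np.ndarray  # boolean over persons
    n_used: int


def _prepare_cml(values: np.ndarray) -> _CmlData:
    """Group non-extreme persons by administered-item pattern and raw score."""
    mask = ~np.isnan(values)
    m_admin = mask.sum(axis=1)
    r = np.nansum(values, axis=1)
    nonext = (m_admin > 0) & (r > 0) & (r < m_admin)
    k = values.shape[1]
    s = np.zeros(k)
    groups: dict = {}
    for n in np.flatnonzero(nonext):
        key = tuple(np.flatnonzero(mask[n]))
        entry = groups.setdefault(key, np.zeros(len(key) + 1, dtype=float))
        entry[int(r[n])] += 1
        s[list(key)] += values[n, list(key)]
    patterns = [_Pattern(np.array(key, dtype=int), counts) for key, counts in groups.items()]
    return _CmlData(s, patterns, nonext, int(nonext.sum()))


def _cml_ll(beta: np.ndarray, data: _CmlData) -> float:
    ll = float(data.item_totals @ beta)
    for pat in data.patterns:
        lg = _log_esf(beta[pat.cols])
        ll -= float(pat.counts @ lg)
    return ll


def _cml_ll_grad_info(beta: np.ndarray, data: _CmlData):
    """Conditional log-likelihood, gradient and observed information in beta."""
    k = beta.size
    ll = float(data.item_totals @ beta)
    grad = data.item_totals.copy()
    info = np.zeros((k, k))
    for pat in data.patterns:
        cols = pat.cols
        b = beta[cols]
        m = b.size
        lg = _log_esf(b)
        ll -= float(pat.counts @ lg)
        loo = _log_esf_loo(b)
        rr = np.arange(1, m)  # interior raw scores
        c = pat.counts[1:m]
        # conditional expectations pi[i, r] = E[x_i | raw score r]
        pi = np.exp(b[:, None] + loo[:, rr - 1] - lg[rr])
        grad[cols] -= pi @ c
        # pairwise expectations for the observed information
        pair = np.zeros((m, m))
        r2 = rr[rr >= 2]
        if r2.size:
            loo2 = _log_esf_loo2(b)
            ee = np.exp(
                b[:, None, None] + b[None, :, None] + loo2[:, :, r2 - 2] - lg[r2]
            )
            pair = ee @ pat.counts[r2]
        np.fill_diagonal(pair, pi @ c)
        cross = (pi * c) @ pi.T
        info[np.ix_(cols, cols)] += pair - cross
    return ll, grad, info


def _fit_cml(
    values: np.ndarray,
    design: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> dict:
    """Maximize the conditional likelihood with delta = design @ x.

    ``design`` is the k x p map from free parameters to item difficulties:
    the sum-zero contrast basis for an unstructured Rasch fit, or the
    Q-matrix for an LLTM fit.  Returns the estimate, covariance (inverse
    observed information, mapped through ``design``), and the maximized
    conditional log-likelihood.
    """
    data = _prepare_cml(values)
    if data.n_used == 0:
        raise ValueError("no persons with non-extreme raw scores")
    A = np.asarray(design, dtype=float)
    p = A.shape[1]
    x = np.zeros(p)
    ll, grad_b, info_b = _cml_ll_grad_info(-A @ x, data)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad_x = -A.T @ grad_b
        if np.max(np.abs(grad_x)) < tol:
            converged = True
            break
        info_x = A.T @ info_b @ A
        try:
            step = np.linalg.solve(info_x, grad_x)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix (collinear design columns?)"
            ) from exc
        lam = 1.0
        for _ in range(40):
            x_new = x + lam * step
            ll_new = _cml_ll(-A @ x_new, data)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        x, ll = x_new, ll_new
        ll, grad_b, info_b = _cml_ll_grad_info(-A @ x, data)
    grad_x = -A.T @ grad_b
    if not converged and np.max(np.abs(grad_x)) >= tol:
        raise ConvergenceError(
            f"CML did not converge in {max_iter} iterations "
            f"(max |gradient| = {np.max(np.abs(grad_x)):.3e})"
        )
    info_x = A.T @ info_b @ A
    cov_x = np.linalg.inv(info_x)
    delta = A @ x
    cov_delta = A @ cov_x @ A.T
    return {
        "x": x,
        "cov_x": cov_x,
        "delta": delta,
        "cov_delta": cov_delta,
        "ll": ll,
        "n_iter": it,
        "n_persons_used": data.n_used,
        "nonextreme": data.nonextreme,
    }


def _sum_zero_basis(k: int) -> np.ndarray:
    """k x (k-1) basis whose image is the sum-zero subspace (last delta = -sum)."""
    return np.vstack([np.eye(k - 1), -np.ones((1, k - 1))])


def _check_estimability(values: np.ndarray) -> None:
    """Require a finite CML maximum: the item comparison digraph (an edge
    i -> j whenever some person solved i but not j) must be strongly
    connected, else some difficulty contrasts diverge to +/- infinity."""
    from scipy.sparse.csgraph import connected_components

    k = values.shape[1]
    adj = np.zeros((k, k), dtype=bool)
    solved = values == 1.0
    failed = values == 0.0
    for i in range(k):
        adj[i] = (solved[:, [i]] & failed).any(axis=0)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        raise ValueError(
            "item difficulties are not finitely estimable: the item "
            "comparison graph is not strongly connected (quasi-separated data)"
        )


def _screen_items(values: np.ndarray):
    """Iteratively drop items without variance among non-extreme persons."""
    n, k = values.shape
    keep = np.ones(k, dtype=bool)
    while True:
        sub = values[:, keep]
        mask = ~np.isnan(sub)
        r = np.nansum(sub, axis=1)
        m = mask.sum(axis=1)
        nonext = (m > 0) & (r > 0) & (r < m)
        changed = False
        for j in np.flatnonzero(keep):
            col = values[nonext, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0 or np.all(obs == obs[0]):
                keep[j] = False
                changed = True
        if not changed:
            return keep, nonext


# ---------------------------------------------------------------------------
# Rasch fit
# ---------------------------------------------------------------------------


@dataclass
class RaschFit:
    """Result of a CML Rasch calibration (sum-zero item difficulties)."""

    item_ids: list[str]
    delta: np.ndarray
    se_delta: np.ndarray
    cov_delta: np.ndarray
    minus2ll: float
    n_iter: int
    person_ids: list[str]
    theta: np.ndarray
    se_theta: np.ndarray
    extreme_person: np.ndarray
    expected: np.ndarray  # persons x retained items, NaN where missing
    residuals: np.ndarray  # standardized residuals, same shape
    item_fit: pd.DataFrame = field(default=None)
    person_fit: pd.DataFrame = field(default=None)
    excluded_items: list[str] = field(default_factory=list)
    n_persons_used: int = 0

    def item_table(self) -> pd.DataFrame:
        """Item calibration table: difficulty, SE, 95% CI and fit statistics."""
        tab = pd.DataFrame(
            {
                "item": self.item_ids,
                "delta": self.delta,
                "se": self.se_delta,
                "ci_lower": self.delta - 1.96 * self.se_delta,
                "ci_upper": self.delta + 1.96 * self.se_delta,
            }
        )
        if self.item_fit is not None:
            tab = tab.merge(self.item_fit, on="item")
        return tab

    def person_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "person": self.person_ids,
                "theta": self.theta,
                "se_theta": self.se_theta,
                "extreme": self.extreme_person,
            }
        )
        if self.person_fit is not None:
            tab = tab.merge(self.person_fit, on="person")
        return tab


def fit_rasch_cml(responses: ResponseMatrix) -> RaschFit:
    """Calibrate item difficulties by CML under the sum-zero constraint.

    Items answered identically by every non-extreme person are excluded with
    a logged warning (their difficulty lies at +/- infinity); persons with
    extreme raw scores do not enter the conditional likelihood but receive
    ability proxies via the half-score adjustment.
    """
    if responses.n_items < 2:
        raise ValueError("need at least 2 items")
    keep, _ = _screen_items(responses.values)
    excluded = [i for i, kept in zip(responses.item_ids, keep) if not kept]
    if excluded:
        logger.warning("excluding degenerate item(s) without variance: %s", excluded)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 estimable items after exclusions")
    _check_estimability(responses.values[:, keep])
    values = responses.values[:, keep]
    item_ids = [i for i, kept in zip(responses.item_ids, keep) if kept]
    k = values.shape[1]
    res = _fit_cml(values, _sum_zero_basis(k))
    delta = res["delta"]
    se_delta = np.sqrt(np.diag(res["cov_delta"]))
    theta, se_theta, extreme = _ability_ml(values, delta)
    with np.errstate(over="ignore"):
        expected = _expit(theta[:, None] - delta[None, :])
    expected[np.isnan(values)] = np.nan
    w = expected * (1 - expected)
    residuals = (values - expected) / np.sqrt(w)
    fit = RaschFit(
        item_ids=item_ids,
        delta=delta,
        se_delta=se_delta,
        cov_delta=res["cov_delta"],
        minus2ll=-2.0 * res["ll"],
        n_iter=res["n_iter"],
        person_ids=list(responses.person_ids),
        theta=theta,
        se_theta=se_theta,
        extreme_person=extreme,
        expected=expected,
        residuals=residuals,
        excluded_items=excluded,
        n_persons_used=res["n_persons_used"],
    )
    fit.item_fit, fit.person_fit = fit_statistics(fit, responses)
    return fit


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _ability_ml(values: np.ndarray, delta: np.ndarray):
    """Person ML abilities given item difficulties.

    For non-extreme raw scores theta solves sum_i P(theta, delta_i) = r over
    the person's administered items.  Extreme scores get finite proxies via
    the half-score adjustment (0 -> 0.3, m -> m - 0.3) and are flagged.
    """
    n = values.shape[0]
    theta = np.full(n, np.nan)
    se = np.full(n, np.nan)
    extreme = np.zeros(n, dtype=bool)
    mask = ~np.isnan(values)
    cache: dict = {}
    for i in range(n):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0:
            extreme[i] = True
            continue
        r = float(values[i, cols].sum())
        m = cols.size
        if r == 0.0:
            r, extreme[i] = 0.3, True
        elif r == m:
            r, extreme[i] = m - 0.3, True
        key = (tuple(cols), r)
        if key not in cache:
            cache[key] = _solve_theta(delta[cols], r)
        theta[i], se[i] = cache[key]
    return theta, se, extreme


def _solve_theta(d: np.ndarray, target: float, max_iter: int = 100):
    m = d.size
    t = np.log(target / (m - target)) + float(d.mean())
    for _ in range(max_iter):
        p = _expit(t - d)
        w = float(np.sum(p * (1 - p)))
        f = float(p.sum()) - target
        if abs(f) < 1e-10:
            break
        t -= f / max(w, 1e-12)
    w = float(np.sum(p * (1 - p)))
    return t, 1.0 / np.sqrt(max(w, 1e-12))


def estimate_abilities(fit: RaschFit, responses: ResponseMatrix) -> np.ndarray:
    """ML person abilities for ``responses`` given the fitted difficulties."""
    sub = responses.subset_items(fit.item_ids)
    theta, _, _ = _ability_ml(sub.values, fit.delta)
    return theta


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def fit_statistics(fit: RaschFit, responses: ResponseMatrix):
    """Infit/outfit mean squares and Wilson-Hilferty standardized z.

    Outfit is the unweighted mean of squared standardized residuals; infit is
    the information-weighted version sum (x - P)^2 / sum P(1 - P).  The
    standardized forms transform the mean square through the Wilson-Hilferty
    cube root with its model variance.  Item statistics aggregate over
    non-extreme persons; person statistics aggregate over each person's
    administered items.
    """
    sub = responses.subset_items(fit.item_ids)
    x = sub.values
    p = fit.expected
    w = p * (1 - p)
    c = w * (1 - 3 * w)  # Bernoulli fourth central moment
    sq = (x - p) ** 2
    z2 = sq / w
    nonext = ~fit.extreme_person

    item_rows = []
    for j, item in enumerate(fit.item_ids):
        use = nonext & ~np.isnan(x[:, j])
        item_rows.append(
            {"item": item, **_msq_pair(sq[use, j], z2[use, j], w[use, j], c[use, j])}
        )
    person_rows = []
    for i, person in enumerate(fit.person_ids):
        use = ~np.isnan(x[i])
        stats_i = (
            _msq_pair(sq[i, use], z2[i, use], w[i, use], c[i, use])
            if use.any()
            else dict.fromkeys(
                ["outfit_msq", "infit_msq", "outfit_z", "infit_z"], np.nan
            )
        )
        person_rows.append({"person": person, "extreme": bool(fit.extreme_person[i]), **stats_i})
    return pd.DataFrame(item_rows), pd.DataFrame(person_rows)


def _msq_pair(sq, z2, w, c) -> dict:
    n = sq.size
    if n == 0 or w.sum() <= 0:
        return dict.fromkeys(["outfit_msq", "infit_msq", "outfit_z", "infit_z"], np.nan)
    outfit = float(z2.mean())
    infit = float(sq.sum() / w.sum())
    var_out = float(np.sum(c / w**2) / n**2 - 1.0 / n)
    var_in = float(np.sum(c - w**2) / w.sum() ** 2)
    return {
        "outfit_msq": outfit,
        "infit_msq": infit,
        "outfit_z": _wilson_hilferty(outfit, var_out),
        "infit_z": _wilson_hilferty(infit, var_in),
    }


def _wilson_hilferty(msq: float, variance: float) -> float:
    if not np.isfinite(variance) or variance <= 0:
        return np.nan
    q = np.sqrt(variance)
    return float((msq ** (1.0 / 3.0) - 1.0) * 3.0 / q + q / 3.0)


def flag_misfit_items(fit: RaschFit, config: AnalysisConfig | None = None) -> set:
    """Items whose |standardized infit z| or |outfit z| reaches the threshold."""
    config = config or AnalysisConfig()
    thr = config.misfit_z_threshold
    tab = fit.item_fit
    bad = tab[(tab["outfit_z"].abs() >= thr) | (tab["infit_z"].abs() >= thr)]
    return set(bad["item"])


# ---------------------------------------------------------------------------
# global model fit
# ---------------------------------------------------------------------------


@dataclass
class AndersenResult:
    statistic: float
    df: int
    p_value: float
    subgroup_sizes: dict
    subgroup_items: dict


def andersen_lr_test(responses: ResponseMatrix, split: str | np.ndarray = "median") -> AndersenResult:
    """Andersen's conditional likelihood-ratio test of subgroup invariance.

    The sample is split (by default at the median raw score) and the model is
    recalibrated within each subgroup; under the Rasch model the item
    difficulties are invariant, so

        LR = 2 * (sum_g cll_g - cll_pooled)  ~  chi-square

    with degrees of freedom equal to the subgroup parameter count minus the
    pooled parameter count, both from the items actually estimated.
    """
    labels = _split_labels(responses, split)
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("split criterion produced fewer than 2 subgroups")
    pooled = fit_rasch_cml(responses)
    stat = pooled.minus2ll
    df = -(len(pooled.item_ids) - 1)
    sizes, items = {}, {}
    for lev in levels:
        sub = responses.subset_persons(np.array([l == lev for l in labels]))
        try:
            fit_g = fit_rasch_cml(sub)
        except ValueError as exc:
            raise ValueError(f"subgroup {lev!r} has no estimable items: {exc}") from exc
        stat -= fit_g.minus2ll
        df += len(fit_g.item_ids) - 1
        sizes[lev] = sub.n_persons
        items[lev] = len(fit_g.item_ids)
        if fit_g.excluded_items:
            logger.info("Andersen subgroup %r excluded items %s", lev, fit_g.excluded_items)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else np.nan
    return AndersenResult(float(stat), int(df), p, sizes, items)


def _split_labels(responses: ResponseMatrix, split) -> list:
    if isinstance(split, str):
        if split not in ("median", "mean"):
            raise ValueError("split must be 'median', 'mean' or explicit labels")
        r = responses.raw_scores()
        cut = float(np.median(r)) if split == "median" else float(np.mean(r))
        return ["low" if v <= cut else "high" for v in r]
    labels = list(split)
    if len(labels) != responses.n_persons:
        raise ValueError("explicit split labels must align with persons")
    return labels


def _residual_matrix(fit: RaschFit):
    """Complete-row standardized residuals over non-extreme persons."""
    res = fit.residuals[~fit.extreme_person]
    complete = ~np.isnan(res).any(axis=1)
    res = res[complete]
    keep = res.std(axis=0) > 0
    dropped = [i for i, k in zip(fit.item_ids, keep) if not k]
    if dropped:
        logger.warning("dropping constant residual column(s) %s", dropped)
    return res[:, keep], [i for i, k in zip(fit.item_ids, keep) if k]


def residual_pca(fit: RaschFit, config: AnalysisConfig | None = None):
    """Eigenvalues (descending) of the item correlation matrix of residuals.

    A largest eigenvalue below the configured threshold (default 2.0) is
    taken as evidence that the responses are sufficiently unidimensional.
    """
    config = config or AnalysisConfig()
    res, items = _residual_matrix(fit)
    if len(items) < 3:
        raise ValueError("residual PCA needs at least 3 items with variance")
    corr = np.corrcoef(res, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    return eig, bool(eig[0] < config.pca_eigen_threshold)


def residual_correlation_summary(fit: RaschFit) -> dict:
    """Mean and SD of the off-diagonal inter-item residual correlations."""
    res, items = _residual_matrix(fit)
    if len(items) < 2:
        raise ValueError("need at least 2 items with residual variance")
    corr = np.corrcoef(res, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    vals = corr[iu]
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}


def variance_explained(fit: RaschFit, responses: ResponseMatrix) -> float:
    """Proportion of raw response variation captured by the model probabilities.

    Computed as 1 - sum (x - P)^2 / sum (x - xbar)^2 over all non-missing
    cells, with xbar the grand mean; the R-squared of the fitted
    probabilities against the observed 0/1 responses.
    """
    sub = responses.subset_items(fit.item_ids)
    x = sub.values
    obs = ~np.isnan(x)
    xv = x[obs]
    pv = fit.expected[obs]
    ss_tot = float(np.sum((xv - xv.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("responses have no variance")
    return float(1.0 - np.sum((xv - pv) ** 2) / ss_tot)
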