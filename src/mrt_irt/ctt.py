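"""Classical test theory summaries: item difficulty, discrimination, reliability.

Before any latent-trait modelling, the response matrix is screened with the
classical indices: per-item proportion correct, sample standard deviation,
the corrected item-total correlation (correlation of an item with the total
score of the *other* items, so the item never correlates with itself), and
Cronbach's alpha for internal consistency,

    alpha = k/(k-1) * (1 - sum_i var_i / var_total),

with sample (n-1) variances.  Alpha is computed on complete cases; the
number of dropped persons is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import ResponseMatrix

logger = logging.getLogger(__name__)


def item_summaries(responses: ResponseMatrix) -> pd.DataFrame:
    """Per-item proportion correct, sample SD and corrected item-total correlation.

    Proportions and SDs use all non-missing responses to the item.  The
    corrected item-total correlation is the Pearson correlation between the
    item scores and the rest-score (sum over the person's other administered
    items).  Items without variance get a missing correlation with a logged
    warning.
    """
    if responses.n_persons < 2 or responses.n_items < 2:
        raise ValueError("need at least 2 persons and 2 items")
    x = responses.values
    rows = []
    totals = np.nansum(x, axis=1)
    for j, item in enumerate(responses.item_ids):
        col = x[:, j]
        obs = ~np.isnan(col)
        p = float(np.mean(col[obs]))
        sd = float(np.std(col[obs], ddof=1)) if obs.sum() > 1 else np.nan
        rest = totals[obs] - col[obs]
        if np.std(col[obs]) == 0.0 or np.std(rest) == 0.0:
            logger.warning("item %s has zero variance; item-total correlation undefined", item)
            r = np.nan
        else:
            r = float(np.corrcoef(col[obs], rest)[0, 1])
        rows.append({"item": item, "p_correct": p, "sd": sd, "r_item_total": r})
    return pd.DataFrame(rows)


def cronbach_alpha(responses: ResponseMatrix) -> float:
    """Cronbach's alpha over complete cases (persons with no missing response)."""
    if responses.n_items < 2:
        raise ValueError("alpha needs at least 2 items")
    complete = responses.mask.all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("alpha computed on complete cases; dropped %d person(s)", dropped)
    x = responses.values[complete]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 complete cases")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
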