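"""Synthetic dichotomous response data with the structure the analysis assumes.

Responses are generated from the logistic Rasch/LLTM response function:
person abilities are drawn from a normal distribution, item difficulties are
built as Q @ eta (optionally with group-specific eta vectors, which plants
differential component functioning) plus optional per-item, per-group
additive logit shifts (which plants differential item functioning), and
responses are independent Bernoulli draws with probability
expit(theta - delta).  Equal eta vectors and zero shifts define the null
design used by the type-I-error calibration tests.

The module also packages the published 15-item mental-rotation instrument's
feature coding: the 15 x 6 binary Q-matrix over (Ncubes, Color, Image
structure, Occlusion, Rotation, Configuration) and the calibrated feature
effect vector eta = (3.65, 2.45, -0.59, -0.62, 1.50, -1.07) logits, which
together define the fixture difficulties delta = Q @ eta used throughout
the test-suite simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import FEATURE_ORDER, QMATRIX_COLUMNS, ItemFeatureTable, QMatrix

__all__ = [
    "SimulationDesign",
    "simulate_responses",
    "mrt_fixture",
    "mrt_feature_table",
    "MRT_ETA",
]

# 15 x 6 feature assignment of the mental-rotation instrument
# columns: Ncubes, Color, Image structure, Occlusion, Rotation, Configuration
_MRT_Q = np.array(
    [
        [0, 0, 0, 0, 0, 1],
        [1, 0, 1, 1, 1, 1],
        [1, 0, 1, 1, 0, 0],
        [1, 0, 1, 0, 0, 0],
        [0, 0, 0, 1, 0, 0],
        [1, 0, 0, 0, 0, 0],
        [1, 0, 0, 0, 1, 1],
        [1, 0, 1, 0, 1, 0],
        [1, 0, 1, 0, 1, 1],
        [1, 0, 0, 1, 0, 0],
        [0, 1, 0, 0, 0, 1],
        [0, 1, 1, 0, 1, 1],
        [0, 1, 1, 0, 1, 0],
        [0, 1, 1, 0, 1, 0],
        [0, 1, 0, 0, 1, 0],
    ],
    dtype=int,
)

#: calibrated feature effects (logits) of the 15-item instrument
MRT_ETA = np.array([3.65, 2.45, -0.59, -0.62, 1.50, -1.07])

_MRT_ITEM_IDS = [str(i) for i in range(1, 16)]

# Synthetic per-item cube counts: the published coding reports only the mean
# (8.6) and the dichotomized column; these integers reproduce both exactly.
_MRT_NCUBES = {
    "1": 6, "2": 10, "3": 11, "4": 10, "5": 7, "6": 11, "7": 10, "8": 11,
    "9": 10, "10": 11, "11": 6, "12": 7, "13": 6, "14": 7, "15": 6,
}


def mrt_fixture():
    """The packaged 15-item instrument: (QMatrix, eta vector, item ids)."""
    q = QMatrix(_MRT_Q.copy(), list(QMATRIX_COLUMNS), list(_MRT_ITEM_IDS))
    return q, MRT_ETA.copy(), list(_MRT_ITEM_IDS)


def mrt_feature_table() -> ItemFeatureTable:
    """Item feature table whose Q-matrix build reproduces the packaged fixture.

    The five binary characteristics are the instrument's published coding;
    the raw cube counts are synthetic integers constructed to have mean
    exactly 8.6 and to dichotomize (strictly greater than the mean) to the
    published Ncubes column.
    """
    df = pd.DataFrame(_MRT_Q, columns=FEATURE_ORDER)
    df.insert(0, "item_id", _MRT_ITEM_IDS)
    df["ncubes"] = [_MRT_NCUBES[i] for i in _MRT_ITEM_IDS]
    return ItemFeatureTable(df)


@dataclass
class SimulationDesign:
    """Generating configuration for synthetic dichotomous responses.

    ``n_persons`` is either a pooled count or a ``{group_label: count}``
    mapping; ``eta`` correspondingly one vector or one per group (equal
    vectors mean no DCF).  ``dif_shifts`` optionally adds per-item logit
    shifts per group after the Q @ eta construction, so DIF can be planted
    with or without DCF.  ``theta_mean=None`` centres abilities on the mean
    generated item difficulty (persons targeted to the instrument), which is
    how an "N(0, 1) ability" population relates to an uncentred Q @ eta
    difficulty scale.
    """

    q: QMatrix
    eta: np.ndarray | dict
    n_persons: int | dict = 500
    theta_mean: float | None = None
    theta_sd: float = 1.0
    dif_shifts: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        groups = self.group_labels()
        for g in groups:
            eta = self.eta_for(g)
            if np.asarray(eta).shape != (self.q.n_features,):
                raise ValueError("eta length does not match the Q-matrix columns")
            shift = self.shift_for(g)
            if shift.shape != (len(self.q.item_ids),):
                raise ValueError("dif_shifts length does not match the items")

    def group_labels(self) -> list:
        if isinstance(self.n_persons, dict):
            return list(self.n_persons)
        return [None]

    def eta_for(self, group) -> np.ndarray:
        if isinstance(self.eta, dict):
            return np.asarray(self.eta[group], dtype=float)
        return np.asarray(self.eta, dtype=float)

    def shift_for(self, group) -> np.ndarray:
        if self.dif_shifts is None:
            return np.zeros(len(self.q.item_ids))
        if isinstance(self.dif_shifts, dict):
            return np.asarray(self.dif_shifts.get(group, np.zeros(len(self.q.item_ids))), dtype=float)
        return np.asarray(self.dif_shifts, dtype=float)

    def delta_for(self, group) -> np.ndarray:
        return self.q.weights @ self.eta_for(group) + self.shift_for(group)

    def truth(self) -> dict:
        """Generating parameters, JSON-serializable (for simulation provenance)."""
        groups = self.group_labels()
        return {
            "seed": self.seed,
            "theta_mean": self.theta_mean,
            "theta_sd": self.theta_sd,
            "groups": [str(g) for g in groups if g is not None],
            "eta": {str(g) if g is not None else "pooled": self.eta_for(g).tolist() for g in groups},
            "delta": {str(g) if g is not None else "pooled": self.delta_for(g).tolist() for g in groups},
            "item_ids": list(self.q.item_ids),
            "feature_names": list(self.q.feature_names),
        }


def simulate_responses(design: SimulationDesign):
    """Draw a ResponseMatrix from the design, fully reproducible from its seed.

    Abilities are drawn per group from N(theta_mean, theta_sd^2); one global
    generator stream governs both the ability and response draws.
    """
    from .data_io import ResponseMatrix  # local import to avoid cycles at doc build

    rng = np.random.default_rng(design.seed)
    blocks, labels, pids = [], [], []
    counter = 0
    for g in design.group_labels():
        n = design.n_persons[g] if isinstance(design.n_persons, dict) else design.n_persons
        delta = design.delta_for(g)
        mean = (
            float(np.mean(delta)) if design.theta_mean is None else design.theta_mean
        )
        theta = rng.normal(mean, design.theta_sd, size=n)
        prob = 1.0 / (1.0 + np.exp(-(theta[:, None] - delta[None, :])))
        blocks.append((rng.random((n, delta.size)) < prob).astype(float))
        labels.extend([g] * n)
        pids.extend([f"p{counter + i + 1}" for i in range(n)])
        counter += n
    values = np.vstack(blocks)
    group = None if design.group_labels() == [None] else np.array(labels, dtype=object)
    return ResponseMatrix(values, pids, list(design.q.item_ids), group)
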