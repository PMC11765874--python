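"""Input/output and validation for response matrices, item feature tables and Q-matrices.

The package analyses dichotomous (0/1) responses to mental rotation test (MRT)
items.  Three tabular inputs are supported:

* a **response CSV** — first column person id, one column per item, entries
  0/1 or blank/NA for "not administered";
* an **item feature CSV** — one row per item coding the six item
  characteristics (number of cubes, colored distractors, image structure,
  occlusion, rotation complexity, configuration type);
* an optional pre-built **Q-matrix CSV** (items x features, binary).

The Q-matrix is derived from the feature table by dichotomizing the cube count
at the mean across items (strictly greater than the mean codes 1) and passing
the five already-binary characteristics through, in a fixed column order so
that feature-effect indices are stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: canonical feature-table column names, in Q-matrix order
FEATURE_ORDER = [
    "ncubes",
    "color",
    "image_structure",
    "occlusion",
    "rotation",
    "configuration",
]

#: display names used for Q-matrix / effect tables
QMATRIX_COLUMNS = [
    "Ncubes",
    "Color",
    "Image structure",
    "Occlusion",
    "Rotation",
    "Configuration",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable thresholds for the full analysis pipeline.

    Parameters
    ----------
    alpha
        Significance level for DIF z tests and the DCF Wald tests
        (Bonferroni-adjusted to ``alpha / n_features`` for the latter).
    misfit_z_threshold
        Items with \\|standardized infit z\\| or \\|standardized outfit z\\| at or
        above this value are flagged as misfitting.
    pca_eigen_threshold
        Largest eigenvalue of the standardized-residual correlation matrix
        below which the responses are treated as sufficiently unidimensional.
    logit_diff_flag
        Absolute between-group logit difference above which an item is
        annotated as showing a practically meaningful difficulty difference.
    ncubes_threshold
        Fixed dichotomization cut point for the cube count.  ``None`` (the
        default) selects a mean split over the items present.
    seed
        Seed for any stochastic step (simulation subcommand).
    reference_group, focal_group
        Group labels for DIF/DCF.  ``None`` means "use the two observed
        levels in sorted order" (first = reference).
    remove_misfit_items
        Whether the pipeline removes flagged misfit items (one pass) before
        the feature-decomposition stage.
    """

    alpha: float = 0.05
    misfit_z_threshold: float = 2.0
    pca_eigen_threshold: float = 2.0
    logit_diff_flag: float = 0.5
    ncubes_threshold: float | None = None
    seed: int = 0
    reference_group: str | None = None
    focal_group: str | None = None
    remove_misfit_items: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("misfit_z_threshold", "pca_eigen_threshold", "logit_diff_flag"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from YAML (or JSON, a YAML subset)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration, for report provenance."""
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self)}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_updates(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# response matrix
# ---------------------------------------------------------------------------


@dataclass
class ResponseMatrix:
    """Persons x items dichotomous responses with a missing-value mask.

    ``values`` is a float array where non-missing entries are 0.0 or 1.0 and
    missing ("not administered") entries are NaN.  Missing responses are
    excluded from a person's raw score and from all likelihood sums.
    ``group`` optionally carries a per-person categorical label; persons with
    a missing label (None/NaN) are retained for pooled analyses and dropped
    from group-wise analyses.
    """

    values: np.ndarray
    person_ids: list[str]
    item_ids: list[str]
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("response values must be a 2-D array")
        n, k = self.values.shape
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_ids = [str(i) for i in self.item_ids]
        if len(self.person_ids) != n or len(self.item_ids) != k:
            raise ValueError("id lists do not match the matrix shape")
        if len(set(self.person_ids)) != n:
            raise ValueError("duplicate person ids")
        if len(set(self.item_ids)) != k:
            raise ValueError("duplicate item ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0))][0]
            raise ValueError(f"non-binary response value {bad!r}")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape != (n,):
                raise ValueError("group labels must align with persons")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a response was observed."""
        return ~np.isnan(self.values)

    def raw_scores(self) -> np.ndarray:
        """Number-correct per person over administered items."""
        return np.nansum(self.values, axis=1)

    def n_administered(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    def group_levels(self) -> list:
        if self.group is None:
            return []
        labelled = [g for g in self.group if not _is_missing_label(g)]
        return sorted(set(labelled), key=str)

    # -- subsetting ---------------------------------------------------------

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(str(i)) for i in item_ids]
        return ResponseMatrix(
            self.values[:, idx],
            self.person_ids,
            [self.item_ids[j] for j in idx],
            self.group,
        )

    def drop_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        drop = {str(i) for i in item_ids}
        keep = [i for i in self.item_ids if i not in drop]
        return self.subset_items(keep)

    def subset_persons(self, index: np.ndarray) -> "ResponseMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ResponseMatrix(
            self.values[index],
            [self.person_ids[i] for i in index],
            self.item_ids,
            None if self.group is None else self.group[index],
        )

    def split_by_group(
        self, reference: str | None = None, focal: str | None = None
    ) -> dict:
        """Return ``{label: ResponseMatrix}`` for the two analysis groups.

        Persons with a missing group label are dropped with a logged count.
        """
        if self.group is None:
            raise ValueError("response matrix carries no group variable")
        missing = np.array([_is_missing_label(g) for g in self.group])
        if missing.any():
            logger.info(
                "dropping %d person(s) with missing group label from group-wise analysis",
                int(missing.sum()),
            )
        levels = self.group_levels()
        if reference is None or focal is None:
            if len(levels) != 2:
                raise ValueError(
                    f"expected exactly 2 group levels, found {levels}; "
                    "specify reference_group/focal_group"
                )
            reference, focal = levels[0], levels[1]
        out = {}
        for label in (reference, focal):
            sel = np.array(
                [(not m) and g == label for g, m in zip(self.group, missing)]
            )
            if not sel.any():
                raise ValueError(f"group level {label!r} has no persons")
            out[label] = self.subset_persons(sel)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.person_ids, columns=self.item_ids)
        df.index.name = "person_id"
        if self.group is not None:
            df.insert(0, "group", self.group)
        return df


def _is_missing_label(g) -> bool:
    return g is None or (isinstance(g, float) and np.isnan(g)) or g == ""


# ---------------------------------------------------------------------------
# item feature table and Q-matrix
# ---------------------------------------------------------------------------


@dataclass
class ItemFeatureTable:
    """Per-item coding of the six MRT item characteristics.

    ``ncubes`` is the raw cube count (a positive integer); the other five
    characteristics are binary: colored distractors, image structure
    (0 structural, 1 mirror), occlusion, rotation complexity (1 complex) and
    configuration type (1 homogenous).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing_cols = [c for c in ["item_id", *FEATURE_ORDER] if c not in df.columns]
        if missing_cols:
            raise ValueError(f"feature table lacks columns {missing_cols}")
        df["item_id"] = df["item_id"].astype(str)
        if df["item_id"].duplicated().any():
            raise ValueError("duplicate item ids in feature table")
        if (df["ncubes"] < 1).any():
            raise ValueError("ncubes must be >= 1 for every item")
        for col in FEATURE_ORDER[1:]:
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"feature column {col!r} must be binary 0/1")
        self.table = df.reset_index(drop=True)

    @property
    def item_ids(self) -> list[str]:
        return list(self.table["item_id"])

    def check_matches(self, responses: ResponseMatrix) -> None:
        if self.item_ids != responses.item_ids:
            raise ValueError(
                "feature table items do not match response matrix items: "
                f"{self.item_ids} vs {responses.item_ids}"
            )

    def subset_items(self, item_ids: Sequence[str]) -> "ItemFeatureTable":
        ids = [str(i) for i in item_ids]
        sub = self.table.set_index("item_id").loc[ids].reset_index()
        return ItemFeatureTable(sub)


@dataclass
class QMatrix:
    """Items x features binary weight matrix assigning characteristics to items."""

    weights: np.ndarray
    feature_names: list[str]
    item_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=int)
        if self.weights.ndim != 2:
            raise ValueError("Q-matrix weights must be 2-D")
        n_items, n_feat = self.weights.shape
        if len(self.item_ids) != n_items or len(self.feature_names) != n_feat:
            raise ValueError("Q-matrix names do not match the weight shape")
        if not np.isin(self.weights, (0, 1)).all():
            raise ValueError("Q-matrix entries must be binary 0/1")
        if n_feat >= n_items:
            # enforced as a hard (rank) condition at estimation time
            logger.warning(
                "Q-matrix has %d features for %d items; the feature effects "
                "are only identifiable with fewer features than items",
                n_feat, n_items,
            )
        self.item_ids = [str(i) for i in self.item_ids]
        self._warn_identifiability()

    def _warn_identifiability(self) -> None:
        w = self.weights
        for j, name in enumerate(self.feature_names):
            col = w[:, j]
            if (col == 0).all():
                logger.warning("Q-matrix column %r is all-zero (unidentified)", name)
            elif (col == col[0]).all():
                logger.warning("Q-matrix column %r is constant (confounded with the scale origin)", name)
        for j in range(w.shape[1]):
            for j2 in range(j + 1, w.shape[1]):
                if (w[:, j] == w[:, j2]).all():
                    logger.warning(
                        "Q-matrix columns %r and %r are identical (collinear)",
                        self.feature_names[j],
                        self.feature_names[j2],
                    )

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def subset_items(self, item_ids: Sequence[str]) -> "QMatrix":
        idx = [self.item_ids.index(str(i)) for i in item_ids]
        return QMatrix(self.weights[idx], list(self.feature_names), [self.item_ids[j] for j in idx])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.weights, columns=self.feature_names)
        df.insert(0, "item_id", self.item_ids)
        return df


def build_qmatrix(
    features: ItemFeatureTable, config: AnalysisConfig | None = None
) -> QMatrix:
    """Build the Q-matrix from an item feature table.

    The cube count is dichotomized at the arithmetic mean over the items
    present (or at ``config.ncubes_threshold`` when fixed): strictly greater
    than the threshold codes 1, ties at the threshold code 0.  The five binary
    characteristics pass through unchanged.  Column order is fixed to
    ``QMATRIX_COLUMNS`` so feature-effect indices are stable.
    """
    config = config or AnalysisConfig()
    df = features.table
    threshold = (
        float(df["ncubes"].mean())
        if config.ncubes_threshold is None
        else float(config.ncubes_threshold)
    )
    ncubes_code = (df["ncubes"].to_numpy(dtype=float) > threshold).astype(int)
    weights = np.column_stack(
        [ncubes_code] + [df[c].to_numpy(dtype=int) for c in FEATURE_ORDER[1:]]
    )
    logger.info("dichotomized ncubes at threshold %.4g", threshold)
    return QMatrix(weights, list(QMATRIX_COLUMNS), features.item_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_responses(path: str | Path, group_column: str | None = None) -> ResponseMatrix:
    """Read a response CSV (first column person id) into a ResponseMatrix.

    Blank cells and the usual NA spellings map to "missing"; any entry other
    than 0/1/missing raises a parse error naming the offending cell.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    group = None
    if group_column is not None:
        if group_column not in df.columns:
            raise ValueError(f"group column {group_column!r} not found in {path}")
        group = np.array(
            [None if v in _NA_STRINGS else v for v in df[group_column]], dtype=object
        )
        labelled = {g for g in group if g is not None}
        if len(labelled) < 2:
            raise ValueError(
                f"group column {group_column!r} has fewer than 2 observed levels"
            )
        df = df.drop(columns=[group_column])
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, (pid, raw) in enumerate(zip(df.index, df[col])):
            cell = raw.strip()
            if cell in _NA_STRINGS:
                values[i, j] = np.nan
            elif cell in ("0", "0.0"):
                values[i, j] = 0.0
            elif cell in ("1", "1.0"):
                values[i, j] = 1.0
            else:
                raise ValueError(
                    f"non-binary entry {raw!r} at person {pid!r}, item {col!r} in {path}"
                )
    return ResponseMatrix(values, list(df.index), list(df.columns), group)


_NA_STRINGS = {"", "NA", "N/A", "na", "NaN", "nan", "None", "."}


def write_responses(responses: ResponseMatrix, path: str | Path) -> None:
    """Write a ResponseMatrix as CSV (inverse of :func:`read_responses`)."""
    df = responses.to_dataframe()
    item_cols = [c for c in df.columns if c != "group"]
    df[item_cols] = df[item_cols].map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.to_csv(path)


def read_features(path: str | Path) -> ItemFeatureTable:
    return ItemFeatureTable(pd.read_csv(path, dtype={"item_id": str}))


def read_qmatrix(path: str | Path) -> QMatrix:
    df = pd.read_csv(path, dtype={"item_id": str})
    if "item_id" not in df.columns:
        raise ValueError("Q-matrix CSV needs an item_id column")
    feature_names = [c for c in df.columns if c != "item_id"]
    return QMatrix(df[feature_names].to_numpy(), feature_names, list(df["item_id"]))


def write_result_table(table: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write a result table as CSV with full precision plus 2-decimal display columns.

    Every float column ``x`` gains a companion ``x_2dp`` rounded to two
    decimals, matching the convention of printed psychometric tables.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table))
    if table.empty:
        raise ValueError("refusing to write an empty result table")
    out = table.copy()
    for col in table.columns:
        if pd.api.types.is_float_dtype(table[col]):
            out[f"{col}_2dp"] = table[col].round(2)
    out.to_csv(path, index=False)
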