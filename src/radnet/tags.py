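"""DICOM tag preprocessing and tag feature extraction.

The preprocessing chain runs in five steps, matching the order in which the
pipeline consumes them:

1. :func:`reconstruct_bpe` — fill blank BodyPartExamined cells from a rule
   table of regular expressions applied to other tags;
2. :func:`split_array_tags` — expand array-valued tags into scalar columns;
3. :func:`filter_tags` — drop sparsely filled columns (< 35 % fill rate by
   default), identifier-like columns, free-text columns and constants;
4. :func:`impute_missing` — MissForest-style iterative random-forest
   imputation of the remaining missing cells;
5. :class:`TagEncoder` — one-hot encode categoricals and min-max scale
   continuous columns into [0, 1].

Feature extraction from the encoded matrix is done with a dense autoencoder
(:func:`fit_tag_autoencoder`) or PCA (:func:`fit_tag_pca`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._nn import DenseAutoencoder

logger = logging.getLogger(__name__)

__all__ = [
    "TagTable",
    "TagAEConfig",
    "TagEncoder",
    "reconstruct_bpe",
    "split_array_tags",
    "filter_tags",
    "impute_missing",
    "encode_tags",
    "fit_tag_autoencoder",
    "fit_tag_pca",
    "DEFAULT_FREETEXT_TAGS",
]

#: tag names treated as free text and dropped during filtering
DEFAULT_FREETEXT_TAGS = (
    "StudyDescription", "SeriesDescription", "ImageComments",
    "AdditionalPatientHistory", "RequestedProcedureDescription",
)

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


@dataclass
class TagTable:
    """A record-by-tag table with per-column kind (categorical/continuous).

    Missing cells are NaN/None; empty strings are normalised to missing at
    construction time.
    """

    frame: pd.DataFrame
    kinds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame = self.frame.copy()
        # empty strings count as missing
        obj_cols = [c for c in self.frame.columns
                    if self.frame[c].dtype == object]
        for c in obj_cols:
            self.frame[c] = self.frame[c].map(
                lambda v: np.nan if (isinstance(v, str) and v.strip() == "") else v)
        if not self.kinds:
            self.kinds = {c: self._infer_kind(self.frame[c])
                          for c in self.frame.columns}

    @staticmethod
    def _infer_kind(series):
        values = series.dropna()
        if len(values) and all(
                isinstance(v, str) or isinstance(v, (list, tuple, np.ndarray))
                for v in values):
            return CATEGORICAL
        return CONTINUOUS

    @classmethod
    def from_records(cls, records):
        """Build from a sequence of fixture/DICOM records (``.tags`` dicts)."""
        rows = {rec.record_id: dict(rec.tags) for rec in records}
        frame = pd.DataFrame.from_dict(rows, orient="index")
        return cls(frame)

    def fill_rate(self):
        return self.frame.notna().mean(axis=0)

    def copy(self):
        return TagTable(self.frame.copy(), dict(self.kinds))


@dataclass(frozen=True)
class TagAEConfig:
    """Dense tag-autoencoder hyperparameters (defaults: the winning
    512 -> 200 -> 125 -> 32 architecture at learning rate 1e-2)."""

    layer_sizes: tuple[int, int, int] = (512, 200, 125)
    bottleneck: int = 32
    learning_rate: float = 1e-2
    max_epochs: int = 100
    batch_size: int = 32
    patience: int = 5
    seed: int = 0

    def validate(self):
        sizes = self.layer_sizes
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("layer sizes must be strictly decreasing")
        if self.bottleneck >= sizes[-1]:
            raise ValueError("bottleneck must be below the last layer size")


# ---------------------------------------------------------------------------
# step 1: BodyPartExamined reconstruction
# ---------------------------------------------------------------------------


def reconstruct_bpe(table: TagTable, rules, bpe_column="BodyPartExamined"):
    """Fill blank BodyPartExamined cells from a rule table.

    ``rules`` is an ordered list of ``(pattern, source_tag, bpe_value)``; for
    each blank BPE cell the first rule whose regular expression matches the
    record's source-tag value wins. Non-blank cells are never overwritten.

    Returns ``(table, n_reconstructed)``.
    """
    if not rules:
        raise ValueError("rule list is empty")
    compiled = []
    for pattern, source, value in rules:
        try:
            compiled.append((re.compile(pattern), source, value))
        except re.error as exc:
            raise ValueError(f"malformed BPE rule pattern {pattern!r}: {exc}") from exc

    out = table.copy()
    frame = out.frame
    if bpe_column not in frame.columns:
        frame[bpe_column] = pd.Series(np.nan, index=frame.index, dtype=object)
        out.kinds[bpe_column] = CATEGORICAL
    frame[bpe_column] = frame[bpe_column].astype(object)
    blank = frame[bpe_column].isna()
    n_filled = 0
    for idx in frame.index[blank]:
        for regex, source, value in compiled:
            if source not in frame.columns:
                continue
            cell = frame.at[idx, source]
            if isinstance(cell, str) and regex.search(cell):
                frame.at[idx, bpe_column] = value
                n_filled += 1
                break
    return out, n_filled


# ---------------------------------------------------------------------------
# step 2: array-tag splitting
# ---------------------------------------------------------------------------


def _is_arraylike(v):
    return isinstance(v, (list, tuple, np.ndarray))


def split_array_tags(table: TagTable) -> TagTable:
    """Expand array-valued columns into suffixed scalar columns.

    A column holding n-element arrays becomes columns ``name_0 .. name_{n-1}``;
    ragged rows are padded with missing and logged. Scalar columns pass
    through unchanged, in their original order.
    """
    frame = table.frame
    pieces = []
    kinds = {}
    for col in frame.columns:
        series = frame[col]
        arr_mask = series.map(_is_arraylike)
        if not arr_mask.any():
            pieces.append(series.to_frame())
            kinds[col] = table.kinds[col]
            continue
        lengths = series[arr_mask].map(len)
        width = int(lengths.max())
        if lengths.nunique() > 1:
            logger.warning("ragged array tag %s: lengths %s, padding with missing",
                           col, sorted(lengths.unique()))
        cols = {}
        for j in range(width):
            cols[f"{col}_{j}"] = series.map(
                lambda v, j=j: (v[j] if _is_arraylike(v) and j < len(v) else
                                (v if not _is_arraylike(v) and j == 0 else np.nan)))
        sub = pd.DataFrame(cols, index=frame.index)
        pieces.append(sub)
        for j in range(width):
            kinds[f"{col}_{j}"] = TagTable._infer_kind(sub[f"{col}_{j}"])
    return TagTable(pd.concat(pieces, axis=1), kinds)


# ---------------------------------------------------------------------------
# step 3: filtering
# ---------------------------------------------------------------------------


def filter_tags(table: TagTable, fill_threshold: float = 0.35,
                freetext_tags=DEFAULT_FREETEXT_TAGS, drop_tags=(),
                train_index=None) -> TagTable:
    """Drop uninformative columns.

    Removed are: columns with fill rate strictly below ``fill_threshold``
    (columns filled in exactly the threshold fraction are kept), columns on
    the free-text or explicit drop lists, categorical columns whose
    non-missing values are all distinct (identifier heuristic — continuous
    columns are exempt, since measured values are near-unique by nature), and
    columns with fewer than two distinct values. Fill rates and distinctness
    are computed on ``train_index`` rows when given, to avoid leakage.
    """
    if not 0.0 < fill_threshold <= 1.0:
        raise ValueError("fill_threshold must be in (0, 1]")
    frame = table.frame if train_index is None else table.frame.loc[train_index]
    keep = []
    for col in table.frame.columns:
        if col in freetext_tags or col in drop_tags:
            continue
        series = frame[col]
        values = series.dropna()
        if series.notna().mean() < fill_threshold:
            continue
        n_distinct = values.nunique()
        if n_distinct < 2:
            continue
        if table.kinds[col] == CATEGORICAL and n_distinct == len(values):
            continue  # identifier heuristic
        keep.append(col)
    if not keep:
        raise ValueError("filtering removed every column (degenerate input)")
    return TagTable(table.frame[keep],
                    {c: table.kinds[c] for c in keep})


# ---------------------------------------------------------------------------
# step 4: MissForest-style imputation
# ---------------------------------------------------------------------------


def impute_missing(table: TagTable, n_trees: int = 100, max_iter: int = 10,
                   seed: int = 0) -> TagTable:
    """Iterative random-forest imputation (MissForest).

    Missing cells are initialised with the column mean (continuous) or mode
    (categorical). Columns are then visited in ascending missingness; for
    each, a forest is fitted on rows where the column is observed and used to
    predict the missing rows. Iteration stops when the change measure — the
    normalised sum of squared changes over continuous cells plus the mismatch
    fraction over categorical cells — rises, returning the previous iterate,
    or after ``max_iter`` sweeps.
    """
    frame = table.frame.copy()
    miss = frame.isna()
    if not miss.values.any():
        return table.copy()
    if (miss.all(axis=0)).any():
        bad = list(frame.columns[miss.all(axis=0)])
        raise ValueError(f"all-missing columns {bad}; filter them first")

    cont = [c for c in frame.columns if table.kinds[c] == CONTINUOUS]
    cat = [c for c in frame.columns if table.kinds[c] == CATEGORICAL]

    # initialisation: mean / mode
    for c in cont:
        frame[c] = pd.to_numeric(frame[c]).fillna(pd.to_numeric(frame[c]).mean())
    cat_codes = {}
    for c in cat:
        levels = sorted(frame[c].dropna().unique())
        cat_codes[c] = levels
        mode = frame[c].mode().iloc[0]
        frame[c] = frame[c].fillna(mode)

    def as_design(df, exclude):
        cols = [c for c in df.columns if c != exclude]
        blocks = []
        for c in cols:
            if c in cat_codes:
                codes = pd.Categorical(df[c], categories=cat_codes[c]).codes
                blocks.append(codes.astype(float))
            else:
                blocks.append(pd.to_numeric(df[c]).to_numpy(dtype=float))
        return np.column_stack(blocks) if blocks else np.zeros((len(df), 0))

    order = list(miss.sum(axis=0).sort_values(kind="stable").index)
    order = [c for c in order if miss[c].any()]

    prev = frame.copy()
    prev_delta = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        for c in order:
            obs = ~miss[c]
            X_obs = as_design(frame.loc[obs], c)
            X_mis = as_design(frame.loc[miss[c]], c)
            rs = int(rng.integers(2**31))
            if c in cat_codes:
                y = frame.loc[obs, c]
                if y.nunique() < 2:
                    continue  # degenerate: keep mode initialisation
                model = RandomForestClassifier(n_estimators=n_trees,
                                               random_state=rs, n_jobs=1)
                model.fit(X_obs, y)
                frame.loc[miss[c], c] = model.predict(X_mis)
            else:
                model = RandomForestRegressor(n_estimators=n_trees,
                                              random_state=rs, n_jobs=1)
                model.fit(X_obs, pd.to_numeric(frame.loc[obs, c]))
                frame.loc[miss[c], c] = model.predict(X_mis)
        # change measure
        delta = 0.0
        for c in order:
            if c in cat_codes:
                changed = (frame.loc[miss[c], c] != prev.loc[miss[c], c]).mean()
                delta += float(changed)
            else:
                new = pd.to_numeric(frame.loc[miss[c], c]).to_numpy(float)
                old = pd.to_numeric(prev.loc[miss[c], c]).to_numpy(float)
                denom = float(np.sum(new**2)) or 1.0
                delta += float(np.sum((new - old) ** 2)) / denom
        if delta >= prev_delta:
            frame = prev  # difference measure rose: keep previous iterate
            break
        prev = frame.copy()
        prev_delta = delta
    return TagTable(frame, dict(table.kinds))


# ---------------------------------------------------------------------------
# step 5: encoding
# ---------------------------------------------------------------------------


class TagEncoder:
    """One-hot categoricals + min-max scaled continuous columns, fitted on the
    training subset and re-applicable to validation/test rows.

    Unseen categories at transform time produce an all-zero one-hot block
    (logged); continuous values outside the training range are clipped to
    [0, 1].
    """

    def fit(self, table: TagTable, train_index=None):
        frame = table.frame if train_index is None else table.frame.loc[train_index]
        self.columns_ = list(table.frame.columns)
        self.kinds_ = dict(table.kinds)
        self.categories_ = {}
        self.ranges_ = {}
        self.feature_names_ = []
        for c in self.columns_:
            if table.kinds[c] == CATEGORICAL:
                self.categories_[c] = sorted(frame[c].dropna().unique())
                self.feature_names_ += [f"{c}={v}" for v in self.categories_[c]]
            else:
                values = pd.to_numeric(frame[c])
                lo, hi = float(values.min()), float(values.max())
                self.ranges_[c] = (lo, hi if hi > lo else lo + 1.0)
                self.feature_names_.append(c)
        return self

    def transform(self, table: TagTable) -> np.ndarray:
        if table.frame.isna().values.any():
            raise ValueError("encode requires a fully imputed table")
        blocks = []
        for c in self.columns_:
            series = table.frame[c]
            if c in self.categories_:
                levels = self.categories_[c]
                codes = pd.Categorical(series, categories=levels).codes
                unseen = codes < 0
                if unseen.any():
                    logger.warning("unseen categories in %s for %d rows; "
                                   "emitting zero block", c, int(unseen.sum()))
                onehot = np.zeros((len(series), len(levels)), dtype=np.float64)
                rows = np.nonzero(codes >= 0)[0]
                onehot[rows, codes[codes >= 0]] = 1.0
                blocks.append(onehot)
            else:
                lo, hi = self.ranges_[c]
                scaled = (pd.to_numeric(series).to_numpy(float) - lo) / (hi - lo)
                blocks.append(np.clip(scaled, 0.0, 1.0)[:, None])
        return np.concatenate(blocks, axis=1)

    def fit_transform(self, table: TagTable, train_index=None):
        return self.fit(table, train_index).transform(table)


def encode_tags(table: TagTable, train_index=None):
    """Convenience wrapper: returns ``(matrix, fitted TagEncoder)``."""
    enc = TagEncoder()
    return enc.fit_transform(table, train_index), enc


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def fit_tag_autoencoder(matrix: np.ndarray, cfg: TagAEConfig = TagAEConfig(),
                        validation: np.ndarray | None = None) -> DenseAutoencoder:
    """Train the dense tag autoencoder; returns the fitted model whose
    ``transform`` yields ``cfg.bottleneck``-length embeddings."""
    cfg.validate()
    matrix = np.asarray(matrix, dtype=np.float32)
    if not np.isfinite(matrix).all():
        raise ValueError("tag matrix must be finite")
    ae = DenseAutoencoder(matrix.shape[1], cfg.layer_sizes, cfg.bottleneck,
                          seed=cfg.seed)
    ae.fit(matrix, X_val=validation, lr=cfg.learning_rate,
           batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
           patience=cfg.patience, seed=cfg.seed)
    return ae


_PCA_SOLVERS = {"lapack": "full", "arpack": "arpack", "randomised": "randomized",
                "randomized": "randomized"}


def fit_tag_pca(matrix: np.ndarray, n_components: int = 50,
                solver: str = "arpack", seed: int = 0) -> PCA:
    """Fit a PCA projection of the encoded tag matrix."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if n_components > min(matrix.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver=_PCA_SOLVERS[solver],
              random_state=seed)
    pca.fit(matrix)
    return pca
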