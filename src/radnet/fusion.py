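"""Late fusion of per-source embeddings.

Three fusion representations are supported, each producing one flat vector
per record in fixed source order (diagnosis, tags, image):

* ``embeddings`` — plain concatenation of the raw per-source embeddings;
* ``clusterdists`` — per source, the distances to that source's fitted
  cluster centres, min-max normalised into [0, 1] with constants fitted on
  the training subset, then concatenated (length = sum of per-source kappa);
* ``clusterprobs`` — softmax of the negated distances per source,

      p_c = exp(-d_c) / sum_j exp(-d_j),

  assigning higher probability to shorter distances; each source block sums
  to 1. By default the softmax consumes the [0, 1]-normalised distances
  (prevents saturation and cross-source scale mismatch); raw distances are
  available via ``use_normalised=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterModel

__all__ = [
    "FusedEmbedding",
    "fuse_embeddings",
    "softmax_neg_distance",
    "DistanceNormaliser",
    "ClusterSpaceFuser",
    "fuse_clusterdists",
    "fuse_clusterprobs",
]


def softmax_neg_distance(d: np.ndarray) -> np.ndarray:
    """p_c = exp(-d_c) / sum_j exp(-d_j) along the last axis."""
    e = np.exp(-np.asarray(d, dtype=np.float64))
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class FusedEmbedding:
    """Fused per-record matrix plus bookkeeping.

    ``vectors`` has one row per record; ``component_spans`` maps each source
    name to its (start, stop) column range.
    """

    vectors: np.ndarray
    method: str
    component_spans: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.vectors.shape[1]


def _spans(names, widths):
    spans, start = {}, 0
    for name, width in zip(names, widths):
        spans[name] = (start, start + width)
        start += width
    return spans


def fuse_embeddings(parts: dict) -> FusedEmbedding:
    """Concatenate raw per-source embedding matrices.

    ``parts`` maps source name to an (n, d_source) matrix, in the desired
    concatenation order (insertion order is preserved).
    """
    names = list(parts)
    mats = [np.asarray(parts[n], dtype=np.float64) for n in names]
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) != 1:
        raise ValueError("all sources must cover the same records")
    vectors = np.concatenate(mats, axis=1)
    return FusedEmbedding(vectors, "embeddings",
                          _spans(names, [m.shape[1] for m in mats]))


class DistanceNormaliser:
    """Per-source scalar min-max normalisation of centre distances, fitted on
    training distances and clipped to [0, 1] at transform time."""

    def fit(self, distances):
        d = np.asarray(distances, dtype=np.float64)
        self.min_ = float(d.min())
        span = float(d.max()) - self.min_
        self.span_ = span if span > 0 else 1.0
        return self

    def transform(self, distances):
        d = np.asarray(distances, dtype=np.float64)
        return np.clip((d - self.min_) / self.span_, 0.0, 1.0)


class ClusterSpaceFuser:
    """Fits per-source cluster-space representations (distances or softmax
    probabilities) and concatenates them.

    Parameters
    ----------
    models : dict
        Source name -> fitted :class:`ClusterModel`, in concatenation order.
    method : str
        ``"clusterdists"`` or ``"clusterprobs"``.
    use_normalised : bool
        Feed [0, 1]-normalised distances to the softmax (default) rather
        than raw distances.
    """

    def __init__(self, models: dict, method: str = "clusterdists",
                 use_normalised: bool = True):
        if method not in ("clusterdists", "clusterprobs"):
            raise ValueError(f"unknown fusion method {method!r}")
        for name, model in models.items():
            if not isinstance(model, ClusterModel):
                raise ValueError(f"source {name!r} has no fitted cluster model")
        self.models = dict(models)
        self.method = method
        self.use_normalised = use_normalised

    def fit(self, train_parts: dict):
        """Fit per-source distance normalisation on training embeddings."""
        self.normalisers_ = {}
        for name, model in self.models.items():
            d = model.distances(train_parts[name])
            self.normalisers_[name] = DistanceNormaliser().fit(d)
        return self

    def transform(self, parts: dict) -> FusedEmbedding:
        blocks = []
        names = list(self.models)
        for name in names:
            model = self.models[name]
            d = model.distances(parts[name])
            d_norm = self.normalisers_[name].transform(d)
            if self.method == "clusterdists":
                blocks.append(d_norm)
            else:
                z = d_norm if self.use_normalised else d
                blocks.append(softmax_neg_distance(z))
        vectors = np.concatenate(blocks, axis=1)
        return FusedEmbedding(vectors, self.method,
                              _spans(names, [b.shape[1] for b in blocks]))

    def fit_transform(self, train_parts: dict, parts: dict | None = None):
        self.fit(train_parts)
        return self.transform(parts if parts is not None else train_parts)


def fuse_clusterdists(parts: dict, models: dict, train_parts: dict | None = None
                      ) -> FusedEmbedding:
    """Concatenated [0, 1]-normalised distances to each source's centres."""
    fuser = ClusterSpaceFuser(models, "clusterdists")
    return fuser.fit_transform(train_parts if train_parts is not None else parts,
                               parts)


def fuse_clusterprobs(parts: dict, models: dict, train_parts: dict | None = None,
                      use_normalised: bool = True) -> FusedEmbedding:
    """Concatenated softmax-of-negative-distance probability blocks."""
    fuser = ClusterSpaceFuser(models, "clusterprobs",
                              use_normalised=use_normalised)
    return fuser.fit_transform(train_parts if train_parts is not None else parts,
                               parts)
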