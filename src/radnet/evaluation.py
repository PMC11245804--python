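"""Cluster-quality metrics, model selection and post-filters.

Agreement between a clustering and the ground-truth labels (imaging modality
y_M and examined body part y_B) is measured with normalised mutual
information

    NMI = 2 I(y, y_hat) / (H(y) + H(y_hat)),   I = H(y) - H(y | y_hat),

and the homogeneity score

    HS = 1 - H(y | y_hat) / H(y),

both in [0, 1]; entropies use natural logs (the ratios are base-invariant).
The composite selection score S is the harmonic mean of HS_B, HS_M, NMI_B
and NMI_M.

Cluster conciseness is measured with mean within-cluster pairwise cosine
distance of image (D_I) and diagnosis (D_D) embeddings, averaged over
clusters, with D_score their harmonic mean (lower is better). Image and text
extractors are ranked by S at the elbow kappa; tag extractors by the lowest
D_score computed with the already-selected image and diagnosis embeddings.

Post-filters for downstream training remove clusters that are too small
(< 100 members by default) or too mixed (normalised label entropy >= 0.9),
and an oversampling plan balances the survivors to the largest cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVector",
    "MetricsReport",
    "DissimilarityReport",
    "entropy",
    "nmi",
    "hs",
    "score_s",
    "metrics_report",
    "cosine_distance",
    "cluster_dissimilarity",
    "d_score",
    "SweepCandidate",
    "select_models",
    "filter_clusters",
    "oversample_plan",
]


@dataclass
class LabelVector:
    """Per-record ground-truth labels."""

    y_m: np.ndarray  # modality
    y_b: np.ndarray  # body part


# ---------------------------------------------------------------------------
# entropy-based metrics
# ---------------------------------------------------------------------------


def entropy(labels) -> float:
    """Empirical Shannon entropy (natural log) of a label vector."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def conditional_entropy(y, y_hat) -> float:
    """H(y | y_hat): cluster-size-weighted entropy of y within clusters."""
    y = np.asarray(y)
    y_hat = np.asarray(y_hat)
    total = 0.0
    n = len(y)
    for c in np.unique(y_hat):
        mask = y_hat == c
        total += mask.sum() / n * entropy(y[mask])
    return total


def mutual_information(y, y_hat) -> float:
    return entropy(y) - conditional_entropy(y, y_hat)


def nmi(y, y_hat) -> float:
    """Normalised mutual information 2 I / (H(y) + H(y_hat)), in [0, 1]."""
    h_y = entropy(y)
    h_hat = entropy(y_hat)
    if h_y == 0.0 and h_hat == 0.0:
        logger.warning("constant labels and constant clustering: NMI := 0")
        return 0.0
    i = h_y - conditional_entropy(y, y_hat)
    value = 2.0 * i / (h_y + h_hat)
    return float(min(max(value, 0.0), 1.0))


def hs(y, y_hat) -> float:
    """Homogeneity score 1 - H(y | y_hat) / H(y); requires H(y) > 0."""
    h_y = entropy(y)
    if h_y == 0.0:
        raise ValueError("homogeneity is undefined for constant ground truth")
    value = 1.0 - conditional_entropy(y, y_hat) / h_y
    return float(min(max(value, 0.0), 1.0))


def score_s(hs_b, hs_m, nmi_b, nmi_m) -> float:
    """Harmonic mean of the four agreement metrics; 0 if any input is 0."""
    parts = (hs_b, hs_m, nmi_b, nmi_m)
    if any(p == 0.0 for p in parts):
        return 0.0
    return 4.0 / sum(1.0 / p for p in parts)


@dataclass
class MetricsReport:
    nmi_m: float
    nmi_b: float
    hs_m: float
    hs_b: float
    s: float
    h_y_m: float
    h_y_b: float
    h_y_hat: float

    def as_dict(self):
        return {"NMI_M": self.nmi_m, "NMI_B": self.nmi_b,
                "HS_M": self.hs_m, "HS_B": self.hs_b, "S": self.s,
                "H_modality": self.h_y_m, "H_bodypart": self.h_y_b,
                "H_clusters": self.h_y_hat}


def metrics_report(labels: LabelVector, y_hat) -> MetricsReport:
    """All agreement metrics plus the composite S for one assignment."""
    return MetricsReport(
        nmi_m=nmi(labels.y_m, y_hat),
        nmi_b=nmi(labels.y_b, y_hat),
        hs_m=hs(labels.y_m, y_hat),
        hs_b=hs(labels.y_b, y_hat),
        s=score_s(hs(labels.y_b, y_hat), hs(labels.y_m, y_hat),
                  nmi(labels.y_b, y_hat), nmi(labels.y_m, y_hat)),
        h_y_m=entropy(labels.y_m),
        h_y_b=entropy(labels.y_b),
        h_y_hat=entropy(y_hat),
    )


# ---------------------------------------------------------------------------
# dissimilarity metrics
# ---------------------------------------------------------------------------


def cosine_distance(u, v) -> float:
    """1 - cosine similarity, in [0, 2]; zero vectors are rejected."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance is undefined for zero vectors")
    return float(1.0 - (u @ v) / (nu * nv))


@dataclass
class DissimilarityReport:
    per_cluster: dict                 # cluster -> mean pairwise cosine distance
    per_cluster_sd: dict
    pair_counts: dict                 # cluster -> k(k-1)/2
    sampled_clusters: list            # clusters where pairs were subsampled
    skipped_clusters: list            # clusters with < 2 members
    mean: float                       # D = mean over clusters with >= 2 members


def cluster_dissimilarity(embeddings, assignment, max_pairs: int = 10_000,
                          seed: int = 0) -> DissimilarityReport:
    """Mean within-cluster pairwise cosine distance (the D statistic).

    All k(k-1)/2 pairs are enumerated per cluster; clusters with more pairs
    than ``max_pairs`` use a seeded uniform pair sample and are flagged.
    Singleton clusters are excluded from the average and reported.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    y_hat = np.asarray(assignment)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("cosine distance is undefined for zero vectors")
    Xn = X / norms[:, None]
    rng = np.random.default_rng(seed)
    per_cluster, per_sd, pair_counts = {}, {}, {}
    sampled, skipped = [], []
    for c in np.unique(y_hat):
        members = np.nonzero(y_hat == c)[0]
        k = len(members)
        u = k * (k - 1) // 2
        pair_counts[int(c)] = u
        if k < 2:
            skipped.append(int(c))
            continue
        if u <= max_pairs:
            sub = Xn[members]
            sims = sub @ sub.T
            iu = np.triu_indices(k, k=1)
            dists = 1.0 - sims[iu]
        else:
            sampled.append(int(c))
            i = rng.integers(0, k, size=max_pairs)
            j = rng.integers(0, k - 1, size=max_pairs)
            j = np.where(j >= i, j + 1, j)  # uniform pairs i != j
            dists = 1.0 - np.einsum("nd,nd->n", Xn[members[i]], Xn[members[j]])
        per_cluster[int(c)] = float(dists.mean())
        per_sd[int(c)] = float(dists.std())
    if not per_cluster:
        raise ValueError("every cluster is a singleton")
    return DissimilarityReport(
        per_cluster=per_cluster, per_cluster_sd=per_sd,
        pair_counts=pair_counts, sampled_clusters=sampled,
        skipped_clusters=skipped,
        mean=float(np.mean(list(per_cluster.values()))),
    )


def d_score(d_i: float, d_d: float) -> float:
    """Harmonic mean of D_I and D_D; 0 if either is 0."""
    if d_i == 0.0 or d_d == 0.0:
        return 0.0
    return 2.0 * d_i * d_d / (d_i + d_d)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


@dataclass
class SweepCandidate:
    """One extractor's kappa sweep on the evaluation subset."""

    name: str
    kappas: list
    inertias: list
    assignments: dict            # kappa -> per-record cluster labels


def _elbow(candidate: SweepCandidate):
    from .clustering import find_elbow

    kappa_star, fallback = find_elbow(candidate.kappas, candidate.inertias)
    return kappa_star, fallback


def select_models(image_sweeps, text_sweeps, tag_sweeps, labels: LabelVector,
                  image_embeddings: dict, text_embeddings: dict,
                  max_pairs: int = 10_000, seed: int = 0) -> dict:
    """Pick the best extractor per source.

    Image and text candidates are ranked by the S score of their assignment
    at the Kneedle elbow kappa. Tag candidates are then ranked by the lowest
    D_score at their elbow, where D_I / D_D are computed from the winning
    image / text embeddings under the tag assignment.
    """
    if not (image_sweeps and text_sweeps and tag_sweeps):
        raise ValueError("all three sources need at least one sweep")

    def rank_by_s(sweeps):
        rows = []
        for cand in sweeps:
            kappa_star, fallback = _elbow(cand)
            report = metrics_report(labels, cand.assignments[kappa_star])
            rows.append({"name": cand.name, "kappa": kappa_star,
                         "elbow_fallback": fallback, **report.as_dict()})
        rows.sort(key=lambda r: -r["S"])
        return rows

    image_rows = rank_by_s(image_sweeps)
    text_rows = rank_by_s(text_sweeps)
    best_image = image_rows[0]["name"]
    best_text = text_rows[0]["name"]

    tag_rows = []
    for cand in tag_sweeps:
        kappa_star, fallback = _elbow(cand)
        y_hat = cand.assignments[kappa_star]
        d_i = cluster_dissimilarity(image_embeddings[best_image], y_hat,
                                    max_pairs=max_pairs, seed=seed).mean
        d_d = cluster_dissimilarity(text_embeddings[best_text], y_hat,
                                    max_pairs=max_pairs, seed=seed).mean
        tag_rows.append({"name": cand.name, "kappa": kappa_star,
                         "elbow_fallback": fallback, "D_I": d_i, "D_D": d_d,
                         "D_score": d_score(d_i, d_d)})
    tag_rows.sort(key=lambda r: r["D_score"])

    return {
        "image": {"winner": best_image, "ranking": image_rows},
        "text": {"winner": best_text, "ranking": text_rows},
        "tags": {"winner": tag_rows[0]["name"], "ranking": tag_rows},
    }


# ---------------------------------------------------------------------------
# post-filters
# ---------------------------------------------------------------------------


def filter_clusters(assignment, labels: LabelVector, min_size: int = 100,
                    entropy_cutoff: float = 0.9):
    """Remove small and heterogeneous clusters.

    A cluster is removed when it has fewer than ``min_size`` members, or when
    the normalised entropy — the entropy of the modality or the body-part
    labels inside the cluster, divided by the log of that label set's global
    size — reaches ``entropy_cutoff`` for either label type. Survivors are
    re-indexed densely (order preserved); removed records get label -1.

    Returns ``(filtered assignment, removal log)``.
    """
    y_hat = np.asarray(assignment)
    n_m = len(np.unique(labels.y_m))
    n_b = len(np.unique(labels.y_b))
    removal = {}
    kept = []
    for c in np.unique(y_hat):
        mask = y_hat == c
        size = int(mask.sum())
        if size < min_size:
            removal[int(c)] = f"size {size} < {min_size}"
            continue
        ent_m = entropy(labels.y_m[mask]) / np.log(n_m) if n_m > 1 else 0.0
        ent_b = entropy(labels.y_b[mask]) / np.log(n_b) if n_b > 1 else 0.0
        if max(ent_m, ent_b) >= entropy_cutoff:
            removal[int(c)] = (f"normalised entropy {max(ent_m, ent_b):.3f} "
                               f">= {entropy_cutoff}")
            continue
        kept.append(int(c))
    remap = {c: i for i, c in enumerate(kept)}
    filtered = np.array([remap.get(int(c), -1) for c in y_hat])
    return filtered, removal


def oversample_plan(filtered_assignment) -> dict:
    """Replication counts lifting every kept cluster to the largest kept
    cluster's size (removed records, label -1, are ignored)."""
    y = np.asarray(filtered_assignment)
    y = y[y >= 0]
    if len(y) == 0:
        return {}
    clusters, counts = np.unique(y, return_counts=True)
    target = int(counts.max())
    return {int(c): int(target - n) for c, n in zip(clusters, counts)}
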