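"""Clustering: k-means and k-medoids fits, kappa sweeps, Kneedle elbow
selection and repeated-run stability reporting.

k-means is the standard Euclidean Lloyd algorithm (k-means++ initialisation,
``n_init`` restarts). k-medoids uses the alternating (Voronoi) heuristic over
a precomputed distance matrix — Euclidean or cosine (1 - cosine similarity)
— with a k-means++-style seeding; medoids are always members of the training
data. Inertia is reported as the sum of squared distances to the closest
centre under the model's own metric.

The number of clusters is chosen on the inertia curve with the Kneedle
knee-detection procedure for decreasing convex curves; when the curve has no
knee (e.g. exactly linear decrease), the kappa with maximum discrete second
difference is returned and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances

__all__ = [
    "ClusterModel",
    "ClusterAssignment",
    "DEFAULT_KAPPA_GRID",
    "fit_cluster",
    "assign",
    "sweep_kappa",
    "find_elbow",
    "stability_check",
]

DEFAULT_KAPPA_GRID = (5, 10, 15, 20, 25, 30, 40, 50, 75, 100, 150)


@dataclass
class ClusterModel:
    algorithm: str               # "k-means" | "k-medoids"
    metric: str                  # "euclidean" | "cosine"
    kappa: int
    centres: np.ndarray          # (kappa, d); medoids are data members
    inertia: float
    seed: int
    medoid_indices: np.ndarray | None = None
    reseeded: bool = False       # an empty cluster forced one re-seed

    def distances(self, X) -> np.ndarray:
        """Distance of every row of X to every centre, shape (n, kappa)."""
        X = np.asarray(X, dtype=np.float64)
        return pairwise_distances(X, self.centres, metric=self.metric)


@dataclass
class ClusterAssignment:
    labels: np.ndarray           # argmin of d_k, ties to the lowest index
    d_k: np.ndarray              # (n, kappa)


def _validate(algorithm, metric):
    if algorithm not in ("k-means", "k-medoids"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    if algorithm == "k-means" and metric != "euclidean":
        raise ValueError("k-means supports only the Euclidean metric")


def _kmedoids_init(D, kappa, rng):
    """k-means++-style seeding on a precomputed distance matrix."""
    n = len(D)
    first = int(rng.integers(n))
    medoids = [first]
    closest = D[:, first].copy()
    for _ in range(kappa - 1):
        probs = closest**2
        total = probs.sum()
        if total <= 0:
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
            continue
        nxt = int(rng.choice(n, p=probs / total))
        medoids.append(nxt)
        closest = np.minimum(closest, D[:, nxt])
    return np.array(medoids, dtype=np.int64)


def _fit_kmedoids(X, kappa, metric, seed, max_iter=100):
    D = pairwise_distances(X, metric=metric)
    rng = np.random.default_rng(seed)

    def run(rng):
        medoids = _kmedoids_init(D, kappa, rng)
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            empty = [c for c in range(kappa) if not np.any(labels == c)]
            if empty:
                return medoids, labels, True
            new = medoids.copy()
            for c in range(kappa):
                members = np.nonzero(labels == c)[0]
                within = D[np.ix_(members, members)].sum(axis=1)
                new[c] = members[int(np.argmin(within))]
            if np.array_equal(np.sort(new), np.sort(medoids)):
                medoids = new
                break
            medoids = new
        labels = np.argmin(D[:, medoids], axis=1)
        return medoids, labels, False

    medoids, labels, had_empty = run(rng)
    reseeded = False
    if had_empty:  # one re-seed, then flag
        reseeded = True
        medoids, labels, _ = run(np.random.default_rng(seed + 1))
    inertia = float(np.sum(D[np.arange(len(X)), medoids[labels]] ** 2))
    return medoids, inertia, reseeded


def fit_cluster(embeddings, algorithm: str, metric: str, kappa: int,
                seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Fit one clustering model. Deterministic given the seed."""
    _validate(algorithm, metric)
    X = np.asarray(embeddings, dtype=np.float64)
    if kappa < 2:
        raise ValueError("kappa must be >= 2")
    if kappa > len(X):
        raise ValueError("kappa exceeds the number of records")
    if algorithm == "k-means":
        km = KMeans(n_clusters=kappa, n_init=n_init, random_state=seed)
        km.fit(X)
        return ClusterModel(algorithm, metric, kappa,
                            centres=km.cluster_centers_.copy(),
                            inertia=float(km.inertia_), seed=seed)
    medoids, inertia, reseeded = _fit_kmedoids(X, kappa, metric, seed)
    return ClusterModel(algorithm, metric, kappa, centres=X[medoids].copy(),
                        inertia=inertia, seed=seed,
                        medoid_indices=medoids, reseeded=reseeded)


def assign(model: ClusterModel, embeddings) -> ClusterAssignment:
    """Nearest-centre assignment; ties break toward the lowest index."""
    d = model.distances(embeddings)
    return ClusterAssignment(labels=np.argmin(d, axis=1), d_k=d)


def sweep_kappa(embeddings, algorithm: str, metric: str,
                kappa_grid=DEFAULT_KAPPA_GRID, seed: int = 0,
                n_init: int = 10) -> list[ClusterModel]:
    """Fit one model per kappa over the grid (default: the 11-value grid
    {5, 10, 15, 20, 25, 30, 40, 50, 75, 100, 150})."""
    models = [fit_cluster(embeddings, algorithm, metric, kappa, seed=seed,
                          n_init=n_init)
              for kappa in sorted(kappa_grid)]
    inertias = [m.inertia for m in models]
    if any(b > a * (1 + 1e-9) for a, b in zip(inertias, inertias[1:])):
        import logging
        logging.getLogger(__name__).warning(
            "inertia not monotone over kappa grid (optimisation noise): %s",
            inertias)
    return models


def find_elbow(kappa_grid, inertias):
    """Kneedle knee of a decreasing inertia curve.

    Returns ``(kappa_star, fallback_flag)``. The curve is normalised to the
    unit square, flipped to increasing form, and the knee is the grid point
    maximising the difference to the diagonal. A flat difference curve means
    no knee; the kappa with maximum discrete second difference is then
    returned with ``fallback_flag=True``.
    """
    kappas = np.asarray(kappa_grid, dtype=float)
    y = np.asarray(inertias, dtype=float)
    if len(kappas) < 3 or len(y) != len(kappas):
        raise ValueError("need >= 3 grid points with matching inertias")
    if np.any(y < 0):
        raise ValueError("inertias must be non-negative")
    order = np.argsort(kappas)
    kappas, y = kappas[order], y[order]
    x_n = (kappas - kappas[0]) / (kappas[-1] - kappas[0])
    span = y.max() - y.min()
    if span <= 0:
        return int(kappas[np.argmax(_second_diff(y))]), True
    y_n = (y - y.min()) / span
    diff = (1.0 - y_n) - x_n
    if diff.max() <= 1e-12:  # no knee (linear or concave curve)
        return int(kappas[np.argmax(_second_diff(y))]), True
    return int(kappas[int(np.argmax(diff))]), False


def _second_diff(y):
    d2 = np.zeros_like(y)
    d2[1:-1] = y[:-2] - 2 * y[1:-1] + y[2:]
    return d2


def stability_check(embeddings, labels_by_name: dict, algorithm: str,
                    metric: str, kappa: int, runs: int = 11,
                    seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """Refit ``runs`` times with distinct seeds and report per-run metrics.

    ``labels_by_name`` maps a label name (e.g. ``"modality"``) to a ground
    truth vector; the report holds one row per run with inertia plus NMI and
    HS per label, and the caller can aggregate mean +/- s.d.
    """
    from .evaluation import hs, nmi

    rows = []
    for r in range(runs):
        model = fit_cluster(embeddings, algorithm, metric, kappa,
                            seed=seed + r, n_init=n_init)
        y_hat = assign(model, embeddings).labels
        row = {"run": r, "seed": seed + r, "inertia": model.inertia}
        for name, y in labels_by_name.items():
            row[f"nmi_{name}"] = nmi(y, y_hat)
            row[f"hs_{name}"] = hs(y, y_hat)
        rows.append(row)
    return pd.DataFrame(rows)
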