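"""Attribution-space geometry: embedding, clustering, projection.

The per-record Shapley vectors of the explanation cohort (records the model
called reduced-LVEF, excluding paced rhythms) are reduced to two dimensions by
PCA followed by UMAP, then clustered with a variational Bayesian Gaussian
mixture (VBGMM).  The VBGMM's Dirichlet weight-concentration prior prunes
unused components, so the number of clusters is data-driven rather than
fixed; clusters smaller than ``min_cluster_size`` are kept but flagged
"unexplained" -- too few members to support a criteria read-out.

New records are projected into the fitted space through the stored PCA basis
and UMAP transform, and assigned the mixture responsibilities at the
projected point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import BayesianGaussianMixture
from umap import UMAP

from .attribution import AttributionMatrix
from .datamodel import PairedDataset


def select_explanation_cohort(ds: PairedDataset, probs: np.ndarray,
                              cutoff: float = 0.5) -> np.ndarray:
    """Indices of records predicted positive (prob > cutoff) and not paced.

    A pure filter: the result is a subset of the input rows and reapplying it
    to the selected subset is the identity.
    """
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(ds):
        raise ValueError("probs and dataset lengths differ")
    return np.flatnonzero((probs > cutoff) & ~ds.paced)


@dataclass
class Embedding2D:
    """Fitted PCA + UMAP transform with the cohort's 2-D coordinates."""

    coords: np.ndarray
    pca: PCA
    umap: Optional[UMAP]        # None when the fitted cohort was degenerate
    pca_dims: int
    seed: int

    def transform(self, attr_rows: np.ndarray) -> np.ndarray:
        """Project new attribution vectors through the stored transforms."""
        attr_rows = np.atleast_2d(np.asarray(attr_rows, dtype=float))
        reduced = self.pca.transform(attr_rows)
        if self.umap is None:   # all fitted rows coincided; so does everything
            return np.zeros((len(reduced), 2))
        return np.asarray(self.umap.transform(reduced))


def embed(attr: AttributionMatrix, pca_dims: int = 20,
          umap_params: Optional[dict] = None, seed: int = 0) -> Embedding2D:
    """PCA to ``pca_dims`` then UMAP to 2; deterministic given ``seed``."""
    X = attr.values
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 records to embed")
    dims = int(min(pca_dims, n - 1, X.shape[1]))
    if dims < 2:
        raise ValueError("fewer than 2 usable PCA dimensions")
    params = {"n_neighbors": 15, "min_dist": 0.1}
    params.update(umap_params or {})
    params["n_neighbors"] = int(min(params["n_neighbors"], n - 1))
    pca = PCA(n_components=dims, random_state=seed)
    reduced = pca.fit_transform(X)
    if np.allclose(reduced, reduced[0], atol=1e-12):
        # degenerate cohort: identical attribution rows map to one point
        # (UMAP's repulsion would artificially spread them apart)
        return Embedding2D(np.zeros((n, 2)), pca, None, dims, seed)
    um = UMAP(n_components=2, random_state=seed, **params)
    coords = np.asarray(um.fit_transform(reduced), dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite embedding coordinates")
    return Embedding2D(coords, pca, um, dims, seed)


@dataclass
class ClusterAssignment:
    """VBGMM hard labels (argmax responsibility) over the 2-D embedding."""

    labels: np.ndarray
    responsibilities: np.ndarray
    effective_K: int
    min_cluster_size: int
    unexplained: list[int] = field(default_factory=list)
    mixture: Optional[BayesianGaussianMixture] = None
    component_order: Optional[np.ndarray] = None   # cluster id -> raw component

    def sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))

    def explained_clusters(self) -> list[int]:
        return [c for c in sorted(self.sizes()) if c not in self.unexplained]


def _fit_vbgmm(X: np.ndarray, K_max: int, seed: int, params: dict
               ) -> tuple[BayesianGaussianMixture, np.ndarray, np.ndarray]:
    bgm = BayesianGaussianMixture(n_components=K_max, random_state=seed, **params)
    bgm.fit(X)
    resp = bgm.predict_proba(X)
    return bgm, resp, np.argmax(resp, axis=1)


def _assignment(X, bgm, resp, raw, min_cluster_size) -> ClusterAssignment:
    used, counts = np.unique(raw, return_counts=True)
    order = used[np.argsort(-counts, kind="stable")]
    relabel = {int(c): i for i, c in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])
    sizes = {relabel[int(c)]: int(n) for c, n in zip(used, counts)}
    unexplained = sorted(c for c, n in sizes.items() if n < min_cluster_size)
    return ClusterAssignment(labels, resp, len(used), min_cluster_size,
                             unexplained, bgm, order)


def _single_cluster(n: int, min_cluster_size: int) -> ClusterAssignment:
    return ClusterAssignment(np.zeros(n, dtype=int), np.ones((n, 1)), 1,
                             min_cluster_size,
                             [0] if n < min_cluster_size else [],
                             None, np.array([0]))


def cluster(emb: Embedding2D, K_max: int = 10, prior: Optional[dict] = None,
            min_cluster_size: int = 10, seed: int = 0,
            min_silhouette: float = 0.5) -> ClusterAssignment:
    """Fit a VBGMM with up to ``K_max`` components to the 2-D coordinates.

    The symmetric Dirichlet weight prior (concentration 1/K_max by default)
    suppresses superfluous components; ``effective_K`` counts components that
    actually claim points under the argmax rule.  Cluster ids are relabelled
    0..effective_K-1 by decreasing size (argmax ties break toward the lower
    raw component index, matching ``np.argmax``).

    Two covariance priors are tried.  The primary fit uses the empirical
    covariance divided by K_max (the within-cluster scale expected when up to
    K_max clusters tile the embedding) with a mildly informative Wishart
    degrees-of-freedom prior: this is the scale on which genuinely distinct
    attribution clusters live, and it prevents the broad default prior from
    absorbing neighbouring clusters into one component.  Because a tight
    scale prior can also tile a diffuse unimodal cloud, the primary solution
    is accepted only when its clusters are actually separated (mean
    silhouette >= ``min_silhouette``); otherwise the fit falls back to the
    uninformative covariance prior, and if that solution is unseparated too,
    the cohort is reported as a single cluster.
    """
    X = emb.coords
    if not np.isfinite(X).all():
        raise ValueError("non-finite coordinates")
    if len(X) < K_max:
        raise ValueError("need at least K_max points")
    if np.ptp(X, axis=0).max() == 0.0:
        # zero-variance cohort: one cluster, full responsibility
        return _single_cluster(len(X), min_cluster_size)
    base = {
        "weight_concentration_prior_type": "dirichlet_distribution",
        "weight_concentration_prior": 1.0 / K_max,
        "covariance_type": "full",
        "max_iter": 2000,
        "n_init": 3,
    }
    tight = {**base,
             "covariance_prior": np.atleast_2d(np.cov(X.T)) / K_max,
             "degrees_of_freedom_prior": X.shape[1] + 3}
    tight.update(prior or {})
    bgm, resp, raw = _fit_vbgmm(X, K_max, seed, tight)
    if len(set(raw)) > 1 and silhouette_score(X, raw) < min_silhouette:
        broad = dict(base)
        broad.update(prior or {})
        bgm, resp, raw = _fit_vbgmm(X, K_max, seed, broad)
        if len(set(raw)) > 1 and silhouette_score(X, raw) < min_silhouette:
            return _single_cluster(len(X), min_cluster_size)
    return _assignment(X, bgm, resp, raw, min_cluster_size)


def project_new(emb: Embedding2D, attr_row: np.ndarray, ca: ClusterAssignment
                ) -> tuple[np.ndarray, int, float]:
    """Project one attribution vector; return (coords, nearest cluster, responsibility)."""
    attr_row = np.asarray(attr_row, dtype=float).ravel()
    if attr_row.size != emb.pca.n_features_in_:
        raise ValueError("attribution vector length does not match the fitted space")
    coords = emb.transform(attr_row[None, :])[0]
    if ca.mixture is None:      # degenerate single-cluster assignment
        return coords, 0, 1.0
    resp = ca.mixture.predict_proba(coords[None, :])[0]
    raw = int(np.argmax(resp))
    order = list(ca.component_order)
    label = order.index(raw) if raw in order else -1
    return coords, label, float(resp[raw])
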