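"""Heterogeneous global graph: supplementation, block assembly, propagation.

The global association graph stacks A-side similarity, B-side similarity
and the (optionally supplemented) bipartite association matrix into one
block adjacency

    A_g = [[S_p, A_s],
           [A_s.T, S_d]]

whose symmetric-normalised propagation matrix
``P_hat = D^{-1/2} (I + A_g) D^{-1/2}`` drives the global GCN.  Because
known associations are sparse, the bipartite block may first be enriched
with supplementary weighted edges: an ensemble of simple base classifiers
scores every unknown pair from similarity-profile features, and pairs
passing the rule enter A_s with their mean score as edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB

from .io import SupplementConfig

__all__ = [
    "GlobalGraph",
    "VariantAdjacency",
    "supplement_associations",
    "build_global_graph",
    "variant_adjacency",
]


@dataclass
class GlobalGraph:
    """Block adjacency of the heterogeneous graph and its propagation matrix."""

    S_p: np.ndarray
    S_d: np.ndarray
    A_s: np.ndarray
    A_g: np.ndarray
    P_hat: np.ndarray

    @property
    def m(self) -> int:
        return self.S_p.shape[0]

    @property
    def n(self) -> int:
        return self.S_d.shape[0]


@dataclass
class VariantAdjacency:
    """Regression target for the global module: alpha on training positives, else 0."""

    A_prime: np.ndarray
    alpha: float


def _base_predictor(family: int, seed: int):
    if family == 0:
        return LogisticRegression(max_iter=1000, random_state=seed)
    if family == 1:
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    return GaussianNB()


def supplement_associations(
    A: np.ndarray,
    S_p: np.ndarray,
    S_d: np.ndarray,
    config: SupplementConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Add supplementary weighted edges to a sparse bipartite adjacency.

    ``n_base`` base predictors (classifier families cycled over independently
    resampled balanced training sets) are trained to separate known positives
    from sampled unknown pairs; each pair's feature vector concatenates its
    A-side and B-side similarity-profile rows.  Every unknown pair is scored
    by all predictors and the mean score becomes its edge weight when it
    passes the supplementation rule (threshold / top_k / all).  Known edges
    are preserved as exact 1s.  ``n_base = 0`` disables supplementation.
    """
    config = config or SupplementConfig()
    A = np.asarray(A)
    m, n = A.shape
    A_s = A.astype(float).copy()
    if config.n_base == 0:
        return A_s

    pos = np.argwhere(A == 1)
    unk = np.argwhere(A == 0)
    if len(pos) == 0:
        raise ValueError("no known positives: cannot train base predictors")
    if len(unk) == 0:
        return A_s
    if len(unk) < len(pos):
        raise ValueError(
            "fewer unknown pairs than positives; reduce the ensemble or supply more pairs"
        )

    def features(pairs: np.ndarray) -> np.ndarray:
        return np.hstack([S_p[pairs[:, 0]], S_d[pairs[:, 1]]])

    X_pos = features(pos)
    X_unk = features(unk)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(pos))])

    rng = np.random.default_rng(seed)
    n_families = 3
    scores = np.zeros(len(unk))
    for i in range(config.n_base):
        neg_idx = rng.choice(len(unk), size=len(pos), replace=False)
        X = np.vstack([X_pos, X_unk[neg_idx]])
        clf = _base_predictor(i % n_families, int(rng.integers(2**31)))
        clf.fit(X, y)
        scores += clf.predict_proba(X_unk)[:, 1]
    scores /= config.n_base

    if config.mode == "threshold":
        keep = scores >= config.threshold
    elif config.mode == "top_k":
        keep = np.zeros(len(unk), dtype=bool)
        keep[np.argsort(-scores, kind="stable")[: config.top_k]] = True
    else:  # "all"
        keep = np.ones(len(unk), dtype=bool)
    A_s[unk[keep, 0], unk[keep, 1]] = scores[keep]
    return A_s


def build_global_graph(S_p: np.ndarray, S_d: np.ndarray, A_s: np.ndarray) -> GlobalGraph:
    """Assemble the block adjacency and its symmetric-normalised propagation.

    ``P_hat = D^{-1/2} (I + A_g) D^{-1/2}`` with ``D(i,i)`` the row sum of
    ``I + A_g``; the added self-loop keeps every degree positive.
    """
    S_p = np.asarray(S_p, dtype=float)
    S_d = np.asarray(S_d, dtype=float)
    A_s = np.asarray(A_s, dtype=float)
    m, n = A_s.shape
    if S_p.shape != (m, m) or S_d.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: S_p {S_p.shape}, S_d {S_d.shape}, A_s {A_s.shape}"
        )
    A_g = np.block([[S_p, A_s], [A_s.T, S_d]])
    A_tilde = A_g + np.eye(m + n)
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    P_hat = A_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)
    return GlobalGraph(S_p=S_p, S_d=S_d, A_s=A_s, A_g=A_g, P_hat=P_hat)


def variant_adjacency(
    A: np.ndarray,
    withheld_pairs: np.ndarray | list[tuple[int, int]],
    alpha: float = 1.0,
) -> VariantAdjacency:
    """Target matrix for the global fit: 0 on withheld pairs and unknowns, alpha on training positives."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    A = np.asarray(A)
    A_prime = np.where(A == 1, alpha, 0.0)
    withheld = np.asarray(list(withheld_pairs), dtype=int).reshape(-1, 2)
    if len(withheld):
        A_prime[withheld[:, 0], withheld[:, 1]] = 0.0
    return VariantAdjacency(A_prime=A_prime, alpha=alpha)
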