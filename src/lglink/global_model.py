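"""Global-level GCN scorer over the heterogeneous graph.

Pipeline: random-walk-with-restart attribute features per side pass through
per-side dense encoders into a common embedding, an L-layer GCN propagates
them over the symmetric-normalised heterogeneous graph

    H^l = ReLU(P_hat @ H^{l-1} @ W^{l-1}),

a three-layer dense head (400/200/100 units) refines the node embeddings,
and a pair score is the inner product of the refined A-side and B-side
vectors.  Training minimises the variant mean-square objective

    ||A' - Y||_F^2 + mu * ||W||_2^2

where A' is alpha on training positives and 0 elsewhere (withheld pairs
contribute a 0 target by construction), so the model regresses the full
score matrix at once.  Gradients are exact hand-derived backprop; the
optimizer is full-batch Adam.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, drelu, glorot, relu
from .global_graph import build_global_graph, supplement_associations, variant_adjacency
from .io import SimilarityMatrix, SupplementConfig
from .similarity import rwr_features

__all__ = ["gcn_forward", "global_scores", "global_loss", "GlobalGCNScorer"]


def gcn_forward(P_hat: np.ndarray, H0: np.ndarray, W_gcn: list[np.ndarray]) -> np.ndarray:
    """Stack of symmetric-normalised propagation layers with ReLU."""
    if H0.shape[0] != P_hat.shape[0]:
        raise ValueError(
            f"H0 has {H0.shape[0]} rows but P_hat is {P_hat.shape[0]}x{P_hat.shape[1]}"
        )
    H = H0
    for W in W_gcn:
        if H.shape[1] != W.shape[0]:
            raise ValueError(f"layer dim mismatch: H {H.shape} vs W {W.shape}")
        H = relu(P_hat @ H @ W)
    return H


def global_scores(H_dense: np.ndarray, m: int) -> np.ndarray:
    """Inner-product score matrix Y[p, d] = h'_p . h'_d from stacked embeddings."""
    H_p, H_d = H_dense[:m], H_dense[m:]
    return H_p @ H_d.T


def global_loss(
    A_prime: np.ndarray,
    Y_global: np.ndarray,
    weights: list[np.ndarray] | None = None,
    mu: float = 0.0,
) -> float:
    """Variant MSE: squared Frobenius data term plus mu * sum of squared weights."""
    if A_prime.shape != Y_global.shape:
        raise ValueError(f"shape mismatch {A_prime.shape} vs {Y_global.shape}")
    loss = float(((A_prime - Y_global) ** 2).sum())
    if mu and weights:
        loss += mu * sum(float((W**2).sum()) for W in weights)
    return loss


def _as_matrix(S) -> np.ndarray:
    return S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)


class GlobalGCNScorer(BaseEstimator):
    """Scores bipartite pairs from the global heterogeneous graph.

    Parameters
    ----------
    S_p, S_d : SimilarityMatrix or array
        A-side and B-side similarity matrices (side information).
    supplement : SupplementConfig, dict or None
        Base-predictor ensemble adding weighted edges to the sparse
        bipartite block; None disables supplementation.
    alpha : float
        Target value for training positives in the variant adjacency.
    mu : float
        L2 decay factor on all trainable weight matrices.

    ``fit(X, y)`` takes an (n_pairs, 2) array of (p, d) indices with 0/1
    labels; only the positives shape the graph and the regression target,
    so withheld (validation/independent) positives simply stay out of X.
    After fitting, ``scores_`` holds the full m x n score matrix and
    ``decision_function(X)`` indexes into it.
    """

    def __init__(
        self,
        S_p=None,
        S_d=None,
        supplement=None,
        alpha: float = 1.0,
        mu: float = 1e-4,
        epochs: int = 1000,
        lr: float = 0.001,
        n_layers: int = 2,
        embed_dim: int = 128,
        dense_dims: tuple[int, ...] = (400, 200, 100),
        rwr_restart: float = 0.9,
        patience: int | None = None,
        min_rel_improvement: float = 1e-6,
        random_state: int = 0,
    ):
        self.S_p = S_p
        self.S_d = S_d
        self.supplement = supplement
        self.alpha = alpha
        self.mu = mu
        self.epochs = epochs
        self.lr = lr
        self.n_layers = n_layers
        self.embed_dim = embed_dim
        self.dense_dims = dense_dims
        self.rwr_restart = rwr_restart
        self.patience = patience
        self.min_rel_improvement = min_rel_improvement
        self.random_state = random_state

    # -- forward/backward -------------------------------------------------

    def _forward(self, params, P_hat, F_p, F_d, m):
        cache = {}
        Z0p = F_p @ params["enc_p"] + params["enc_p_b"]
        Z0d = F_d @ params["enc_d"] + params["enc_d_b"]
        Z0 = np.vstack([Z0p, Z0d])
        H = relu(Z0)
        cache["Z0"], cache["H0"] = Z0, H
        for l in range(self.n_layers):
            Zl = P_hat @ H @ params[f"gcn_{l}"]
            H = relu(Zl)
            cache[f"Zg{l}"], cache[f"Hg{l}"] = Zl, H
        A_prev = H
        n_dense = len(self.dense_dims)
        for l in range(n_dense):
            Z = A_prev @ params[f"dense_{l}"] + params[f"dense_{l}_b"]
            A_prev = relu(Z) if l < n_dense - 1 else Z
            cache[f"Zd{l}"], cache[f"Ad{l}"] = Z, A_prev
        Y = global_scores(A_prev, m)
        cache["H_dense"] = A_prev
        return Y, cache

    def _backward(self, params, cache, P_hat, F_p, F_d, A_prime, Y, m):
        grads = {}
        dY = 2.0 * (Y - A_prime)
        H_dense = cache["H_dense"]
        H_p, H_d = H_dense[:m], H_dense[m:]
        dH = np.vstack([dY @ H_d, dY.T @ H_p])
        n_dense = len(self.dense_dims)
        for l in reversed(range(n_dense)):
            dZ = dH if l == n_dense - 1 else dH * drelu(cache[f"Zd{l}"])
            A_in = cache[f"Hg{self.n_layers - 1}"] if l == 0 else cache[f"Ad{l - 1}"]
            grads[f"dense_{l}"] = A_in.T @ dZ
            grads[f"dense_{l}_b"] = dZ.sum(axis=0)
            dH = dZ @ params[f"dense_{l}"].T
        for l in reversed(range(self.n_layers)):
            dZ = dH * drelu(cache[f"Zg{l}"])
            H_in = cache["H0"] if l == 0 else cache[f"Hg{l - 1}"]
            grads[f"gcn_{l}"] = (P_hat @ H_in).T @ dZ
            dH = P_hat.T @ dZ @ params[f"gcn_{l}"].T
        dZ0 = dH * drelu(cache["Z0"])
        grads["enc_p"] = F_p.T @ dZ0[:m]
        grads["enc_p_b"] = dZ0[:m].sum(axis=0)
        grads["enc_d"] = F_d.T @ dZ0[m:]
        grads["enc_d_b"] = dZ0[m:].sum(axis=0)
        if self.mu:
            for k in params:
                if not k.endswith("_b"):
                    grads[k] = grads[k] + 2.0 * self.mu * params[k]
        return grads

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=int)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n_pairs, 2) array of (p, d) indices")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        S_p = _as_matrix(self.S_p)
        S_d = _as_matrix(self.S_d)
        m, n = S_p.shape[0], S_d.shape[0]
        if X[:, 0].max(initial=0) >= m or X[:, 1].max(initial=0) >= n:
            raise ValueError("pair index outside similarity-matrix dimensions")

        A_train = np.zeros((m, n), dtype=np.int8)
        pos = X[y == 1]
        if len(pos) == 0:
            raise ValueError("no training positives")
        A_train[pos[:, 0], pos[:, 1]] = 1

        supp = self.supplement
        if isinstance(supp, dict):
            supp = SupplementConfig(**supp)
        if supp is not None and supp.n_base > 0:
            A_s = supplement_associations(A_train, S_p, S_d, supp, seed=self.random_state)
        else:
            A_s = A_train.astype(float)
        graph = build_global_graph(S_p, S_d, A_s)
        self.graph_ = graph

        A_prime = variant_adjacency(A_train, [], alpha=self.alpha).A_prime
        F_p = rwr_features(S_p, restart=self.rwr_restart).F
        F_d = rwr_features(S_d, restart=self.rwr_restart).F

        rng = np.random.default_rng(self.random_state)
        k = self.embed_dim
        params: dict[str, np.ndarray] = {
            "enc_p": glorot(rng, m, k),
            "enc_p_b": np.zeros(k),
            "enc_d": glorot(rng, n, k),
            "enc_d_b": np.zeros(k),
        }
        for l in range(self.n_layers):
            params[f"gcn_{l}"] = glorot(rng, k, k)
        dims = (k, *self.dense_dims)
        for l in range(len(self.dense_dims)):
            params[f"dense_{l}"] = glorot(rng, dims[l], dims[l + 1])
            params[f"dense_{l}_b"] = np.zeros(dims[l + 1])

        opt = Adam(params, lr=self.lr)
        P_hat = graph.P_hat
        history: list[float] = []
        best = np.inf
        stale = 0
        for _ in range(self.epochs):
            Y, cache = self._forward(params, P_hat, F_p, F_d, m)
            weights = [v for kk, v in params.items() if not kk.endswith("_b")]
            loss = global_loss(A_prime, Y, weights, self.mu)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite global training loss; lower the learning rate")
            history.append(loss)
            grads = self._backward(params, cache, P_hat, F_p, F_d, A_prime, Y, m)
            opt.step(params, grads)
            if self.patience is not None:
                if loss < best * (1.0 - self.min_rel_improvement):
                    best, stale = loss, 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        Y, _ = self._forward(params, P_hat, F_p, F_d, m)
        self.params_ = params
        self.loss_history_ = np.asarray(history)
        self.scores_ = Y
        self.A_train_ = A_train
        self.n_features_in_ = 2
        return self

    def decision_function(self, X):
        check_is_fitted(self, "scores_")
        X = np.asarray(X, dtype=int)
        return self.scores_[X[:, 0], X[:, 1]]

    def predict(self, X):
        s = self.decision_function(X)
        lo, hi = s.min(), s.max()
        scaled = (s - lo) / (hi - lo) if hi > lo else np.full_like(s, 0.5)
        return (scaled >= 0.5).astype(int)
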