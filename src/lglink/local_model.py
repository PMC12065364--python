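"""Local-level message-passing scorer over enclosing subgraphs.

Each candidate pair is encoded as its h-hop enclosing subgraph with one-hot
hop/type labels as initial node features.  L message-passing layers

    x_i^l = tanh(W1 x_i^{l-1} + sum_{j in N(i)} x_j^{l-1} W2)

are concatenated per node, the two core nodes are concat-pooled into the
pair representation, and a small MLP (hidden 128, output 1, no output
squashing) produces the association score.  Training minimises mean-square
error against 0/1 labels with mini-batch Adam; backprop is hand-derived.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, drelu, glorot, relu
from .local_graph import (
    LocalGraph,
    bipartite_neighbors,
    encode_labels,
    extract_enclosing_subgraph,
    label_nodes,
)

__all__ = [
    "local_layer",
    "node_representation",
    "pool_pair",
    "mlp_score",
    "LocalSubgraphScorer",
]


def local_layer(
    X_prev: np.ndarray,
    edges: list[tuple[int, int]] | np.ndarray,
    W1: np.ndarray,
    W2: np.ndarray,
) -> np.ndarray:
    """One tanh message-passing layer; isolated nodes use only the self term."""
    X_prev = np.asarray(X_prev)
    n = X_prev.shape[0]
    adj = np.zeros((n, n))
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i}, {j}) references unknown node (n={n})")
        adj[i, j] = adj[j, i] = 1.0
    return np.tanh(X_prev @ W1 + adj @ X_prev @ W2)


def node_representation(layer_outputs: list[np.ndarray]) -> np.ndarray:
    """Concatenate the L per-layer node embeddings into the final representation."""
    n_nodes = {X.shape[0] for X in layer_outputs}
    if len(n_nodes) != 1:
        raise ValueError("layer outputs disagree on node count")
    return np.concatenate(layer_outputs, axis=1)


def pool_pair(local_graph: LocalGraph, node_reprs: np.ndarray) -> np.ndarray:
    """Concat-pool only the two core nodes into the pair feature vector."""
    if not (0 <= local_graph.core_a < len(node_reprs)) or not (
        0 <= local_graph.core_b < len(node_reprs)
    ):
        raise ValueError("core node index outside node representation matrix")
    return np.concatenate([node_reprs[local_graph.core_a], node_reprs[local_graph.core_b]])


def mlp_score(X_pairs: np.ndarray, mlp: dict[str, np.ndarray]) -> np.ndarray:
    """Two-layer perceptron score: W2 @ ReLU(W1 x + b1) + b2, unsquashed."""
    X_pairs = np.atleast_2d(X_pairs)
    hidden = relu(X_pairs @ mlp["W1"] + mlp["b1"])
    return (hidden @ mlp["W2"] + mlp["b2"]).ravel()


class LocalSubgraphScorer(BaseEstimator):
    """Scores pairs from their h-hop enclosing subgraphs.

    ``fit(X, y)`` receives (n_pairs, 2) index pairs with 0/1 labels.  The
    training-visible bipartite graph is built from the positive pairs in X
    only, so withheld positives never appear in any extracted subgraph.
    ``n_a``/``n_b`` fix the bipartite dimensions; left as None they are
    inferred from the largest index seen in fit.
    """

    def __init__(
        self,
        h: int = 2,
        n_layers: int = 2,
        width: int = 32,
        mlp_hidden: int = 128,
        epochs: int = 20,
        lr: float = 0.001,
        batch_size: int = 50,
        n_a: int | None = None,
        n_b: int | None = None,
        random_state: int = 0,
    ):
        self.h = h
        self.n_layers = n_layers
        self.width = width
        self.mlp_hidden = mlp_hidden
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.n_a = n_a
        self.n_b = n_b
        self.random_state = random_state

    # -- per-subgraph forward/backward ------------------------------------

    def _prepare(self, pairs: np.ndarray):
        """Extract subgraphs and cache (X0, adjacency, core positions)."""
        out = []
        for p, d in pairs:
            g = extract_enclosing_subgraph(self.A_vis_, int(p), int(d), self.h, self.nbrs_)
            X0 = encode_labels(label_nodes(g), self.h)
            out.append((X0, g.adjacency(), g.core_a, g.core_b))
        return out

    def _forward_one(self, item, params):
        X0, adj, ca, cb = item
        Xs, Ss = [X0], []
        for l in range(self.n_layers):
            S = Xs[-1] @ params[f"W1_{l}"] + adj @ Xs[-1] @ params[f"W2_{l}"]
            Xs.append(np.tanh(S))
            Ss.append(S)
        reprs = node_representation(Xs[1:])
        x_pair = np.concatenate([reprs[ca], reprs[cb]])
        hidden_pre = x_pair @ params["W1"] + params["b1"]
        hidden = relu(hidden_pre)
        y = float((hidden @ params["W2"] + params["b2"])[0])
        return y, (Xs, adj, ca, cb, x_pair, hidden_pre, hidden)

    def _backward_one(self, cache, params, dy, grads):
        Xs, adj, ca, cb, x_pair, hidden_pre, hidden = cache
        grads["b2"] += dy
        grads["W2"] += dy * hidden[:, None]
        dhidden = dy * params["W2"].ravel() * drelu(hidden_pre)
        grads["b1"] += dhidden
        grads["W1"] += np.outer(x_pair, dhidden)
        dx_pair = params["W1"] @ dhidden
        w = self.width
        L = self.n_layers
        # scatter pair-feature gradient back to the per-layer core rows
        dX_layers = [np.zeros_like(Xs[l + 1]) for l in range(L)]
        for l in range(L):
            dX_layers[l][ca] += dx_pair[l * w : (l + 1) * w]
            dX_layers[l][cb] += dx_pair[L * w + l * w : L * w + (l + 1) * w]
        dX_next = None
        for l in reversed(range(L)):
            dX = dX_layers[l] if dX_next is None else dX_layers[l] + dX_next
            dS = dX * (1.0 - Xs[l + 1] ** 2)
            grads[f"W1_{l}"] += Xs[l].T @ dS
            grads[f"W2_{l}"] += (adj @ Xs[l]).T @ dS
            dX_next = dS @ params[f"W1_{l}"].T + adj.T @ dS @ params[f"W2_{l}"].T
        return grads

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=int)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n_pairs, 2) array of (p, d) indices")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not (y == 1).any():
            raise ValueError("no training positives")
        m = self.n_a if self.n_a is not None else int(X[:, 0].max()) + 1
        n = self.n_b if self.n_b is not None else int(X[:, 1].max()) + 1
        A_vis = np.zeros((m, n), dtype=np.int8)
        pos = X[y == 1]
        A_vis[pos[:, 0], pos[:, 1]] = 1
        self.A_vis_ = A_vis
        self.nbrs_ = bipartite_neighbors(A_vis)

        rng = np.random.default_rng(self.random_state)
        in_dim = 2 * self.h + 2
        w = self.width
        params: dict[str, np.ndarray] = {}
        dims = [in_dim] + [w] * self.n_layers
        for l in range(self.n_layers):
            params[f"W1_{l}"] = glorot(rng, dims[l], dims[l + 1])
            params[f"W2_{l}"] = glorot(rng, dims[l], dims[l + 1])
        pair_dim = 2 * self.n_layers * w
        params["W1"] = glorot(rng, pair_dim, self.mlp_hidden)
        params["b1"] = np.zeros(self.mlp_hidden)
        params["W2"] = glorot(rng, self.mlp_hidden, 1)
        params["b2"] = np.zeros(1)

        items = self._prepare(X)
        opt = Adam(params, lr=self.lr)
        order = np.arange(len(items))
        history = []
        for _ in range(self.epochs):
            rng_epoch = rng  # single stream: reshuffle each epoch, deterministic
            rng_epoch.shuffle(order)
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                grads = {k: np.zeros_like(v) for k, v in params.items()}
                for idx in batch:
                    pred, cache = self._forward_one(items[idx], params)
                    err = pred - y[idx]
                    epoch_loss += err * err
                    self._backward_one(cache, params, 2.0 * err / len(batch), grads)
                opt.step(params, grads)
            loss = epoch_loss / len(order)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite local training loss; lower the learning rate")
            history.append(loss)
        self.params_ = params
        self.loss_history_ = np.asarray(history)
        self.n_features_in_ = 2
        return self

    def decision_function(self, X):
        """Score pairs by extracting their subgraphs from the training-visible graph."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=int)
        items = self._prepare(X)
        return np.array([self._forward_one(it, self.params_)[0] for it in items])

    def predict(self, X):
        s = self.decision_function(X)
        lo, hi = s.min(), s.max()
        scaled = (s - lo) / (hi - lo) if hi > lo else np.full_like(s, 0.5)
        return (scaled >= 0.5).astype(int)
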