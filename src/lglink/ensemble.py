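"""Dataset partitioning, score fusion, metrics, and evaluation protocols.

The splitting protocol mirrors the benchmark construction used for sparse
bipartite association data: the known positives of each B-side entity
(disease) are folded five ways in input order; one fold pooled over all
diseases forms the independent positives, the rest are re-folded into
train/validation; each positive set is paired with an equal number of
negatives sampled uniformly without replacement from the unknown pairs,
disjoint across the three sets.

The final association score of a pair fuses the global and local module
scores with a convex coefficient delta:

    y_fused = delta * y_global + (1 - delta) * y_local.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ranksums
from sklearn.base import BaseEstimator
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .global_model import GlobalGCNScorer
from .io import AssociationSet, Config, ScoreSet, SimilarityMatrix
from .local_model import LocalSubgraphScorer

__all__ = [
    "SplitSpec",
    "MetricReport",
    "make_splits",
    "fuse_scores",
    "compute_metrics",
    "LocalGlobalEnsemble",
    "repeated_partition_eval",
    "leave_one_disease_out",
    "compare_methods",
]

_DELTA_GRID = np.round(np.arange(0.0, 1.01, 0.1), 1)


@dataclass
class SplitSpec:
    """Indexed positive/negative pairs for train / validation / independent sets."""

    train_pos: np.ndarray
    train_neg: np.ndarray
    validation_pos: np.ndarray
    validation_neg: np.ndarray
    independent_pos: np.ndarray
    independent_neg: np.ndarray
    seed: int

    def _sets(self):
        return {
            "train_pos": self.train_pos,
            "train_neg": self.train_neg,
            "validation_pos": self.validation_pos,
            "validation_neg": self.validation_neg,
            "independent_pos": self.independent_pos,
            "independent_neg": self.independent_neg,
        }

    @staticmethod
    def _xy(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.vstack([pos.reshape(-1, 2), neg.reshape(-1, 2)])
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        return X, y

    def train_xy(self):
        return self._xy(self.train_pos, self.train_neg)

    def validation_xy(self):
        return self._xy(self.validation_pos, self.validation_neg)

    def independent_xy(self):
        return self._xy(self.independent_pos, self.independent_neg)


@dataclass
class MetricReport:
    """AUC/AUPR plus thresholded binary metrics at a stated threshold."""

    auc: float
    aupr: float
    f1: float
    acc: float
    pre: float
    spe: float
    sen: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "f1": self.f1,
            "acc": self.acc,
            "pre": self.pre,
            "spe": self.spe,
            "sen": self.sen,
            "threshold": self.threshold,
        }


def make_splits(
    association_set: AssociationSet, seed: int, n_folds: int = 5
) -> SplitSpec:
    """Per-disease sequential folding into train / validation / independent sets.

    Each disease's positives are folded in input order (fold = position mod
    n_folds); the independent fold and the validation fold of the re-folded
    benchmark positives are chosen by the seeded rng, as is the negative
    sampling, so repeated calls with fresh seeds realise the repeated random
    partitioning of the evaluation protocol.  Deterministic per seed.
    """
    A = association_set.A
    m, n = A.shape
    rng = np.random.default_rng(seed)
    indep_fold = int(rng.integers(n_folds))
    val_fold = int(rng.integers(n_folds))

    independent_pos: list[np.ndarray] = []
    benchmark_pos: list[np.ndarray] = []
    for d in range(n):
        rows = np.flatnonzero(A[:, d] == 1)
        if len(rows) == 0:
            continue
        folds = np.arange(len(rows)) % n_folds
        independent_pos.append(np.column_stack([rows[folds == indep_fold], np.full((folds == indep_fold).sum(), d)]))
        benchmark_pos.append(np.column_stack([rows[folds != indep_fold], np.full((folds != indep_fold).sum(), d)]))
    indep = np.vstack(independent_pos) if independent_pos else np.empty((0, 2), dtype=int)
    bench = np.vstack(benchmark_pos) if benchmark_pos else np.empty((0, 2), dtype=int)
    if len(bench) == 0:
        raise ValueError("no benchmark positives left after independent folding")

    bench_folds = np.arange(len(bench)) % n_folds
    validation_pos = bench[bench_folds == val_fold]
    train_pos = bench[bench_folds != val_fold]
    if len(train_pos) == 0:
        raise ValueError("no training positives; too few known associations")

    n_neg = len(train_pos) + len(validation_pos) + len(indep)
    zeros = np.flatnonzero(A.ravel() == 0)
    if len(zeros) < n_neg:
        raise ValueError(
            f"need {n_neg} negatives but only {len(zeros)} unknown pairs exist"
        )
    chosen = rng.choice(zeros, size=n_neg, replace=False)
    neg = np.column_stack(np.unravel_index(chosen, (m, n)))
    train_neg = neg[: len(train_pos)]
    validation_neg = neg[len(train_pos) : len(train_pos) + len(validation_pos)]
    independent_neg = neg[len(train_pos) + len(validation_pos) :]
    return SplitSpec(
        train_pos=train_pos.astype(int),
        train_neg=train_neg.astype(int),
        validation_pos=validation_pos.astype(int),
        validation_neg=validation_neg.astype(int),
        independent_pos=indep.astype(int),
        independent_neg=independent_neg.astype(int),
        seed=seed,
    )


def fuse_scores(y_global: np.ndarray, y_local: np.ndarray, delta: float) -> np.ndarray:
    """Convex fusion delta * y_global + (1 - delta) * y_local."""
    y_global = np.asarray(y_global, dtype=float)
    y_local = np.asarray(y_local, dtype=float)
    if y_global.shape != y_local.shape:
        raise ValueError("misaligned global/local score arrays")
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    return delta * y_global + (1.0 - delta) * y_local


def _minmax(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi <= lo:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> MetricReport:
    """Ranking metrics (AUC, AUPR) plus thresholded binary metrics.

    The threshold applies to min-max-rescaled scores.  With single-class
    labels AUC/AUPR are undefined: they are returned as NaN with a warning
    while the thresholded metrics are still computed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUC/AUPR undefined (NaN)", stacklevel=2)
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    pred = (_minmax(scores) >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return MetricReport(auc=auc, aupr=aupr, f1=f1, acc=acc, pre=pre, spe=spe, sen=sen,
                        threshold=threshold)


class LocalGlobalEnsemble(BaseEstimator):
    """Fuses a global GCN scorer and a local subgraph scorer.

    ``delta`` may be a number in [0, 1] or "auto", in which case fit
    sweeps {0, 0.1, ..., 1} and keeps the value maximising validation AUC
    (validation pairs must then be passed to fit).  Fitted attributes:
    ``global_``, ``local_``, ``delta_``.
    """

    def __init__(
        self,
        S_p=None,
        S_d=None,
        config: Config | None = None,
        delta: float | str | None = None,
        random_state: int | None = None,
    ):
        self.S_p = S_p
        self.S_d = S_d
        self.config = config
        self.delta = delta
        self.random_state = random_state

    def _resolved(self):
        cfg = self.config or Config()
        delta = self.delta if self.delta is not None else cfg.delta
        seed = self.random_state if self.random_state is not None else cfg.seed
        return cfg, delta, seed

    def fit(self, X, y, X_val=None, y_val=None):
        cfg, delta, seed = self._resolved()
        S_p = self.S_p.S if isinstance(self.S_p, SimilarityMatrix) else np.asarray(self.S_p)
        S_d = self.S_d.S if isinstance(self.S_d, SimilarityMatrix) else np.asarray(self.S_d)
        self.global_ = GlobalGCNScorer(
            S_p=S_p,
            S_d=S_d,
            supplement=cfg.supplement,
            alpha=cfg.alpha,
            mu=cfg.mu,
            epochs=cfg.epochs_global,
            lr=cfg.lr_global,
            n_layers=cfg.n_layers_global,
            embed_dim=cfg.embed_dim,
            dense_dims=tuple(cfg.dense_dims),
            rwr_restart=cfg.rwr_restart,
            random_state=seed,
        ).fit(X, y)
        self.local_ = LocalSubgraphScorer(
            h=cfg.h,
            n_layers=cfg.n_layers_local,
            width=cfg.local_width,
            mlp_hidden=cfg.mlp_hidden,
            epochs=cfg.epochs_local,
            lr=cfg.lr_local,
            batch_size=cfg.batch_size,
            n_a=S_p.shape[0],
            n_b=S_d.shape[0],
            random_state=seed + 1,
        ).fit(X, y)

        if delta == "auto":
            if X_val is None or y_val is None:
                raise ValueError("delta='auto' requires validation pairs")
            yg = self.global_.decision_function(X_val)
            yl = self.local_.decision_function(X_val)
            aucs = [
                roc_auc_score(y_val, fuse_scores(yg, yl, float(dd)))
                for dd in _DELTA_GRID
            ]
            self.delta_ = float(_DELTA_GRID[int(np.argmax(aucs))])
            self.delta_sweep_ = dict(zip(_DELTA_GRID.tolist(), map(float, aucs)))
        else:
            self.delta_ = float(delta)
        self.n_features_in_ = 2
        return self

    def decision_function(self, X):
        check_is_fitted(self, "delta_")
        return fuse_scores(
            self.global_.decision_function(X),
            self.local_.decision_function(X),
            self.delta_,
        )

    def predict(self, X):
        s = self.decision_function(X)
        return (_minmax(s) >= 0.5).astype(int)

    def score_set(self, X, a_ids: list[str], b_ids: list[str]) -> ScoreSet:
        """Full per-pair score record for writing to disk."""
        X = np.asarray(X, dtype=int)
        yg = self.global_.decision_function(X)
        yl = self.local_.decision_function(X)
        return ScoreSet(
            pairs=[(a_ids[p], b_ids[d]) for p, d in X],
            y_global=yg,
            y_local=yl,
            y_fused=fuse_scores(yg, yl, self.delta_),
            delta=self.delta_,
        )


def evaluate_split(
    association_set: AssociationSet,
    S_p,
    S_d,
    config: Config,
    splits: SplitSpec,
    seed: int,
) -> dict:
    """Train both modules on one split and evaluate on the independent set."""
    model = LocalGlobalEnsemble(S_p=S_p, S_d=S_d, config=config, random_state=seed)
    X_tr, y_tr = splits.train_xy()
    X_val, y_val = splits.validation_xy()
    model.fit(X_tr, y_tr, X_val=X_val, y_val=y_val)
    X_ind, y_ind = splits.independent_xy()
    yg = model.global_.decision_function(X_ind)
    yl = model.local_.decision_function(X_ind)
    yf = fuse_scores(yg, yl, model.delta_)
    return {
        "seed": seed,
        "delta": model.delta_,
        "global": compute_metrics(yg, y_ind),
        "local": compute_metrics(yl, y_ind),
        "fused": compute_metrics(yf, y_ind),
        "model": model,
        "labels": y_ind,
        "scores": {"global": yg, "local": yl, "fused": yf},
    }


def repeated_partition_eval(
    association_set: AssociationSet,
    S_p,
    S_d,
    config: Config | None = None,
    n_repeats: int = 5,
    base_seed: int = 0,
) -> dict:
    """Repeat the partition/train/evaluate cycle and aggregate metrics.

    Repeat r uses seed base_seed + r for both the split and the model;
    returns per-repeat MetricReports for the global, local and fused
    scorers plus their means.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    per_repeat = []
    for r in range(n_repeats):
        seed = base_seed + r
        splits = make_splits(association_set, seed=seed)
        per_repeat.append(
            evaluate_split(association_set, S_p, S_d, config or Config(), splits, seed)
        )
    means = {}
    for kind in ("global", "local", "fused"):
        reports = [rep[kind].as_dict() for rep in per_repeat]
        means[kind] = {
            k: float(np.mean([rp[k] for rp in reports])) for k in reports[0]
        }
    return {"per_repeat": per_repeat, "means": means, "base_seed": base_seed}


def leave_one_disease_out(
    association_set: AssociationSet,
    S_p,
    S_d,
    config: Config | None = None,
    base_seed: int = 0,
) -> dict:
    """Leave-one-disease-out cross-validation.

    For each disease all its known associations are withheld; the model
    trains on the remaining diseases' positives plus an equal number of
    sampled unknowns (excluding the held-out disease's column), then scores
    the held-out disease's positives against an equal number of its unknown
    pairs.  delta='auto' is replaced by the config's numeric default (no
    validation set exists in this protocol).
    """
    A = association_set.A
    m, n = A.shape
    if n < 2:
        raise ValueError("leave-one-disease-out needs at least 2 diseases")
    cfg = config or Config()
    delta = 0.5 if cfg.delta == "auto" else float(cfg.delta)
    per_disease = {}
    for t in range(n):
        test_pos_rows = np.flatnonzero(A[:, t] == 1)
        if len(test_pos_rows) == 0:
            warnings.warn(f"disease {t} has no positives; skipped", stacklevel=2)
            continue
        rng = np.random.default_rng(base_seed + t)
        train_pos = association_set.positive_pairs()
        train_pos = train_pos[train_pos[:, 1] != t]
        if len(train_pos) == 0:
            warnings.warn(f"no training positives outside disease {t}; skipped", stacklevel=2)
            continue
        # training negatives: unknown pairs of the other diseases
        mask = A == 0
        mask[:, t] = False
        zeros = np.argwhere(mask)
        neg_idx = rng.choice(len(zeros), size=min(len(train_pos), len(zeros)), replace=False)
        train_neg = zeros[neg_idx]
        X_tr = np.vstack([train_pos, train_neg])
        y_tr = np.concatenate([np.ones(len(train_pos)), np.zeros(len(train_neg))])

        test_pos = np.column_stack([test_pos_rows, np.full(len(test_pos_rows), t)])
        t_zeros = np.flatnonzero(A[:, t] == 0)
        k = min(len(test_pos), len(t_zeros))
        test_neg_rows = rng.choice(t_zeros, size=k, replace=False)
        test_neg = np.column_stack([test_neg_rows, np.full(k, t)])
        X_te = np.vstack([test_pos, test_neg])
        y_te = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])

        model = LocalGlobalEnsemble(
            S_p=S_p, S_d=S_d, config=cfg, delta=delta, random_state=base_seed + t
        )
        model.fit(X_tr, y_tr)
        per_disease[association_set.b_ids[t]] = compute_metrics(
            model.decision_function(X_te), y_te
        )
    return per_disease


def compare_methods(metrics_a: np.ndarray, metrics_b: np.ndarray) -> dict:
    """Two-sided Wilcoxon rank-sum between two methods' per-repeat metrics."""
    stat, p = ranksums(np.asarray(metrics_a), np.asarray(metrics_b))
    if p < 0.001:
        tier = "***"
    elif p < 0.01:
        tier = "**"
    elif p < 0.05:
        tier = "*"
    else:
        tier = "ns"
    return {"statistic": float(stat), "p_value": float(p), "tier": tier}
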