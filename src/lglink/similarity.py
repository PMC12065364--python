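"""Sequence similarity (Smith-Waterman) and random-walk-with-restart features.

The A side (small RNA sequences) gets a pairwise similarity matrix from
local alignment scores normalised by the geometric mean of self-scores;
the B side (disease semantic similarity) is consumed as a precomputed
matrix.  Both sides are then diffused with a random walk with restart to
produce attribute feature vectors for the global graph model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SimilarityMatrix

__all__ = [
    "AlignScoring",
    "FeatureMatrix",
    "smith_waterman",
    "sequence_similarity_matrix",
    "rwr_features",
]

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignScoring:
    """Linear-gap local alignment scoring: match reward, mismatch and gap penalties."""

    match: int = 2
    mismatch: int = -1
    gap: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be > 0")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


@dataclass
class FeatureMatrix:
    """Per-entity attribute features; RWR rows are probability vectors."""

    ids: list[str]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not np.isfinite(self.F).all():
            raise ValueError("feature matrix contains non-finite values")


def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    # N scores as a mismatch against everything, including N itself.
    sub = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == b and a != "N":
                sub[a, b] = scoring.match
            else:
                sub[a, b] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise ValueError(f"{name}: characters outside ACGTN: {sorted(bad)}")
    return seq


def smith_waterman(seq_a: str, seq_b: str, scoring: AlignScoring | None = None) -> int:
    """Maximal local-alignment score with linear gap penalty (always >= 0)."""
    scoring = scoring or AlignScoring()
    seq_a = _check_seq(seq_a, "seq_a")
    seq_b = _check_seq(seq_b, "seq_b")
    score = _aligner(scoring).score(seq_a, seq_b)
    return int(round(score))


def sequence_similarity_matrix(
    seqs: dict[str, str], scoring: AlignScoring | None = None
) -> SimilarityMatrix:
    """Pairwise similarity S[i,j] = SW(i,j) / sqrt(SW(i,i) * SW(j,j)).

    The geometric-mean normalisation gives values in [0, 1] with unit
    diagonal (a local alignment can never outscore the shorter self-match).
    """
    scoring = scoring or AlignScoring()
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = list(seqs)
    cleaned = [_check_seq(seqs[i], i) for i in ids]
    aligner = _aligner(scoring)
    k = len(ids)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            raw[i, j] = raw[j, i] = aligner.score(cleaned[i], cleaned[j])
    self_scores = np.diag(raw)
    if (self_scores <= 0).any():
        bad = ids[int(np.argmin(self_scores))]
        raise ValueError(f"sequence {bad!r} has non-positive self-alignment score")
    S = raw / np.sqrt(np.outer(self_scores, self_scores))
    np.fill_diagonal(S, 1.0)
    np.clip(S, 0.0, 1.0, out=S)
    return SimilarityMatrix(ids=ids, S=S)


def rwr_features(
    S: SimilarityMatrix | np.ndarray,
    restart: float = 0.9,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> FeatureMatrix:
    """Random walk with restart on a similarity network.

    For each seed entity e the walker distribution is iterated as
    ``r <- c*e + (1-c) * P.T @ r`` with ``P`` the row-normalised similarity
    and restart probability ``c``, until the L1 change drops below ``tol``.
    Returns one stationary distribution per seed (rows sum to 1).

    Isolated entities (all-zero similarity rows) get a uniform transition
    row, with a warning.
    """
    if isinstance(S, SimilarityMatrix):
        ids, mat = S.ids, S.S
    else:
        mat = np.asarray(S, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("similarity must be square")
    if (mat < 0).any():
        raise ValueError("similarity must be non-negative")
    if not 0.0 < restart <= 1.0:
        raise ValueError("restart probability must lie in (0, 1]")

    k = mat.shape[0]
    row_sums = mat.sum(axis=1)
    zero = row_sums == 0
    P = np.empty_like(mat)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} isolated entities: transition rows set to uniform",
            stacklevel=2,
        )
        P[zero] = 1.0 / k
    nz = ~zero
    P[nz] = mat[nz] / row_sums[nz, None]

    c = restart
    # All seeds at once: column s holds the walker distribution for seed s.
    R = np.eye(k)
    E = np.eye(k)
    PT = P.T
    for _ in range(max_iter):
        R_next = c * E + (1.0 - c) * (PT @ R)
        delta = np.abs(R_next - R).sum(axis=0).max()
        R = R_next
        if delta < tol:
            break
    return FeatureMatrix(ids=ids, F=R.T)
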