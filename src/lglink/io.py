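"""Domain containers and readers/writers for the formats the tool touches.

The central objects are :class:`AssociationSet` (a sparse binary bipartite
adjacency between A-side entities, e.g. piRNAs, and B-side entities, e.g.
diseases), :class:`SimilarityMatrix` (a validated square similarity matrix
with unit diagonal) and :class:`ScoreSet` (per-pair global/local/fused
association scores).  All files use entity identifiers, never indices;
indices are 0-based and internal.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "AssociationSet",
    "SimilarityMatrix",
    "ScoreSet",
    "Config",
    "SupplementConfig",
    "read_association_table",
    "write_association_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_fasta",
    "write_scores",
    "read_scores",
    "load_config",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def _check_unique(ids: Sequence[str], side: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate identifier {dup!r} on {side} side")


@dataclass
class AssociationSet:
    """Known bipartite associations: identifiers plus an m x n 0/1 matrix."""

    a_ids: list[str]
    b_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        _check_unique(self.a_ids, "A")
        _check_unique(self.b_ids, "B")
        if self.A.shape != (len(self.a_ids), len(self.b_ids)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match id lists "
                f"({len(self.a_ids)}, {len(self.b_ids)})"
            )
        if self.m < 1 or self.n < 1:
            raise ValueError("need at least one entity on each side")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("association matrix must contain only 0/1")
        self.A = self.A.astype(np.int8)

    @property
    def m(self) -> int:
        return len(self.a_ids)

    @property
    def n(self) -> int:
        return len(self.b_ids)

    def positive_pairs(self) -> np.ndarray:
        """Indices of known associations as an (k, 2) array of (p, d)."""
        return np.argwhere(self.A == 1)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] with unit diagonal."""

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        _check_unique(self.ids, "similarity")
        k = len(self.ids)
        if self.S.shape != (k, k):
            raise ValueError(f"similarity must be {k}x{k}, got {self.S.shape}")
        if np.abs(self.S - self.S.T).max(initial=0.0) > 1e-8:
            raise ValueError("similarity matrix not symmetric within 1e-8")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-6):
            raise ValueError("similarity diagonal must equal 1")
        if self.S.min(initial=1.0) < -1e-9 or self.S.max(initial=0.0) > 1 + 1e-9:
            raise ValueError("similarity values must lie in [0, 1]")
        np.clip(self.S, 0.0, 1.0, out=self.S)


@dataclass
class ScoreSet:
    """Per-pair global, local and fused association scores.

    ``y_fused`` always equals ``delta * y_global + (1 - delta) * y_local``.
    """

    pairs: list[tuple[str, str]]
    y_global: np.ndarray
    y_local: np.ndarray
    y_fused: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.y_global = np.asarray(self.y_global, dtype=float)
        self.y_local = np.asarray(self.y_local, dtype=float)
        self.y_fused = np.asarray(self.y_fused, dtype=float)
        k = len(self.pairs)
        if not (len(self.y_global) == len(self.y_local) == len(self.y_fused) == k):
            raise ValueError("score arrays must align with the pair list")


@dataclass
class SupplementConfig:
    """Settings for the base-predictor ensemble that adds weighted edges.

    n_base predictors are built from a small set of classifier families,
    each trained on a balanced resample of positives and sampled unknowns;
    unknown pairs whose mean score passes the rule become weighted edges.
    """

    n_base: int = 15
    threshold: float = 0.5
    mode: str = "threshold"  # "threshold" | "top_k" | "all"
    top_k: int = 100

    def __post_init__(self) -> None:
        if self.n_base < 0:
            raise ValueError("n_base must be >= 0")
        if self.mode not in ("threshold", "top_k", "all"):
            raise ValueError(f"unknown supplementation mode {self.mode!r}")


@dataclass
class Config:
    """Hyperparameters for the full local+global pipeline.

    Defaults for the local module (h=2 hops, 20 epochs, lr 0.001, 2 GCN
    layers) follow the parameter analysis of the method; the remaining
    knobs are documented in docs/methods.md.
    """

    h: int = 2
    epochs_local: int = 20
    lr_local: float = 0.001
    n_layers_local: int = 2
    n_layers_global: int = 2
    epochs_global: int = 1000
    lr_global: float = 0.001
    delta: float | str = 0.5  # fusion coefficient, or "auto" for a sweep
    alpha: float = 1.0  # positive target weight in the variant adjacency
    mu: float = 1e-4  # L2 decay factor of the global objective
    rwr_restart: float = 0.9
    seed: int = 0
    embed_dim: int = 128
    dense_dims: tuple[int, ...] = (400, 200, 100)
    mlp_hidden: int = 128
    local_width: int = 32
    batch_size: int = 50
    supplement: SupplementConfig = field(default_factory=SupplementConfig)

    def __post_init__(self) -> None:
        if isinstance(self.supplement, dict):
            self.supplement = SupplementConfig(**self.supplement)
        if self.h < 1:
            raise ValueError("neighbor order h must be >= 1")
        if isinstance(self.delta, str):
            if self.delta != "auto":
                raise ValueError("delta must be a number in [0,1] or 'auto'")
        elif not 0.0 <= float(self.delta) <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0.0 < self.rwr_restart <= 1.0:
            raise ValueError("rwr_restart must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dense_dims"] = list(self.dense_dims)
        return d


def load_config(path: str | Path) -> Config:
    """Load a YAML config file; absent keys fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    if "dense_dims" in raw:
        raw["dense_dims"] = tuple(raw["dense_dims"])
    return Config(**raw)


# ---------------------------------------------------------------------------
# association tables


def read_association_table(path: str | Path, dialect: str = "edge-list") -> AssociationSet:
    """Read associations from a TSV edge list or a labelled 0/1 matrix.

    Edge-list rows are ``a_id<TAB>b_id[<TAB>label]``; an absent label means 1,
    rows labelled 0 introduce the entities without an edge.  Row/column order
    follows first appearance.  The matrix dialect expects identifiers in the
    header row and first column.
    """
    path = Path(path)
    if dialect == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique([str(i) for i in df.index], "A (matrix rows)")
        _check_unique([str(c) for c in df.columns], "B (matrix columns)")
        values = df.to_numpy()
        return AssociationSet(
            a_ids=[str(i) for i in df.index],
            b_ids=[str(c) for c in df.columns],
            A=values,
        )
    if dialect != "edge-list":
        raise ValueError(f"unknown dialect {dialect!r}")

    a_ids: list[str] = []
    b_ids: list[str] = []
    a_pos: dict[str, int] = {}
    b_pos: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(row)}"
                )
            a, b = row[0].strip(), row[1].strip()
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty identifier")
            label = 1
            if len(row) == 3:
                try:
                    label = int(row[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: label must be 0/1") from exc
                if label not in (0, 1):
                    raise FormatError(f"{path}:{lineno}: label must be 0/1")
            if a not in a_pos:
                a_pos[a] = len(a_ids)
                a_ids.append(a)
            if b not in b_pos:
                b_pos[b] = len(b_ids)
                b_ids.append(b)
            if label == 1:
                edges.add((a_pos[a], b_pos[b]))
    if not a_ids:
        raise FormatError(f"{path}: no associations")
    A = np.zeros((len(a_ids), len(b_ids)), dtype=np.int8)
    for p, d in edges:
        A[p, d] = 1
    return AssociationSet(a_ids=a_ids, b_ids=b_ids, A=A)


def write_association_matrix(assoc: AssociationSet, path: str | Path) -> None:
    """Write the 0/1 matrix with identifiers (matrix dialect round-trip)."""
    df = pd.DataFrame(assoc.A, index=assoc.a_ids, columns=assoc.b_ids)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# similarity matrices


def read_similarity_matrix(
    path: str | Path, require_unit_diagonal: bool = True
) -> SimilarityMatrix:
    """Read a labelled square similarity matrix (TSV).

    Asymmetry up to 1e-6 is repaired by averaging ``(S + S.T) / 2``;
    larger asymmetry is an error.  A diagonal that deviates from 1 beyond
    1e-6 is rejected unless ``require_unit_diagonal`` is False, in which
    case the diagonal is forced to 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    _check_unique(ids, "similarity rows")
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: similarity matrix must be square, got {df.shape}")
    if [str(c) for c in df.columns] != ids:
        raise FormatError(f"{path}: row and column identifiers differ")
    S = df.to_numpy(dtype=float)
    asym = np.abs(S - S.T).max(initial=0.0)
    if asym > 1e-6:
        raise FormatError(f"{path}: asymmetry {asym:.2e} exceeds 1e-6")
    S = (S + S.T) / 2.0
    if not np.allclose(np.diag(S), 1.0, atol=1e-6):
        if require_unit_diagonal:
            raise FormatError(f"{path}: diagonal deviates from 1 beyond 1e-6")
        np.fill_diagonal(S, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=ids, S=S)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.S, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping.

    Sequences are upper-cased and U is mapped to T (RNA deposited
    sequences are scored over the DNA alphabet).  Duplicate headers and
    empty sequences are errors.
    """
    mapping: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in mapping:
            raise FormatError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"empty sequence for {record.id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                f"sequence {record.id!r} contains characters outside ACGUTN: {sorted(bad)}"
            )
        mapping[record.id] = seq
    if not mapping:
        raise FormatError(f"{path}: no FASTA records")
    return mapping


# ---------------------------------------------------------------------------
# scores


def write_scores(score_set: ScoreSet, path: str | Path) -> None:
    """Write scores as TSV sorted by fused score (desc, ties lexicographic)."""
    df = pd.DataFrame(
        {
            "a_id": [p[0] for p in score_set.pairs],
            "b_id": [p[1] for p in score_set.pairs],
            "y_global": score_set.y_global,
            "y_local": score_set.y_local,
            "y_fused": score_set.y_fused,
        }
    )
    df = df.sort_values(
        ["y_fused", "a_id", "b_id"], ascending=[False, True, True], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores(path: str | Path, delta: float = 0.5) -> ScoreSet:
    df = pd.read_csv(path, sep="\t")
    return ScoreSet(
        pairs=list(zip(df["a_id"].astype(str), df["b_id"].astype(str))),
        y_global=df["y_global"].to_numpy(),
        y_local=df["y_local"].to_numpy(),
        y_fused=df["y_fused"].to_numpy(),
        delta=delta,
    )
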