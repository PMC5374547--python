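"""Readers, writers and preprocessing for matched expression datasets.

Expression matrices are plain :class:`pandas.DataFrame` objects: rows are
genes or miRNAs, columns are samples, and ``NaN`` marks a missing
measurement.  The preprocessing functions mirror the usual pipeline for
level-3 tumour expression profiles:

1. drop entities missing in more than half the samples (:func:`filter_missing`),
2. impute the remaining gaps with k-nearest-neighbour averaging
   (:func:`knn_impute`),
3. drop rows without a usable gene symbol (:func:`drop_unnamed`),
4. collapse replicate rows by averaging (:func:`average_replicates`).

Sequence-level evidence comes in as a TargetScan-style summary table of
(miRNA, gene, context++ score) records; only strictly negative scores —
predicted repression — are retained.  Known regulatory edges (TF->target,
protein-protein interactions, validation ground truth) are held in
:class:`EdgeSet`.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

#: tokens accepted as "missing" in expression TSVs, besides an empty cell
NA_TOKENS = ("", "NA", "NaN", "nan", "na", "null", "NULL")

#: edge-set kinds whose pairs are direction-sensitive
ORDERED_KINDS = frozenset({"tf", "target"})
UNORDERED_KINDS = frozenset({"ppi", "sponge"})


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered id pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EdgeSet:
    """A set of id pairs with ordered or unordered membership semantics.

    Parameters
    ----------
    pairs
        The edges.  Unordered kinds store each pair in canonical sorted form.
    kind
        One of ``"tf"`` (TF -> target, ordered), ``"target"``
        (miRNA -> mRNA, ordered), ``"ppi"`` or ``"sponge"`` (unordered).
    """

    pairs: frozenset = field(default_factory=frozenset)
    kind: str = "ppi"

    def __post_init__(self) -> None:
        if self.kind not in ORDERED_KINDS | UNORDERED_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")

    @property
    def ordered(self) -> bool:
        return self.kind in ORDERED_KINDS

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], kind: str) -> "EdgeSet":
        """Build an edge set, canonicalising unordered pairs and dropping self-pairs."""
        ordered = kind in ORDERED_KINDS
        clean = set()
        for a, b in pairs:
            if a == b:
                continue
            clean.add((a, b) if ordered else canonical_pair(a, b))
        return cls(pairs=frozenset(clean), kind=kind)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        if self.ordered:
            return (a, b) in self.pairs
        return canonical_pair(a, b) in self.pairs

    def contains_unordered(self, pair: tuple[str, str]) -> bool:
        """Membership ignoring direction (used when filtering sponge pairs)."""
        a, b = pair
        return (a, b) in self.pairs or (b, a) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.pairs))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def load_expression(path: str | Path, entity_kind: str | None = None) -> pd.DataFrame:
    """Read an expression TSV (first column ids, header row of sample ids).

    NA tokens (:data:`NA_TOKENS`) become ``NaN``; any other non-numeric cell
    raises.  Duplicate sample headers raise; duplicate entity ids are kept
    (collapse them later with :func:`average_replicates`).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dupes = sorted(s for s, c in Counter(samples).items() if c > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate sample columns {dupes}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(NA_TOKENS),
        keep_default_na=False, dtype=str,
    )
    df.columns = [str(c) for c in df.columns]
    df.index = df.index.fillna("").astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    df = df.astype(float)
    df.index.name = None
    df.attrs["entity_kind"] = entity_kind
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def filter_missing(df: pd.DataFrame, max_missing_frac: float = 0.5) -> pd.DataFrame:
    """Drop rows whose missing fraction strictly exceeds ``max_missing_frac``.

    A row missing in exactly half of the samples is kept (the filter is
    strict ``>``), matching the ">50% of samples" rule.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = df.isna().mean(axis=1)
    out = df.loc[frac <= max_missing_frac].copy()
    out.attrs.update(df.attrs)
    return out


def knn_impute(df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing cells from the ``k`` nearest rows.

    Neighbours are other entities, ranked by Euclidean distance over
    co-observed samples (scikit-learn's nan-Euclidean metric); each missing
    cell becomes the unweighted mean of the neighbours observed in that
    sample.  Rows must not be entirely missing — filter first.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k >= df.shape[0]:
        raise ValueError(f"k={k} must be smaller than the number of rows ({df.shape[0]})")
    fully_missing = df.index[df.isna().all(axis=1)]
    if len(fully_missing):
        raise ValueError(f"rows fully missing (filter first): {list(fully_missing[:5])}")
    if not df.isna().any().any():
        out = df.copy()
    else:
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        values = imputer.fit_transform(df.to_numpy())
        out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.attrs.update(df.attrs)
    return out


def average_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing an id to their element-wise mean (order preserved)."""
    out = df.groupby(level=0, sort=False).mean()
    out.attrs.update(df.attrs)
    return out


def drop_unnamed(df: pd.DataFrame, null_pattern: str = r"\??") -> pd.DataFrame:
    """Drop rows whose id fully matches ``null_pattern`` (default: empty or '?')."""
    pat = re.compile(null_pattern)
    keep = [i for i in df.index if not pat.fullmatch(str(i))]
    out = df.loc[keep].copy()
    out.attrs.update(df.attrs)
    return out


def preprocess_expression(
    df: pd.DataFrame,
    max_missing_frac: float = 0.5,
    knn_k: int = 10,
    null_pattern: str = r"\??",
) -> pd.DataFrame:
    """Full preprocessing chain: missing filter, KNN imputation, symbol filter,
    replicate averaging."""
    out = filter_missing(df, max_missing_frac)
    if out.isna().any().any():
        out = knn_impute(out, k=knn_k)
    out = drop_unnamed(out, null_pattern)
    return average_replicates(out)


def align_samples(mrna: pd.DataFrame, mirna: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reorder the miRNA matrix columns to the mRNA matrix's sample order.

    The two matrices of one dataset must profile the same samples; a
    mismatch beyond ordering is an error, not something to silently subset.
    """
    if set(mrna.columns) != set(mirna.columns):
        only_m = sorted(set(mrna.columns) - set(mirna.columns))[:5]
        only_mi = sorted(set(mirna.columns) - set(mrna.columns))[:5]
        raise ValueError(
            f"sample sets differ between matrices (mRNA-only: {only_m}, miRNA-only: {only_mi})"
        )
    return mrna, mirna[list(mrna.columns)]


# ---------------------------------------------------------------------------
# binding-score tables and edge lists
# ---------------------------------------------------------------------------

def load_binding_table(path: str | Path) -> pd.DataFrame:
    """Read a 3-column (miRNA, gene, context++ score) TSV.

    Records with score >= 0 are dropped (only predicted repression counts);
    duplicate (miRNA, gene) pairs collapse to their most negative score.
    A first line whose third field is non-numeric is treated as a header.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {ln}: expected 3 tab-separated columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError:
                if ln == 1:
                    continue  # header line
                raise ValueError(f"{path}: line {ln}: non-numeric score {parts[2]!r}") from None
            rows.append((parts[0], parts[1], score))
    df = pd.DataFrame(rows, columns=["mirna", "mrna", "score"])
    df = df[df["score"] < 0.0]
    df = (
        df.groupby(["mirna", "mrna"], as_index=False, sort=False)["score"].min()
    )
    return df.reset_index(drop=True)


def write_binding_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def load_edge_list(path: str | Path, kind: str) -> EdgeSet:
    """Read a 2-column id-pair TSV into an :class:`EdgeSet` of the given kind.

    Self-pairs are dropped with a warning; malformed rows raise with their
    line number.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    n_self = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 tab-separated columns, got {len(parts)}")
            a, b = parts
            if a == b:
                n_self += 1
                continue
            pairs.append((a, b))
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-pair(s)", stacklevel=2)
    return EdgeSet.from_pairs(pairs, kind)


def write_edge_list(edges: EdgeSet | Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")
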