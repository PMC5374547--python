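"""Regulatory-score matrices linking miRNAs to candidate target mRNAs.

Expression and sequence evidence are fused into a single score per
(mRNA, miRNA) pair:

    S = a * W + b * T

where ``W`` is the Pearson correlation of the pair across matched samples
(range [-1, 1]), ``T`` is the TargetScan-style context++ binding score
(clamped to [-1, 0]; 0 when no binding record exists), and ``a``, ``b`` in
[0, 1] weight the two sources (default 0.5 each, giving S a range of
[-1, 0.5]).  Pairs with ``S <= s`` (default s = -0.3) are taken as
*reconstructed* miRNA-target interactions: strongly negative scores reflect
the repressive action of a miRNA on its target, supported by expression
anti-correlation, predicted binding, or both.  Because absent binding
records contribute T = 0, a pair can be reconstructed on expression
evidence alone — the scores do not rely wholly on the putative
target network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import EdgeSet


@dataclass
class ScoringParams:
    """Weights and reconstruction threshold for the regulatory score.

    a, b : float in [0, 1]
        Contributions of expression correlation (W) and binding score (T).
        They are not renormalised; a + b may differ from 1.
    s : float < 0
        Reconstruction threshold: pairs with S <= s become target edges.
    """

    a: float = 0.5
    b: float = 0.5
    s: float = -0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [0, 1], got {self.a}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must be in [0, 1], got {self.b}")
        if not self.s < 0.0:
            raise ValueError(f"s must be strictly negative, got {self.s}")


def correlation_matrix(mrna: pd.DataFrame, mirna: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every mRNA row against every miRNA row.

    Both matrices must share the same samples in the same order (use
    :func:`mirsm.data_io.align_samples` first) and have at least 3 samples.
    Zero-variance rows yield correlation 0 rather than NaN.
    """
    if list(mrna.columns) != list(mirna.columns):
        raise ValueError("sample columns differ or are ordered differently; align first")
    n = mrna.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 matched samples, got {n}")
    x = mrna.to_numpy(dtype=float)
    y = mirna.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc ** 2).sum(axis=1))
    yn = np.sqrt((yc ** 2).sum(axis=1))
    denom = np.outer(xn, yn)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (xc @ yc.T) / denom
    w[~np.isfinite(w)] = 0.0
    np.clip(w, -1.0, 1.0, out=w)
    out = pd.DataFrame(w, index=mrna.index, columns=mirna.index)
    out.attrs["role"] = "W"
    return out


def context_score_matrix(
    binding: pd.DataFrame, mrna_ids, mirna_ids
) -> pd.DataFrame:
    """Dense context++ score matrix T (mRNA rows x miRNA cols).

    Pairs without a binding record get 0 (no sequence evidence); recorded
    scores are clamped to [-1, 0] so T keeps its nominal range even for the
    rare TargetScan totals below -1.
    """
    mrna_ids = list(mrna_ids)
    mirna_ids = list(mirna_ids)
    t = pd.DataFrame(0.0, index=mrna_ids, columns=mirna_ids)
    if len(binding):
        sub = binding[binding["mrna"].isin(t.index) & binding["mirna"].isin(t.columns)]
        if len(sub):
            pivot = sub.pivot_table(index="mrna", columns="mirna", values="score", aggfunc="min")
            t = t.add(pivot.reindex(index=t.index, columns=t.columns).fillna(0.0), fill_value=0.0)
    t = t.clip(lower=-1.0, upper=0.0)
    t.attrs["role"] = "T"
    return t


def regulatory_score_matrix(
    w: pd.DataFrame, t: pd.DataFrame, params: ScoringParams | None = None
) -> pd.DataFrame:
    """Element-wise S = a*W + b*T over identically indexed matrices."""
    params = params or ScoringParams()
    if not (w.index.equals(t.index) and w.columns.equals(t.columns)):
        raise ValueError("W and T must share identical row/column ids in identical order")
    s = params.a * w + params.b * t
    s.attrs["role"] = "S"
    return s


def reconstruct_targets(s: pd.DataFrame, params: ScoringParams | None = None) -> EdgeSet:
    """All (miRNA, mRNA) pairs with S <= s (the threshold is inclusive)."""
    params = params or ScoringParams()
    rows, cols = np.nonzero(s.to_numpy() <= params.s)
    pairs = [(str(s.columns[j]), str(s.index[i])) for i, j in zip(rows, cols)]
    return EdgeSet.from_pairs(pairs, kind="target")


def targets_by_mrna(targets: EdgeSet | pd.DataFrame) -> dict[str, set[str]]:
    """Map each mRNA to the set of miRNAs targeting it.

    Accepts a reconstructed target :class:`EdgeSet` (miRNA -> mRNA pairs)
    or a putative binding-score table.
    """
    out: dict[str, set[str]] = {}
    if isinstance(targets, pd.DataFrame):
        for mirna, mrna in zip(targets["mirna"], targets["mrna"]):
            out.setdefault(str(mrna), set()).add(str(mirna))
    else:
        if targets.kind != "target":
            raise ValueError("expected an EdgeSet of kind 'target'")
        for mirna, mrna in targets:
            out.setdefault(mrna, set()).add(mirna)
    return out


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson correlations via the t distribution (n-2 df)."""
    r = np.asarray(r, dtype=float)
    if n < 3:
        raise ValueError("need at least 3 samples")
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rr), 1.0), 0.0, p)
    return p


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
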