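"""Benchmark sponge-interaction methods: PC, SPPC, and a reduced Hermes.

All three search the *unrestricted* mRNA-pair universe (no biclustering,
no TF/PPI filter) and, by default, define each mRNA's miRNA regulators
from the putative binding table rather than from reconstructed regulatory
scores — the convention of the pair-wise correlation and partial
association literatures.

PC (Positive Correlation)
    keeps pairs with a significant hypergeometric sharing of miRNAs and a
    significant positive expression correlation (both p < 0.01).

SPPC (Sensitivity Partial Pearson Correlation)
    additionally conditions the pair's correlation on the expression of
    the shared miRNAs; the *sensitivity* r - r_partial measures how much
    of the correlation the shared miRNAs mediate, and pairs below the 0.3
    cutoff are discarded.  The conditioning is joint over the full shared
    set (precision-matrix partial correlation); a per-miRNA averaging
    variant is available via ``per_mirna=True``.

Hermes (conditional mutual information)
    scores, for each shared miRNA z, the gain in miRNA-target information
    when conditioning on the partner: dI = I(m1; z | m2) - I(m1; z),
    estimated with equal-frequency binning.  Significance is assessed by
    permuting m2's sample labels, and the per-miRNA p-values are combined
    per pair with Fisher's method.  This is a reduced re-statement of the
    published method, which it approximates rather than reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_io import EdgeSet, canonical_pair
from .scoring import pearson_pvalues, targets_by_mrna
from .sponge import hypergeom_shared_pvalue


@dataclass(frozen=True)
class BaselineResult:
    """Interactions found by one baseline, with per-pair statistics."""

    method: str
    table: pd.DataFrame

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {
            canonical_pair(a, b)
            for a, b in zip(self.table["mrna1"], self.table["mrna2"])
        }

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# information-theoretic helpers (equal-frequency binning, plug-in estimates)
# ---------------------------------------------------------------------------

def equal_frequency_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based discretisation into ``bins`` near-equal-count levels."""
    x = np.asarray(x, dtype=float)
    n = x.size
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (ranks * bins) // n


def _mi_codes(cx: np.ndarray, cy: np.ndarray, bx: int, by: int) -> float:
    n = cx.size
    counts = np.bincount(cx * by + cy, minlength=bx * by).reshape(bx, by)
    nx = counts.sum(axis=1, keepdims=True)
    ny = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts * n / (nx * ny))
    return float(np.nansum(terms)) / n


def _cmi_codes(cx, cy, cz, bx, by, bz) -> float:
    n = cx.size
    counts = np.bincount((cx * by + cy) * bz + cz, minlength=bx * by * bz).reshape(bx, by, bz)
    n_xz = counts.sum(axis=1, keepdims=True)
    n_yz = counts.sum(axis=0, keepdims=True)
    n_z = counts.sum(axis=(0, 1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts * n_z / (n_xz * n_yz))
    return float(np.nansum(terms)) / n


def mutual_info(x, y, bins: int = 4) -> float:
    """Plug-in mutual information (nats) after equal-frequency binning."""
    return _mi_codes(equal_frequency_codes(x, bins), equal_frequency_codes(y, bins), bins, bins)


def conditional_mutual_info(x, y, z, bins: int = 4) -> float:
    """Plug-in conditional mutual information I(x; y | z) after binning."""
    return _cmi_codes(
        equal_frequency_codes(x, bins),
        equal_frequency_codes(y, bins),
        equal_frequency_codes(z, bins),
        bins, bins, bins,
    )


def partial_correlation(x1: np.ndarray, x2: np.ndarray, z: np.ndarray) -> float:
    """Pearson correlation of x1 and x2 given the rows of z (joint conditioning)."""
    z = np.atleast_2d(z)
    data = np.vstack([x1, x2, z])
    corr = np.corrcoef(data)
    prec = np.linalg.pinv(corr)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom <= 0:
        return 0.0
    return float(np.clip(-prec[0, 1] / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _resolve_targets(targets) -> dict[str, set[str]]:
    if isinstance(targets, dict):
        return targets
    return targets_by_mrna(targets)


def _pc_table(mrna_expr: pd.DataFrame, tset: dict, n_mirnas: int, p_cut: float) -> pd.DataFrame:
    genes = [g for g in mrna_expr.index if tset.get(g)]
    cols = ["mrna1", "mrna2", "r", "r_pvalue", "x", "M", "K", "hyper_p"]
    if len(genes) < 2:
        return pd.DataFrame(columns=cols)
    mirnas = sorted({m for g in genes for m in tset[g]})
    midx = {m: i for i, m in enumerate(mirnas)}
    b = np.zeros((len(genes), len(mirnas)), dtype=np.int64)
    for gi, g in enumerate(genes):
        for m in tset[g]:
            b[gi, midx[m]] = 1
    shared = b @ b.T
    m_counts = b.sum(axis=1)
    if m_counts.max() > n_mirnas:
        raise ValueError("a target set exceeds the declared miRNA universe")
    sub = mrna_expr.loc[genes].to_numpy(dtype=float)
    n_samples = sub.shape[1]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    pmat = pearson_pvalues(corr, n_samples)
    hyper = hypergeom_shared_pvalue(shared, n_mirnas, m_counts[:, None], m_counts[None, :])
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = (hyper[iu, ju] < p_cut) & (corr[iu, ju] > 0.0) & (pmat[iu, ju] < p_cut)
    rows = []
    for i, j in zip(iu[keep], ju[keep]):
        g1, g2 = canonical_pair(genes[i], genes[j])
        rows.append(
            (g1, g2, float(corr[i, j]), float(pmat[i, j]),
             int(shared[i, j]), int(m_counts[i]), int(m_counts[j]), float(hyper[i, j]))
        )
    return pd.DataFrame(rows, columns=cols).sort_values(["mrna1", "mrna2"]).reset_index(drop=True)


class PositiveCorrelation(BaseEstimator):
    """PC baseline: dual significance over all mRNA pairs, no filtering."""

    def __init__(self, p_cut: float = 0.01):
        self.p_cut = p_cut

    def fit(self, mrna_expr: pd.DataFrame, targets, n_mirnas: int):
        tset = _resolve_targets(targets)
        table = _pc_table(mrna_expr, tset, n_mirnas, self.p_cut)
        self.result_ = BaselineResult(method="PC", table=table)
        self.interactions_ = self.result_.pairs
        return self


class SensitivityPartialCorrelation(BaseEstimator):
    """SPPC baseline: PC pairs kept when shared miRNAs mediate the correlation.

    Pairs whose conditioning set has ``k >= n_samples - 2`` miRNAs are
    skipped with a warning (the partial correlation is undefined).
    """

    def __init__(self, sens_cut: float = 0.3, p_cut: float = 0.01, per_mirna: bool = False):
        self.sens_cut = sens_cut
        self.p_cut = p_cut
        self.per_mirna = per_mirna

    def fit(self, mrna_expr: pd.DataFrame, mirna_expr: pd.DataFrame, targets, n_mirnas: int | None = None):
        tset = _resolve_targets(targets)
        if n_mirnas is None:
            n_mirnas = mirna_expr.shape[0]
        pc = _pc_table(mrna_expr, tset, n_mirnas, self.p_cut)
        n_samples = mrna_expr.shape[1]
        rows = []
        n_skipped = 0
        for rec in pc.itertuples(index=False):
            zset = sorted((tset[rec.mrna1] & tset[rec.mrna2]) & set(mirna_expr.index))
            if not zset:
                continue
            if len(zset) >= n_samples - 2:
                n_skipped += 1
                continue
            x1 = mrna_expr.loc[rec.mrna1].to_numpy(dtype=float)
            x2 = mrna_expr.loc[rec.mrna2].to_numpy(dtype=float)
            z = mrna_expr.columns  # sample order shared by construction
            zmat = mirna_expr.loc[zset, z].to_numpy(dtype=float)
            if self.per_mirna:
                parts = [partial_correlation(x1, x2, zmat[i:i + 1]) for i in range(zmat.shape[0])]
                pr = float(np.mean(parts))
            else:
                pr = partial_correlation(x1, x2, zmat)
            sens = rec.r - pr
            if sens >= self.sens_cut:
                rows.append(rec._asdict() | {"partial_r": pr, "sensitivity": sens})
        if n_skipped:
            warnings.warn(
                f"skipped {n_skipped} pair(s) whose conditioning set size >= n_samples - 2",
                stacklevel=2,
            )
        cols = list(pc.columns) + ["partial_r", "sensitivity"]
        table = pd.DataFrame(rows, columns=cols)
        self.result_ = BaselineResult(method="SPPC", table=table)
        self.interactions_ = self.result_.pairs
        return self


class Hermes(BaseEstimator):
    """Reduced Hermes baseline: permutation-calibrated conditional MI.

    For each candidate pair (m1, m2) sharing at least one putative miRNA
    regulator z, the statistic dI = I(m1; z | m2) - I(m1; z) is estimated
    by equal-frequency binning (``bins`` levels per variable); the
    permutation null shuffles m2's sample labels.  Per-miRNA p-values are
    combined with Fisher's method and pairs with a combined p below
    ``p_cut`` are reported.
    """

    def __init__(self, permutations: int = 100, p_cut: float = 0.01, bins: int = 4, random_state=None):
        self.permutations = permutations
        self.p_cut = p_cut
        self.bins = bins
        self.random_state = random_state

    def fit(
        self,
        mrna_expr: pd.DataFrame,
        mirna_expr: pd.DataFrame,
        targets,
        candidate_pairs: Iterable[tuple[str, str]] | None = None,
    ):
        rng = np.random.default_rng(self.random_state)
        tset = _resolve_targets(targets)
        bins = self.bins
        mirna_ids = set(mirna_expr.index)
        genes = [g for g in mrna_expr.index if tset.get(g)]
        if candidate_pairs is None:
            candidate_pairs = [
                (genes[i], genes[j])
                for i in range(len(genes))
                for j in range(i + 1, len(genes))
                if tset[genes[i]] & tset[genes[j]] & mirna_ids
            ]
        codes_mrna = {g: equal_frequency_codes(mrna_expr.loc[g].to_numpy(dtype=float), bins) for g in genes}
        codes_mirna = {
            m: equal_frequency_codes(mirna_expr.loc[m].to_numpy(dtype=float), bins)
            for m in mirna_ids
        }
        rows = []
        b = self.permutations
        for g1, g2 in candidate_pairs:
            g1, g2 = canonical_pair(g1, g2)
            zset = sorted(tset.get(g1, set()) & tset.get(g2, set()) & mirna_ids)
            if not zset:
                continue
            cx = codes_mrna[g1]
            cc = codes_mrna[g2]
            pvals = []
            dis = []
            for m in zset:
                cz = codes_mirna[m]
                mi = _mi_codes(cx, cz, bins, bins)
                obs_cmi = _cmi_codes(cx, cz, cc, bins, bins, bins)
                dis.append(obs_cmi - mi)
                exceed = 0
                for _ in range(b):
                    perm = rng.permutation(cc)
                    if _cmi_codes(cx, cz, perm, bins, bins, bins) >= obs_cmi - 1e-12:
                        exceed += 1
                pvals.append((1 + exceed) / (b + 1))
            fisher_stat = -2.0 * float(np.sum(np.log(pvals)))
            combined = float(stats.chi2.sf(fisher_stat, df=2 * len(pvals)))
            if combined < self.p_cut:
                rows.append((g1, g2, len(zset), float(np.mean(dis)), combined))
        table = pd.DataFrame(rows, columns=["mrna1", "mrna2", "x", "mean_delta_mi", "combined_p"])
        self.result_ = BaselineResult(method="Hermes", table=table)
        self.interactions_ = self.result_.pairs
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def pc_infer(mrna_expr: pd.DataFrame, targets, n_mirnas: int, p_cut: float = 0.01) -> BaselineResult:
    return PositiveCorrelation(p_cut=p_cut).fit(mrna_expr, targets, n_mirnas).result_


def sppc_infer(
    mrna_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    targets,
    sens_cut: float = 0.3,
    p_cut: float = 0.01,
    n_mirnas: int | None = None,
    per_mirna: bool = False,
) -> BaselineResult:
    est = SensitivityPartialCorrelation(sens_cut=sens_cut, p_cut=p_cut, per_mirna=per_mirna)
    return est.fit(mrna_expr, mirna_expr, targets, n_mirnas=n_mirnas).result_


def hermes_infer(
    mrna_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    targets,
    permutations: int = 100,
    p_cut: float = 0.01,
    seed=None,
    bins: int = 4,
    candidate_pairs: Sequence[tuple[str, str]] | None = None,
) -> BaselineResult:
    est = Hermes(permutations=permutations, p_cut=p_cut, bins=bins, random_state=seed)
    return est.fit(mrna_expr, mirna_expr, targets, candidate_pairs=candidate_pairs).result_
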