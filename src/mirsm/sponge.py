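"""From biclusters to miRNA sponge modules.

Two mRNAs act as sponges (ceRNAs) for each other when they compete for the
same miRNAs: they share a significant number of miRNA regulators, and
because sequestering those miRNAs de-represses both transcripts, their
expression is positively correlated.  Within each bicluster every
unordered mRNA pair is therefore scored with

* an upper-tail hypergeometric test on the number of shared miRNA
  regulators, drawn from the universe of all N miRNAs in the dataset:
  ``p = 1 - sum_{i<x} C(M,i) C(N-M, K-i) / C(N,K)`` where M and K are the
  two mRNAs' reconstructed target-set sizes and x their overlap;
* a Pearson correlation with its two-sided t-distribution p-value.

Pairs passing both tests (p < 0.01 each, r > 0) are candidate sponge
interactions.  Candidates that are already known TF-target edges (either
orientation) or protein-protein interactions are direct interactions, not
competition, and are removed; mRNAs left without any interaction are
dropped.  The surviving sponges, the bicluster's miRNAs, and the
interactions form a sponge module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_io import EdgeSet, align_samples, canonical_pair
from .plaid import Bicluster, fit_plaid
from .scoring import (
    ScoringParams,
    context_score_matrix,
    correlation_matrix,
    pearson_pvalues,
    reconstruct_targets,
    regulatory_score_matrix,
    targets_by_mrna,
)


@dataclass(frozen=True)
class SharedMiRNAStat:
    """Hypergeometric evidence that two mRNAs share miRNA regulators."""

    N: int  # miRNAs in the dataset
    M: int  # miRNAs targeting mRNA 1
    K: int  # miRNAs targeting mRNA 2
    x: int  # shared miRNAs
    p: float  # upper-tail probability P(X >= x)


@dataclass(frozen=True)
class CandidateInteraction:
    """An unordered sponge pair with its correlation and sharing statistics."""

    mrna_pair: tuple[str, str]  # canonical (sorted) order
    r: float
    r_pvalue: float
    shared: SharedMiRNAStat


@dataclass(frozen=True)
class SpongeModule:
    """Surviving sponges, the bicluster's miRNAs, and their interactions."""

    mirna_ids: tuple[str, ...]
    sponge_ids: tuple[str, ...]
    interactions: tuple[CandidateInteraction, ...]

    def interaction_pairs(self) -> set[tuple[str, str]]:
        return {i.mrna_pair for i in self.interactions}

    def to_dict(self) -> dict:
        return {
            "mirna_ids": list(self.mirna_ids),
            "sponge_ids": list(self.sponge_ids),
            "interactions": [asdict(i) for i in self.interactions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpongeModule":
        inter = tuple(
            CandidateInteraction(
                mrna_pair=tuple(i["mrna_pair"]),
                r=i["r"],
                r_pvalue=i["r_pvalue"],
                shared=SharedMiRNAStat(**i["shared"]),
            )
            for i in d["interactions"]
        )
        return cls(tuple(d["mirna_ids"]), tuple(d["sponge_ids"]), inter)


def hypergeom_shared_pvalue(x, N, M, K):
    """Upper-tail hypergeometric probability of sharing >= x of N miRNAs.

    Vectorised over any of the arguments; computed through scipy's
    survival function rather than 1 - cdf for numerical stability.
    """
    x = np.asarray(x)
    return stats.hypergeom.sf(x - 1, N, M, K)


def shared_mirna_test(targets1: set, targets2: set, n_mirnas: int) -> SharedMiRNAStat:
    """Hypergeometric test for the miRNA regulators shared by two mRNAs.

    ``n_mirnas`` is the size of the miRNA universe — all miRNAs in the
    preprocessed dataset, not just those in one bicluster.
    """
    m, k = len(targets1), len(targets2)
    if m > n_mirnas or k > n_mirnas:
        raise ValueError(f"target sets ({m}, {k}) exceed the miRNA universe ({n_mirnas})")
    x = len(set(targets1) & set(targets2))
    p = float(hypergeom_shared_pvalue(x, n_mirnas, m, k))
    return SharedMiRNAStat(N=n_mirnas, M=m, K=k, x=x, p=min(p, 1.0))


def pair_correlation(mrna_expr: pd.DataFrame, id1: str, id2: str) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df) for one mRNA pair."""
    for g in (id1, id2):
        if g not in mrna_expr.index:
            raise KeyError(f"{g!r} not in expression matrix")
    x = mrna_expr.loc[id1].to_numpy(dtype=float)
    y = mrna_expr.loc[id2].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0.0 or y.std() == 0.0:
        warnings.warn(f"zero-variance profile in pair ({id1}, {id2}); r set to 0", stacklevel=2)
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    p = float(pearson_pvalues(np.array(r), n))
    return r, p


def infer_module(
    bicluster: Bicluster,
    mrna_expr: pd.DataFrame,
    targets: EdgeSet | dict,
    tf: EdgeSet | None = None,
    ppi: EdgeSet | None = None,
    p_cut: float = 0.01,
    n_mirnas: int | None = None,
    adjust: bool = False,
) -> SpongeModule:
    """Turn one bicluster into a sponge module.

    Parameters
    ----------
    targets
        Reconstructed miRNA->mRNA edges (or a precomputed mRNA -> miRNA-set
        mapping) defining each mRNA's regulator set.
    n_mirnas
        Size of the miRNA universe (all miRNAs in the dataset). Required.
    adjust
        Benjamini-Hochberg-adjust both p-value families across the
        bicluster's pairs before thresholding (off by default; the raw
        dual p < 0.01 rule is the standard procedure).
    """
    if n_mirnas is None:
        raise ValueError("n_mirnas (the miRNA universe size) is required")
    tset = targets if isinstance(targets, dict) else targets_by_mrna(targets)
    genes = [g for g in bicluster.mrna_ids if g in mrna_expr.index]
    n_samples = mrna_expr.shape[1]

    records: list[CandidateInteraction] = []
    if len(genes) >= 2:
        sub = mrna_expr.loc[genes].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)
        pmat = pearson_pvalues(corr, n_samples)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                g1, g2 = genes[i], genes[j]
                stat = shared_mirna_test(tset.get(g1, set()), tset.get(g2, set()), n_mirnas)
                records.append(
                    CandidateInteraction(
                        mrna_pair=canonical_pair(g1, g2),
                        r=float(corr[i, j]),
                        r_pvalue=float(pmat[i, j]),
                        shared=stat,
                    )
                )

    if adjust and records:
        hyper_adj = stats.false_discovery_control([c.shared.p for c in records])
        corr_adj = stats.false_discovery_control([c.r_pvalue for c in records])
    else:
        hyper_adj = [c.shared.p for c in records]
        corr_adj = [c.r_pvalue for c in records]

    kept = []
    for cand, ph, pr in zip(records, hyper_adj, corr_adj):
        if not (ph < p_cut and cand.r > 0.0 and pr < p_cut):
            continue
        if tf is not None and tf.contains_unordered(cand.mrna_pair):
            continue
        if ppi is not None and cand.mrna_pair in ppi:
            continue
        kept.append(cand)

    sponges = sorted({g for c in kept for g in c.mrna_pair})
    return SpongeModule(
        mirna_ids=tuple(bicluster.mirna_ids),
        sponge_ids=tuple(sponges),
        interactions=tuple(kept),
    )


class SpongeModuleDetector(BaseEstimator):
    """End-to-end sponge module discovery, scikit-learn style.

    ``fit`` consumes a preprocessed matched dataset and runs the full
    pipeline: build W (expression correlation), T (context++ scores) and
    S = a*W + b*T; reconstruct target edges at threshold ``s``; bicluster
    S with the plaid model; and convert each bicluster into a sponge
    module via the dual hypergeometric/correlation tests with TF/PPI
    filtering.  Modules without any interaction are discarded.

    Attributes (after fit)
    ----------------------
    correlation_, context_, scores_ : pandas.DataFrame
        The W, T and S matrices (mRNA rows x miRNA columns).
    targets_ : EdgeSet
        Reconstructed miRNA -> mRNA interactions (S <= s).
    biclusters_ : list of Bicluster
    modules_ : list of SpongeModule
    summary_ : pandas.DataFrame
        Per-module counts of miRNAs, sponges and interactions.
    """

    def __init__(
        self,
        a: float = 0.5,
        b: float = 0.5,
        s: float = -0.3,
        p_cut: float = 0.01,
        adjust: bool = False,
        max_layers: int = 20,
        background: bool = True,
        row_release: float = 0.7,
        col_release: float = 0.7,
        shuffles: int = 3,
        iterations: int = 10,
        random_state=None,
    ):
        self.a = a
        self.b = b
        self.s = s
        self.p_cut = p_cut
        self.adjust = adjust
        self.max_layers = max_layers
        self.background = background
        self.row_release = row_release
        self.col_release = col_release
        self.shuffles = shuffles
        self.iterations = iterations
        self.random_state = random_state

    def fit(
        self,
        mrna: pd.DataFrame,
        mirna: pd.DataFrame,
        binding: pd.DataFrame,
        tf_edges: EdgeSet | None = None,
        ppi_edges: EdgeSet | None = None,
    ):
        params = ScoringParams(a=self.a, b=self.b, s=self.s)
        mrna, mirna = align_samples(mrna, mirna)
        w = correlation_matrix(mrna, mirna)
        t = context_score_matrix(binding, mrna.index, mirna.index)
        s_mat = regulatory_score_matrix(w, t, params)
        targets = reconstruct_targets(s_mat, params)
        tset = targets_by_mrna(targets) if len(targets) else {}
        biclusters = fit_plaid(
            s_mat,
            max_layers=self.max_layers,
            background=self.background,
            row_release=self.row_release,
            col_release=self.col_release,
            shuffles=self.shuffles,
            iterations=self.iterations,
            random_state=self.random_state,
        )
        modules = []
        for b in biclusters:
            mod = infer_module(
                b,
                mrna,
                tset,
                tf=tf_edges,
                ppi=ppi_edges,
                p_cut=self.p_cut,
                n_mirnas=mirna.shape[0],
                adjust=self.adjust,
            )
            if mod.interactions:
                modules.append(mod)

        self.correlation_ = w
        self.context_ = t
        self.scores_ = s_mat
        self.targets_ = targets
        self.biclusters_ = biclusters
        self.modules_ = modules
        self.summary_ = module_summary(modules)
        return self


def module_summary(modules: Sequence[SpongeModule]) -> pd.DataFrame:
    """Module-size table: #miRNAs, #miRNA sponges, #sponge interactions."""
    rows = [
        {
            "module": k,
            "n_mirnas": len(m.mirna_ids),
            "n_sponges": len(m.sponge_ids),
            "n_interactions": len(m.interactions),
        }
        for k, m in enumerate(modules, start=1)
    ]
    return pd.DataFrame(rows, columns=["module", "n_mirnas", "n_sponges", "n_interactions"])


def run_pipeline(
    mrna: pd.DataFrame,
    mirna: pd.DataFrame,
    binding: pd.DataFrame,
    tf_edges: EdgeSet | None = None,
    ppi_edges: EdgeSet | None = None,
    **params,
) -> list[SpongeModule]:
    """Functional wrapper over :class:`SpongeModuleDetector`."""
    det = SpongeModuleDetector(**params)
    det.fit(mrna, mirna, binding, tf_edges=tf_edges, ppi_edges=ppi_edges)
    return det.modules_


def write_modules(modules: Iterable[SpongeModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in modules], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_modules(path: str | Path) -> list[SpongeModule]:
    with open(path) as fh:
        return [SpongeModule.from_dict(d) for d in json.load(fh)]
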