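"""Synthetic matched-expression datasets with implanted sponge modules.

The generator emulates the shape of a matched tumour expression study
(defaults: 72 samples) with a known, recoverable module structure:

* each module has a latent *driver* profile, standard normal across
  samples; the module's miRNAs load on it with co-expression weight ``w``
  (miRNA_j = sqrt(w) * driver + sqrt(1 - w) * noise, unit marginal
  variance), so the miRNAs of a module are co-expressed as a cluster;
* each module mRNA is repressed by the module's miRNAs:
  mRNA_i = baseline_i - strength * mean(module miRNA profiles) + sigma * e;
* background miRNAs and mRNAs are independent noise;
* the binding table holds a negative context++-style score for every true
  (module miRNA, module mRNA) pair plus random decoy records;
* a fraction of the true sponge pairs is also planted into the TF-target
  and PPI edge lists, to exercise the direct-interaction filter.

Writing v = w + (1 - w) / k for a module with k miRNAs, the model implies
closed-form population correlations

    rho(mRNA, miRNA_j)  = -strength * v / sqrt(strength^2 * v + sigma^2)
    rho(mRNA, mean miRNA profile) = -strength * sqrt(v) / sqrt(strength^2 * v + sigma^2)
    rho(mRNA_i, mRNA_j) =  strength^2 * v / (strength^2 * v + sigma^2)

which the tests check by Monte Carlo.  Everything is reproducible given a
seed, and the written files round-trip through :mod:`mirsm.data_io`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    EdgeSet,
    canonical_pair,
    write_binding_table,
    write_edge_list,
    write_expression,
)


@dataclass
class SynthConfig:
    """Generator settings; the defaults define the standard study conditions."""

    n_samples: int = 72
    n_mirnas: int = 60
    n_mrnas: int = 150
    n_modules: int = 2
    module_mirna_size: int = 8
    module_mrna_size: int = 15
    regulation_strength: float = 1.0
    noise_sd: float = 0.3
    mirna_coexpression: float = 0.5  # weight w of the shared module driver
    binding_score_low: float = -0.8
    binding_score_high: float = -0.2
    decoy_binding_frac: float = 0.1  # decoy records per true binding record
    tf_contamination_frac: float = 0.1  # true sponge pairs planted as TF edges
    ppi_contamination_frac: float = 0.1
    n_background_tf_edges: int = 50
    n_background_ppi_edges: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_mirna_size > self.n_mirnas:
            raise ValueError("module miRNAs exceed the miRNA total")
        if self.n_modules * self.module_mrna_size > self.n_mrnas:
            raise ValueError("module mRNAs exceed the mRNA total")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.regulation_strength < 0:
            raise ValueError("regulation_strength must be non-negative")
        if not 0.0 <= self.mirna_coexpression <= 1.0:
            raise ValueError("mirna_coexpression must be in [0, 1]")
        if not (self.binding_score_low < self.binding_score_high <= 0.0
                and self.binding_score_low >= -1.0):
            raise ValueError("binding score range must lie within [-1, 0)")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")


@dataclass(frozen=True)
class GroundTruth:
    """What was implanted: modules, target pairs, sponge pairs, contamination."""

    modules: tuple[tuple[frozenset, frozenset], ...]  # (miRNA set, mRNA set) per module
    target_pairs: EdgeSet  # ordered miRNA -> mRNA
    sponge_pairs: EdgeSet  # unordered within-module mRNA pairs
    planted_tf: frozenset  # sponge pairs hidden in the TF edge list
    planted_ppi: frozenset


@dataclass(frozen=True)
class SyntheticDataset:
    mirna_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    binding: pd.DataFrame
    tf_edges: EdgeSet
    ppi_edges: EdgeSet
    truth: GroundTruth
    config: SynthConfig


def expected_mirna_mrna_correlation(cfg: SynthConfig) -> float:
    """Population correlation between a module mRNA and one of its miRNAs."""
    k = cfg.module_mirna_size
    w = cfg.mirna_coexpression
    v = w + (1.0 - w) / k
    s = cfg.regulation_strength
    denom = np.sqrt(s * s * v + cfg.noise_sd ** 2)
    if denom == 0.0:
        return 0.0
    return float(-s * v / denom)


def expected_driver_correlation(cfg: SynthConfig) -> float:
    """Population correlation between a module mRNA and the mean miRNA profile."""
    k = cfg.module_mirna_size
    w = cfg.mirna_coexpression
    v = w + (1.0 - w) / k
    s = cfg.regulation_strength
    denom = np.sqrt(s * s * v + cfg.noise_sd ** 2)
    if denom == 0.0:
        return 0.0
    return float(-s * np.sqrt(v) / denom)


def generate_dataset(cfg: SynthConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Draw one dataset; ``seed`` overrides ``cfg.seed`` when given."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirnas)]
    mrna_ids = [f"G{i + 1:04d}" for i in range(cfg.n_mrnas)]

    # random module membership, disjoint across modules
    mirna_perm = rng.permutation(cfg.n_mirnas)
    mrna_perm = rng.permutation(cfg.n_mrnas)
    modules = []
    for m in range(cfg.n_modules):
        mi = mirna_perm[m * cfg.module_mirna_size:(m + 1) * cfg.module_mirna_size]
        mr = mrna_perm[m * cfg.module_mrna_size:(m + 1) * cfg.module_mrna_size]
        modules.append((frozenset(mirna_ids[i] for i in mi),
                        frozenset(mrna_ids[i] for i in mr)))

    mirna_mat = rng.standard_normal((cfg.n_mirnas, cfg.n_samples))
    mrna_mat = rng.standard_normal((cfg.n_mrnas, cfg.n_samples))
    baselines = rng.standard_normal(cfg.n_mrnas)
    mrna_mat += baselines[:, None]  # background mRNAs: baseline + unit noise

    w = cfg.mirna_coexpression
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}
    mrna_index = {g: i for i, g in enumerate(mrna_ids)}
    for mi_set, mr_set in modules:
        driver = rng.standard_normal(cfg.n_samples)
        rows = sorted(mirna_index[m] for m in mi_set)
        eps = rng.standard_normal((len(rows), cfg.n_samples))
        mirna_mat[rows] = np.sqrt(w) * driver + np.sqrt(1.0 - w) * eps
        mean_profile = mirna_mat[rows].mean(axis=0)
        grows = sorted(mrna_index[g] for g in mr_set)
        noise = rng.standard_normal((len(grows), cfg.n_samples))
        mrna_mat[grows] = (
            baselines[grows, None]
            - cfg.regulation_strength * mean_profile[None, :]
            + cfg.noise_sd * noise
        )

    mirna_expr = pd.DataFrame(mirna_mat, index=mirna_ids, columns=samples)
    mirna_expr.attrs["entity_kind"] = "miRNA"
    mrna_expr = pd.DataFrame(mrna_mat, index=mrna_ids, columns=samples)
    mrna_expr.attrs["entity_kind"] = "mRNA"

    # binding table: every true target pair, plus decoys
    true_pairs = sorted(
        (m, g) for mi_set, mr_set in modules for m in sorted(mi_set) for g in sorted(mr_set)
    )
    low, high = cfg.binding_score_low, cfg.binding_score_high
    records = [(m, g, float(rng.uniform(low, high))) for m, g in true_pairs]
    true_set = set(true_pairs)
    n_decoys = round(cfg.decoy_binding_frac * len(true_pairs))
    n_drawn = 0
    while n_drawn < n_decoys:
        m = mirna_ids[rng.integers(cfg.n_mirnas)]
        g = mrna_ids[rng.integers(cfg.n_mrnas)]
        if (m, g) in true_set:
            continue
        true_set.add((m, g))  # avoid duplicate decoys
        records.append((m, g, float(rng.uniform(low, high))))
        n_drawn += 1
    binding = pd.DataFrame(records, columns=["mirna", "mrna", "score"])

    # ground-truth sponge pairs: within-module mRNA pairs (all share the
    # module's miRNAs by construction)
    sponge_pairs = sorted(
        canonical_pair(a, b)
        for _, mr_set in modules
        for a, b in combinations(sorted(mr_set), 2)
    )

    # TF/PPI contamination: disjoint samples of true sponge pairs
    n_tf = ceil(cfg.tf_contamination_frac * len(sponge_pairs))
    n_ppi = ceil(cfg.ppi_contamination_frac * len(sponge_pairs))
    if n_tf + n_ppi > len(sponge_pairs):
        raise ValueError("contamination fractions exceed available sponge pairs")
    picked = rng.choice(len(sponge_pairs), size=n_tf + n_ppi, replace=False)
    planted_tf = frozenset(sponge_pairs[i] for i in picked[:n_tf])
    planted_ppi = frozenset(sponge_pairs[i] for i in picked[n_tf:])

    background_genes = sorted(set(mrna_ids) - {g for _, mr in modules for g in mr})
    def _background_edges(n_edges: int) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        while len(out) < n_edges:
            a, b = rng.choice(len(background_genes), size=2, replace=False)
            out.add(canonical_pair(background_genes[a], background_genes[b]))
        return out

    tf_edges = EdgeSet.from_pairs(
        sorted(planted_tf | _background_edges(cfg.n_background_tf_edges)), kind="tf"
    )
    ppi_edges = EdgeSet.from_pairs(
        sorted(planted_ppi | _background_edges(cfg.n_background_ppi_edges)), kind="ppi"
    )

    truth = GroundTruth(
        modules=tuple(modules),
        target_pairs=EdgeSet.from_pairs(true_pairs, kind="target"),
        sponge_pairs=EdgeSet.from_pairs(sponge_pairs, kind="sponge"),
        planted_tf=planted_tf,
        planted_ppi=planted_ppi,
    )
    return SyntheticDataset(
        mirna_expr=mirna_expr,
        mrna_expr=mrna_expr,
        binding=binding,
        tf_edges=tf_edges,
        ppi_edges=ppi_edges,
        truth=truth,
        config=cfg,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the dataset in the TSV formats :mod:`mirsm.data_io` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(ds.mirna_expr, outdir / "mirna_expr.tsv")
    write_expression(ds.mrna_expr, outdir / "mrna_expr.tsv")
    write_binding_table(ds.binding, outdir / "binding.tsv")
    write_edge_list(ds.tf_edges, outdir / "tf_edges.tsv")
    write_edge_list(ds.ppi_edges, outdir / "ppi_edges.tsv")
    write_edge_list(ds.truth.sponge_pairs, outdir / "truth_sponges.tsv")
    write_edge_list(ds.truth.target_pairs, outdir / "truth_targets.tsv")
    truth_modules = [
        {"mirna_ids": sorted(mi), "mrna_ids": sorted(mr)} for mi, mr in ds.truth.modules
    ]
    manifest = {
        "config": asdict(ds.config),
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"),
    }
    with open(outdir / "truth_modules.json", "w") as fh:
        json.dump(truth_modules, fh, indent=1, sort_keys=True)
    manifest["files"] = sorted(set(manifest["files"]) | {"truth_modules.json"})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
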