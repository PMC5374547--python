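"""Cross-module overlap analysis and validation against ground truth.

Sponge interactions are identified purely by their unordered mRNA id pair;
an interaction found in two or more modules is *module-conserved*, one
found in exactly one module is *module-specific*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_io import EdgeSet, canonical_pair
from .sponge import SpongeModule


@dataclass(frozen=True)
class OverlapReport:
    """Interaction overlap structure across a set of sponge modules."""

    per_module: tuple[int, ...]
    pairwise: pd.DataFrame  # shared-interaction counts, modules x modules
    specific: frozenset  # pairs present in exactly one module
    conserved: frozenset  # pairs present in >= 2 modules

    def to_dict(self) -> dict:
        return {
            "per_module": list(self.per_module),
            "pairwise": self.pairwise.to_dict(),
            "n_specific": len(self.specific),
            "n_conserved": len(self.conserved),
            "specific": sorted(map(list, self.specific)),
            "conserved": sorted(map(list, self.conserved)),
        }


def interaction_overlap(modules: Sequence[SpongeModule]) -> OverlapReport:
    """Count module-specific and module-conserved interactions.

    The pairwise table's diagonal holds each module's interaction count;
    off-diagonal cells the size of the pairwise intersections.
    """
    if not modules:
        raise ValueError("need at least one module")
    pair_sets = [m.interaction_pairs() for m in modules]
    labels = [f"module_{k}" for k in range(1, len(modules) + 1)]
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i, si in enumerate(pair_sets):
        for j, sj in enumerate(pair_sets):
            table.iloc[i, j] = len(si) if i == j else len(si & sj)
    membership = Counter(p for s in pair_sets for p in s)
    specific = frozenset(p for p, c in membership.items() if c == 1)
    conserved = frozenset(p for p, c in membership.items() if c >= 2)
    return OverlapReport(
        per_module=tuple(len(s) for s in pair_sets),
        pairwise=table,
        specific=specific,
        conserved=conserved,
    )


def validate_interactions(
    predicted: Iterable[tuple[str, str]], truth: EdgeSet
) -> tuple[tuple[tuple[str, str], ...], int]:
    """Predicted sponge pairs confirmed by an unordered ground-truth set."""
    if truth.ordered:
        raise ValueError("sponge-interaction truth must be an unordered edge set")
    matched = sorted({canonical_pair(a, b) for a, b in predicted if (a, b) in truth})
    return tuple(matched), len(matched)


def validate_targets(reconstructed: EdgeSet, truth: EdgeSet) -> int:
    """Number of reconstructed miRNA->mRNA edges confirmed by ordered truth."""
    if not (reconstructed.ordered and truth.ordered):
        raise ValueError("target validation uses ordered miRNA->mRNA edge sets")
    return len(set(reconstructed.pairs) & set(truth.pairs))


def gene_list_overlap(ids: Iterable[str], reference: Iterable[str]) -> float:
    """Fraction of ``ids`` found in a reference gene list (0 for an empty input)."""
    ids = set(ids)
    if not ids:
        return 0.0
    return len(ids & set(reference)) / len(ids)
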