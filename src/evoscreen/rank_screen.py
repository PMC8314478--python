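"""Rank-based branch-length screen for rapidly evolving proteins.

For each single-copy gene a phylogeny is available; the total branch length
of the gene tree summarises the gene's overall evolutionary rate, while the
terminal branch subtending a focal species summarises its rate after that
species diverged.  Genes are ranked (ascending, rank 1 = shortest) by both
quantities, binned into consecutive groups by total-length rank so that no
general-rate category is over-represented, and within each bin the genes
with the largest rank discrepancy (focal rank minus total rank) are flagged
as rapidly evolving on the focal branch.

Defaults (bin size 300, top fraction 10%) follow the published screen of
2992 single-copy hymenopteran proteins, which selects exactly 300 genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ValidationError

__all__ = [
    "GeneTreeRecord",
    "extract_branch_lengths",
    "RankDiscrepancyScreen",
    "rank_screen",
]


@dataclass
class GeneTreeRecord:
    """Per-gene tree summary: focal terminal and total branch lengths.

    Lengths are in substitutions per site (or whatever unit the trees carry).
    The tree itself is optional once the two lengths are extracted.
    """

    gene_id: str
    focal_terminal_length: float
    total_length: float
    tree: dendropy.Tree | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        for name in ("focal_terminal_length", "total_length"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{self.gene_id}: {name} must be finite and >= 0")
        if self.focal_terminal_length > self.total_length + 1e-12:
            raise ValidationError(
                f"{self.gene_id}: focal terminal length exceeds total length"
            )


def extract_branch_lengths(
    tree: dendropy.Tree, focal_taxon: str
) -> tuple[float, float]:
    """Return (focal terminal branch length, total tree length).

    The focal terminal length is the length of the edge subtending the tip
    labelled ``focal_taxon``; the total length is the sum of all edge lengths.
    """
    focal_leaf = None
    total = 0.0
    for edge in tree.preorder_edge_iter():
        length = edge.length or 0.0
        if length < 0:
            raise ValidationError(f"negative branch length {length}")
        total += length
        node = edge.head_node
        if node.is_leaf() and node.taxon is not None and node.taxon.label == focal_taxon:
            focal_leaf = node
    if focal_leaf is None:
        raise KeyError(f"focal taxon {focal_taxon!r} is not a tip of the tree")
    return float(focal_leaf.edge.length or 0.0), float(total)


class RankDiscrepancyScreen(BaseEstimator):
    """Select genes whose focal-branch rank exceeds their total-length rank.

    Parameters
    ----------
    bin_size : int, default 300
        Number of genes per total-length-rank bin; the final bin keeps the
        remainder.
    top_fraction : float, default 0.10
        Fraction of each bin selected; the per-bin count is
        ``ceil(top_fraction * bin_size)``, so every non-empty bin contributes
        at least one gene.

    Ranks are ascending (rank 1 = shortest).  Equal lengths are ordered by
    larger focal terminal length first, then lexicographic gene id, before
    ranks are assigned, keeping each ranking a strict permutation of 1..N.
    The same rule breaks discrepancy ties during selection.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per gene: gene_id, total_length, focal_length, total_rank,
        focal_rank, discrepancy, bin_index, selected.
    selected_ : frozenset of str
        Gene ids flagged as rapidly evolving.
    """

    def __init__(self, bin_size: int = 300, top_fraction: float = 0.10):
        self.bin_size = bin_size
        self.top_fraction = top_fraction

    def fit(
        self, X: Sequence[GeneTreeRecord] | pd.DataFrame, y: None = None
    ) -> "RankDiscrepancyScreen":
        if not isinstance(self.bin_size, (int, np.integer)) or self.bin_size < 1:
            raise ValidationError("bin_size must be an integer >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValidationError("top_fraction must be in (0, 1]")
        df = _records_to_frame(X)
        n = len(df)
        if n == 0:
            raise ValidationError("no gene records supplied")
        if df["gene_id"].duplicated().any():
            dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"])
            raise ValidationError(f"duplicate gene ids: {dupes}")

        # Tie-break ordering: larger focal first, then gene_id, applied
        # symmetrically to both rankings so a fully degenerate input yields
        # identical ranks (all discrepancies zero).
        total_order = df.sort_values(
            ["total_length", "focal_length", "gene_id"],
            ascending=[True, False, True],
            kind="mergesort",
        ).index
        focal_order = df.sort_values(
            ["focal_length", "total_length", "gene_id"],
            ascending=[True, False, True],
            kind="mergesort",
        ).index
        df["total_rank"] = 0
        df.loc[total_order, "total_rank"] = np.arange(1, n + 1)
        df["focal_rank"] = 0
        df.loc[focal_order, "focal_rank"] = np.arange(1, n + 1)
        df["discrepancy"] = df["focal_rank"] - df["total_rank"]
        df["bin_index"] = (df["total_rank"] - 1) // self.bin_size + 1

        df["selected"] = False
        for _, members in df.groupby("bin_index"):
            k = math.ceil(self.top_fraction * len(members))
            chosen = members.sort_values(
                ["discrepancy", "focal_length", "gene_id"],
                ascending=[False, False, True],
                kind="mergesort",
            ).index[:k]
            df.loc[chosen, "selected"] = True

        df = df.sort_values("total_rank", kind="mergesort").reset_index(drop=True)
        self.results_ = df
        self.selected_ = frozenset(df.loc[df["selected"], "gene_id"])
        return self

    def overlap(self, other_genes: Iterable[str]) -> frozenset:
        """Intersection of the selected set with another gene set."""
        return self.selected_ & frozenset(other_genes)


def _records_to_frame(X: Sequence[GeneTreeRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        required = {"gene_id", "total_length", "focal_length"}
        missing = required - set(X.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        return X[["gene_id", "total_length", "focal_length"]].reset_index(drop=True)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in X],
            "total_length": [r.total_length for r in X],
            "focal_length": [r.focal_terminal_length for r in X],
        }
    )


def rank_screen(
    records: Sequence[GeneTreeRecord] | pd.DataFrame,
    bin_size: int = 300,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Run the rank-discrepancy screen and return its per-gene result table."""
    return RankDiscrepancyScreen(bin_size=bin_size, top_fraction=top_fraction).fit(
        records
    ).results_
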