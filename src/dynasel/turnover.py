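"""Gene age and loss inference from ortholog presence/absence on a dated tree.

A gene's minimum age is the age of the most recent common ancestor of the
species that still carry an ortholog (equivalently, the divergence time of the
two most distantly related carriers).  Losses are inferred under single-origin
Dollo parsimony: within the origin clade, every maximal subtree containing no
carrier is one loss event.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence, Union

import dendropy
import pandas as pd

__all__ = [
    "DatedSpeciesTree",
    "GeneAge",
    "LossEvent",
    "infer_gene_age",
    "infer_losses",
    "load_presence_matrix",
    "turnover_table",
]


class DatedSpeciesTree:
    """A rooted, ultrametric species tree with node ages in million years (Ma).

    Node ages are computed from branch lengths (leaves at age 0, ages
    non-decreasing root-ward); a deviation from ultrametricity beyond
    ``precision`` raises.  Multifurcations are allowed.
    """

    def __init__(self, tree: dendropy.Tree, precision: float = 1e-4) -> None:
        if tree.seed_node is None or not tree.leaf_nodes():
            raise ValueError("empty tree")
        self.tree = tree
        self.tree.is_rooted = True
        self.tree.calc_node_ages(ultrametricity_precision=precision)
        self._leaf_labels = frozenset(
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        )

    @classmethod
    def from_newick(cls, source: Union[str, Path], **kwargs) -> "DatedSpeciesTree":
        """Parse a newick tree from a path or a newick string."""
        text = None
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
            text = Path(source).read_text()
        else:
            text = str(source)
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        return cls(tree, **kwargs)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self._leaf_labels

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def _check_species(self, species: Sequence[str]) -> None:
        unknown = set(species) - self._leaf_labels
        if unknown:
            raise ValueError(f"species absent from tree: {sorted(unknown)}")

    def mrca(self, species: Sequence[str]) -> dendropy.Node:
        self._check_species(species)
        if len(set(species)) == 1:
            (label,) = set(species)
            return next(
                leaf for leaf in self.tree.leaf_node_iter() if leaf.taxon.label == label
            )
        return self.tree.mrca(taxon_labels=list(species))


def _leaf_set(node: dendropy.Node) -> tuple[str, ...]:
    return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


@dataclass(frozen=True)
class GeneAge:
    """Minimum gene age: MRCA age of all carrier species."""

    age_ma: float
    origin_clade: tuple[str, ...]
    species_specific: bool


@dataclass(frozen=True)
class LossEvent:
    """One inferred loss: a maximal carrier-free subtree within the origin clade."""

    clade: tuple[str, ...]


def infer_gene_age(
    present: Iterable[str], tree: DatedSpeciesTree
) -> GeneAge:
    """Age of the MRCA of all species carrying the gene.

    A gene present in a single species gets age 0 with a species-specific flag.
    """
    species = sorted(set(present))
    if not species:
        raise ValueError("gene must be present in at least one species")
    tree._check_species(species)
    origin = tree.mrca(species)
    return GeneAge(
        age_ma=float(origin.age),
        origin_clade=_leaf_set(origin),
        species_specific=len(species) == 1,
    )


def infer_losses(
    present: Iterable[str], tree: DatedSpeciesTree
) -> list[LossEvent]:
    """Loss events under single-origin Dollo parsimony.

    The origin is the MRCA of all carriers; each maximal subtree under it
    containing no carrier is one loss (a carrier-free child of a
    multifurcation counts as a single loss).
    """
    species = set(present)
    if not species:
        raise ValueError("gene must be present in at least one species")
    tree._check_species(sorted(species))
    origin = tree.mrca(sorted(species))
    losses: list[LossEvent] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            leaves = set(leaf.taxon.label for leaf in child.leaf_iter())
            if leaves & species:
                walk(child)
            else:
                losses.append(LossEvent(clade=tuple(sorted(leaves))))

    walk(origin)
    return losses


def load_presence_matrix(
    source: Union[str, Path, pd.DataFrame], tree: DatedSpeciesTree | None = None
) -> pd.DataFrame:
    """Read a genes x species 0/1 presence matrix (TSV, first column = gene).

    Validates that species are tree leaves (when a tree is given) and that
    every gene is present in at least one species.
    """
    if isinstance(source, pd.DataFrame):
        matrix = source.copy()
    else:
        matrix = pd.read_csv(source, sep="\t", index_col=0)
    matrix = matrix.astype(int).astype(bool)
    if tree is not None:
        unknown = set(matrix.columns) - tree.leaf_labels
        if unknown:
            raise ValueError(f"species absent from tree: {sorted(unknown)}")
    empty = matrix.index[~matrix.any(axis=1)]
    if len(empty):
        raise ValueError(f"genes present in no species: {list(empty)}")
    return matrix


def turnover_table(matrix: pd.DataFrame, tree: DatedSpeciesTree) -> pd.DataFrame:
    """Per-gene age and loss summary (gene, age_Ma, species_specific, n_losses,
    lost_clades) for a presence matrix over the tree's species."""
    rows = []
    for gene, row in matrix.iterrows():
        carriers = [sp for sp, present in row.items() if present]
        age = infer_gene_age(carriers, tree)
        losses = infer_losses(carriers, tree)
        rows.append(
            {
                "gene": gene,
                "age_Ma": age.age_ma,
                "species_specific": age.species_specific,
                "n_losses": len(losses),
                "lost_clades": ";".join(",".join(l.clade) for l in losses),
            }
        )
    return pd.DataFrame(rows)
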