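"""Gene-set contingency analysis: does evolutionary dynamism predict essentiality?

Builds 2x2 contingency tables from per-gene categorical attributes (essential,
conserved across the species group, positively selected) and tests association
with the two-tailed Fisher exact test.  Also covers the rescue-cross sex-ratio
comparison (male:female counts under two rescue genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .mk_core import fisher_exact_two_tailed

__all__ = [
    "GeneAttributeTable",
    "ContingencyTable",
    "load_gene_table",
    "build_contingency",
    "association_test",
    "sex_ratio_comparison",
    "ATTRIBUTE_LEVELS",
]

#: allowed values per attribute column; the first two levels are the
#: contingency rows/columns (in order), anything after is treated as missing
ATTRIBUTE_LEVELS: dict[str, tuple[str, ...]] = {
    "essential": ("yes", "no", "missing"),
    "conserved_all_species": ("yes", "no"),
    "positively_selected": ("yes", "no", "untestable"),
}

_MISSING_LEVELS = frozenset({"missing", "untestable"})


@dataclass(frozen=True)
class GeneAttributeTable:
    """Validated per-gene attribute table keyed by unique gene symbol."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        frame = self.frame
        if "gene" not in frame.columns:
            raise ValueError("gene table requires a 'gene' column")
        dup = frame["gene"][frame["gene"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate gene symbols: {sorted(dup.unique())}")
        for column, levels in ATTRIBUTE_LEVELS.items():
            if column not in frame.columns:
                continue
            bad = ~frame[column].isin(levels)
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise ValueError(
                    f"column {column!r}, row {row + 1} "
                    f"(gene {frame['gene'].iloc[row]!r}): value "
                    f"{frame[column].iloc[row]!r} not in {levels}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> list[str]:
        return list(self.frame["gene"])


def load_gene_table(
    source: Union[str, Path, TextIO, pd.DataFrame], provenance: str = ""
) -> GeneAttributeTable:
    """Load and validate a TSV gene-attribute table.

    Requires a header with ``gene`` plus at least one known attribute column;
    unknown attribute values raise with the offending row number.
    """
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        frame = pd.read_csv(source, sep="\t", dtype=str)
    if "gene" not in frame.columns:
        raise ValueError("missing required column 'gene'")
    known = set(ATTRIBUTE_LEVELS) & set(frame.columns)
    if not known:
        raise ValueError(
            f"no attribute columns found; expected at least one of {sorted(ATTRIBUTE_LEVELS)}"
        )
    return GeneAttributeTable(frame=frame, provenance=provenance)


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 count table with labels and the number of rows dropped as missing."""

    counts: np.ndarray
    row_attribute: str
    col_attribute: str
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    n_excluded_missing: int

    def as_list(self) -> list[list[int]]:
        return self.counts.astype(int).tolist()


def build_contingency(
    table: GeneAttributeTable,
    attr_a: str,
    attr_b: str,
    drop_missing: bool = True,
) -> ContingencyTable:
    """Cross-tabulate two binary attributes into a 2x2 table.

    Rows are ``attr_a`` levels (``yes`` first), columns ``attr_b`` levels.
    Genes missing either attribute (``missing``/``untestable``) are dropped
    and counted in ``n_excluded_missing``.
    """
    frame = table.frame
    if len(frame) == 0:
        raise ValueError("empty gene table")
    for attr in (attr_a, attr_b):
        if attr not in frame.columns:
            raise ValueError(f"attribute {attr!r} not present in gene table")
    usable = ~(frame[attr_a].isin(_MISSING_LEVELS) | frame[attr_b].isin(_MISSING_LEVELS))
    if not drop_missing and not usable.all():
        raise ValueError("missing attribute values present and drop_missing=False")
    kept = frame[usable]
    n_excluded = int((~usable).sum())
    counts = np.zeros((2, 2), dtype=int)
    levels = ("yes", "no")
    for attr, axis in ((attr_a, 0), (attr_b, 1)):
        observed = set(kept[attr].unique())
        if len(observed & set(levels)) < 2:
            raise ValueError(
                f"attribute {attr!r} has a single observed level {sorted(observed)}; "
                "contingency table degenerate"
            )
    for i, level_a in enumerate(levels):
        for j, level_b in enumerate(levels):
            counts[i, j] = int(((kept[attr_a] == level_a) & (kept[attr_b] == level_b)).sum())
    return ContingencyTable(
        counts=counts,
        row_attribute=attr_a,
        col_attribute=attr_b,
        row_labels=levels,
        col_labels=levels,
        n_excluded_missing=n_excluded,
    )


def association_test(ct: ContingencyTable) -> float:
    """Two-tailed Fisher exact p-value for a built contingency table."""
    return fisher_exact_two_tailed(ct.counts)


def sex_ratio_comparison(
    males_a: int, females_a: int, males_b: int, females_b: int
) -> float:
    """Compare two male:female recovery ratios with a two-tailed Fisher test.

    Used for rescue crosses: e.g. a conspecific rescue transgene recovering
    67 males:101 females versus a heterospecific one recovering 2:33.
    """
    counts = (males_a, females_a, males_b, females_b)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all-zero sex-ratio table")
    return fisher_exact_two_tailed([[males_a, females_a], [males_b, females_b]])
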