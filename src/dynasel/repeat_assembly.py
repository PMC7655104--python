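"""Repeat-assembly reference construction and per-repeat count normalization.

To quantify repeat-derived expression, all genomic instances of each repeat
type are extracted (with fixed flanking sequence) and concatenated, separated
by runs of ``N``, into one pseudo-chromosome per repeat type.  Reads mapped to
this "repeat assembly" with a standard aligner can then be counted per
pseudo-chromosome.  This module builds the assembly and its instance offset
index, merges counts of reverse-complement simple-repeat pairs, and converts
raw counts to counts-per-million; read mapping itself is delegated to external
aligners.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "RepeatInstance",
    "RepeatAssembly",
    "PseudoChromosome",
    "read_genome_fasta",
    "read_repeat_annotations",
    "read_repeatmasker_out",
    "build_repeat_assembly",
    "merge_revcomp_simple_repeats",
    "canonical_simple_repeat",
    "normalize_counts",
]

DEFAULT_FLANK_BP = 75  # half the read length used for mapping
DEFAULT_SPACER_BP = 150

_SIMPLE_REPEAT_RE = re.compile(r"^\(([ACGT]+)\)n$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated genomic repeat instance (0-based half-open coordinates)."""

    repeat_type: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid instance coordinates {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IndexedInstance:
    """Placement of one instance inside its pseudo-chromosome."""

    instance: RepeatInstance
    offset: int  # 0-based start of the flanked segment in the pseudo-chromosome
    flank_left: int  # actual left flank after clipping at the contig edge
    flank_right: int

    @property
    def instance_offset(self) -> int:
        """Offset of the repeat instance proper (flank excluded)."""
        return self.offset + self.flank_left


@dataclass(frozen=True)
class PseudoChromosome:
    """One concatenated pseudo-chromosome for a repeat type."""

    repeat_type: str
    sequence: str
    index: tuple[IndexedInstance, ...]


@dataclass(frozen=True)
class RepeatAssembly:
    """The full repeat assembly: one pseudo-chromosome per repeat type."""

    chromosomes: dict[str, PseudoChromosome]
    flank_bp: int
    spacer_bp: int

    def __len__(self) -> int:
        return len(self.chromosomes)

    def to_fasta(self, destination: Union[str, Path, TextIO]) -> None:
        lines = []
        for name in self.chromosomes:
            lines.append(f">{name}")
            seq = self.chromosomes[name].sequence
            lines.extend(seq[i : i + 80] for i in range(0, len(seq), 80))
        text = "\n".join(lines) + "\n"
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)

    def index_frame(self) -> pd.DataFrame:
        """Offset index: where each genomic instance sits in its pseudo-chromosome."""
        rows = []
        for chrom in self.chromosomes.values():
            for item in chrom.index:
                ins = item.instance
                rows.append(
                    {
                        "repeat_type": ins.repeat_type,
                        "chrom": ins.chrom,
                        "start": ins.start,
                        "end": ins.end,
                        "strand": ins.strand,
                        "offset": item.offset,
                        "instance_offset": item.instance_offset,
                        "flank_left": item.flank_left,
                        "flank_right": item.flank_right,
                    }
                )
        return pd.DataFrame(rows)


def read_genome_fasta(source: Union[str, Path, TextIO]) -> dict[str, str]:
    """Genome FASTA -> {contig name: sequence} (uppercased)."""
    handle = str(source) if isinstance(source, (str, Path)) else source
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def read_repeat_annotations(source: Union[str, Path, TextIO, pd.DataFrame]) -> list[RepeatInstance]:
    """Read the simplified TSV annotation dialect (type, chrom, start, end, strand;
    0-based half-open coordinates)."""
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        frame = pd.read_csv(source, sep="\t")
    required = {"repeat_type", "chrom", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    strands = frame["strand"] if "strand" in frame.columns else ["+"] * len(frame)
    return [
        RepeatInstance(
            repeat_type=str(row.repeat_type),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(strand),
        )
        for row, strand in zip(frame.itertuples(index=False), strands)
    ]


def read_repeatmasker_out(source: Union[str, Path, TextIO]) -> list[RepeatInstance]:
    """Parse UCSC RepeatMasker ``.out`` whitespace format.

    The three header lines are skipped; 1-based inclusive query coordinates are
    converted to 0-based half-open.  Column 9 holds the strand (``+`` or ``C``
    for reverse), column 10 the repeat name.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    instances: list[RepeatInstance] = []
    for line in text.splitlines():
        fields = line.split()
        if len(fields) < 11 or not fields[0].replace(".", "").isdigit():
            continue  # header or blank
        chrom = fields[4]
        start = int(fields[5]) - 1
        end = int(fields[6])
        strand = "-" if fields[8] == "C" else "+"
        name = fields[9]
        instances.append(
            RepeatInstance(repeat_type=name, chrom=chrom, start=start, end=end, strand=strand)
        )
    return instances


def build_repeat_assembly(
    genome: Union[Mapping[str, str], str, Path],
    annotations: Union[Sequence[RepeatInstance], str, Path],
    flank_bp: int = DEFAULT_FLANK_BP,
    spacer_bp: int = DEFAULT_SPACER_BP,
) -> RepeatAssembly:
    """Concatenate all instances of each repeat type into pseudo-chromosomes.

    Each instance is extracted as plus-strand genome sequence with ``flank_bp``
    of flanking sequence on both sides (clipped at contig edges) and instances
    are joined, in annotation order, by ``spacer_bp`` ``N`` characters.  The
    interior-placement length formula is
    ``sum(instance + 2*flank) + (n-1)*spacer`` per repeat type.
    """
    if not isinstance(genome, Mapping):
        genome = read_genome_fasta(genome)
    if not isinstance(annotations, Sequence) or isinstance(annotations, (str, Path)):
        path = Path(str(annotations))
        if path.suffix == ".out":
            annotations = read_repeatmasker_out(path)
        else:
            annotations = read_repeat_annotations(path)

    by_type: dict[str, list[RepeatInstance]] = {}
    for ins in annotations:
        if ins.chrom not in genome:
            raise ValueError(f"unknown contig {ins.chrom!r} in annotations")
        if ins.end > len(genome[ins.chrom]):
            raise ValueError(
                f"instance {ins.chrom}:{ins.start}-{ins.end} exceeds contig length "
                f"{len(genome[ins.chrom])}"
            )
        by_type.setdefault(ins.repeat_type, []).append(ins)

    chromosomes: dict[str, PseudoChromosome] = {}
    spacer = "N" * spacer_bp
    for repeat_type, instances in by_type.items():
        segments: list[str] = []
        index: list[IndexedInstance] = []
        offset = 0
        for i, ins in enumerate(instances):
            contig = genome[ins.chrom]
            lo = max(0, ins.start - flank_bp)
            hi = min(len(contig), ins.end + flank_bp)
            segment = contig[lo:hi]
            index.append(
                IndexedInstance(
                    instance=ins,
                    offset=offset,
                    flank_left=ins.start - lo,
                    flank_right=hi - ins.end,
                )
            )
            segments.append(segment)
            offset += len(segment) + spacer_bp
        chromosomes[repeat_type] = PseudoChromosome(
            repeat_type=repeat_type,
            sequence=spacer.join(segments),
            index=tuple(index),
        )
    return RepeatAssembly(chromosomes=chromosomes, flank_bp=flank_bp, spacer_bp=spacer_bp)


def _rotations(motif: str) -> Iterable[str]:
    return (motif[i:] + motif[:i] for i in range(len(motif)))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_simple_repeat(name: str) -> str:
    """Canonical name for a simple repeat ``(MOTIF)n``.

    The motif is replaced by the lexicographically smallest of all rotations of
    itself and of its reverse complement, so that a repeat and its reverse
    complement (e.g. ``(AC)n`` and ``(GT)n``) share one canonical name.
    Non-simple-repeat names are returned unchanged.
    """
    match = _SIMPLE_REPEAT_RE.match(name)
    if not match:
        return name
    motif = match.group(1)
    candidates = list(_rotations(motif)) + list(_rotations(reverse_complement(motif)))
    return f"({min(candidates)})n"


def merge_revcomp_simple_repeats(counts: Mapping[str, float]) -> dict[str, float]:
    """Sum counts of simple repeats that are reverse complements of one another."""
    merged: dict[str, float] = {}
    for name, value in counts.items():
        canon = canonical_simple_repeat(name)
        merged[canon] = merged.get(canon, 0.0) + value
    return merged


def normalize_counts(
    counts: Union[Mapping[str, float], Sequence[float], pd.Series, np.ndarray],
    total_fragments: float,
):
    """Counts-per-million: each count divided by (total fragments / 1e6)."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    scale = total_fragments / 1e6
    if isinstance(counts, Mapping):
        return {k: v / scale for k, v in counts.items()}
    if isinstance(counts, pd.Series):
        return counts / scale
    arr = np.asarray(counts, dtype=float) / scale
    return arr
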