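"""Codon alignments of population samples: parsing, validation, filtering, slicing.

The central container is :class:`PopulationAlignment`: an in-frame, codon-aligned
set of ingroup haplotypes (a within-species population sample) together with one
sister-species reference sequence and, optionally, one outgroup reference used to
polarize fixed differences.  All downstream divergence/polymorphism counting
(:mod:`dynasel.mk_core`) consumes this container.

Coordinate conventions: codons are 1-based inclusive in every user-facing
interface (:class:`DomainSpan`); nucleotides are 0-based half-open internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PopulationAlignment",
    "DomainSpan",
    "ConsensusSequence",
    "MaskedSite",
    "read_alignment",
    "read_role_map",
    "write_alignment",
    "filter_low_frequency_variants",
    "major_allele_profile",
    "extract_domain",
    "masked_report_frame",
]

VALID_CHARS = frozenset("ACGTN-")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = "ACGT"
_BASE_ORDS = np.frombuffer(_BASES.encode(), dtype=np.uint8)

Roles = Mapping[str, str]
FastaSource = Union[str, Path, TextIO]


@dataclass(frozen=True)
class DomainSpan:
    """A named codon interval of a gene, 1-based inclusive.

    Used to restrict MK counting to individual protein domains (e.g. the ZAD,
    linker, or C2H2 zinc-finger region of a ZAD-ZNF gene).
    """

    name: str
    start_codon: int
    end_codon: int

    def __post_init__(self) -> None:
        if self.start_codon < 1 or self.end_codon < self.start_codon:
            raise ValueError(
                f"invalid domain span {self.name!r}: "
                f"start={self.start_codon}, end={self.end_codon}"
            )

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon + 1

    def overlaps(self, other: "DomainSpan") -> bool:
        return not (self.end_codon < other.start_codon or other.end_codon < self.start_codon)


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-site major-allele sequence of the ingroup with allele frequencies.

    ``frequencies[i]`` is the frequency of the major allele among non-missing
    ingroup alleles at site ``i`` (0.0 where every haplotype is missing, in
    which case the sequence carries ``N``).
    """

    sequence: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.frequencies):
            raise ValueError("consensus sequence and frequency vector lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


def _seq_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Sequences -> (n, L) uint8 matrix of character codes."""
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _base_counts(matrix: np.ndarray) -> np.ndarray:
    """Per-site counts of A, C, G, T (4, L); gaps and N are not counted."""
    return np.stack([(matrix == o).sum(axis=0) for o in _BASE_ORDS])


@dataclass(frozen=True)
class PopulationAlignment:
    """A codon-aligned population sample with sister and optional outgroup.

    Invariants (enforced at construction):

    * all sequences have equal length, divisible by 3;
    * alphabet is restricted to ``A C G T N -``;
    * at least two ingroup haplotypes;
    * the ingroup major-allele sequence contains no in-frame stop codon.
    """

    name: str
    ingroup: tuple[str, ...]
    sister: str
    outgroup: str | None = None
    ingroup_names: tuple[str, ...] = ()
    sister_name: str = "sister"
    outgroup_name: str = "outgroup"

    def __post_init__(self) -> None:
        ingroup = tuple(s.upper() for s in self.ingroup)
        object.__setattr__(self, "ingroup", ingroup)
        object.__setattr__(self, "sister", self.sister.upper())
        if self.outgroup is not None:
            object.__setattr__(self, "outgroup", self.outgroup.upper())
        if not self.ingroup_names:
            object.__setattr__(
                self, "ingroup_names", tuple(f"hap{i+1}" for i in range(len(ingroup)))
            )
        self._validate()

    def _validate(self) -> None:
        if len(self.ingroup) < 2:
            raise ValueError(f"{self.name}: need >=2 ingroup haplotypes, got {len(self.ingroup)}")
        seqs = list(self.ingroup) + [self.sister] + ([self.outgroup] if self.outgroup else [])
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"{self.name}: ragged alignment (lengths {sorted(lengths)})")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"{self.name}: alignment length {length} not divisible by 3")
        for s in seqs:
            bad = set(s) - VALID_CHARS
            if bad:
                raise ValueError(f"{self.name}: illegal characters {sorted(bad)}")
        consensus = major_allele_profile(self)
        for codon_idx in range(length // 3):
            codon = consensus.sequence[3 * codon_idx : 3 * codon_idx + 3]
            if codon in STOP_CODONS:
                raise ValueError(
                    f"{self.name}: in-frame stop codon {codon} in ingroup "
                    f"major-allele sequence at codon {codon_idx + 1}"
                )

    @property
    def length(self) -> int:
        return len(self.sister)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup)

    def ingroup_matrix(self) -> np.ndarray:
        return _seq_matrix(self.ingroup)


@dataclass(frozen=True)
class MaskedSite:
    """One minor allele masked to the major allele by the MAF filter."""

    site: int  # 1-based nucleotide position
    allele: str
    count: int
    frequency: float
    replacement: str


def major_allele_profile(aln: PopulationAlignment) -> ConsensusSequence:
    """Per-site most frequent non-missing ingroup allele with its frequency.

    Gaps and ``N`` are excluded from the denominator.  Ties are broken
    alphabetically (A < C < G < T); a site missing in every haplotype yields
    ``N`` with frequency 0.
    """
    matrix = _seq_matrix(aln.ingroup)
    counts = _base_counts(matrix)
    non_missing = counts.sum(axis=0)
    # argmax returns the first maximum, i.e. the alphabetically smallest base
    major = _BASE_ORDS[counts.argmax(axis=0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(non_missing > 0, counts.max(axis=0) / np.maximum(non_missing, 1), 0.0)
    major = np.where(non_missing > 0, major, np.uint8(ord("N"))).astype(np.uint8)
    return ConsensusSequence(major.tobytes().decode("ascii"), freqs)


def filter_low_frequency_variants(
    aln: PopulationAlignment, threshold: float = 0.05
) -> tuple[PopulationAlignment, list[MaskedSite]]:
    """Mask minor alleles below a minor-allele-frequency threshold.

    At every site where a minor allele's frequency among non-missing ingroup
    alleles is strictly below ``threshold``, that allele is replaced by the
    site's major allele in every carrier.  Sister and outgroup sequences are
    untouched.  Masking (rather than deleting columns) preserves coordinates,
    and a masked site can still contribute a fixed difference downstream.

    Returns the filtered alignment and a report of masked (site, allele) pairs.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"threshold must be in [0, 0.5], got {threshold}")
    matrix = _seq_matrix(aln.ingroup).copy()
    counts = _base_counts(matrix)
    non_missing = counts.sum(axis=0)
    major = _BASE_ORDS[counts.argmax(axis=0)]
    report: list[MaskedSite] = []
    if threshold > 0:
        for bi, base_ord in enumerate(_BASE_ORDS):
            allele_counts = counts[bi]
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs = allele_counts / np.maximum(non_missing, 1)
            to_mask = (allele_counts > 0) & (freqs < threshold) & (base_ord != major)
            for site in np.nonzero(to_mask)[0]:
                column = matrix[:, site]
                column[column == base_ord] = major[site]
                report.append(
                    MaskedSite(
                        site=int(site) + 1,
                        allele=chr(base_ord),
                        count=int(allele_counts[site]),
                        frequency=float(freqs[site]),
                        replacement=chr(major[site]),
                    )
                )
    report.sort(key=lambda m: (m.site, m.allele))
    n = aln.n_ingroup
    length = aln.length
    flat = matrix.tobytes().decode("ascii")
    new_ingroup = tuple(flat[i * length : (i + 1) * length] for i in range(n))
    filtered = PopulationAlignment(
        name=aln.name,
        ingroup=new_ingroup,
        sister=aln.sister,
        outgroup=aln.outgroup,
        ingroup_names=aln.ingroup_names,
        sister_name=aln.sister_name,
        outgroup_name=aln.outgroup_name,
    )
    return filtered, report


def masked_report_frame(report: Iterable[MaskedSite]) -> pd.DataFrame:
    """Masked-site report as a tidy table (site, allele, count, frequency, replacement)."""
    return pd.DataFrame(
        [(m.site, m.allele, m.count, m.frequency, m.replacement) for m in report],
        columns=["site", "allele", "count", "frequency", "replacement"],
    )


def extract_domain(aln: PopulationAlignment, span: DomainSpan) -> PopulationAlignment:
    """Slice the alignment to the codons of ``span`` (1-based inclusive), all roles alike."""
    if span.end_codon > aln.n_codons:
        raise ValueError(
            f"{aln.name}: span {span.name!r} ({span.start_codon}-{span.end_codon}) "
            f"exceeds alignment of {aln.n_codons} codons"
        )
    lo = 3 * (span.start_codon - 1)
    hi = 3 * span.end_codon
    return PopulationAlignment(
        name=f"{aln.name}:{span.name}",
        ingroup=tuple(s[lo:hi] for s in aln.ingroup),
        sister=aln.sister[lo:hi],
        outgroup=aln.outgroup[lo:hi] if aln.outgroup else None,
        ingroup_names=aln.ingroup_names,
        sister_name=aln.sister_name,
        outgroup_name=aln.outgroup_name,
    )


def read_role_map(tsv_source: Union[str, Path, TextIO]) -> dict[str, str]:
    """Read a sidecar role table (columns: name, role) into a mapping."""
    frame = pd.read_csv(tsv_source, sep="\t", dtype=str)
    missing = {"name", "role"} - set(frame.columns)
    if missing:
        raise ValueError(f"role map missing columns: {sorted(missing)}")
    return dict(zip(frame["name"], frame["role"]))


def read_alignment(
    fasta_source: FastaSource,
    role_map: Roles | None = None,
    name: str | None = None,
) -> PopulationAlignment:
    """Parse a FASTA population alignment into a validated :class:`PopulationAlignment`.

    Roles are taken from ``role_map`` (record name -> ``ingroup``/``sister``/
    ``outgroup``) when given, otherwise from a ``|role`` suffix on each FASTA
    header.  Exactly one sister is required and at most one outgroup is
    allowed; ingroup order is preserved.
    """
    if isinstance(fasta_source, (str, Path)):
        records = list(SeqIO.parse(str(fasta_source), "fasta"))
        default_name = Path(str(fasta_source)).stem
    else:
        records = list(SeqIO.parse(fasta_source, "fasta"))
        default_name = "alignment"
    if not records:
        raise ValueError("empty FASTA source")

    ingroup: list[str] = []
    ingroup_names: list[str] = []
    sister: list[tuple[str, str]] = []
    outgroup: list[tuple[str, str]] = []
    for rec in records:
        header = rec.id
        if role_map is not None:
            if header not in role_map:
                raise ValueError(f"no role for sequence {header!r}")
            seq_name, role = header, role_map[header]
        else:
            if "|" not in header:
                raise ValueError(
                    f"sequence {header!r} lacks a '|role' suffix and no role map was given"
                )
            seq_name, role = header.rsplit("|", 1)
        role = role.lower()
        seq = str(rec.seq).upper()
        if role == "ingroup":
            ingroup.append(seq)
            ingroup_names.append(seq_name)
        elif role == "sister":
            sister.append((seq_name, seq))
        elif role == "outgroup":
            outgroup.append((seq_name, seq))
        else:
            raise ValueError(f"unknown role {role!r} for sequence {seq_name!r}")

    if len(sister) != 1:
        raise ValueError(f"exactly one sister sequence required, found {len(sister)}")
    if len(outgroup) > 1:
        raise ValueError(f"at most one outgroup sequence allowed, found {len(outgroup)}")

    lengths = {len(s) for s in ingroup} | {len(sister[0][1])} | {len(o[1]) for o in outgroup}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")

    return PopulationAlignment(
        name=name or default_name,
        ingroup=tuple(ingroup),
        ingroup_names=tuple(ingroup_names),
        sister=sister[0][1],
        sister_name=sister[0][0],
        outgroup=outgroup[0][1] if outgroup else None,
        outgroup_name=outgroup[0][0] if outgroup else "outgroup",
    )


def write_alignment(aln: PopulationAlignment, destination: Union[str, Path, TextIO]) -> None:
    """Write the alignment as FASTA with ``|role`` header suffixes (round-trips with
    :func:`read_alignment`)."""
    records = [
        SeqRecord(Seq(seq), id=f"{nm}|ingroup", description="")
        for nm, seq in zip(aln.ingroup_names, aln.ingroup)
    ]
    records.append(SeqRecord(Seq(aln.sister), id=f"{aln.sister_name}|sister", description=""))
    if aln.outgroup is not None:
        records.append(
            SeqRecord(Seq(aln.outgroup), id=f"{aln.outgroup_name}|outgroup", description="")
        )
    if isinstance(destination, (str, Path)):
        with open(destination, "w") as handle:
            SeqIO.write(records, handle, "fasta")
    else:
        SeqIO.write(records, destination, "fasta")
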