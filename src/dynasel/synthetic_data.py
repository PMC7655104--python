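"""Synthetic inputs with ground truth for every pipeline stage.

Generates (i) codon alignments of a population sample plus sister and outgroup
references with planted, class-labelled substitutions and polymorphisms;
(ii) gene-attribute tables with a planted selection-essentiality odds ratio;
(iii) small genomes with planted repeat instances.  Each generator returns a
truth ledger recording exactly what was planted, so downstream counting can be
tested for exact parameter recovery.

Substitutions are planted by count rather than by continuous-time simulation:
the analysis consumes counts, and exact recovery is the test currency.  A
Poisson mode (``poisson=True``) draws each count from its configured mean
instead, for type-I-error and power experiments.

The default gene-history configuration emulates the shape of the study system:
a ~450-codon gene, a population sample of ~200 ingroup haplotypes (a single
large ancestral-range *D. melanogaster*-style sample) with one sister-species
and one outgroup reference, lineage-specific fixed differences on both the
focal and sister branches, common polymorphisms, and a handful of
low-frequency variants that sit below the 0.05 MAF filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_set_stats import GeneAttributeTable
from .mk_core import GENETIC_CODE, SENSE_CODONS
from .popgen_io import PopulationAlignment, STOP_CODONS
from .repeat_assembly import RepeatInstance

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "SubstitutionRecord",
    "PolymorphismRecord",
    "simulate_gene_history",
    "simulate_gene_table",
    "RepeatSpec",
    "simulate_repeat_genome",
    "write_annotations_tsv",
    "write_annotations_out",
    "write_genome_fasta",
]

_BRANCHES = ("focal", "sister", "outgroup")


@dataclass(frozen=True)
class SimulationConfig:
    """Planted-event configuration for one gene history.

    Counts are exact numbers of events unless ``poisson`` is set, in which
    case they are Poisson means.  With ``allow_multihit`` false (the default)
    no codon receives more than one event across all branches and the
    polymorphism layer, which makes downstream counting exactly invertible.
    """

    seed: int = 0
    name: str = "sim_gene"
    n_codons: int = 448
    n_ingroup_haplotypes: int = 197
    dn_focal: int = 17
    ds_focal: int = 8
    dn_sister: int = 26
    ds_sister: int = 16
    dn_outgroup: int = 30
    ds_outgroup: int = 20
    pn: int = 14
    ps: int = 20
    n_singleton_n: int = 5  # non-synonymous singletons, below the MAF filter
    n_singleton_s: int = 5
    poly_freq_range: tuple[float, float] = (0.10, 0.90)
    allow_multihit: bool = False
    poisson: bool = False
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_ingroup_haplotypes < 2:
            raise ValueError("need >= 2 ingroup haplotypes")
        counts = (
            self.dn_focal, self.ds_focal, self.dn_sister, self.ds_sister,
            self.dn_outgroup, self.ds_outgroup, self.pn, self.ps,
            self.n_singleton_n, self.n_singleton_s,
        )
        if any(c < 0 for c in counts):
            raise ValueError("event counts must be non-negative")
        lo, hi = self.poly_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("poly_freq_range must satisfy 0 < lo <= hi < 1")


@dataclass(frozen=True)
class SubstitutionRecord:
    branch: str
    codon: int  # 1-based
    site: int  # 1-based nucleotide
    ancestral: str
    derived: str
    synonymous: bool


@dataclass(frozen=True)
class PolymorphismRecord:
    codon: int
    site: int
    background: str
    derived: str
    synonymous: bool
    count: int
    frequency: float
    below_threshold: bool


@dataclass
class TruthLedger:
    """Record of every planted event, with tallies that equal the record lists."""

    substitutions: list[SubstitutionRecord] = field(default_factory=list)
    polymorphisms: list[PolymorphismRecord] = field(default_factory=list)

    def totals(self) -> dict[str, int]:
        t = {f"d{c}_{b}": 0 for b in _BRANCHES for c in ("n", "s")}
        t.update({"pn": 0, "ps": 0, "pn_low": 0, "ps_low": 0})
        for rec in self.substitutions:
            key = f"d{'s' if rec.synonymous else 'n'}_{rec.branch}"
            t[key] += 1
        for rec in self.polymorphisms:
            cls = "s" if rec.synonymous else "n"
            t[f"p{cls}_low" if rec.below_threshold else f"p{cls}"] += 1
        return t

    def expected_unpolarized(self) -> tuple[int, int, int, int]:
        """(Pn, Ps, Dn, Ds) the MK pipeline should recover after MAF filtering."""
        t = self.totals()
        return (
            t["pn"],
            t["ps"],
            t["dn_focal"] + t["dn_sister"],
            t["ds_focal"] + t["ds_sister"],
        )


def _single_step_changes(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """All (position, alternative base) single-nucleotide changes of the given
    class that do not create a stop codon."""
    out = []
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            derived = codon[:pos] + alt + codon[pos + 1 :]
            if derived in STOP_CODONS:
                continue
            if (GENETIC_CODE[codon] == GENETIC_CODE[derived]) == synonymous:
                out.append((pos, alt))
    return out


def _plant_event(
    rng: np.random.Generator,
    seqs: dict[str, list[str]],
    branch: str,
    synonymous: bool,
    available: list[int],
    allow_multihit: bool,
    max_retries: int,
) -> tuple[int, int, str, str]:
    """Choose a codon and apply one substitution of the requested class on a
    branch; returns (codon index, position, ancestral codon, derived codon)."""
    for _ in range(max_retries):
        if not available:
            raise RuntimeError("no codons left to mutate; reduce event counts")
        idx = int(rng.integers(len(available)))
        codon_idx = available[idx]
        current = seqs[branch][codon_idx]
        candidates = _single_step_changes(current, synonymous)
        if not candidates:
            continue
        pos, alt = candidates[int(rng.integers(len(candidates)))]
        derived = current[:pos] + alt + current[pos + 1 :]
        seqs[branch][codon_idx] = derived
        if not allow_multihit:
            available.pop(idx)
        return codon_idx, pos, current, derived
    raise RuntimeError(
        f"failed to place a {'synonymous' if synonymous else 'non-synonymous'} "
        f"change after {max_retries} retries"
    )


def _resolve_counts(config: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    names = (
        "dn_focal", "ds_focal", "dn_sister", "ds_sister",
        "dn_outgroup", "ds_outgroup", "pn", "ps",
        "n_singleton_n", "n_singleton_s",
    )
    out = {}
    for name in names:
        value = getattr(config, name)
        out[name] = int(rng.poisson(value)) if config.poisson else int(value)
    return out


def simulate_gene_history(
    config: SimulationConfig, seed: int | None = None
) -> tuple[PopulationAlignment, TruthLedger]:
    """Simulate one gene: ancestral sequence, per-branch fixed substitutions,
    and within-population polymorphisms, fully reproducible from the seed.

    The ancestral codon sequence is drawn uniformly from the 61 sense codons.
    Fixed substitutions are single-nucleotide changes of the requested
    synonymous/non-synonymous class (stop-creating changes are rejected)
    applied to the focal, sister, or outgroup-stem branch; polymorphisms are
    planted on the focal population at derived-allele frequencies drawn from
    ``poly_freq_range``, plus optional sub-threshold singletons.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = _resolve_counts(config, rng)
    n_events = sum(counts.values())
    if not config.allow_multihit and n_events > config.n_codons:
        raise ValueError(
            f"{n_events} events cannot be planted one-per-codon in "
            f"{config.n_codons} codons"
        )

    ancestral = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=config.n_codons)]
    seqs = {branch: list(ancestral) for branch in _BRANCHES}
    available = list(range(config.n_codons))
    ledger = TruthLedger()

    for branch in _BRANCHES:
        for cls, synonymous in (("n", False), ("s", True)):
            for _ in range(counts[f"d{cls}_{branch}"]):
                codon_idx, pos, anc, der = _plant_event(
                    rng, seqs, branch, synonymous, available,
                    config.allow_multihit, config.max_retries,
                )
                ledger.substitutions.append(
                    SubstitutionRecord(
                        branch=branch,
                        codon=codon_idx + 1,
                        site=3 * codon_idx + pos + 1,
                        ancestral=anc,
                        derived=der,
                        synonymous=synonymous,
                    )
                )

    n = config.n_ingroup_haplotypes
    lo = max(1, math.ceil(config.poly_freq_range[0] * n))
    hi = min(n - 1, math.floor(config.poly_freq_range[1] * n))
    if lo > hi:
        raise ValueError("poly_freq_range admits no valid derived-allele count")
    haplotypes = np.array(
        [list("".join(seqs["focal"]))] * n, dtype="U1"
    )
    poly_events = (
        [(False, False)] * counts["pn"]
        + [(True, False)] * counts["ps"]
        + [(False, True)] * counts["n_singleton_n"]
        + [(True, True)] * counts["n_singleton_s"]
    )
    for synonymous, singleton in poly_events:
        codon_idx, pos, background, derived = _plant_event(
            rng, seqs, "focal", synonymous, available,
            config.allow_multihit, config.max_retries,
        )
        # _plant_event mutated the focal branch sequence; polymorphism means the
        # derived allele segregates, so restore the background as the base state
        seqs["focal"][codon_idx] = background
        k = 1 if singleton else int(rng.integers(lo, hi + 1))
        carriers = rng.choice(n, size=k, replace=False)
        haplotypes[carriers, 3 * codon_idx + pos] = derived[pos]
        ledger.polymorphisms.append(
            PolymorphismRecord(
                codon=codon_idx + 1,
                site=3 * codon_idx + pos + 1,
                background=background,
                derived=derived,
                synonymous=synonymous,
                count=k,
                frequency=k / n,
                below_threshold=singleton,
            )
        )

    ingroup = tuple("".join(row) for row in haplotypes)
    aln = PopulationAlignment(
        name=config.name,
        ingroup=ingroup,
        sister="".join(seqs["sister"]),
        outgroup="".join(seqs["outgroup"]),
    )
    return aln, ledger


def simulate_gene_table(
    n_genes: int = 91,
    p_selected: float = 12 / 91,
    p_essential_given_selected: float = 8 / 12,
    p_essential_given_not: float = 14 / 73,
    p_missing: float = 6 / 91,
    p_conserved: float = 61 / 91,
    seed: int = 0,
) -> tuple[GeneAttributeTable, dict]:
    """Simulate a per-gene attribute table with a planted selection-essentiality
    odds ratio; defaults place the expected margins near the study's gene set
    (91 genes, 12 positively selected, ~6 without phenotype data).

    Returns the table and a truth dict with the planted odds ratio and the
    per-gene latent draws.
    """
    rng = np.random.default_rng(seed)
    selected = rng.random(n_genes) < p_selected
    p_ess = np.where(selected, p_essential_given_selected, p_essential_given_not)
    essential = rng.random(n_genes) < p_ess
    missing = rng.random(n_genes) < p_missing
    conserved = rng.random(n_genes) < p_conserved

    def odds(p: float) -> float:
        return p / (1 - p) if p < 1 else math.inf

    planted_or = (
        odds(p_essential_given_selected) / odds(p_essential_given_not)
        if 0 < p_essential_given_not < 1
        else math.inf
    )
    frame = pd.DataFrame(
        {
            "gene": [f"gene{i + 1:03d}" for i in range(n_genes)],
            "essential": np.where(missing, "missing", np.where(essential, "yes", "no")),
            "conserved_all_species": np.where(conserved, "yes", "no"),
            "positively_selected": np.where(selected, "yes", "no"),
        }
    )
    truth = {
        "planted_odds_ratio": planted_or,
        "n_selected": int(selected.sum()),
        "n_essential": int(essential.sum()),
        "n_missing": int(missing.sum()),
    }
    return GeneAttributeTable(frame=frame, provenance=f"simulated seed={seed}"), truth


@dataclass(frozen=True)
class RepeatSpec:
    """One repeat type to plant: a simple-repeat motif or an explicit sequence."""

    name: str
    n_instances: int
    motif: str | None = None  # simple repeat, name conventionally "(MOTIF)n"
    sequence: str | None = None  # TE-like consensus
    lengths: tuple[int, ...] = ()  # per-instance lengths; motif repeats are cut to fit

    def instance_sequence(self, length: int) -> str:
        if self.sequence is not None:
            return self.sequence[:length]
        if self.motif is None:
            raise ValueError(f"repeat spec {self.name!r} needs a motif or a sequence")
        reps = -(-length // len(self.motif))
        return (self.motif * reps)[:length]


def simulate_repeat_genome(
    repeat_catalog: Sequence[RepeatSpec],
    n_contigs: int = 2,
    contig_length: int = 5000,
    seed: int = 0,
    edge_instance: bool = False,
) -> tuple[dict[str, str], list[RepeatInstance], list[dict]]:
    """Random background contigs with planted repeat instances at recorded,
    non-overlapping coordinates.

    With ``edge_instance`` the first planted instance starts at position 0 of
    the first contig, exercising flank clipping downstream.  Returns the
    genome, the annotation list, and a truth ledger of planted sequences.
    """
    if not repeat_catalog:
        raise ValueError("repeat catalog is empty")
    rng = np.random.default_rng(seed)
    contigs = {
        f"contig{i + 1}": list(
            "".join(np.array(list("ACGT"))[rng.integers(4, size=contig_length)])
        )
        for i in range(n_contigs)
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in contigs}
    instances: list[RepeatInstance] = []
    ledger: list[dict] = []
    contig_names = list(contigs)
    first = True
    for spec in repeat_catalog:
        lengths = spec.lengths or tuple(
            [len(spec.sequence) if spec.sequence else 5 * len(spec.motif or "ACGT")]
            * spec.n_instances
        )
        if len(lengths) != spec.n_instances:
            raise ValueError(f"{spec.name!r}: lengths do not match n_instances")
        for length in lengths:
            if length > contig_length:
                raise ValueError(
                    f"{spec.name!r}: instance of {length} bp exceeds contig length "
                    f"{contig_length}"
                )
            seq = spec.instance_sequence(length)
            placed = False
            for _ in range(1000):
                if first and edge_instance:
                    chrom, start = contig_names[0], 0
                else:
                    chrom = contig_names[int(rng.integers(len(contig_names)))]
                    start = int(rng.integers(contig_length - length + 1))
                end = start + length
                if any(not (end <= s or e <= start) for s, e in occupied[chrom]):
                    if first and edge_instance:
                        raise RuntimeError("edge placement collided")
                    continue
                occupied[chrom].append((start, end))
                contigs[chrom][start:end] = list(seq)
                instances.append(
                    RepeatInstance(
                        repeat_type=spec.name, chrom=chrom, start=start, end=end, strand="+"
                    )
                )
                ledger.append(
                    {"repeat_type": spec.name, "chrom": chrom, "start": start,
                     "end": end, "sequence": seq}
                )
                placed = True
                first = False
                break
            if not placed:
                raise RuntimeError(
                    f"could not place an instance of {spec.name!r} without overlap"
                )
    genome = {name: "".join(chars) for name, chars in contigs.items()}
    return genome, instances, ledger


def write_genome_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


def write_annotations_tsv(instances: Sequence[RepeatInstance], path) -> None:
    pd.DataFrame(
        [
            {"repeat_type": i.repeat_type, "chrom": i.chrom, "start": i.start,
             "end": i.end, "strand": i.strand}
            for i in instances
        ]
    ).to_csv(path, sep="\t", index=False)


def write_annotations_out(instances: Sequence[RepeatInstance], path) -> None:
    """Write annotations in RepeatMasker ``.out``-style whitespace format
    (1-based inclusive coordinates, 'C' for minus strand)."""
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as handle:
        handle.write(header)
        for k, ins in enumerate(instances, start=1):
            strand = "C" if ins.strand == "-" else "+"
            handle.write(
                f"  100  0.0  0.0  0.0  {ins.chrom}  {ins.start + 1}  {ins.end}  (0)  "
                f"{strand}  {ins.repeat_type}  Unknown  1  {ins.length}  (0)  {k}\n"
            )
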