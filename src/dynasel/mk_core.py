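"""Codon-aware McDonald-Kreitman statistics.

The McDonald-Kreitman (MK) test compares the ratio of non-synonymous to
synonymous fixed differences between a focal species and its sister species
(Dn:Ds) with the same ratio among polymorphisms segregating within the focal
population (Pn:Ps).  Under neutrality the two ratios agree; an excess of fixed
non-synonymous changes (neutrality index NI < 1) indicates adaptive fixation.

This module classifies each change as synonymous or non-synonymous by
enumerating minimal mutational pathways between codons (Nei-Gojobori style),
polarizes fixed differences onto the focal or sister lineage with an outgroup
under parsimony, and assembles whole-gene and per-domain MK tables with
neutrality indices and p-values (Fisher exact, Pearson chi-square, G-test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats

from .popgen_io import (
    ConsensusSequence,
    DomainSpan,
    PopulationAlignment,
    STOP_CODONS,
    extract_domain,
    filter_low_frequency_variants,
    major_allele_profile,
)

__all__ = [
    "PathwaySummary",
    "SiteClassCounts",
    "PolarizedCounts",
    "MKResult",
    "codon_change_paths",
    "count_polymorphisms",
    "count_divergence",
    "polarize",
    "neutrality_index",
    "fisher_exact_two_tailed",
    "chi_square_test",
    "run_mk",
    "results_to_table",
    "round_half_up",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _STANDARD_TABLE.stop_codons})
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD_TABLE.forward_table))

_ACGT = frozenset("ACGT")


def round_half_up(x: float) -> int:
    """Round a non-negative fractional count half-up for table-style reporting."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PathwaySummary:
    """Average synonymous/non-synonymous split over minimal codon pathways.

    ``dn_frac + ds_frac == n_diff`` whenever at least one pathway was used.
    ``per_site`` maps each differing codon position (0..2) to its fractional
    (dn, ds) contribution, which sums to the totals; this decomposition is what
    lineage polarization buckets site by site.
    """

    n_diff: int
    dn_frac: float
    ds_frac: float
    n_paths_used: int
    all_paths_hit_stop: bool = False
    per_site: tuple[tuple[int, float, float], ...] = ()


@lru_cache(maxsize=None)
def _paths_cached(codon_a: str, codon_b: str) -> PathwaySummary:
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    n_diff = len(diffs)
    if n_diff == 0:
        return PathwaySummary(0, 0.0, 0.0, 0)

    # steps per ordering: list of (position, is_synonymous); admissible if no
    # intermediate codon is a stop
    orderings: list[tuple[bool, list[tuple[int, bool]]]] = []
    for order in permutations(diffs):
        current = codon_a
        hit_stop = False
        steps: list[tuple[int, bool]] = []
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((pos, GENETIC_CODE[current] == GENETIC_CODE[nxt]))
            if nxt != codon_b and nxt in STOP_CODONS:
                hit_stop = True
            current = nxt
        orderings.append((hit_stop, steps))

    admissible = [steps for hit, steps in orderings if not hit]
    all_hit_stop = not admissible
    used = admissible if admissible else [steps for _, steps in orderings]

    site_dn = {pos: 0.0 for pos in diffs}
    site_ds = {pos: 0.0 for pos in diffs}
    for steps in used:
        for pos, is_syn in steps:
            if is_syn:
                site_ds[pos] += 1.0
            else:
                site_dn[pos] += 1.0
    k = len(used)
    per_site = tuple((pos, site_dn[pos] / k, site_ds[pos] / k) for pos in sorted(diffs))
    dn = sum(v for _, v, _ in per_site)
    ds = sum(v for _, _, v in per_site)
    return PathwaySummary(n_diff, dn, ds, k, all_hit_stop, per_site)


def codon_change_paths(codon_a: str, codon_b: str) -> PathwaySummary:
    """Classify the nucleotide differences between two codons.

    All orderings of the differing positions are enumerated; orderings passing
    through a stop codon are discarded, and the synonymous/non-synonymous split
    of the steps is averaged over the admissible orderings.  If every ordering
    hits a stop, the average is taken over all orderings and flagged.

    Both codons must be gap-free, unambiguous, and not themselves stop codons.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for codon in (codon_a, codon_b):
        if len(codon) != 3 or not set(codon) <= _ACGT:
            raise ValueError(f"codon {codon!r} contains gaps or ambiguous bases")
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon!r} is not a valid pathway endpoint")
    return _paths_cached(codon_a, codon_b)


@dataclass(frozen=True)
class SiteClassCounts:
    """The MK quadruple: polymorphisms (Pn, Ps) and fixed differences (Dn, Ds).

    Counts are kept fractional internally (multi-difference codons contribute
    pathway averages) and rounded half-up for table-style reporting.
    """

    pn: float = 0.0
    ps: float = 0.0
    dn: float = 0.0
    ds: float = 0.0

    def rounded(self) -> "SiteClassCounts":
        return SiteClassCounts(*(round_half_up(v) for v in (self.pn, self.ps, self.dn, self.ds)))

    def divergence_table(self) -> list[list[int]]:
        """2x2 [[Dn, Ds], [Pn, Ps]] of rounded counts, as tested in an MK table."""
        r = self.rounded()
        return [[int(r.dn), int(r.ds)], [int(r.pn), int(r.ps)]]


@dataclass(frozen=True)
class PolarizedCounts:
    """Fixed differences apportioned to the focal and sister lineages.

    ``focal + sister + ambiguous`` equals the unpolarized fixed-difference
    count, separately for Dn and Ds, on every input (per-site pathway
    contributions are bucketed, never recomputed).
    """

    focal_dn: float = 0.0
    focal_ds: float = 0.0
    sister_dn: float = 0.0
    sister_ds: float = 0.0
    ambiguous_dn: float = 0.0
    ambiguous_ds: float = 0.0

    @property
    def total_dn(self) -> float:
        return self.focal_dn + self.sister_dn

    @property
    def total_ds(self) -> float:
        return self.focal_ds + self.sister_ds


@dataclass(frozen=True)
class MKResult:
    """MK statistics for one region (whole gene or a domain)."""

    gene: str
    region: str
    n_codons: int
    counts: SiteClassCounts
    ni: float | None
    p_fisher: float | None
    p_chisq: float | None
    polarized: PolarizedCounts | None = None
    ni_polarized: float | None = None
    p_fisher_polarized: float | None = None
    p_chisq_polarized: float | None = None
    flags: tuple[str, ...] = ()
    ledger: tuple[dict, ...] = ()


def _codon_clean(codon: str) -> bool:
    return set(codon) <= _ACGT


def count_polymorphisms(
    aln: PopulationAlignment, consensus: ConsensusSequence | None = None
) -> tuple[float, float, list[dict]]:
    """Count non-synonymous (Pn) and synonymous (Ps) segregating changes.

    Each segregating change among the observed ingroup codons is classified as
    a single step from the site's major-allele codon background.  Haplotypes
    with gaps/``N`` in a codon are skipped for that codon; a codon missing in
    every haplotype is skipped and logged.

    Returns ``(Pn, Ps, ledger)`` where the ledger records each classified
    change (and skipped codons).
    """
    if consensus is None:
        consensus = major_allele_profile(aln)
    matrix = aln.ingroup_matrix()
    counts = np.stack([(matrix == ord(c)).sum(axis=0) for c in "ACGT"])
    segregating = np.nonzero((counts > 0).sum(axis=0) > 1)[0]
    pn = ps = 0.0
    ledger: list[dict] = []
    for codon_idx in sorted({int(s) // 3 for s in segregating}):
        lo = 3 * codon_idx
        background = consensus.sequence[lo : lo + 3]
        codon_block = matrix[:, lo : lo + 3]
        clean = np.all(
            (codon_block[:, :, None] == np.frombuffer(b"ACGT", dtype=np.uint8)).any(axis=2),
            axis=1,
        )
        if not clean.any() or not _codon_clean(background):
            ledger.append({"kind": "skipped_codon", "codon": codon_idx + 1, "region": None})
            continue
        observed = {bytes(row).decode("ascii") for row in codon_block[clean]}
        changes: set[tuple[int, str]] = set()
        for codon in observed:
            for pos in range(3):
                if codon[pos] != background[pos]:
                    changes.add((pos, codon[pos]))
        for pos, alt in sorted(changes):
            derived = background[:pos] + alt + background[pos + 1 :]
            synonymous = GENETIC_CODE[background] == GENETIC_CODE[derived]
            if synonymous:
                ps += 1.0
            else:
                pn += 1.0
            ledger.append(
                {
                    "kind": "polymorphism",
                    "codon": codon_idx + 1,
                    "site": lo + pos + 1,
                    "from": background,
                    "to": derived,
                    "class": "syn" if synonymous else "nonsyn",
                }
            )
    return pn, ps, ledger


def _fixed_difference_sites(consensus: ConsensusSequence, sister: str) -> np.ndarray:
    """0-based sites monomorphic in the ingroup whose allele differs from the sister."""
    cons = np.frombuffer(consensus.sequence.encode("ascii"), dtype=np.uint8)
    sis = np.frombuffer(sister.encode("ascii"), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    clean = (cons[:, None] == acgt).any(axis=1) & (sis[:, None] == acgt).any(axis=1)
    mono = consensus.frequencies >= 1.0
    return np.nonzero(clean & mono & (cons != sis))[0]


def _divergence_codons(
    consensus: ConsensusSequence, sister: str
) -> Iterable[tuple[int, str, str, list[int]]]:
    """Yield (codon_idx, consensus codon, derived codon, fixed positions) per codon
    carrying at least one fixed difference; skipped codons yield derived=None."""
    fixed = _fixed_difference_sites(consensus, sister)
    by_codon: dict[int, list[int]] = {}
    for site in fixed:
        by_codon.setdefault(int(site) // 3, []).append(int(site) % 3)
    for codon_idx in sorted(by_codon):
        lo = 3 * codon_idx
        ccod = consensus.sequence[lo : lo + 3]
        scod = sister[lo : lo + 3]
        if not (_codon_clean(ccod) and _codon_clean(scod)):
            yield codon_idx, ccod, None, by_codon[codon_idx]
            continue
        positions = by_codon[codon_idx]
        derived = "".join(
            scod[p] if p in positions else ccod[p] for p in range(3)
        )
        if ccod in STOP_CODONS or derived in STOP_CODONS:
            yield codon_idx, ccod, None, positions
            continue
        yield codon_idx, ccod, derived, positions


def count_divergence(
    consensus: ConsensusSequence, sister: str
) -> tuple[float, float, list[dict]]:
    """Count non-synonymous (Dn) and synonymous (Ds) fixed differences.

    A fixed difference is a site monomorphic in the (filtered) ingroup whose
    allele differs from the sister sequence; sites polymorphic in the ingroup
    contribute no divergence even when the sister differs.  Multi-difference
    codons are resolved by pathway averaging (:func:`codon_change_paths`), so
    fractional totals are returned.  Codons with gaps/``N`` in either sequence
    are skipped and logged.
    """
    if len(consensus) != len(sister):
        raise ValueError("consensus and sister sequences have different lengths")
    dn = ds = 0.0
    ledger: list[dict] = []
    for codon_idx, ccod, derived, positions in _divergence_codons(consensus, sister):
        if derived is None:
            ledger.append({"kind": "skipped_codon", "codon": codon_idx + 1})
            continue
        summary = codon_change_paths(ccod, derived)
        dn += summary.dn_frac
        ds += summary.ds_frac
        entry = {
            "kind": "divergence",
            "codon": codon_idx + 1,
            "sites": tuple(3 * codon_idx + p + 1 for p, _, _ in summary.per_site),
            "from": ccod,
            "to": derived,
            "dn": summary.dn_frac,
            "ds": summary.ds_frac,
        }
        if summary.all_paths_hit_stop:
            entry["all_paths_hit_stop"] = True
        ledger.append(entry)
    return dn, ds, ledger


def polarize(
    consensus: ConsensusSequence, sister: str, outgroup: str | None
) -> tuple[PolarizedCounts, list[dict]]:
    """Assign fixed differences to the focal or sister lineage with an outgroup.

    Per fixed-difference site, parsimony dictates: the change lies on the focal
    lineage iff sister == outgroup != focal; on the sister lineage iff
    focal == outgroup != sister; otherwise (three distinct alleles, or outgroup
    missing at the site) it is ambiguous and excluded from both lineages.

    Each site's fractional (dn, ds) contribution from the codon pathway
    decomposition is bucketed whole, so focal + sister + ambiguous reproduces
    the unpolarized counts exactly.
    """
    if outgroup is None:
        raise ValueError("polarization requires outgroup")
    if len(outgroup) != len(consensus):
        raise ValueError("outgroup sequence length differs from alignment")
    counts = {
        "focal": [0.0, 0.0],
        "sister": [0.0, 0.0],
        "ambiguous": [0.0, 0.0],
    }
    ledger: list[dict] = []
    for codon_idx, ccod, derived, _positions in _divergence_codons(consensus, sister):
        if derived is None:
            continue
        summary = codon_change_paths(ccod, derived)
        for pos, dn_i, ds_i in summary.per_site:
            site = 3 * codon_idx + pos
            focal_allele = consensus.sequence[site]
            sister_allele = sister[site]
            out_allele = outgroup[site]
            if out_allele not in _ACGT:
                bucket = "ambiguous"
            elif out_allele == sister_allele:
                bucket = "focal"
            elif out_allele == focal_allele:
                bucket = "sister"
            else:
                bucket = "ambiguous"
            counts[bucket][0] += dn_i
            counts[bucket][1] += ds_i
            ledger.append(
                {
                    "kind": "polarized",
                    "codon": codon_idx + 1,
                    "site": site + 1,
                    "focal": focal_allele,
                    "sister": sister_allele,
                    "outgroup": out_allele,
                    "lineage": bucket,
                    "dn": dn_i,
                    "ds": ds_i,
                }
            )
    polarized = PolarizedCounts(
        focal_dn=counts["focal"][0],
        focal_ds=counts["focal"][1],
        sister_dn=counts["sister"][0],
        sister_ds=counts["sister"][1],
        ambiguous_dn=counts["ambiguous"][0],
        ambiguous_ds=counts["ambiguous"][1],
    )
    return polarized, ledger


def neutrality_index(counts: SiteClassCounts) -> float | None:
    """Neutrality index NI = (Pn/Ps) / (Dn/Ds); NI < 1 suggests an excess of
    fixed non-synonymous changes (positive selection).

    Degenerate-count conventions: ``Dn == 0`` with ``Pn == 0`` is undefined
    (no signal on either axis); otherwise ``Pn == 0`` yields 0; ``Ds == 0``
    with ``Dn > 0`` yields 0; remaining ``Ps == 0`` or ``Dn == 0`` cases are
    undefined (``None``, rendered blank in tables).
    """
    pn, ps, dn, ds = counts.pn, counts.ps, counts.dn, counts.ds
    if min(pn, ps, dn, ds) < 0:
        raise ValueError("counts must be non-negative")
    if dn == 0 and pn == 0:
        return None
    if pn == 0:
        return 0.0
    if ds == 0 and dn > 0:
        return 0.0
    if ps == 0 or dn == 0:
        return None
    return (pn / ps) / (dn / ds)


def fisher_exact_two_tailed(table: Sequence[Sequence[float]]) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 table of non-negative counts.

    The two-tailed p is the exact hypergeometric sum of the probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed table's (no tail-doubling).  A zero row or column
    margin yields p = 1.0 by convention.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    arr = np.vectorize(round_half_up)(arr).astype(int)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1.0 by convention")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def chi_square_test(
    table: Sequence[Sequence[float]],
    correction: bool = False,
    method: str = "pearson",
) -> float:
    """Pearson chi-square (or G-test) p-value on a 2x2 table, 1 df.

    ``correction`` applies the Yates continuity correction; ``method='g'``
    switches to the log-likelihood-ratio G-test.  All expected cell counts
    must be positive.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    expected = stats.contingency.expected_freq(arr) if arr.sum() > 0 else np.zeros((2, 2))
    if (expected <= 0).any():
        raise ValueError("zero expected cell count; chi-square undefined")
    lambda_ = "log-likelihood" if method == "g" else "pearson"
    if method not in ("pearson", "g"):
        raise ValueError(f"unknown method {method!r}")
    result = stats.chi2_contingency(arr, correction=correction, lambda_=lambda_)
    return float(result[1])


def run_mk(
    aln: PopulationAlignment,
    domains: Sequence[DomainSpan] = (),
    *,
    maf_threshold: float = 0.05,
    polarize_lineages: bool | None = None,
    keep_ledger: bool = False,
) -> list[MKResult]:
    """Run the full MK analysis: one result per region, full-length first.

    The alignment is MAF-filtered once, then counted whole-gene and per domain.
    Polarization is performed when an outgroup is present (or when forced with
    ``polarize_lineages=True``, which errors without one).  Polarized
    neutrality indices and p-values reuse the region's unpolarized
    polymorphism counts with the focal-lineage fixed counts.
    """
    if polarize_lineages is None:
        polarize_lineages = aln.outgroup is not None
    if polarize_lineages and aln.outgroup is None:
        raise ValueError("polarization requires outgroup")
    for i, a in enumerate(domains):
        for b in domains[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"domain spans {a.name!r} and {b.name!r} overlap")

    filtered, _masked = filter_low_frequency_variants(aln, maf_threshold)
    regions: list[tuple[str, PopulationAlignment]] = [("full-length", filtered)]
    regions += [(span.name, extract_domain(filtered, span)) for span in domains]

    results: list[MKResult] = []
    for region_name, sub in regions:
        consensus = major_allele_profile(sub)
        pn, ps, poly_ledger = count_polymorphisms(sub, consensus)
        dn, ds, div_ledger = count_divergence(consensus, sub.sister)
        counts = SiteClassCounts(pn=pn, ps=ps, dn=dn, ds=ds)
        flags: list[str] = []
        rounded = counts.rounded()
        table = counts.divergence_table()

        if sum(sum(row) for row in table) == 0:
            flags.append("no-variation")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_fisher = fisher_exact_two_tailed(table)
        try:
            p_chisq = chi_square_test(table, correction=False)
        except ValueError:
            p_chisq = None
        ni = neutrality_index(rounded)

        pol = ni_pol = p_f_pol = p_c_pol = None
        pol_ledger: list[dict] = []
        if polarize_lineages:
            pol, pol_ledger = polarize(consensus, sub.sister, sub.outgroup)
            pol_counts = SiteClassCounts(
                pn=rounded.pn,
                ps=rounded.ps,
                dn=round_half_up(pol.focal_dn),
                ds=round_half_up(pol.focal_ds),
            )
            pol_table = pol_counts.divergence_table()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_f_pol = fisher_exact_two_tailed(pol_table)
            try:
                p_c_pol = chi_square_test(pol_table, correction=False)
            except ValueError:
                p_c_pol = None
            ni_pol = neutrality_index(pol_counts)

        ledger: tuple[dict, ...] = ()
        if keep_ledger:
            for entry in poly_ledger + div_ledger + pol_ledger:
                entry["region"] = region_name
            ledger = tuple(poly_ledger + div_ledger + pol_ledger)

        results.append(
            MKResult(
                gene=aln.name,
                region=region_name,
                n_codons=sub.n_codons,
                counts=counts,
                ni=ni,
                p_fisher=p_fisher,
                p_chisq=p_chisq,
                polarized=pol,
                ni_polarized=ni_pol,
                p_fisher_polarized=p_f_pol,
                p_chisq_polarized=p_c_pol,
                flags=tuple(flags),
                ledger=ledger,
            )
        )
    return results


def _fmt_ni(value: float | None) -> str:
    return "" if value is None else f"{value:.3f}"


def _fmt_p(value: float | None) -> str:
    if value is None:
        return ""
    if value < 0.01:
        return f"{value:.2g}"
    return f"{value:.3f}"


def results_to_table(results: Iterable[MKResult]) -> pd.DataFrame:
    """Assemble MK results into a table shaped like a published MK summary
    (gene, region, length, p, Dn, Ds, Pn, Ps, NI, polarized columns)."""
    rows = []
    for r in results:
        c = r.counts.rounded()
        row = {
            "gene": r.gene,
            "region": r.region,
            "n_codons": r.n_codons,
            "p_chisq": _fmt_p(r.p_chisq),
            "p_fisher": _fmt_p(r.p_fisher),
            "Dn": int(c.dn),
            "Ds": int(c.ds),
            "Pn": int(c.pn),
            "Ps": int(c.ps),
            "NI": _fmt_ni(r.ni),
        }
        if r.polarized is not None:
            p = r.polarized
            row.update(
                {
                    "p_polarized": _fmt_p(r.p_chisq_polarized),
                    "Dn_focal": round_half_up(p.focal_dn),
                    "Ds_focal": round_half_up(p.focal_ds),
                    "NI_polarized": _fmt_ni(r.ni_polarized),
                    "Dn_sister": round_half_up(p.sister_dn),
                    "Ds_sister": round_half_up(p.sister_ds),
                    "Dn_polarized_total": round_half_up(p.total_dn),
                    "Ds_polarized_total": round_half_up(p.total_ds),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
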