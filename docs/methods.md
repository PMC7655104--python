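# Methods

## Scope and model

`dynasel` implements a codon-aware McDonald–Kreitman (MK) analysis and its
surrounding gene-family bookkeeping. The MK framework assumes that synonymous
changes are effectively neutral, so the ratio of non-synonymous to synonymous
polymorphism within the focal population (Pn:Ps) estimates the constraint a
gene evolves under, and the corresponding ratio of fixed differences to the
sister species (Dn:Ds) should match it under neutrality. The neutrality index
NI = (Pn/Ps)/(Dn/Ds) summarizes the departure; NI < 1 indicates an excess of
fixed non-synonymous differences, the signature of recurrent positive
selection. The analysis operates on a codon alignment of ≥ 2 ingroup
haplotypes, one sister-species reference, and optionally one outgroup
reference, and assumes the alignment is in frame and already built and
trimmed — alignment construction is out of scope.

## Counting rules

**MAF filter.** Before counting, variants whose minor-allele frequency among
non-missing ingroup alleles is strictly below the threshold (default 0.05)
are masked to the site's major allele in every carrier. Masking, rather than
deleting columns, preserves coordinates and lets a masked site still
contribute a fixed difference; this matches common MK-preprocessing practice.
The frequency denominator excludes gaps and `N`. Because the filter's
semantics (mask vs. delete; denominator under missing data) are a genuine
design choice, recomputed Pn/Ps may shift slightly relative to analyses made
with other tools.

**Major-allele consensus.** Per site, the most frequent non-missing ingroup
base; ties break alphabetically (A < C < G < T) for determinism; an all-missing
site yields `N` with frequency 0. Validation rejects alignments whose
consensus carries an in-frame stop codon.

**Polymorphism counting.** For each codon containing a segregating site, every
distinct (site, allele) change observed among gap-free haplotype codons is
classified as one step from the major-allele codon background: synonymous if
the amino acid is unchanged, else non-synonymous. Haplotypes with `N`/gaps in
a codon are skipped for that codon only.

**Divergence counting.** A fixed difference is a site monomorphic in the
filtered ingroup whose allele differs from the sister; sites still
polymorphic contribute nothing even when the sister differs (shared
polymorphism), and a sister allele at a polymorphic site never creates
divergence. Codons carrying k fixed differences are resolved by enumerating
all k! orderings of the changes, discarding orderings that pass through a
stop codon, and averaging the per-step synonymous/non-synonymous splits over
the admissible orderings (Nei–Gojobori-style pathway averaging). If every
ordering passes through a stop, the average is taken over all orderings and
flagged. Fractional counts are kept internally and rounded half-up only for
table-style reporting.

**Polarization.** Per fixed-difference site, parsimony assigns the change to
the focal lineage iff sister = outgroup ≠ focal, to the sister lineage iff
focal = outgroup ≠ sister, and otherwise (three alleles, or outgroup missing
at the site) to an ambiguous class excluded from both lineages. For
multi-difference codons, the pathway average is first decomposed into
per-site fractional (dn, ds) contributions (each pathway step is attributed
to the site it changes), and each site's contribution is bucketed whole.
This makes the additivity identity — focal + sister + ambiguous = unpolarized,
separately for Dn and Ds — an exact theorem on every input, and coincides
with classifying against the inferred ancestral codon in the
one-change-per-codon case, which dominates real data. Polarized NI and
p-values reuse the region's (unpolarized) Pn/Ps with the focal-lineage
Dn/Ds, following the convention of the published summary table.

## Test statistics

* **Fisher exact (two-tailed):** the exact hypergeometric sum of all tables
  with the observed margins whose point probability does not exceed the
  observed table's. This "sum of ≤-probable tables" definition differs from
  tail-doubling; it is the one implemented by `scipy.stats.fisher_exact` and
  verified in the test suite against an independent exact-rational
  enumeration oracle. A zero margin yields p = 1.0 by convention (logged).
* **Pearson χ², 1 df, no continuity correction:** the statistic used for the
  per-gene MK p-values (it reproduces the published MK-table p-values, which
  the Fisher and G variants do not at these counts). Yates-corrected and
  G-test variants are available; zero expected cells raise.
* **NI conventions:** Dn = 0 with Pn = 0 → undefined (no signal on either
  axis, rendered blank); Pn = 0 → 0; Ds = 0 with Dn > 0 → 0; remaining
  Ps = 0 or Dn = 0 cases → undefined. These mirror how the published table
  renders degenerate rows (blank when Dn = 0, `0.000` when only the
  polymorphism ratio vanishes).
* **Rounding:** counts half-up for reporting; NI to 3 decimals; p-values to
  3 decimals, or 2 significant figures below 0.01.

## Gene turnover

The species tree must be rooted and ultrametric (node ages are computed from
branch lengths; leaves sit at age 0; deviations beyond a precision of 1e-4
raise). Gene age is the MRCA age of all carriers — equal to the divergence
time of the two most distantly related carriers — with single-carrier genes
flagged species-specific at age 0. Losses assume a single origin and no
regain (Dollo): each maximal carrier-free subtree under the origin is one
loss; a carrier-free child of a multifurcation counts once. Choosing the
MRCA as origin minimizes the loss count over all admissible origins
(verified exhaustively in the tests on trees of ≤ 8 leaves). Duplications
are out of scope; presence/absence matrices are treated as given inputs, not
re-derived from homology searches.

## Repeat assembly

Instances are extracted as plus-strand genome sequence regardless of
annotated strand (a downstream aligner handles read orientation, so counting
is unaffected), with `flank_bp = 75` (half of a 150 bp read) on each side,
clipped at contig boundaries, and concatenated in annotation-file order with
`spacer_bp = 150` `N`s between instances. For interior placements the
pseudo-chromosome length is Σ(instance + 2·flank) + (n−1)·spacer. Both the
UCSC RepeatMasker `.out` whitespace dialect (1-based inclusive, `C` = minus
strand) and a simplified 0-based half-open TSV are accepted. Simple-repeat
count merging canonicalizes each `(MOTIF)n` name to the lexicographically
smallest rotation of the motif or of its reverse complement; CPM
normalization divides by (total fragments / 1e6). Instance ordering and
flank clipping are conventions without effect on counting.

## Synthetic data

The generator plants events by count rather than by continuous-time
simulation: the analysis consumes counts, so exact recovery of the planted
(Pn, Ps, Dn-per-lineage, Ds-per-lineage) quadruple is the test currency. A
Poisson mode draws each count from its configured mean instead, for
type-I-error and power experiments. The ancestral sequence is uniform over
the 61 sense codons; each substitution is a single-nucleotide change of the
requested class, with stop-creating changes rejected (bounded retries,
default 1000). With multi-hit disallowed (the default) no codon receives
more than one event across all branches and the polymorphism layer — the
condition under which counting is exactly invertible; allowing multi-hits
exercises the fractional pathway machinery instead.

Defaults are chosen to emulate the study system: a 448-codon gene;
197 ingroup haplotypes (a single large ancestral-range population sample,
the scale of the population-genomic resources the analysis is designed for);
planted fixed differences 17/8 (focal non-syn/syn) and 26/16 (sister),
mirroring a strongly selected gene's published polarized counts; an
outgroup-stem at 30/20, the order of magnitude expected for a roughly
twice-deeper branch; 14 non-synonymous and 20 synonymous common
polymorphisms with derived-allele frequencies uniform on 10–90% of
haplotypes; and 5 + 5 singletons that fall below the 0.05 MAF filter so that
default runs exercise the filter's bookkeeping. What the generator does
*not* emulate: linkage and demography (no coalescent), sequencing error,
alignment error, codon-usage bias, and rate heterogeneity along the gene.
Passing the recovery tests therefore shows the counting machinery is exact
under its own assumptions, not that real alignments are free of those
complications.

The gene-table generator draws per-gene attributes independently with a
planted selection→essentiality odds ratio; defaults put the expected margins
near the study's 91-gene set. The repeat-genome generator plants
non-overlapping instances (optionally at a contig edge) on random background
and records exact coordinates and sequences.

## Problem sizes and stochastic test design

The test suite runs entirely on generated data: exact-recovery checks use
100 seeds of the default 448-codon/197-haplotype configuration; type-I-error
checks use 500 neutral replicates each — Poisson-rate gene histories
(expected ~30 counts per table cell, Pearson χ² as the test, since Fisher's
discreteness makes it conservative at these sizes) and 400-gene attribute
tables with balanced margins — asserted against the exact binomial 95% CI
around the nominal 0.05 ([0.031, 0.069]). The Fisher oracle enumerates
tables with N ≤ 40; Dollo minimality is brute-forced on random trees of ≤ 8
leaves. The full suite completes in well under a minute on one CPU.

## Known limitations

* Pn/Ps from real population data depend on filtering and manual-trimming
  choices that are not recoverable from published tables; the package
  reproduces published statistics from printed counts, and its own counting
  is validated against planted truth, not against re-derived raw counts.
* No α estimation (asymptotic MK), DoS, or ML dN/dS — deliberately out of
  scope.
* Polarization treats the outgroup allele as ancestral evidence under strict
  parsimony; parallel changes and multiple hits on deep branches bias
  lineage assignment toward "ambiguous" rather than being modelled.
* The gene-table generator draws attributes independently per gene; it does
  not model phylogenetic non-independence between related genes.
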