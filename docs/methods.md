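# Methods

## Model and procedure

The pipeline treats a comparative annotation survey as a three-stage
computation.

**Counting.** Annotation hits are parsed from NCBI BLAST tabular output
(12-column `-outfmt 6`; used for peptidase/MEROPS and transporter/TCDB
searches) and HMMER3 `--domtblout` tables (CAZyme/dbCAN searches; the
domain independent e-value, i-Evalue, is the filtering statistic). Family
identifiers are extracted from subject ids — `<prefix>:<accession>` with
the family as the pre-dot part for MEROPS-style accessions (`A01.001` →
`A01`) and the first three dotted components for TCDB (`2.A.1.8.1` →
`2.A.1`) — with a user mapping file overriding parsing, since header
conventions vary across database releases. The e-value cutoff is
**inclusive** (≤), fixed for determinism. Hits are resolved to assignments
under one of three policies; the default,
`per_protein_per_family_once`, counts distinct proteins per family, because
HSP-level counting double-counts multi-domain proteins while
best-family-per-protein hides genuine multi-family proteins. Families
absent from an organism are counts of zero, never missing, so contrasts
always use full group sizes.

**Contrasts.** Lifestyle groups are multi-label and may overlap; by default
shared organisms stay in both samples of a contrast (`drop_shared`
excludes them from both sides instead — the default exposes rather than
hides the independence violation inherent in overlapping groups). For each
of the 45 unordered label pairs (or an explicit `pairs:` list) and each
family, the package computes group medians (midpoint convention for even
sizes), the absolute median difference, and a two-sided
Mann–Whitney–Wilcoxon test. The exact permutation p (a subset-sum dynamic
programme over doubled midranks, so ties are handled by the true
permutation distribution) is used when requested or automatically for
tie-free pooled samples of ≤ 12; otherwise the normal approximation with
tie and continuity correction (scipy). An all-identical pooled sample is
degenerate: p = 1. A contrast with an empty group is skipped with a logged
warning.

**Listing and selection.** Eligible families (nonzero median difference
and, by default, significance) are ranked by absolute median difference;
ties at the top-k cutoff break by smaller p, then family id, so reruns are
bit-identical. `max_k` defaults to 10. Families listed in ≥
`min_recurrence` = 3 contrasts are selected. The packaged reference table
of previously reported differential families annotates the output and
never influences selection.

## Multiple testing: why Benjamini–Hochberg is the default

The significance gate defaults to a per-contrast Benjamini–Hochberg step at
α = 0.05 rather than the raw p < α rule. The reason is measurable: a screen
of 200 families over 45 correlated contrasts produces, uncorrected, about
ten nominally significant families per contrast under the null (per-test
calibration is fine — 0.048 at nominal 0.05); because every eligible family
then fits the top-ten list and the overlapping groups correlate the
contrasts, recurrence ≥ 3 becomes common noise behaviour, and ~17% of
families are "selected" with nothing planted, with a fold-8 planted
false-discovery proportion of ~0.66. With the BH step the null selection
fraction drops to ~0% and the fold-8 FDP to ~0.005, at a sensitivity cost
(≈ 0.85 rather than 1.0 at fold 8 — losses concentrate in low-baseline
families near the detection boundary). A recurrence heuristic without
error control is not defensible as a default; `correction: none`
reproduces the uncorrected historical procedure for comparison.

The Shapiro–Wilk diagnostic (scipy's Royston approximation) is reported
per sample but gates nothing; samples with n < 3 or no variation are
flagged "not assessable" rather than raising.

## Curation filter

Catalytic positions and conserved regions are specified in 1-based
coordinates of an ungapped reference present in the alignment and mapped
to columns through the reference row's gaps. A sequence fails on
`catalytic_gap` (gap character `-` or `.` at a catalytic column),
`invalid_substitution` (residue outside the allowed set; default strict =
the reference/spec residue, relaxed mode accepts same-chemistry groups
S/T/C, D/E, K/R/H, N/Q), or `conserved_region_deletion` (gap fraction
> 0.5 across the region's columns; threshold configurable — the manual
criterion "deletion in the conserved region" needs a numeric
operationalisation to be testable). Verdicts are per-sequence independent,
so curation is idempotent and removing one sequence never changes
another's status.

## Synthetic studies

The generator emulates the statistical shape of real annotation surveys,
not their sequences. Counts are negative-binomial (mean μ_f, dispersion
k_f; variance μ + μ²/k) because family copy numbers are overdispersed
across lineages — whole-genome duplications alone guarantee that. Default
baselines are heterogeneous: μ_f log-uniform on [1, 20] copies, k_f uniform
on [1, 4], drawn once per scenario seed. Organisms cycle deterministically
through eight ecotype bundles of co-occurring labels (terrestrial
saprotroph, aquatic saprotroph, plant pathogen, animal pathogen,
opportunist/commensal, endophyte/mutualist, aquatic parasite, terrestrial
mutualist), so lifestyle groups overlap as in real surveys while every
label keeps a distinct organism set. A planted expansion multiplies one
family's mean by a fold factor in carriers of one label; planted labels
are restricted to groups of ≥ 8 carriers.

Emitted hit files use placeholder alignments and a fixed e-value of 1e-50
(below any sensible cutoff) with one unique synthetic protein id per count,
so parse → filter → assign → count reconstructs the generating row exactly
under every policy. The generator does not emulate sequence evolution,
realistic score distributions, annotation noise (false or missed hits), or
phylogenetic autocorrelation between organisms — so passing recovery tests
demonstrate the statistical machinery, not robustness to annotation error
or shared ancestry, neither of which the pipeline models (no phylogenetic
correction is applied, matching standard practice for this kind of
count screen).

## Problem sizes and measured behaviour

Calibration and recovery statements use the standard synthetic study:
40 organisms, 200 families, 20 replicate seeds, ten planted fold-8
expansions when planting; curation checks use 10 seeded fixtures of
9 sequences; exactness checks cover all group sizes n, m ≤ 6 against
brute-force enumeration at 10⁻¹² tolerance. Under the default config the
measured null selected fraction is ~0%, fold-8 sensitivity ≈ 0.85 with
FDP ≈ 0.005, and sensitivity degrades monotonically through folds
8 → 4 → 2 → 1 (≈ 0.85 / 0.34 / 0.0 / 0.0); the uncorrected variant trades
this for sensitivity 1.0 at FDP ≈ 0.66. The acceptance script reports only
quantities it recomputes at run time.

## Numerical and degenerate-input conventions

Exact MWW uses integer doubled midranks, so tied half-ranks stay exact;
two-sided p sums the permutation mass with |U − nm/2| at least the
observed value (the permutation distribution is symmetric under group
exchange). Medians use numpy's midpoint convention. Deterministic orderings
throughout: matrix columns sort by (database, family); selections by
(recurrence desc, family id); label pairs lexicographically. Empty inputs
are contracts, not crashes: an empty hit stream parses to an empty list, an
empty assignment set to an all-zero matrix, an empty contrast list to an
empty selection; configuration errors (non-positive e-value cutoff, unknown
policy or label, empty pair list) raise immediately.

## Known limitations

* Overlapping groups violate the two-sample independence assumption of the
  rank-sum test; `drop_shared` is available but shrinks groups.
* Recurrence counts contrasts, not independent evidence: duplicated or
  near-duplicated label extents inflate recurrence mechanically.
* The curation filter depends entirely on the user-supplied catalytic-site
  spec; no default spec claims to reproduce any published manual curation.
* Median differences are not effect sizes on a common scale across
  families with very different baselines.
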