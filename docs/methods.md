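# Methods

## Scope and data model

`rarehap` analyses a panel of per-locus multiple alignments: for each locus,
aligned sequences of many accessions of a focal species over
`{A, C, G, T, N, -}`, plus an aligned ortholog of an outgroup species named
in a tab-separated manifest.  Internally coordinates are 0-based half-open;
reports print 1-based positions.  A gap in an accession row is missing data
for substitution-level analysis; maximal gap runs are promoted to indel
events and analysed separately.  Ambiguity codes other than `N` are mapped
to `N` with a warning — the inputs this package targets are consensus
calls, where other codes are rare and uninterpretable for the haplotype
criterion.

Locus-level quality filters follow the design of resequencing panels with
patchy coverage: at least 60 accessions, at least 400 aligned bp, and
outgroup identity of at least 0.85 (a locus exactly at a threshold is
kept).  Identity is computed between the outgroup and the panel's
majority-rule consensus over columns where both carry a called base.  The
consensus is used rather than a privileged reference accession because it
is deterministic and accession-agnostic; on synthetic panels there is no
distinguished accession at all.

## Haplotype discovery

A *distinct haplotype* is a set of accessions separated from its complement
by at least `min_fixed = 5` perfectly co-segregating fixed substitutions.
Discovery is exact-carrier-set grouping: every biallelic column is assigned
the set of accessions carrying its minor allele (ties broken toward the
alphabetically smaller allele), columns are grouped by identical carrier
set, and any carrier set supported by `min_fixed` or more columns becomes a
candidate group.  Perfect co-segregation is deliberate — a
mismatch-tolerant clustering would blur the boundary between fixed (gSNP)
and non-fixed (nfSNP) substitutions, which the downstream statistics rely
on.

Missing data: a column enters discovery only if at least 80 % of
accessions are called there, so "fixed" remains meaningful; because
carrier sets are matched exactly, a column whose carrier set is perturbed
by missingness simply fails to join its group rather than corrupting it.

Candidates covering at least half the called sample are re-read from the
other side (the fixed substitutions separate both sides equally; the major
allele is by definition the larger side).  Candidates that overlap without
nesting are resolved by keeping the one with more supporting sites, then
fewer members, then the lexicographically smallest member tuple — the
delimitation of partially overlapping candidates is this package's
convention, as no published rule exists.  Nested candidates are all kept
(producing a *complex* locus); reported member sets are made disjoint by
assigning each accession to its smallest containing candidate, so the
groups always partition the called accessions.  Frequency labels use
counts over called accessions with strict thresholds: rare < 0.10,
intermediate < 0.50.

## Polarization and relative rates

For a biallelic site with a *focus* allele (the haplotype's allele at a
fixed substitution; the minor allele at a dispersed SNP) and an *other*
allele, the outgroup decides direction: outgroup = other ⇒ the focus
allele is the derived mutation; outgroup = focus ⇒ the mutation happened
on the other lineage (ancient); outgroup gapped, missing or a third state
⇒ excluded.  No parsimony rescue is attempted for third states.  Fixed
indels between haplotype groups are polarized the same way; indels whose
spans overlap but differ between groups are excluded.  Relative rates
(derived/ancient) print at two decimals, round-half-up; per-class tallies
always conserve derived + ancient + excluded = candidate sites.

`rate_by_frequency` bins sites by the focus-allele frequency and reports
the per-bin derived/ancient ratio.  Under neutrality a site whose minor
allele is at count i out of n is the derived one with odds (n−i)/i, so the
ratio decays with frequency; this decay is the package's calibration
property for the statistic.  (Binning by derived-allele frequency instead
would put only derived-polarized sites below 0.5 and make the per-bin
ratio degenerate, so the focus-frequency axis is the implemented
convention.)

The indel vs non-indel mutation-rate comparison defines an *indel locus*
as any locus containing at least one indel event, and compares polymorphic
sites per aligned bp between the two locus classes; restricting the indel
class to windows around events is available via `window_bp`.

## Statistics

* **Random occurrence.** If a single rare-allele type arises at a locus
  with probability F₁ (estimated as the fraction of loci with exactly one
  type), independence predicts E[Fᵢ] = F₁ⁱ for i types.  The χ² compares
  observed and expected counts over i = 1..5, pooling cells with expected
  count < 5 into the previous cell; df = cells − 1.  The pooling rule is
  standard small-count practice and is this package's choice.
* **Per-accession occurrence.** With p̂ = total rare memberships /
  (n_loci × n_accessions), each accession's membership count is
  Binomial(n_loci, p̂); accessions in the two-sided 1 % tail are flagged
  as outliers (the tail threshold is a convention).
* **Tajima's D** uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
  e₂) over complete-case columns only — columns with any gap or missing
  base are dropped from both S and π, which keeps the statistic
  deterministic under missing data.  D is undefined for S = 0 or n < 4.
* **Unfolded SFS.** Polarized sites are binned by derived-allele frequency
  into ten half-open bins [0, 0.1) … [0.9, 1); unpolarizable sites are
  excluded from both numerator and denominator.  The neutral expectation
  per derived count i is (1/i)/aₙ, aggregated into the same bins;
  frequency excess is observed/expected − 1.
* **Extrapolation to fixation.** An OLS quadratic through the binned
  counts is evaluated at frequency 1; Pearson r is computed between
  observed and fitted values.  Fixation probability is the high-frequency
  (0.9–1) to low-frequency (0–0.1) count ratio as a percentage.
* **Dxy** averages, over member accessions, the per-site difference
  fraction to the outgroup across columns where both are called.  Group
  contrasts use a two-sample permutation test on per-locus values (the
  test construction is a convention).
* **Codon effects** read the reference codon from the majority consensus
  (standing in for the major allele), substitute the derived (or focus)
  allele, and translate with the standard nuclear code; reverse-strand
  frames are handled by complementing.  Codons overlapping a gap or
  uncalled base are excluded.
* **Rare-allele extent** walks outward from the core locus in windows of
  500 bp and ends at the first window with no substitution fixed between
  the haplotype's members and the rest; flanks shorter than one window are
  flagged truncated.

## Synthetic panels

The generator emulates the study conditions of a selfing-annual
resequencing panel: n = 96 accessions, 500 bp loci, mean pairwise
diversity 0.44 % (θ per site = 0.0044 in coalescent units where
E[π] = θ), outgroup divergence 5 % per site, and optional implants.  The
background is a standard neutral coalescent: Kingman genealogy, mutations
Poisson with rate θ/2 per site per unit time on branches, infinite sites
placed uniformly at untouched columns.  Calibration is checked against
closed forms (E[S] = θ·aₙ·L within 5 %, E[π] = θ, singleton fraction
1/aₙ).  The outgroup is generated from the sample's common ancestor, so
every mutation's derived/ancient status is exact ground truth; an optional
misassignment rate corrupts the outgroup to exercise exclusion paths.

Structured loci add implants: a chosen carrier set receives private
substitutions at fresh columns (defaults: 5 carriers × 10 fixed sites for
a rare haplotype, matching the study's ≈10 fixed substitutions per rare
haplotype; 23.4 % of loci receive one, matching the observed rare-locus
fraction).  An indel implant gaps a carrier group over a short span and
adds carrier-private substitutions in the flanking window with per-bp mean
(multiplier − 1)·θ/2, emulating indel-associated local mutation-rate
elevation; the multiplier is exposed as a parameter and recovered
monotonically by the indel/non-indel rate comparison.

Randomness contract: one root seed; each locus uses an independent stream
keyed by `[seed, locus_index]`, so per-locus output is byte-identical
regardless of how many loci are generated.

What the generator does *not* emulate: recombination within loci,
selection, demographic history, population structure, alignment error, and
missing data patterns of real panels.  Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated model, not
robustness to all features of real data.

## Known behaviour of the haplotype criterion under neutrality

The ≥5-fixed-substitution criterion is not conservative against the
neutral coalescent at this diversity.  The basal bipartition of a neutral
genealogy is itself a perfectly co-segregating carrier set, and its two
root branches jointly carry a Poisson number of mutations with mean ≈
θ·L ≈ 2.2 and heavy (exponential branch-length) tails, so roughly a fifth
of purely neutral loci display a "distinct haplotype" — mostly at
intermediate frequency.  `null_haplotype_rate` measures this directly
(~0.21 at the defaults; ~0.06 for the rare class alone), and the
acceptance script reports the computed value.  Interpreting observed
haplotype counts therefore requires this simulated null as the reference,
not an assumption that neutral loci stay haplotype-free.

## Numerical conventions

Ratios print at two decimals and percentages at one, round-half-up
(`decimal.Decimal`); Ts/Tv uses three decimals.  Quadratic extrapolations
are rounded to one decimal before integer rounding to suppress
floating-point noise at exact .5 boundaries.  Undefined quantities (zero
ancient count, zero transversions, no comparable columns) are returned as
`None`/NA rather than raised, except where the input itself is invalid.
Reported χ² values are computed from the package's own pooling; where a
published statistic cannot be reproduced from its printed operands, the
computed value is authoritative.

## Limitations

* Haplotype delimitation under partial overlap and the per-side
  missing-data rule are this package's conventions; other choices would
  change complex-locus counts at the margin.
* Ancestral-state misinference (outgroup homoplasy) is not corrected;
  sites are excluded, not rescued, which slightly depletes the SFS at both
  tails.
* The codon classifier evaluates one substitution at a time against the
  consensus codon; multi-site codons are classified per site, not jointly.
* Tajima's D on complete-case columns discards information at loci with
  scattered missingness.
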