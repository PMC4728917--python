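# rarehap

Rare-allele haplotype discovery and population-genetic statistics for
multi-accession, per-locus sequence alignments with an outgroup.

## The problem

In a resequencing panel of many accessions of one species, a *rare allele*
(in the type II sense) is a distinct haplotype — a set of accessions
separated from everyone else by a block of perfectly co-segregating fixed
substitutions — carried at low frequency (<10 %).  Such haplotypes are of
interest because they bias genome-wide association studies and because
their mutational history discriminates between competing explanations for
their origin: selective sweeps, population structure, or locally elevated
mutation rates around indels.  `rarehap` implements the full analysis
pipeline for this question over per-locus aligned FASTA files (e.g. ~96
*Arabidopsis thaliana* accessions per ~500 bp locus, with an aligned
*A. lyrata* ortholog as outgroup):

* **Haplotype discovery** — a distinct haplotype requires at least `k = 5`
  fixed nucleotide substitutions between a set of accessions and its
  complement.  Groups are labelled *rare* (frequency < 0.10),
  *intermediate* (0.10 ≤ f < 0.50) or *major* (the complement).  Loci are
  typed as gSNP loci (≥1 distinct haplotype), dSNP loci (none) or complex
  (≥2).
* **SNP taxonomy** — fixed substitutions between haplotypes are **gSNPs**;
  remaining dispersed SNPs are **nfSNPs** (at haplotype-bearing loci) or
  **dSNPs** (at single-haplotype loci); low-frequency (<10 %) nfSNPs and
  dSNPs are *type I* rare substitutions.
* **Polarization** — each substitution (and each fixed indel) is oriented
  by the outgroup: if the outgroup matches the major allele, the focal
  allele carries the new (*derived*) mutation; if it matches the focal
  allele the mutation is *ancient*; a third state, gap or missing base
  excludes the site.  The **relative rate** of a class is
  derived/ancient — values above 1 mean the focal allele evolved faster.
* **Statistics** — a random-occurrence model E[Fᵢ] = F₁ⁱ for the number of
  rare-allele types per locus (with χ² goodness of fit); Tajima's D per
  locus; the unfolded site-frequency spectrum against the neutral
  constant-size expectation P(i) = (1/i)/aₙ, aₙ = Σⱼ₌₁ⁿ⁻¹ 1/j, with the
  *frequency excess* observed/expected − 1 per bin; quadratic
  extrapolation of binned SNP counts to frequency 1 (fixation);
  fixation-probability ratios (high-/low-frequency bin counts); Dₓᵧ
  divergence to the outgroup per haplotype; synonymous/nonsynonymous and
  codon-position classification; Ts/Tv ratios; and the chromosomal extent
  of a rare-allele pattern in flanking sequence.
* **Synthetic panels** — a seeded generator producing neutral coalescent
  loci (Kingman genealogy, Poisson mutations on branches, infinite sites)
  with an outgroup derived from the sample's ancestor, plus implanted rare
  or intermediate haplotypes and indels with locally elevated flanking
  substitution rates.  Every planted event is recorded in a truth ledger,
  so recovery is testable end to end.

## Worked example

Simulate a 60-locus panel (96 accessions, 500 bp loci, 0.44 % diversity,
25 % of loci given a 5-accession rare haplotype with 10 fixed sites, 10 %
an intermediate one) and run the pipeline:

```python
from rarehap import SimConfig, simulate_dataset
from rarehap.cli import RunConfig, run_pipeline
import pandas as pd

cfg = SimConfig(n_loci=60, seed=7, rare_locus_fraction=0.25,
                intermediate_locus_fraction=0.1, intermediate_spec=((20, 8),))
manifest, ledger = simulate_dataset(cfg, "panel")
report = run_pipeline(RunConfig(manifest=manifest, out="report"))
print(pd.read_csv(report / "summary.tsv", sep="\t", index_col=0))
```

```
                 loci  haplotypes  total  derived  ancient  ratio
category
gSNP               30          32    267      234       25   9.36
rare_typeII        18          18    166      156        7  22.29
intermediate       14          14    101       78       18   4.33
nfSNP              30           0    318      284       20  14.20
rare_typeI_nf       0           0    190      181        3  60.33
intermediate_nf     0           0    125      100       17   5.88
dSNP               30           0    311      262       36   7.28
rare_typeI_d       0           0    183      171        5  34.20
intermediate_d      0           0    128       91       31   2.94
total              60          32    896      780       81   9.63
```

Reading the table: 30 of the 60 loci carry at least one distinct haplotype
(gSNP loci) — the 15 implanted rare haplotypes are all recovered, and the
excess comes from intermediate-frequency splits that arise naturally under
the neutral coalescent.  The 267 gSNPs are the fixed substitutions
supporting those haplotypes; their high derived/ancient ratios reflect
that implanted and coalescent-private mutations are genuinely new relative
to the outgroup.  `rarehap classify`, `rarehap simulate`, `rarehap stats`
and `rarehap audit` expose the same steps on the command line; the report
directory also contains per-row tables (`loci.tsv`, `haplotypes.tsv`,
`snps.tsv`, `sfs.tsv`, `dxy.tsv`, …) and a `run.json` with the
random-occurrence fit and run metadata.

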