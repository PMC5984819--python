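# Methods

## The problem

Resequencing (or RNA-seq-based) comparisons of transgenic plant lines
against a reference genome routinely report apparent de-novo sequence
variants. Three artifact sources can inflate such counts by orders of
magnitude:

1. **Misidentified genetic background.** If an event series was actually
   developed in a different cultivar than assumed, every standing
   difference between that cultivar and the reference genome is counted as
   a "mutation". The signature is a large, dense variant set whose profile
   at pre-ascertained panel positions matches a single germplasm accession
   almost perfectly.
2. **Standing within-cultivar heterogeneity.** Inbred cultivars are bulked
   before complete fixation, so sub-lines differ in bounded genomic
   intervals. The signature is a dense positional cluster of variants,
   not dispersed singletons.
3. **Bioinformatic false positives.** Calls made without depth/quality
   filtering and without replicate-concordance checks concentrate at 1–2
   reads of depth and Phred quality ≤ 10, are roughly half heterozygous
   (inconsistent with generations of selfing), and are private to single
   samples.

`varprov` implements the discrimination pipeline as composable library
functions plus a CLI, and ships a synthetic-data generator that plants all
three artifact classes (plus sparse true de-novo mutations) with full
ground-truth bookkeeping, so the whole analysis is exercisable and testable
at desk scale without any external download.

## Pipeline stages and their rules

### Hard site filters (`varprov.filters`)

GATK-style hard-filter predicates over annotated records, applied as flags
(never deletions): SNPs fail on FS > 30 or QD < 2.0; indels fail on
FS > 200; and any SNP in a run of ≥ 3 SNPs spanning ≤ 35 bp on one
chromosome is flagged `SnpCluster`. Comparisons are strict inequalities
exactly as printed (FS = 30.0 passes); a record lacking an annotation is
not flagged by that predicate, because absent evidence should not fail a
site. The cluster-span convention is max(pos) − min(pos) + 1 ≤ window,
evaluated over every run of `count` consecutive SNPs; the upstream tools
this emulates do not document their window semantics, so this package fixes
one convention and tests it against subset enumeration. Indels neither
trigger nor receive the cluster flag.

### Group-unique homozygous variants (`varprov.unique`)

De-novo mutations induced at T0 and then selfed for generations should be
homozygous and shared by a whole event series. Per variant and group:

* missingness is evaluated first: strictly more than 1/3 missing calls
  removes the variant for that group (4 of 9 missing removes; 3 of 9 =
  33.3% survives, reading the "more than 33%" rule as the fraction 1/3);
* consensus requires ≥ 6 of 9 samples sharing the same homozygous call;
  heterozygous calls never form or count toward a consensus;
* a variant is unique to group G iff G's consensus is homozygous-alternate
  and **every** other group has an explicit homozygous-reference consensus.
  A group with no consensus or too much missing data disqualifies the
  variant everywhere — mere absence of the alternate allele elsewhere is
  not enough.

The output sets are pairwise disjoint by construction and the
implementation is verified against an exhaustive per-variant re-evaluation
of the stated rule.

### Accession fingerprinting (`varprov.identity`)

The group's unique-variant profile is intersected with a SNP panel
(pre-ascertained positions × accessions). Identity is categorical genotype
equality (HOM_REF / HET / HOM_ALT); a query homozygote against a panel
heterozygote is a mismatch. Positions missing on either side leave that
accession's denominator, so identity is never diluted by no-calls (and
denominators may differ across accessions). Allele-orientation conflicts at
a shared position are remapped when the two allele pairs are equal as sets,
otherwise dropped with a warning. Results are ranked by percent identity,
ties broken by accession id. Residual mismatches of the best match are
merged into intervals (gap ≤ 1 Mb by default); a clustered residue against
a near-perfect match is flagged as possible heterogeneity between
individuals of the matched accession rather than evidence against the
match.

### Heterogeneity scan (`varprov.clusters`)

The source study identified clustering visually from genome-distribution
plots; this package formalises it as single-linkage merging: consecutive
same-chromosome variants ≤ 500 kb apart join one cluster, and clusters
with fewer than 5 members dissolve into the dispersed set. Both thresholds
are configurable (`ScanConfig`); they are package decisions, not claims
inherited from any upstream analysis, and are validated against a
connected-components oracle and by planted-cluster recovery. Intervals are
1-based half-open; BED input (0-based) is converted on read. Known-region
overlap uses half-open intersection, so touching boundaries do not overlap.

### QC diagnostics (`varprov.qc`)

* **Depth histogram**: per-sample carrying calls (HET/HOM_ALT) binned at
  depths 1–20 plus a closed 21+ bin. A call with unknown or zero DP is
  excluded, not binned as zero (no reads informing a call means its depth
  was not observed). A site contributes once per carrying sample.
* **Low-quality fraction**: fraction of records with QUAL ≤ cut
  (default Q10, inclusive). Phred semantics: Q10 ⇒ 10% error chance,
  Q20 ⇒ 1%.
* **Zygosity fractions**: het vs hom-alt over carrying calls only
  (HOM_REF calls are not "variant calls" and leave the denominator).
* **Selfing expectation**: a locus heterozygous at T0 retains
  heterozygosity 100 × (1/2)^g percent after g selfing generations
  (no segregation distortion, no fitness effect): g = 8 → 0.390625%,
  g = 4 → 6.25%. Declared generation counts are configuration inputs,
  never inferred from data.
* **Sibling concordance**: exact Venn region counts over per-sample
  variant-key sets; the region counts partition the union.
* **Indel classes**: counts keyed by (insertion|deletion, |length|); the
  artifact flag fires when all mass lies at |length| ≤ 2, since genuine
  indel spectra carry a longer tail.

## The synthetic-data generator (`varprov.simulate`)

`SimConfig` defaults define the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| design | 4 groups × (3 families × 3 siblings) | three event series + controls, 36 samples |
| genome | 20 chromosomes × 50 Mb | positions only; no FASTA |
| panel | 2 000 positions × 200 accessions | alt-allele frequency U(0.05, 0.95), 2% missing |
| background swap | group `series_1`, 600 expressed panel positions | all nine plants carry the drawn accession's homozygous-alt genotypes (~300 variants) |
| heterogeneity | group `series_2`, Chr15:1.4–2.2 Mb, 140 variants | homozygous-alt in all nine plants |
| de novo | 3 per group | homozygous-alt, full group concordance |
| false positives | 20 000 per sample | private to one sample; P(depth 1) = 0.43, P(depth 2) = 0.20, geometric tail; P(QUAL ≤ 10) = 0.55; P(het) = 0.5; 10% short indels |
| annotation mixing | 15% failing FS, 15% failing QD | hard filters remove only part of the false positives |
| missing-call rate | 0.002 | independent per cell |

Panel accessions are simulated homozygous-only (HOM_ALT with probability p,
else HOM_REF), as appropriate for inbred germplasm; under this model two
independent accessions agree at a fraction 1 − 2E[p] + 2E[p²] ≈ 63.5% of
positions, which produces the large top-match/runner-up separation the
fingerprinting stage relies on. The missing-call rate is kept low (0.2%)
so that a planted true variant essentially never loses its group consensus
to chance missingness; the rate is a per-cell no-call probability after
filtering, not a raw genotyping missingness.

All randomness flows from a single `numpy` Generator seeded by
`SimConfig.seed`; identical configuration gives byte-identical VCF output.
All planted positions are collision-free genome-wide, so the truth key sets
are disjoint by construction.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium within the panel;
expression-level variation in which transcribed positions are observable;
read-level error processes (annotations are drawn from stylised pass/fail
regions rather than computed from alignments); shared (systematic) false
positives such as mapping artifacts that recur across samples at the same
site; and reference-genome errors. In particular, because simulated false
positives are never shared between samples, replicate-consensus filtering
is close to perfectly effective here; on real data systematic artifacts
survive it, which is exactly why the panel-fingerprint and clustering
diagnostics remain necessary.

## Numerical and design choices

* Coordinates are 1-based (VCF); all intervals are half-open
  [start, end) in 1-based coordinates; BED input is converted.
* Multi-allelic sites are split per alternate allele at ingestion;
  genotypes referencing a different alternate become MISSING for that
  split record.
* VCF round-tripping is exact on the domain model up to float32 storage of
  QUAL/FS/QD; the generator rounds annotations (1–2 decimals) so
  round-trips compare cleanly.
* Identity ties are broken by accession id ascending; cluster members are
  ordered by position; filter application is idempotent.
* Degenerate inputs: an empty identity profile is an error (identity is
  undefined); fractions over empty denominators return NaN rather than 0;
  a header-only VCF yields an empty record list with the header's samples.
* The missingness test precedes the consensus test within each group; the
  ordering is observable when ≥ 4 of 9 calls are missing *and* ≥ 6 are
  homozygous-alternate, which cannot co-occur at group size 9, so the
  choice only matters for non-default group sizes.

## Problem sizes used in validation

Unit and property tests run on matrices of ≤ 1 000 variants with exhaustive
or graph-based oracles. End-to-end validation runs 20 simulated studies at
the full default conditions (seeds 1–20; ~720 000 false-positive records
each) and requires: the planted accession ranked first 20/20, the planted
cluster recovered with ≥ 95% member capture 20/20, and the unique sets
equal to the planted truth surviving the hard filters 20/20. Distribution
fidelity of the false-positive depth/quality/zygosity masses is checked
against binomial 99% bounds at the generated counts. `scripts/acceptance.py`
repeats the closed-form, worked-example and bookkeeping computations and
three default-scale simulated studies at the caller's seed.

## Known limitations

* The reader targets standard VCF 4.x with FORMAT GT[:DP] and INFO FS/QD;
  exotic dialects (per-sample split files, renamed annotation keys) must be
  normalised upstream, e.g. with `bcftools`.
* Identity scoring assumes a bi-allelic panel; positions whose allele sets
  disagree between query and panel are dropped rather than strand-flipped
  (A/T and C/G ambiguities are not resolved).
* The heterogeneity scan reports descriptive clusters; it attaches no
  statistical significance to clustering.
* Venn region counts are exact for any number of sets, but no Venn figure
  is drawn; outputs are tabular.
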