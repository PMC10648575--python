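# Methods

## The problem

In classical Hodgkin lymphoma the malignant Hodgkin/Reed-Sternberg (HRS)
cells make up only a few percent of a lymph-node biopsy, so somatic
variants in bulk sequencing data sit at variant allele fractions (VAFs) of
roughly 0.5-25% — a range where ordinary callers cannot separate true
variants from sequencing error.  `umivar` implements the computational
machinery for this regime: UMI consensus error correction, an empirical
per-site background-noise test for orthogonal validation of candidate
SNVs, deterministic rule filters for indels and de novo low-VAF calls,
AID hotspot-motif enrichment testing, and cohort-level statistics.  A
synthetic-data module generates every input the pipeline consumes, since
real cohorts of this kind are controlled-access.

## UMI consensus (`umivar.consensus`)

Reads sharing a unique molecular identifier and alignment start are
grouped into families after excluding reads with mapping quality < 10 or
more than 5 mismatches (NM).  Families with fewer than 3 members are
discarded.  The consensus base at a site must win a **strict majority**
(> 50%) of the calls covering the site; otherwise the consensus is `N`,
and `N` is never tallied as ref, alt, or other in downstream counts.  The
strict-majority rule is deliberately conservative — it can abstain but
never invents an allele — and base qualities do not enter the vote, since
the family structure itself is the error-correcting code.  A 2-2 split
and a 2-1-1 plurality both yield `N` under this rule.

The family key is (UMI, alignment start).  In amplicon chemistry the
start is probe-determined, so this is equivalent to keying on the probe;
for fixtures either works.

## Iterative background validation (`umivar.validation`)

At a candidate site, the foreground sample's error-corrected (alt, ref)
counts are compared against the pooled (alt, ref) counts at that exact
site across **all other samples** — tumors and normals alike, including
the matched normal (a config switch excludes it).  Pooling at the same
position absorbs position- and context-specific error without an explicit
noise model.  The test is the one-sided Fisher exact test toward alt
enrichment in the foreground, computed through the hypergeometric
survival function so whole rounds vectorise; equality with
`scipy.stats.fisher_exact(alternative="greater")` is asserted in the test
suite.

Testing iterates because a true variant in one sample contaminates the
background used to judge the same site in another sample:

1. In each round, every not-yet-retained candidate is tested against the
   pooled background, excluding all previously retained (sample, site)
   pairs from the pool.  Only the retained pairs leave the pool, not their
   whole samples, which preserves background depth.
2. The round's p values are Holm-adjusted as one family (all tests of the
   round, across samples and sites).  Candidates with adjusted p < 0.1 are
   retained.
3. Rounds repeat until one retains nothing.  Termination is guaranteed
   (the retained set strictly grows and is bounded); a guard caps rounds
   at the candidate count.

Retained candidates whose adjusted p (from the round in which they were
retained — retained candidates are not re-tested) is ≤ 0.05 are carried
forward.  Final SNV status adds depth gates: tumor consensus depth ≥ 100
is required at all; with an evaluable normal (depth ≥ 100) a PASS
requires tumor adjusted p ≤ 0.05 **and** normal adjusted p > 0.05;
without one, a significant tumor site is classified TUMOR_ONLY.  The
matched-normal p values are produced by one extra Fisher pass against the
background excluding retained pairs, Holm-adjusted across the normals
tested as one family — the same machinery as the tumor side, chosen
because nothing else about the normal test is specified.

Correctness is anchored by a from-scratch brute-force re-implementation
(independent Fisher and Holm routes) on hundreds of random small cohorts,
and calibration by spike-in/null experiments at the study's scale:
30 tumor/normal pairs × 500 sites at ~2,000× depth and background error
10⁻³, with 50 variants spiked at VAF 2%.  At these conditions sensitivity
is 1.0 and ~1% of null cohorts retain any false site (Holm controls the
familywise error within each round at 0.05; the iteration adds little
inflation because later rounds only run when something was retained).

## Rule filters (`umivar.filters`)

Indel validation on consensus counts, paired path (strict inequalities as
printed): tumor and normal depth > 5, tumor alt reads > 1, normal alt
reads < 20, tumor VAF > 0.01%, normal VAF < 5%.  When the normal lacks
depth, the tumor-only path requires depth ≥ 5, ≥ 1 tumor alt read, and
tumor VAF > 0.01%.  The strict-vs-inclusive reading of the paired depth
gate is genuinely ambiguous in prose, so both are encoded
(`indel_paired_depth_strict`).  De novo filter: tumor and normal depth
≥ 5, normal VAF < 5%, tumor VAF > 0.5%, normal alt < 5, tumor alt ≥ 2.
Every decision carries the list of failed rule identifiers, each naming
one `PipelineConfig` constant, so a FAIL is fully explained and the
boundary behaviour of every threshold is tested on both sides.
Manually rescued sites are handled by an explicit allowlist input, not
re-derived.

## AID motif enrichment (`umivar.aid`)

The canonical AID hotspot is the C of a WRC trinucleotide (W = A/T,
R = A/G) or, equivalently on the opposite strand, the G of GYW (Y = C/T);
GYW is the reverse-complement image of WRC, so scanning both patterns on
the forward strand is strand-symmetric (property-tested).  The enrichment
test places each gene's observed mutation count uniformly at random
(distinct positions) over the placement space, counts motif hits per
replicate, and reports the empirical tail p = count_ge / n_perm at
100,000 replicates (the (count+1)/(n_perm+1) estimator is available by
flag).  The cohort-total test places each gene independently and sums
hits.  The placement space defaults to the full sequence and can be
restricted — to panel-covered intervals, or to C/G positions
(`restrict_to_cg`) to emulate testing C>T/G substitutions specifically.

Under uniform distinct placement the hit count is exactly hypergeometric,
which gives closed-form oracles for the mean, the tail, and — with biased
placement being Wallenius noncentral hypergeometric — the exact power of
the procedure, all asserted in the test suite.  At motif fraction 0.2
with 19 mutations, the expected hit count is 3.8 and the exact power
against 5-fold motif bias at α = 0.05 is 0.92.

## Cohort statistics (`umivar.cohort`)

EBV positivity requires ≥ 2 reads aligned to the EBV reference at mapping
quality ≥ 60 ("MQ60" read as ≥ 60, the aligner maximum).  Concordance
with the EBER ISH label is reported as a 2×2 confusion table with
per-cell sample lists.  Mutation burden between groups uses Student's
equal-variance two-tailed t test by default (a Welch flag exists; the
equal-variance choice is a convention, not a claim).  Pairwise gene
co-occurrence uses the two-sided Fisher exact test per unordered pair on
the 2×2 sample table with Benjamini-Hochberg FDR across pairs; direction
comes from the odds ratio relative to 1.

## Synthetic data (`umivar.simulate`)

The generators emulate the statistical structure the pipeline assumes, at
the study's stated conditions (defaults): ~30 tumor/normal pairs,
error-corrected depths around 2,000-4,000×, background error ~10⁻³,
spiked true variants in the VAF 0.5-25% range (default spike 2%).

* Depths are negative binomial around the mean (shape 10, clipped ≥ 1),
  mimicking uneven coverage.
* Background alt counts are binomial at the site error rate; a dispersion
  parameter switches to beta-binomial across samples (the standard
  overdispersion model for amplicon error).  Dispersion 0 recovers the
  pure binomial, which the calibration tests exploit.
* Spikes add binomial(depth, VAF) alt reads at their (sample, site).
* Read families carry the true base flipped independently per read at the
  error rate, to a uniformly chosen other base.
* Motif-controlled genes are built as a uniform random interleaving of
  "AAC" trigram blocks with A/T filler: each block contributes exactly one
  WRC position and no G (hence no GYW), so the motif fraction is exact by
  construction.  AID-biased mutations are sampled without replacement with
  weight `motif_bias` at motif positions.

One `SeedSequence` per call spawns per-sample substreams, so outputs are
bit-reproducible and partial reruns agree.

What the generators do **not** model: strand bias, position-in-read
error, trinucleotide-specific error spectra, alignment artifacts, real
gene-level mutation spectra, or raw FASTQ scale.  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated noise model, not that real-cohort validation rates would be
reproduced.

## Numerical and design choices

* Positions are 1-based internally (VCF convention); BED's half-open
  0-based coordinates are converted at the parsing boundary only, and the
  conversion is checked against a brute-force per-position scan.
* Indels are represented as anchored ref/alt strings; duplicate removal
  matches on exact (sample, chrom, pos, ref, alt) keys and assumes
  left-aligned, decomposed input.
* The Fisher background uses ref and alt counts only ("other" bases are
  neither), and an empty background pool is an error, not a p of 1.
* Holm adjustment is step-down with a running maximum, capped at 1;
  ties are handled by stable sorting.
* Zero-variance burden tests return t = 0, p = 1 when means agree (and
  p = 0 otherwise) rather than NaN.
* Problem sizes in the test suite and experiment drivers (500-site
  panels, 100 null replicates, 10⁴ read families, 10⁵ permutation
  replicates) were chosen as the smallest sizes at which the measured
  quantities' Monte-Carlo error is well below the margins being asserted.

## Known limitations

* The iterative scheme's familywise error control is per round; the
  overall false-retention rate across rounds is bounded empirically, not
  analytically.
* Consensus collapsing is SNV-oriented; indel-aware realignment within
  families and duplex (double-strand) consensus are out of scope.
* The per-gene placement space for motif enrichment matters: enrichment
  p values against a full-gene space and against a panel-restricted space
  differ, and reproducing any specific published per-gene value requires
  knowing that space.
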