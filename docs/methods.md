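# Methods

## Statistical model

Calling proceeds per sample in four ordered stages; a candidate's final
status records the first stage it fails.

1. **Frequency gate.**  At each pileup position the consensus base is the
   count-majority base (ties resolved toward the reference base, then
   alphabetically; zero depth gives N).  Every non-consensus base with
   count *k* and frequency *k/n* **strictly** greater than `min_freq`
   (default 0.015) is a candidate; when several alternate bases qualify the
   site is represented once, by the highest-count alternate (alphabetical
   tie-break), and flagged multi-allelic.  Indels never produce candidates:
   deletion- and N-bearing read positions are excluded from counts when the
   pileup is built, so depth is always the sum of the four base counts.
   Because candidates are relative to the per-sample consensus rather than
   an external reference, minor-allele frequency is bounded at ≤ 0.5.

2. **Binomial false-positive probability.**  `P_f = C(n,k) p^k (1-p)^(n-k)`
   with the platform error rate `p` (default 0.005), evaluated via the
   log-PMF for numerical range.  This is a *point* probability, not a tail;
   it is kept as the default (`pf_mode="pmf"`) because it is the quantity
   the thresholds below were defined against, while the statistically
   conventional upper tail `P(X ≥ k)` is available as `pf_mode="tail"`.
   Note the point PMF is non-monotone in *n* at fixed frequency — the
   coverage-cutoff helper (`min_coverage_for_significance`) therefore
   reports the coverage beyond which the curve *stays* under the threshold.

3. **Q-values.**  Storey step-up over the sample's candidate set:
   `q(i) = min_{j≥i} π0·m·p(j)/j` on the sorted p-values, mapped back to
   input order.  π0 defaults to the fixed value 0.05; passing `pi0=None`
   estimates it with the Storey λ-grid smoother instead.  Pooling
   candidates across samples is available (`pool_samples=True`) but off by
   default, since per-sample calling keeps samples exchangeable.
   Thresholds: `P_f < 0.01`, `Q_f < 0.001`.

4. **Hotspot exclusion.**  Two error-hotspot classes: (a) homopolymer
   context — the four reference bases immediately 5′ of the site on either
   strand are one repeated base (both strands are checked because reads
   come in both orientations; the genomic context is the proxy for the
   read-direction rule, which is not recoverable from counts alone);
   modular on circular chromosomes, and a truncated side of a linear
   chromosome never flags; (b) adjacency — both members of a pair of
   called sites at consecutive positions in the same sample.  Adjacency is
   evaluated among the significance survivors (exclusion is a correction
   applied *after* significance filtering), while the homopolymer flag
   depends only on the reference.  Setting `apply_hotspot_filter=False`
   keeps the flags but not the exclusions.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_freq` | 0.015 | minimum variant frequency, strict; three times the error rate, the conventional safety factor for Illumina amplicon data |
| `error_rate` | 0.005 | per-base platform error probability |
| `pf_max`, `qf_max` | 0.01, 0.001 | significance thresholds on P_f and Q_f |
| `pi0` | 0.05 | assumed true-null proportion in the q-value step-up |
| `homopolymer_len` | 4 | run length defining homopolymer context |

## Annotation

Sites map to every overlapping annotation unit (the joint `atp8-atp6` unit
is one annotation row, so reporting matches per-unit tables; a site in
overlapping units counts once in totals, attributed to its first unit).
Protein-gene codons are read on the coding strand using the annotated
frame offset; minus-strand genes substitute the complement of the variant
base.  Translation uses the gene's annotated code table, defaulting to the
invertebrate mitochondrial code (table 5).  Effects are synonymous,
nonsynonymous, nonsense (stop gained/lost; amino-acid property dimensions
suppressed) or unknown (codon contains N; excluded from syn/nonsyn
tallies).  Property dimensions compare hydropathy
(hydrophobic = {A,V,L,I,M,F,W,C,Y}), polarity
(polar = {S,T,N,Q,Y,C,H,K,R,D,E}) and charge (+ = {K,R,H}, − = {D,E});
these sets are a conventional choice (Y and C sit in both hydrophobic and
polar classes, which is deliberate — the dimensions are independent) and
can be replaced from a TSV.  tRNA sites report third-anticodon-base hits
only when the annotation supplies `anticodon_start`.

## Cohort statistics

Per-sample summaries partition sites by gene class and effect (the
invariants `total = protein + rRNA + tRNA` and
`syn + nonsyn + unknown = protein` are enforced and tested); per-gene rates
are sites per kb of annotated gene length.  Shared sites between samples
match on chromosome + position + variant base by default (position-only
optional, since published matrices do not state whether the allele must
agree).  Two-sample comparisons default to Welch's t-test — per-sample
totals show strongly unequal variances between groups — with the pooled
test available; SDs use the n−1 denominator, and both SD and SEM are
reported because published dispersion conventions mix the two.  Degenerate
inputs: equal-mean zero-variance groups return t=0, p=1; unequal-mean
zero-variance input is an error rather than an infinite statistic.

## Synthetic data

The generator emulates the two study architectures: 20 circular 3–4 kb
minichromosomes carrying 1–3 of the 36 annotation units (13 protein-coding
genes with `atp8-atp6` joint, 2 rRNAs, 22 tRNAs) at mean depth 6,000×, or a
single ~14.5 kb chromosome with the full repertoire at 1,700×.  Protein
genes are random stop-free codon sequences; chromosome lengths land exactly
in the configured band because spacers are fitted after gene payloads are
drawn (very small test-scale chromosomes carry the subset of genes that
fits).  Depth is Poisson around the configured mean (the study reports only
approximate averages; a fixed-depth mode exists for exact tests).  Errors
are uniform: each non-template base at rate p/3, drawn multinomially so
counts always sum to depth.  A planted site at frequency *f* gives its
minor base a marginal Binomial(n, f(1−p)) count.  Artifact sites are
created by overwriting the four reference bases 5′ of a chosen position
with one repeated base and raising one alternate base's error rate 20-fold
(≈3.3% observed frequency at default settings — above the detection
threshold, so only the hotspot filter can remove them).  Planted
non-artifact sites are chosen away from homopolymer context and never
adjacent; roughly 3% of uniformly random positions sit in hotspot context
by chance, which would otherwise contaminate recall and retention
estimates.  All randomness flows from one seeded generator and outputs are
byte-identical under a fixed seed.

Read emission decomposes each pileup column into depth layers (template
base first, variants after, in fixed order) and writes layer runs as Q40
reads chopped to the requested length, so rebuilding the pileup from the
emitted SAM reproduces the counts exactly; optional junk reads (60% of
bases at Q5) are appended unmapped for QC-filter testing.

What the simulations do *not* model: realistic quality-score profiles, GC
and strand bias, PCR chimeras, alignment ambiguity and mapping error,
indels, and non-uniform error spectra.  Passing the synthetic calibration
therefore shows the *pipeline arithmetic* is right under the stated error
model, not that the thresholds are optimal for any particular instrument
run.

## Numerical and design notes

- P_f is computed through the binomial log-PMF and agrees with exact
  big-rational arithmetic to better than 1e-10 relative error across all
  k for depths up to 500 (verified in the test suite).
- Q-value mapping uses a stable argsort, so tied p-values resolve
  deterministically.
- Consensus ties prefer the reference base, then the alphabetically first
  tied base; alternate-allele ties in candidate selection are alphabetical.
  Both rules exist purely for determinism.
- Coordinates are 1-based inclusive in every user-facing file; circular
  chromosomes support origin-spanning genes via modular arithmetic.
- Gene identification, read mapping and assembly are out of scope:
  references, annotations and alignments (or pileup TSVs) are inputs.
- No minimum mapping or base quality is applied when tallying aligned
  bases (configurable upstream by filtering reads); the read-level QC rule
  drops reads with more than 50% of bases at Phred ≤ 5 (strict boundary:
  exactly half is kept).

## Problem sizes used in the shipped checks

The calibration runs are sized to be quick while keeping the statistics
meaningful: null calibration uses ten 3.5 kb chromosomes at 6,000×
(35,000 sites, expected per-alt-base error frequency ≈0.17%, so zero calls
is the correct outcome); the recall check plants 1,000 sites at 5% across a
full 20-minichromosome genome at 2,000×; the hotspot check injects 60
artifacts into a 14.5 kb chromosome at 6,000×.

## Known limitations

- The q-value step-up with a fixed π0 = 0.05 makes Q_f essentially always
  pass once P_f does at these depths; it is retained as the defined
  procedure, with the smoother estimate available for data where π0 is
  genuinely unknown.
- The point-PMF definition of P_f is unconventional; tail mode changes
  borderline calls at low coverage (at 6,000× the two agree on everything
  that matters).
- Overlapping-gene attribution follows annotation order, which is a
  convention, not biology.
- The bundled cohort tables are transcribed published summaries used as
  fixtures for the aggregation layer; two of their printed rows are
  internally inconsistent in the source (see the dataset docstrings), and
  they are shipped verbatim rather than corrected.
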