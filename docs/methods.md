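# Methods

## Model and assumptions

The detector treats candidate-HGT identification as unsupervised novelty
ranking. Assumptions:

1. **Pervasive signatures.** Genes inherent to a virus family share
   compositional statistics; recently transferred genes retain the
   statistics of their source. Gene amelioration limits detection to
   recent transfers — old transfers have converged and are invisible to
   any compositional method.
2. **Outliers are a minority.** The one-class SVM encloses the bulk of
   the data; if most of a family were alien, the "typical" model would be
   learned from aliens.
3. **Strand and frame are meaningful.** Sequences are used as given (the
   coding strand, frame 0). No reverse-complement canonicalisation is
   applied: single-stranded viral genomes violate Chargaff's second
   parity rule, and that asymmetry is part of the signature.

Given a standardized feature matrix, a ν-SVM with Gaussian kernel is
fitted on all genes and each gene is scored by the fitted decision
function. The signed distance is negative outside the boundary; sorting
ascending yields the most-atypical-first ranking. Equal distances keep
dataset ingest order, making ties deterministic.

## Feature sets

| name | D | normalization group |
|---|---|---|
| mono/di/tri/tetra | 4/16/64/256 | whole vector (overlapping words) |
| codon_usage | 64 | whole vector, frame 0, stops included |
| relative_codon_usage | 64 | synonymous family (stops are one family) |
| amino_acid | 20 | whole vector, stops excluded |
| position_nt | 12 | each codon position's 4 entries |
| gc_content | 1 | — (baseline, not fed to the SVM) |

k > 4 oligonucleotides are deliberately unsupported: small viral families
cannot populate higher-dimensional word spaces. Words or codons containing
non-ACGT characters are skipped rather than imputed, so ambiguity codes
reduce the effective count but never fabricate signal. A gene with no
valid word under a feature set is excluded from that matrix and reported.
A trailing partial codon is dropped with a logged warning. Translation
uses the standard genetic code (NCBI table 1, configurable). For
`relative_codon_usage`, a synonymous family never observed in a gene gets
the uniform value 1/|family| instead of 0/0 — rows stay finite and
comparable at the cost of pulling unobserved families toward the
uninformative centre.

Standardization is column-wise z-scoring with the *population* standard
deviation (bit-reproducible, idempotent); zero-variance columns map to
all-zeros rather than NaN. The GC-regression variant
(`--experimental-gc-regression`) residualizes features on GC before
standardization; after standardization it collapses to essentially the
same solution, so it is excluded from the default nine feature sets and
from all benchmarks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ν | 0.2 | upper bound on the expected fraction of boundary outliers; chosen from the stability analysis (small ν is unstable, large ν indifferent) |
| γ | (2D)⁻¹ | Gaussian-kernel width; the rule of thumb is stable over a wide ν range for every feature set |
| identity | 0.95 | redundancy-reduction level before statistics are collected |
| fraction | 0.05 | simulated-outlier share of the amended family |
| window/step | user | sliding-window mode; trailing segment kept iff ≥ window/2 |

The stability sweep explores ν ∈ {0.001, …, 1.000} (1,000 equidistant
values) and γ ∈ {10⁻⁶, 10⁻⁵, 10⁻⁴, 10⁻³, 0.01, 0.1, 1, 10, 100, (2D)⁻¹}.
Stability at ν_i is the Spearman ρ between the ranking at ν_i and each
available neighbour, averaged; boundary grid points use their single
neighbour. Degenerate fits become missing grid points (profile `coverage`
reports the defined fraction) — never interpolated, never fatal.

## Redundancy reduction

External clustering binaries are not a dependency. The built-in reducer
sorts genes by length (descending, stable), and assigns each gene to the
first cluster whose founder shares at least the identity threshold of the
gene's 5-mers (containment over the shorter sequence); otherwise the gene
founds a new cluster. Founders are the representatives. This
overestimates identity relative to alignment for shuffled repeats, but
the downstream method only needs near-duplicates collapsed, not exact
identity values. The procedure is idempotent, and a precomputed
representative list from an external tool can be supplied instead
(`--representatives`).

## Simulated-outlier evaluation

A base family of n genes receives m = max(1, round(n·f/(1−f))) aliens
sampled uniformly without replacement from the genes of all other
families, so aliens are f of the amended family (exact where divisible,
and never zero). AUC is computed over all cutoffs of the ranking with the
pair-counting tie convention (verified exhaustively against a brute-force
oracle); the "top 5% called" set is reported separately, since AUC itself
is cutoff-free. Success means AUC > 0.9, semi-success AUC > 0.8, both
strict — the boundary values do not qualify. Real families may contain
genuine unlabeled outliers that compete with injected ones; benchmark
output carries this caveat, and measured AUC is conservative in that
respect.

## Synthetic data generator

Each synthetic gene is ATG + L codons i.i.d. from a family codon
distribution (L uniform in a length range, default 100–400 codons,
~300–1,200 nt, a realistic viral CDS range) + one stop codon; internal
stop weights are forced to zero. Sampling whole codons rather than a
nucleotide Markov chain lets one parameter set drive codon-usage,
amino-acid, position-wise and oligonucleotide signatures simultaneously.

`generate_benchmark` draws a base distribution (Dirichlet over the 61
sense codons, concentration 5: moderately even, as a family-average
usage) and per-family unique distributions (concentration 0.5: strongly
biased); family f uses (1−d)·base + d·unique_f. At d = 0 families are
statistically identical — injected aliens are undetectable by
construction and AUC is 0.5 in expectation; at d = 1 they are maximally
distinct. The `match_gc` mode exponentially tilts every family
distribution to the base's expected GC (the KL-minimal adjustment meeting
the constraint, solved by 1-d root finding), which isolates codon-level
signal from the GC baseline.

What the generator does *not* emulate: phylogenetic correlation between
genes of a family (genes are i.i.d., real families are clustered),
within-gene composition heterogeneity, length–composition correlation,
sequencing artefacts and ambiguity codes, and the heavy species imbalance
of real archives. Passing benchmarks therefore demonstrate that the
machinery recovers compositional outliers under the model's own
assumptions — not that any particular real family is this separable.

## Numerical choices

- **SVM solver**: libsvm via scikit-learn's `OneClassSVM`, stopping
  tolerance fixed at 1e-12. The tight tolerance is what makes signed
  distances reproducible to ~1e-9 under row permutation or repeated runs
  (at looser tolerances the converged distances differ by more than
  typical gaps between adjacent ranks); it costs no measurable runtime at
  the family sizes involved.
- **Spearman ρ**: mid-rank tie convention; values within 1e-12 of ±1 are
  snapped to exactly ±1 so identical/reversed rankings test cleanly.
- **Ties in rankings**: stable sort on ingest order, everywhere.
- **Randomness**: every stochastic step (generation, injection,
  subsampling, benchmark) flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; outputs are byte-identical across
  reruns and independent of evaluation order.
- **Degenerate inputs**: all-identical rows, single-class labels,
  sub-minimal families (≤ 3 genes) and unencodable sequences raise typed
  errors (`ValidationError`, `DegenerateFitError`, …) mapped to distinct
  CLI exit codes (2/3/4).

## Problem sizes

The shipped benchmarks use 10 synthetic families of 200 genes (5%
injection, tetranucleotide features) for signal recovery, 10 GC-matched
families of 100 genes for the baseline comparison, a 5-point divergence
ladder at 6 families × 80 genes for the monotonicity check, and 1,000
random-ranking replicates on a 526-gene amended family for the
no-information AUC baseline. These sizes give Monte-Carlo standard errors
small enough for the stated checks while keeping the default suite fast.

## Known limitations

- Compositional methods detect *recent* transfers only; ameliorated genes
  are invisible.
- The method flags atypicality, not provenance or direction of transfer;
  interpretation needs external evidence.
- A family dominated by one over-sequenced species makes that species the
  "typical" model; subsampling (`subsample_large_family`) mitigates size,
  not imbalance.
- The greedy clusterer is a redundancy reducer, not an alignment-accurate
  clustering; word size and coverage behaviour differ from CD-HIT's.
- Very small families (4–10 genes) fit an SVM but the boundary and hence
  the tail of the ranking is weakly determined; stability profiles are
  the diagnostic.
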