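# Methods

## Model and assumptions

`statecall` treats the distribution of one sample's gene-level TPM
abundances as a two-component mixture: a low-abundance mode produced by
transcriptional and technical noise around genes that are not
functionally expressed, and a high-abundance mode for expressed genes.
Both components are lognormal, so on the log2 scale the positive
abundances follow a two-component normal mixture

    f(y) = π_ne N(y; μ_ne, σ_ne) + π_e N(y; μ_e, σ_e),   y = log2(TPM).

Assumptions worth making explicit:

* **Single-sample fitting.** Each sample gets its own mixture; no
  information is shared across samples. This is the method's point — it
  adapts the expressed/not-expressed boundary to each library — and its
  cost: per-sample fits need enough genes (≥ 500 positive by default)
  to be identifiable.
* **Exact zeros are uninformative for the fit.** Zeros are excluded
  from the EM and assigned posterior 0 by the piecewise rule below. No
  pseudocount is added anywhere.
* **Label convention.** The component with the higher fitted location
  is the expressed component (`μ_e > μ_ne` is enforced by relabelling
  after the fit), making the procedure invariant to label swaps.
* **Log base.** The fit uses log2. Any base gives the identical
  posterior (the Jacobian of the transform cancels in the density
  ratio); log2 keeps the scale consistent with the zFPKM comparator.

The posterior that a gene with abundance x is expressed is

    P(expressed | x) = 0                                         if x = 0,
                       π_e f_e(x) / (π_ne f_ne(x) + π_e f_e(x))  otherwise,

computed as the logistic of the log-density difference, which is exact
at a log-odds of zero. The binary state is 1 iff the posterior is
≥ 0.5; a posterior of exactly 0.5 is called expressed, following the
inclusive inequality.

## EM estimation

Initial values are anchored by housekeeping genes (constitutively
expressed in essentially every tissue, hence samples of the expressed
mode):

* `μ_e, σ_e` ← mean and SD of the log2 abundances of the detected
  housekeeping genes (≥ 10 required with positive abundance);
* `μ_ne, σ_ne` ← mean and SD of the lowest quartile of the remaining
  positive genes' log2 abundances;
* `π_e` ← fraction of positive genes above the midpoint of the two
  initial locations, clipped to [0.05, 0.95].

Standard EM updates follow, with the observed-data log likelihood
recorded each iteration (it is non-decreasing by construction; the test
suite asserts it). Stopping: relative log-likelihood change below 1e-8
or 1,000 iterations. Collapse — a component weight under 1e-3, a scale
under 1e-3, or locations closer than 1e-2 log2 units — triggers up to 3
restarts with seeded jitter (N(0, 0.5) on locations, ±20% lognormal on
scales, N(0, 0.05) on π_e) before a non-convergence error carrying the
last diagnostics. Degenerate inputs (too few positive genes, zero
variance) are rejected up front rather than fitted.

The bundled default housekeeping list (30 HGNC symbols drawn from
standard RT-qPCR reference panels) is a data file and can be replaced
with any identifier list matching the matrix's gene ids; the synthetic
cohorts emit their own list.

## Aggregation cutoffs

The non-expressed ratio of gene i in tissue j with m samples is
`Σ(1 − state)/m`, computed from integer counts so printed fractions are
exact. Operating points and their inclusivity follow the published
wording:

| quantity | default | rule |
| --- | --- | --- |
| posterior state cutoff | 0.5 | expressed iff ≥ |
| dormancy (non-expressed ratio, each non-testis tissue) | 0.9 | dormant iff ≥ |
| tumor expressed ratio for candidate TAAs | 0.05 | candidate iff ≥ |
| testis-exclusive (testis expressed ratio) | 0.10 | strict > |

All are flags; the defaults are the published operating points. Tissues
with fewer than 10 samples are aggregated as-is but logged, since their
ratios quantize coarsely. An atlas without a testis label degrades
gracefully: dormancy then requires every tissue to pass and the testis
ratio is recorded as missing (category `silent_everywhere`). Genes
missing a summary for a required tissue raise an error naming the gene
and tissue rather than being silently treated as non-expressed.

## Comparator methods

**Fixed threshold** — state 0 iff TPM < cutoff; the "TPM < 1" label's
boundary convention means a value exactly at the cutoff is expressed.

**zFPKM-style z-scoring** — the active-peak location is the mode of a
Gaussian KDE over log2 positive abundances; the scale is the RMS
deviation of values on the right flank of the mode (the active peak is
assumed symmetric; the left flank is contaminated by the inactive
mode). The kernel bandwidth is double Scott's rule: the mode of a
symmetric peak is invariant under Gaussian smoothing, and the wider
kernel roughly halves the sampling noise of the mode estimate, which
with the plain plug-in rule is the dominant error term at realistic
gene counts. A gene is expressed iff z = (log2 TPM − μ)/σ ≥ −3, with
z = −∞ at TPM 0.

**EnB** — an exponential density (inactive) plus a negative binomial
(active) fitted by EM on positive abundances. The NB is a count model,
so abundances are rounded to the nearest integer for that component
while the exponential uses raw values — an explicit approximation for
continuous TPM. The NB M-step uses the closed-form weighted mean and a
bounded 1-D search on log(size). The state boundary is the abundance
where the active-component posterior (evaluated with the
gamma-function continuous extension of the NB pmf, so it is a smooth
function of x) crosses 1 − p for probability cutoff p (default 0.01),
solved by bracketed root finding; a larger p gives a smaller, more
permissive threshold.

## Reference standard and benchmarking

From a 15-state chromatin segmentation, a gene is **active** iff (1) a
state-1/2 (promoter) segment overlaps its exons, (2) a state-3/4/5
(transcription) segment overlaps its gene body, and (3) no state-9..15
(repressed) segment overlaps it; **inactive** iff no state-1..5 overlap
exists anywhere and at least one state-9..15 overlap does; otherwise
**ambiguous**, and excluded from every metric. The span checked for the
transcription requirement is a switch (`body`, the default, or
`exons`); the genomic region for the repression check is the gene body
including exons. Intervals are 0-based half-open and intersected with
an interval tree per chromosome.

Per-sample evaluation scores both classes separately (reference
inactive as positives for the non-expressed class, active for the
expressed class) and reports mean and SD across samples, with the
sample (n−1) standard deviation. A sample with no predicted positives
in a class has undefined precision there; it is excluded from that
metric's mean/SD and counted, not scored as zero.

The tissue-level PR curve sweeps the non-expressed-ratio threshold over
all distinct values (descending, so recall is non-decreasing along the
sweep), predicts non-expressed at ratio ≥ t, and integrates precision
over recall by the trapezoidal rule with an anchor at recall 0 carrying
the precision of the highest-threshold prediction set. The curve also
reports precision at the fixed ratio 0.9, the dormancy operating point.
AUPRC is invariant to strictly monotone transforms of the score
(property-tested).

## Synthetic cohorts

The generator draws abundances exactly from the model above: expressed
genes from lognormal(μ_e, σ_e), not-expressed genes 0 with probability
`zero_inflation` (default 0.7 — real TPM matrices contain many exact
zeros, and the posterior has a special case there) and otherwise from
lognormal(μ_ne, σ_ne). Defaults (π_e 0.55, μ_ne −1.0, σ_ne 0.8, μ_e
4.5, σ_e 1.6 on log2) describe a genome-wide TPM vector with a noise
mode around 0.5 TPM and an expressed mode around 23 TPM. Planted
structure: housekeeping genes on everywhere; dormant genes off in every
non-testis normal sample, with a configurable fraction testis-exclusive
(on in a configurable fraction of testis samples, default 0.8); per
tumor cohort, a chosen subset of dormant genes reactivates i.i.d. per
sample at the configured prevalence. Ordinary genes switch on i.i.d.
per (gene, sample) with a probability calibrated so the expected
per-sample expressed fraction equals π_e; the i.i.d. choice (rather
than tissue-coherent gene programs) keeps the planted dormant set the
*only* dormant set — under tissue-coherent switching a few percent of
ordinary genes go silent in every tissue by chance, which would make
exact-set recovery ill-posed. Per-tissue location shifts (seeded
normal, SD 0.2 log2 units, disableable) keep samples from being
unrealistically identical.

What the generator does **not** emulate: gene–gene correlation and
co-regulated programs, batch and library-size effects, transcript-length
biases, multimodal expressed populations, or partial-silencing
intermediate states. Passing tests therefore demonstrate correctness of
the algorithms under the model's own assumptions and exact recovery of
planted structure — not performance on real GTEx/TCGA-scale data, whose
headline numbers require the external cohorts.

The toy chromatin fixture assigns each gene its own locus: active genes
get a promoter segment over the first exon and a transcription segment
over the body; silent genes a single repressed segment; a seeded
`noise_rate` fraction receives a conflicting pair (states 1 + 10) that
forces the ambiguous label, and the flipped set is recorded.

## Problem sizes and numerical choices

The test suite and the acceptance script use 20,000-gene single-sample
fits for parameter recovery (10 seeds), 4,000-gene samples for
call-accuracy measurement, and a 1,500-gene, 46 + 40-sample
atlas/tumor cohort in the well-separated regime (μ_e − μ_ne = 5.5,
scales ≤ 1) for end-to-end exact recovery — sizes chosen so the whole
suite runs in well under a minute while keeping binomial sampling noise
far below the asserted tolerances. Ties at a posterior of exactly 0.5
are expressed; ratios are computed from integer counts; the EM
convergence test is relative; all randomness flows from explicit seeds
(`numpy.random.default_rng`).

## Known limitations

* The mixture assumes exactly two lognormal components; strongly
  trimodal samples or heavy contamination violate it, and the per-sample
  π_e estimate refers to positive abundances only.
* EnB's NB-on-rounded-TPM is an approximation; it is provided as a
  comparator, not a recommended caller.
* The chromatin reference treats a gene as one unit; alternative
  promoters or isoform-level activity are out of scope.
* Tissue-level inference is a deterministic aggregation of per-sample
  calls; no shrinkage or hierarchical pooling across samples is
  attempted (single-sample applicability is the design goal).
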