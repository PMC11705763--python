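# statecall

Single-sample Bayesian gene expression state inference and
tumor-associated antigen (TAA) prediction from bulk RNA-seq TPM
matrices.

## The problem

Immunotherapy targets such as cancer/testis antigens are genes that are
transcriptionally silent in normal tissues (or restricted to testicular
germ cells) yet reactivated in tumors. Finding them requires deciding,
per gene and per sample, whether a gene is *expressed* or *not
expressed* — a decision that fixed TPM cutoffs handle poorly because the
noise floor varies between samples. `statecall` infers a per-sample
threshold probabilistically and chains the calls into a screening
workflow: silent ("dormant") genes in a normal-tissue atlas, reactivated
dormant genes in tumor cohorts, and per-patient antigen assignments.

## The model

Within one sample, the TPM abundances *x* of all genes are modelled as a
two-component lognormal mixture,

    f(x) = π_ne · f_ne(x) + π_e · f_e(x),

where `f_ne` and `f_e` are lognormal densities for the not-expressed and
expressed populations (normal on the log2 scale) and `π_e = 1 − π_ne`.
The mixture is fitted per sample by EM on the strictly positive
abundances, with initial values anchored by housekeeping genes
(constitutively expressed, so they locate the expressed mode). The
posterior probability that a gene with abundance *x* is expressed is

    P(expressed | x) = 0                                          if x = 0,
                       π_e f_e(x) / (π_ne f_ne(x) + π_e f_e(x))   otherwise,

and the binary state is 1 iff the posterior is ≥ 0.5. States aggregate
per tissue *j* over its *m* samples into the non-expressed ratio

    ratio(gene i not expressed in tissue j) = Σ_n (1 − state_n) / m.

A gene is **dormant** if its non-expressed ratio is ≥ 0.9 in every
normal tissue except testis (dormant genes with testicular expressed
ratio > 10% are flagged *testis_exclusive*). Dormant genes expressed in
≥ 5% of a tumor cohort's samples are **candidate TAAs**.

The package also implements three comparator methods (fixed TPM
thresholds; zFPKM z-scoring against the active density peak with the −3
activity threshold; an exponential + negative binomial "EnB" mixture
with a 1% probability threshold), a chromatin-state reference standard
(active/inactive labels from 15-state chromHMM-style segmentations), and
the two benchmarking protocols used to compare the methods: per-sample
precision/recall for both classes and tissue-level precision-recall
curves with AUPRC over the non-expressed ratio.

## Worked example

Simulate a small multi-tissue atlas with known latent states, fit one
sample and call states:

```python
import numpy as np
from statecall import (SimulationConfig, simulate_cohorts,
                       ExpressionVector, fit_mixture, call_states)

res = simulate_cohorts(SimulationConfig(seed=7, n_genes=2000))
expr = ExpressionVector.from_series(res.normal_matrix["liver_000"])
fit = fit_mixture(expr, res.housekeeping)
print(f"pi_e={fit.pi_e:.3f}  mu_ne={fit.mu_ne:.2f}  mu_e={fit.mu_e:.2f}")
calls = call_states(expr, fit)
print(f"expressed fraction: {calls.expressed_fraction:.3f}")
latent = res.truth.latent_normal["liver_000"].to_numpy()
print(f"agreement with simulated truth: {np.mean(calls.state == latent):.3f}")
```

prints

```
pi_e=0.791  mu_ne=-1.27  mu_e=4.25
expressed fraction: 0.542
agreement with simulated truth: 0.994
```

`pi_e` is the expressed-component weight *among positive abundances*
(zeros are excluded from the fit and called not expressed by
definition), so it exceeds the overall expressed fraction of 0.542; the
fitted locations sit close to the generating values (−1.0 and 4.5 on
the log2 scale, shifted by the simulated tissue effect). 99.4% of the
2,000 per-gene calls match the simulation's latent truth.

The same workflow runs from the shell:

```sh
statecall simulate --outdir sim --seed 7
statecall run --normal-matrix sim/normal.gct --normal-map sim/normal_samples.tsv \
              --tumor-matrix sim/tumor.gct  --tumor-map  sim/tumor_samples.tsv \
              --housekeeping sim/housekeeping.txt --outdir out
```

which writes per-sample state tables, tissue ratios, the dormant gene
table, the candidate TAA table (with per-patient expressed sample ids)
and a JSON manifest under `out/`.

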