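"""Synthetic multi-tissue cohorts with known latent expression states.

The generator mirrors the model assumed by the inference: within each
sample, expressed genes draw TPM from a lognormal with location ``mu_e``
and scale ``sigma_e`` (log2 scale), not-expressed genes draw 0 with
probability ``zero_inflation`` and otherwise from a low lognormal
(``mu_ne``, ``sigma_ne``). On top of this single-sample model it plants
the structures the downstream workflow must recover:

* housekeeping genes, expressed in every sample of every cohort;
* dormant genes, silent in every non-testis normal sample, a configured
  fraction of which are testis-exclusive (expressed in a configured
  fraction of testis samples);
* tumor cohorts in which a chosen subset of dormant genes ("planted
  TAAs") reactivates independently per tumor sample at a configured
  prevalence.

Ordinary genes switch on independently per (gene, sample) with a
probability chosen so the expected per-sample expressed fraction equals
the configured ``pi_e`` — exactly the exchangeable single-sample mixture
the inference assumes. Small per-tissue location shifts (seeded normal, SD
``tissue_effect_sd`` log2 units) keep samples from being unrealistically
identical; set the SD to 0 to disable. Everything is reproducible from
the mandatory seed.

What this emulates — multi-tissue TPM atlases with exact zeros, a
testis-like tissue and tumor reactivation — and what it does not
(gene-gene correlation, batch effects, length biases) is discussed in
the package's methods documentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "ChromatinSim",
    "simulate_cohorts",
    "simulate_chromatin_reference",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a synthetic atlas + tumor cohort.

    ``tissues`` is a list of (name, n_samples) for the normal atlas;
    ``tumor_cohorts`` a list of (name, n_samples, taa_prevalence) where
    the prevalence is the per-sample reactivation probability of each
    planted TAA gene. Locations/scales are on the log2-TPM scale.
    """

    seed: int
    n_genes: int = 2000
    n_housekeeping: int = 50
    tissues: tuple = (
        ("liver", 20), ("lung", 20), ("brain", 20), ("testis", 12),
    )
    tumor_cohorts: tuple = (("LIHC", 60, 0.10),)
    testis_label: str = "testis"
    pi_e: float = 0.55
    mu_ne: float = -1.0
    sigma_ne: float = 0.8
    mu_e: float = 4.5
    sigma_e: float = 1.6
    zero_inflation: float = 0.7
    dormant_fraction: float = 0.05
    testis_exclusive_fraction: float = 0.4
    testis_prevalence: float = 0.8
    n_taa: int = 30
    tissue_effect_sd: float = 0.2

    def validate(self) -> "SimulationConfig":
        fracs = {
            "pi_e": self.pi_e,
            "zero_inflation": self.zero_inflation,
            "dormant_fraction": self.dormant_fraction,
            "testis_exclusive_fraction": self.testis_exclusive_fraction,
            "testis_prevalence": self.testis_prevalence,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.mu_e <= self.mu_ne:
            raise ConfigError("mu_e must exceed mu_ne")
        if self.sigma_e <= 0 or self.sigma_ne <= 0:
            raise ConfigError("component scales must be positive")
        for name, n, prev in self.tumor_cohorts:
            if not 0 <= prev <= 1:
                raise ConfigError(
                    f"taa_prevalence={prev} for cohort {name!r} outside [0, 1]"
                )
        n_dormant = int(round(self.dormant_fraction * self.n_genes))
        if self.tumor_cohorts and self.n_taa > n_dormant:
            raise ConfigError(
                f"n_taa={self.n_taa} exceeds the {n_dormant} dormant genes "
                f"implied by dormant_fraction={self.dormant_fraction}"
            )
        if self.n_housekeeping + n_dormant > self.n_genes:
            raise ConfigError("housekeeping + dormant genes exceed n_genes")
        return self


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the simulated matrices."""

    latent_normal: pd.DataFrame      # gene x sample, {0,1}
    latent_tumor: pd.DataFrame       # gene x sample across all cohorts
    dormant: pd.DataFrame            # gene_id, category
    taa_genes: dict                  # cohort -> ordered list of gene ids
    housekeeping: list
    config: SimulationConfig

    def tumor_expressed_counts(self, cohort: str, tissue_of: pd.Series) -> pd.Series:
        """Realized per-gene expressed sample counts in one tumor cohort."""
        samples = tissue_of[tissue_of == cohort].index
        return self.latent_tumor[list(samples)].sum(axis=1)


@dataclass
class SimulationResult:
    normal_matrix: pd.DataFrame      # gene x sample TPM
    normal_tissue_of: pd.Series
    tumor_matrix: pd.DataFrame
    tumor_tissue_of: pd.Series
    housekeeping: list
    truth: SimulationTruth


def _abundances(rng, latent, mu_ne, sigma_ne, mu_e, sigma_e, zero_inflation,
                shift):
    """Draw TPM for one sample given latent 0/1 states."""
    n = latent.size
    out = np.empty(n)
    expr = latent == 1
    out[expr] = 2.0 ** rng.normal(mu_e + shift, sigma_e, size=int(expr.sum()))
    n_off = int((~expr).sum())
    zero = rng.random(n_off) < zero_inflation
    low = 2.0 ** rng.normal(mu_ne + shift, sigma_ne, size=n_off)
    low[zero] = 0.0
    out[~expr] = low
    return out


def simulate_cohorts(config: SimulationConfig) -> SimulationResult:
    """Generate the normal atlas and tumor cohorts described by ``config``.

    Returns matrices in TPM (genes x samples), sample-to-tissue maps, the
    housekeeping gene list, and a :class:`SimulationTruth` holding every
    latent state and planted set.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = np.array([f"G{i:06d}" for i in range(1, n + 1)], dtype=object)

    perm = rng.permutation(n)
    hk_idx = perm[: cfg.n_housekeeping]
    n_dormant = int(round(cfg.dormant_fraction * n))
    dormant_idx = perm[cfg.n_housekeeping: cfg.n_housekeeping + n_dormant]
    ordinary_idx = perm[cfg.n_housekeeping + n_dormant:]
    n_tx = int(round(cfg.testis_exclusive_fraction * n_dormant))
    testis_excl_idx = dormant_idx[:n_tx]

    # per-(gene, tissue) switch probability for ordinary genes, chosen so
    # the expected per-sample expressed fraction equals pi_e
    n_ord = ordinary_idx.size
    p_ord = 0.0 if n_ord == 0 else float(
        np.clip((cfg.pi_e * n - cfg.n_housekeeping) / n_ord, 0.0, 1.0)
    )

    tissue_names = [t[0] for t in cfg.tissues]
    shifts = {
        name: (rng.normal(0.0, cfg.tissue_effect_sd)
               if cfg.tissue_effect_sd > 0 else 0.0)
        for name in tissue_names + [c[0] for c in cfg.tumor_cohorts]
    }

    def build_cohort(name, n_samples, latent_for_sample):
        cols, latents, ids = {}, {}, []
        for i in range(n_samples):
            sid = f"{name}_{i:03d}"
            latent = latent_for_sample(i)
            cols[sid] = _abundances(
                rng, latent, cfg.mu_ne, cfg.sigma_ne, cfg.mu_e, cfg.sigma_e,
                cfg.zero_inflation, shifts[name],
            )
            latents[sid] = latent
            ids.append(sid)
        return cols, latents, ids

    normal_cols, normal_latents = {}, {}
    normal_map = {}
    for tissue, n_samples in cfg.tissues:
        is_testis = tissue == cfg.testis_label

        # ordinary genes switch on independently per sample, matching the
        # single-sample mixture model the inference assumes
        def latent_for_sample(_i, is_testis=is_testis):
            latent = np.zeros(n, dtype=np.int8)
            latent[hk_idx] = 1
            ord_on = rng.random(n_ord) < p_ord
            latent[ordinary_idx[ord_on]] = 1
            if is_testis and testis_excl_idx.size:
                on = rng.random(testis_excl_idx.size) < cfg.testis_prevalence
                latent[testis_excl_idx[on]] = 1
            return latent

        cols, latents, ids = build_cohort(tissue, n_samples, latent_for_sample)
        normal_cols.update(cols)
        normal_latents.update(latents)
        normal_map.update({sid: tissue for sid in ids})

    tumor_cols, tumor_latents, tumor_map = {}, {}, {}
    taa_genes: dict = {}
    for cname, n_samples, prevalence in cfg.tumor_cohorts:
        taa_idx = rng.choice(dormant_idx, size=cfg.n_taa, replace=False)
        taa_genes[cname] = [str(g) for g in gene_ids[np.sort(taa_idx)]]

        def latent_for_sample(_i, taa_idx=taa_idx, prevalence=prevalence):
            latent = np.zeros(n, dtype=np.int8)
            latent[hk_idx] = 1
            ord_on = rng.random(n_ord) < p_ord
            latent[ordinary_idx[ord_on]] = 1
            on = rng.random(taa_idx.size) < prevalence
            latent[taa_idx[on]] = 1
            return latent

        cols, latents, ids = build_cohort(cname, n_samples, latent_for_sample)
        tumor_cols.update(cols)
        tumor_latents.update(latents)
        tumor_map.update({sid: cname for sid in ids})

    index = pd.Index(gene_ids, name="gene_id")
    normal_matrix = pd.DataFrame(normal_cols, index=index)
    tumor_matrix = pd.DataFrame(tumor_cols, index=index)
    dormant_categories = np.where(
        np.isin(dormant_idx, testis_excl_idx), "testis_exclusive",
        "silent_everywhere",
    )
    order = np.argsort(dormant_idx)
    dormant_df = pd.DataFrame(
        {
            "gene_id": gene_ids[dormant_idx[order]],
            "category": dormant_categories[order],
        }
    )
    truth = SimulationTruth(
        latent_normal=pd.DataFrame(normal_latents, index=index),
        latent_tumor=pd.DataFrame(tumor_latents, index=index),
        dormant=dormant_df,
        taa_genes=taa_genes,
        housekeeping=[str(g) for g in gene_ids[np.sort(hk_idx)]],
        config=cfg,
    )
    return SimulationResult(
        normal_matrix=normal_matrix,
        normal_tissue_of=pd.Series(normal_map, name="tissue"),
        tumor_matrix=tumor_matrix,
        tumor_tissue_of=pd.Series(tumor_map, name="tissue"),
        housekeeping=truth.housekeeping,
        truth=truth,
    )


@dataclass
class ChromatinSim:
    """Toy chromatin segmentation consistent with a simulation's truth."""

    genes: pd.DataFrame          # gene_id, chrom, start, end, exon_starts, exon_ends
    segmentation: pd.DataFrame   # chrom, start, end, state
    flipped: list                # genes forced ambiguous by noise
    expected_labels: pd.DataFrame  # gene_id, label (the construction target)


def simulate_chromatin_reference(
    truth: SimulationTruth,
    tissue: str,
    tissue_of: pd.Series,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> ChromatinSim:
    """Emit toy interval annotations matching a tissue's latent truth.

    Each gene occupies its own locus on a synthetic chromosome. Genes
    whose dominant latent state in ``tissue`` is expressed receive an
    active promoter segment (state 1) over their first exon and an active
    transcription segment (state 4) over their body; silent genes receive
    a single repressed segment (state 13). At ``noise_rate`` 0 the
    reference-standard rules therefore label every gene by its latent
    tissue state; a ``noise_rate`` fraction of genes (seeded choice,
    recorded in ``flipped``) additionally receive a conflicting segment
    pair (states 1 + 10) that forces the ambiguous label.
    """
    if not 0 <= noise_rate <= 1:
        raise ParameterError("noise_rate must lie in [0, 1]")
    samples = list(tissue_of[tissue_of == tissue].index)
    if not samples:
        raise ParameterError(f"no samples with tissue label {tissue!r}")
    latent = truth.latent_normal[samples]
    dominant_expressed = latent.mean(axis=1) >= 0.5

    rng = np.random.default_rng(seed)
    gene_ids = list(latent.index)
    n_flip = int(round(noise_rate * len(gene_ids)))
    flipped = sorted(
        str(g) for g in rng.choice(gene_ids, size=n_flip, replace=False)
    )
    flipped_set = set(flipped)

    gene_rows, seg_rows = [], []
    span, body_len, exon_len = 3000, 2000, 200
    for i, gid in enumerate(gene_ids):
        start = i * span
        end = start + body_len
        exon_starts = [start, end - exon_len]
        exon_ends = [start + exon_len, end]
        gene_rows.append(
            {
                "gene_id": gid, "chrom": "chrS", "start": start, "end": end,
                "exon_starts": exon_starts, "exon_ends": exon_ends,
            }
        )
        if gid in flipped_set:
            seg_rows.append(("chrS", start, start + exon_len, "E1"))
            seg_rows.append(("chrS", start + exon_len, end, "E10"))
        elif dominant_expressed.loc[gid]:
            seg_rows.append(("chrS", start, start + exon_len, "E1"))
            seg_rows.append(("chrS", start + exon_len, end, "E4"))
        else:
            seg_rows.append(("chrS", start, end, "E13"))
    expected = pd.DataFrame(
        {
            "gene_id": [str(g) for g in gene_ids],
            "label": [
                "ambiguous" if g in flipped_set
                else ("active" if dominant_expressed.loc[g] else "inactive")
                for g in gene_ids
            ],
        }
    )
    return ChromatinSim(
        genes=pd.DataFrame(gene_rows),
        segmentation=pd.DataFrame(
            seg_rows, columns=["chrom", "start", "end", "state"]
        ),
        flipped=flipped,
        expected_labels=expected,
    )
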