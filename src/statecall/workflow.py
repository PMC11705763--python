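"""The end-to-end TAA-prediction workflow.

Stage 1 infers per-sample expression states over the normal atlas and
aggregates them into tissue-level non-expressed ratios; stage 2 runs the
same inference over the tumor cohorts; stage 3 intersects dormant genes
with tumor-expressed genes to produce candidate TAAs; stage 4 emits the
cross-cohort ratio table and annotation flags. Every run writes a JSON
manifest recording configuration, seed and package version; a failed
stage leaves earlier artifacts on disk and a FAILED marker in the
manifest.
"""

from __future__ import annotations

import importlib.metadata
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd

from . import io
from .aggregate import (
    CohortStateMatrix,
    annotate_candidates,
    identify_dormant_genes,
    predict_taas,
    tissue_ratios,
)
from .baselines import enb_states, fixed_threshold_states, zfpkm_states
from .errors import ConfigError, StatecallError
from .mixture import EMConfig, ExpressionVector, call_states, fit_mixture

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "default_housekeeping",
    "call_matrix",
    "fit_summary_frame",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class PipelineStageError(StatecallError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a composite workflow run.

    All cutoffs default to the published operating points: posterior 0.5
    (fixed inside the caller), dormancy non-expressed ratio 0.9, tumor
    expressed ratio 0.05, testis-exclusive expressed ratio 0.10 (strict),
    zFPKM threshold -3, EnB probability 0.01.
    """

    normal_matrix: str
    normal_map: str
    outdir: str
    tumor_matrix: str | None = None
    tumor_map: str | None = None
    housekeeping: str | None = None
    method: str = "variable"
    testis_label: str = "testis"
    dormancy_cutoff: float = 0.9
    taa_cutoff: float = 0.05
    testis_exclusive_cutoff: float = 0.10
    zfpkm_threshold: float = -3.0
    enb_prob_cutoff: float = 0.01
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    em_restarts: int = 3
    seed: int = 0
    membrane_list: str | None = None
    cta_list: str | None = None
    testis_specific_list: str | None = None
    log_level: str = "INFO"

    def em_config(self) -> EMConfig:
        return EMConfig(
            tol=self.em_tol, max_iter=self.em_max_iter,
            n_restarts=self.em_restarts, seed=self.seed,
        )

    def validate(self) -> "RunConfig":
        for name, v, lo, hi in (
            ("dormancy_cutoff", self.dormancy_cutoff, 0, 1),
            ("taa_cutoff", self.taa_cutoff, 0, 1),
            ("testis_exclusive_cutoff", self.testis_exclusive_cutoff, 0, 1),
            ("enb_prob_cutoff", self.enb_prob_cutoff, 0, 1),
        ):
            if not lo < v <= hi:
                raise ConfigError(f"{name}={v} outside ({lo}, {hi}]")
        _parse_method(self.method)
        return self


def default_housekeeping() -> list[str]:
    """The bundled housekeeping gene list (HGNC symbols)."""
    text = (
        resources.files("statecall.data")
        .joinpath("housekeeping_default.txt")
        .read_text()
    )
    return [
        line.split("#", 1)[0].strip()
        for line in text.splitlines()
        if line.split("#", 1)[0].strip()
    ]


def _parse_method(method: str):
    if method in ("variable", "zfpkm", "enb"):
        return method, None
    if method.startswith("fixed:"):
        try:
            return "fixed", float(method.split(":", 1)[1])
        except ValueError:
            pass
    raise ConfigError(
        f"unknown method {method!r}; expected variable, zfpkm, enb or "
        "fixed:<TPM>"
    )


def call_matrix(
    matrix: pd.DataFrame,
    method: str = "variable",
    housekeeping=None,
    em_config: EMConfig | None = None,
    zfpkm_threshold: float = -3.0,
    enb_prob_cutoff: float = 0.01,
):
    """Run one state-calling method over every sample of a matrix.

    Returns ``(call_sets, fits)`` where ``fits`` maps sample ids to the
    per-sample MixtureFit (variable method only; empty otherwise).
    """
    kind, fixed_cutoff = _parse_method(method)
    call_sets, fits = [], {}
    for sample_id in matrix.columns:
        expr = ExpressionVector.from_series(matrix[sample_id])
        if kind == "variable":
            fit = fit_mixture(expr, housekeeping, em_config)
            cs = call_states(expr, fit)
            fits[sample_id] = fit
            log.info(
                "sample %s: EM converged=%s iter=%d pi_e=%.3f",
                sample_id, fit.converged, fit.n_iter, fit.pi_e,
            )
        elif kind == "zfpkm":
            cs, _, _ = zfpkm_states(expr, threshold=zfpkm_threshold)
        elif kind == "enb":
            cs, _, _ = enb_states(expr, prob_cutoff=enb_prob_cutoff)
        else:
            cs = fixed_threshold_states(expr, fixed_cutoff)
        call_sets.append(cs)
    return call_sets, fits


def fit_summary_frame(fits: dict) -> pd.DataFrame:
    """Per-sample mixture-fit summary table."""
    rows = []
    for sample_id, f in fits.items():
        rows.append(
            {
                "sample_id": sample_id, "pi_e": f.pi_e, "mu_ne": f.mu_ne,
                "sigma_ne": f.sigma_ne, "mu_e": f.mu_e, "sigma_e": f.sigma_e,
                "n_iter": f.n_iter, "converged": f.converged,
                "log_likelihood": f.log_likelihood, "n_fitted": f.n_fitted,
            }
        )
    return pd.DataFrame(rows)


def states_long_frame(call_sets) -> pd.DataFrame:
    return pd.concat([cs.to_frame() for cs in call_sets], ignore_index=True)


def serialize_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Flatten list/flag columns for the TSV on-disk form."""
    out = candidates.copy()
    out["expressed_sample_ids"] = out["expressed_sample_ids"].map(
        lambda ids: ",".join(ids)
    )
    flag_cols = [c for c in ("membrane", "known_CTA", "testis_specific")
                 if c in out.columns]
    if flag_cols:
        out["annotations"] = out[flag_cols].apply(
            lambda row: ";".join(c for c in flag_cols if row[c]), axis=1
        )
        out = out.drop(columns=flag_cols)
    return out


def _package_version() -> str:
    try:
        return importlib.metadata.version("statecall")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the composite workflow; returns the manifest dict.

    Raises :class:`PipelineStageError` on any stage failure, after
    writing the manifest with a FAILED marker; artifacts from completed
    stages remain on disk.
    """
    cfg = config.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "package_version": _package_version(),
        "stages_completed": [],
        "status": "RUNNING",
        "artifacts": {},
    }

    def checkpoint(stage=None, status=None):
        if stage:
            manifest["stages_completed"].append(stage)
        if status:
            manifest["status"] = status
        io.write_manifest(manifest, outdir / "manifest.json")

    def fail(stage, exc):
        manifest["status"] = f"FAILED at stage {stage}"
        manifest["error"] = str(exc)
        io.write_manifest(manifest, outdir / "manifest.json")
        raise PipelineStageError(stage, exc)

    hk = (
        io.read_gene_list(cfg.housekeeping)
        if cfg.housekeeping else default_housekeeping()
    )
    em_cfg = cfg.em_config()

    # --- stage 1: normal atlas inference + tissue ratios -----------------
    try:
        normal = io.read_expression(cfg.normal_matrix)
        normal_map = io.read_sample_map(cfg.normal_map)
        calls, fits = call_matrix(
            normal, cfg.method, hk, em_cfg,
            cfg.zfpkm_threshold, cfg.enb_prob_cutoff,
        )
        cohort = CohortStateMatrix.from_call_sets(calls, normal_map)
        ratios = tissue_ratios(cohort)
        states_long_frame(calls).to_csv(
            outdir / "normal_states.tsv", sep="\t", index=False
        )
        if fits:
            fit_summary_frame(fits).to_csv(
                outdir / "normal_fit_summary.tsv", sep="\t", index=False
            )
        ratios.to_csv(outdir / "tissue_ratios.tsv", sep="\t", index=False)
        manifest["artifacts"]["tissue_ratios"] = "tissue_ratios.tsv"
        dormant = identify_dormant_genes(
            ratios,
            testis_label=cfg.testis_label,
            ratio_cutoff=cfg.dormancy_cutoff,
            testis_exclusive_cutoff=cfg.testis_exclusive_cutoff,
        )
        dormant.to_csv(outdir / "dormant_genes.tsv", sep="\t", index=False)
        manifest["artifacts"]["dormant_genes"] = "dormant_genes.tsv"
        checkpoint(stage="normal_inference")
    except PipelineStageError:
        raise
    except Exception as exc:
        fail("normal_inference", exc)

    if cfg.tumor_matrix is None:
        checkpoint(status="OK")
        return manifest

    # --- stage 2: tumor cohort inference ---------------------------------
    try:
        tumor = io.read_expression(cfg.tumor_matrix)
        tumor_map = io.read_sample_map(cfg.tumor_map)
        tumor_calls, tumor_fits = call_matrix(
            tumor, cfg.method, hk, em_cfg,
            cfg.zfpkm_threshold, cfg.enb_prob_cutoff,
        )
        tumor_cohort = CohortStateMatrix.from_call_sets(tumor_calls, tumor_map)
        states_long_frame(tumor_calls).to_csv(
            outdir / "tumor_states.tsv", sep="\t", index=False
        )
        if tumor_fits:
            fit_summary_frame(tumor_fits).to_csv(
                outdir / "tumor_fit_summary.tsv", sep="\t", index=False
            )
        checkpoint(stage="tumor_inference")
    except Exception as exc:
        fail("tumor_inference", exc)

    # --- stage 3: TAA intersection ---------------------------------------
    try:
        candidates = predict_taas(
            tumor_cohort, dormant, expressed_cutoff=cfg.taa_cutoff
        )
        checkpoint(stage="taa_prediction")
    except Exception as exc:
        fail("taa_prediction", exc)

    # --- stage 4: annotation + cross-cohort table ------------------------
    try:
        membrane = (
            io.read_gene_list(cfg.membrane_list) if cfg.membrane_list else ()
        )
        cta = io.read_gene_list(cfg.cta_list) if cfg.cta_list else ()
        testis_specific = (
            io.read_gene_list(cfg.testis_specific_list)
            if cfg.testis_specific_list else ()
        )
        candidates = annotate_candidates(
            candidates, membrane=membrane, cta=cta,
            testis_specific=testis_specific,
        )
        serialize_candidates(candidates).to_csv(
            outdir / "taa_candidates.tsv", sep="\t", index=False
        )
        manifest["artifacts"]["taa_candidates"] = "taa_candidates.tsv"
        cross = candidates.pivot_table(
            index="gene_id", columns="cancer_type",
            values="tumor_expressed_ratio", fill_value=0.0,
        )
        cross.to_csv(outdir / "cross_cohort_expressed_ratio.tsv", sep="\t")
        manifest["artifacts"]["cross_cohort_table"] = (
            "cross_cohort_expressed_ratio.tsv"
        )
        checkpoint(stage="annotation", status="OK")
    except Exception as exc:
        fail("annotation", exc)
    return manifest
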