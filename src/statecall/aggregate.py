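"""Tissue-level aggregation of expression states and TAA prediction.

Single-sample binary states are aggregated per tissue into the
non-expressed ratio

    ratio(gene i not expressed in tissue j) = sum_n (1 - state_n) / m

over the m samples of tissue j. Dormant genes are those with
non-expressed ratio >= 0.9 in every normal tissue except testis;
dormant genes called expressed in at least 5% of a tumor cohort's
samples are candidate tumor-associated antigens (TAAs). Dormant genes
whose testicular expressed ratio exceeds 10% are classed
``testis_exclusive`` (the cancer/testis antigen pattern); the rest are
``silent_everywhere``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompleteAtlasError, MappingError, ParameterError, ShapeError
from .mixture import StateCallSet

__all__ = [
    "CohortStateMatrix",
    "tissue_ratios",
    "identify_dormant_genes",
    "predict_taas",
    "annotate_candidates",
    "cutoff_sweep",
    "patient_coverage",
]

log = logging.getLogger(__name__)

TESTIS_EXCLUSIVE = "testis_exclusive"
SILENT_EVERYWHERE = "silent_everywhere"

#: TissueSummary table columns (one row per gene x tissue)
TISSUE_SUMMARY_COLUMNS = (
    "gene_id", "tissue", "m", "non_expressed_ratio", "expressed_ratio",
)


@dataclass
class CohortStateMatrix:
    """Binary expression states for a cohort of samples.

    Attributes
    ----------
    states
        Gene x sample DataFrame with values strictly in {0, 1}.
    tissue_of
        Series mapping every sample id to its tissue (or cancer-cohort)
        label.
    """

    states: pd.DataFrame
    tissue_of: pd.Series

    def __post_init__(self):
        vals = self.states.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ShapeError("states must be strictly 0/1")
        self.states = self.states.astype(np.int8)
        missing = [s for s in self.states.columns if s not in self.tissue_of.index]
        if missing:
            raise MappingError(
                f"samples without a tissue label: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        self.tissue_of = self.tissue_of.loc[list(self.states.columns)]

    @classmethod
    def from_call_sets(
        cls, call_sets: list[StateCallSet], tissue_of: pd.Series
    ) -> "CohortStateMatrix":
        """Assemble from per-sample call sets sharing one gene universe."""
        first = call_sets[0]
        cols = {}
        for cs in call_sets:
            if not np.array_equal(cs.gene_ids, first.gene_ids):
                raise ShapeError(
                    f"sample {cs.sample_id!r} has a different gene universe"
                )
            cols[cs.sample_id] = cs.state
        states = pd.DataFrame(cols, index=pd.Index(first.gene_ids, name="gene_id"))
        return cls(states=states, tissue_of=tissue_of)

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.tissue_of))


def tissue_ratios(cohort: CohortStateMatrix) -> pd.DataFrame:
    """Per-gene, per-tissue non-expressed and expressed ratios.

    Returns a long-format DataFrame with columns
    ``gene_id, tissue, m, non_expressed_ratio, expressed_ratio``, one row
    per gene x tissue, computed as the exact sample fractions.
    """
    frames = []
    for tissue, samples in cohort.tissue_of.groupby(cohort.tissue_of).groups.items():
        block = cohort.states[list(samples)]
        m = block.shape[1]
        n_expressed = block.sum(axis=1).to_numpy(dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": block.index,
                    "tissue": tissue,
                    "m": m,
                    "non_expressed_ratio": (m - n_expressed) / m,
                    "expressed_ratio": n_expressed / m,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    small = out.loc[out["m"] < 10, "tissue"].unique()
    if len(small):
        log.warning(
            "tissues with fewer than 10 samples (ratios are noisy): %s",
            ", ".join(map(str, small)),
        )
    return out


def identify_dormant_genes(
    summaries: pd.DataFrame,
    testis_label: str | None = "testis",
    ratio_cutoff: float = 0.9,
    testis_exclusive_cutoff: float = 0.10,
) -> pd.DataFrame:
    """Genes non-expressed in >= ``ratio_cutoff`` of samples in every
    non-testis tissue.

    Returns a DataFrame with columns ``gene_id,
    min_non_expressed_ratio, testis_expressed_ratio, category`` where
    category is ``testis_exclusive`` iff the testicular expressed ratio
    is strictly greater than ``testis_exclusive_cutoff`` and
    ``silent_everywhere`` otherwise (including when the atlas has no
    testis tissue).

    Raises
    ------
    IncompleteAtlasError
        If any gene lacks a summary for any required (non-testis) tissue.
    """
    if not 0 < ratio_cutoff <= 1:
        raise ParameterError("ratio_cutoff must be in (0, 1]")
    wide = summaries.pivot(
        index="gene_id", columns="tissue", values="non_expressed_ratio"
    )
    tissues = list(wide.columns)
    has_testis = testis_label is not None and testis_label in tissues
    non_testis = [t for t in tissues if t != testis_label]
    if not non_testis:
        raise IncompleteAtlasError("atlas contains no non-testis tissues")
    block = wide[non_testis]
    if block.isna().any().any():
        gene = block.index[block.isna().any(axis=1)][0]
        tissue = block.columns[block.loc[gene].isna()][0]
        raise IncompleteAtlasError(
            f"gene {gene!r} has no summary for tissue {tissue!r}"
        )
    min_ratio = block.min(axis=1)
    dormant = min_ratio >= ratio_cutoff
    genes = wide.index[dormant]
    if has_testis:
        testis_expr = 1.0 - wide.loc[genes, testis_label]
        testis_expr = testis_expr.fillna(np.nan)
    else:
        testis_expr = pd.Series(np.nan, index=genes)
    category = np.where(
        testis_expr.to_numpy() > testis_exclusive_cutoff,
        TESTIS_EXCLUSIVE,
        SILENT_EVERYWHERE,
    )
    return pd.DataFrame(
        {
            "gene_id": genes,
            "min_non_expressed_ratio": min_ratio[dormant].to_numpy(),
            "testis_expressed_ratio": testis_expr.to_numpy(),
            "category": category,
        }
    ).reset_index(drop=True)


def _cohort_expressed_ratios(tumor_cohort: CohortStateMatrix) -> pd.DataFrame:
    """Expressed ratios per gene per cohort label, with sample id lists."""
    rows = []
    for cohort_label, samples in tumor_cohort.tissue_of.groupby(
        tumor_cohort.tissue_of
    ).groups.items():
        block = tumor_cohort.states[list(samples)]
        ratio = block.mean(axis=1)
        n_expr = block.sum(axis=1)
        expressed_ids = block.apply(
            lambda row: [s for s, v in row.items() if v == 1], axis=1
        )
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": block.index,
                    "cancer_type": cohort_label,
                    "tumor_expressed_ratio": ratio.to_numpy(),
                    "n_expressed": n_expr.to_numpy(),
                    "n_samples": block.shape[1],
                    "expressed_sample_ids": expressed_ids.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def predict_taas(
    tumor_cohort: CohortStateMatrix,
    dormant: pd.DataFrame,
    expressed_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Candidate TAAs: dormant genes expressed in >= ``expressed_cutoff``
    of a tumor cohort's samples.

    Runs independently per cohort label in ``tumor_cohort.tissue_of``;
    rows are (gene, cancer_type) pairs with the exact expressed sample
    ids, enabling per-patient antigen assignment.
    """
    if not 0 < expressed_cutoff <= 1:
        raise ParameterError("expressed_cutoff must be in (0, 1]")
    if dormant.empty:
        raise ParameterError("dormant gene list is empty")
    ratios = _cohort_expressed_ratios(tumor_cohort)
    dormant_set = set(dormant["gene_id"])
    hits = ratios[
        ratios["gene_id"].isin(dormant_set)
        & (ratios["tumor_expressed_ratio"] >= expressed_cutoff)
    ].copy()
    return hits.sort_values(
        ["cancer_type", "tumor_expressed_ratio"], ascending=[True, False]
    ).reset_index(drop=True)


def annotate_candidates(
    candidates: pd.DataFrame,
    membrane=(),
    cta=(),
    testis_specific=(),
) -> pd.DataFrame:
    """Flag candidates by membership in annotation gene sets.

    Adds boolean ``membrane``, ``known_CTA`` and ``testis_specific``
    columns; empty sets simply yield all-false flags.
    """
    out = candidates.copy()
    for col, geneset in (
        ("membrane", set(membrane)),
        ("known_CTA", set(cta)),
        ("testis_specific", set(testis_specific)),
    ):
        if not geneset:
            log.warning("annotation list %r is empty; all flags false", col)
        out[col] = out["gene_id"].isin(geneset)
        log.info("annotation %s: %d of %d candidates", col, int(out[col].sum()), len(out))
    return out


def cutoff_sweep(
    tumor_cohort: CohortStateMatrix,
    dormant: pd.DataFrame,
    cutoffs,
) -> pd.DataFrame:
    """Candidate counts across a grid of expressed-ratio cutoffs.

    ``cutoffs`` must be sorted ascending, each in (0, 1]; by threshold
    nesting the counts are non-increasing in the cutoff. Returns columns
    ``cancer_type, cutoff, candidate_count``.
    """
    cutoffs = list(cutoffs)
    if any(not 0 < c <= 1 for c in cutoffs):
        raise ParameterError("cutoffs must each lie in (0, 1]")
    if cutoffs != sorted(cutoffs):
        raise ParameterError("cutoffs must be sorted ascending")
    ratios = _cohort_expressed_ratios(tumor_cohort)
    ratios = ratios[ratios["gene_id"].isin(set(dormant["gene_id"]))]
    rows = []
    for cancer_type, grp in ratios.groupby("cancer_type"):
        for c in cutoffs:
            rows.append(
                {
                    "cancer_type": cancer_type,
                    "cutoff": c,
                    "candidate_count": int(
                        (grp["tumor_expressed_ratio"] >= c).sum()
                    ),
                }
            )
    return pd.DataFrame(rows)


def patient_coverage(
    candidates: pd.DataFrame, tumor_cohort: CohortStateMatrix
) -> pd.DataFrame:
    """Fraction of tumors per cohort expressing at least one candidate.

    Computed as the union of the candidates' expressed sample id lists
    divided by the cohort size.
    """
    rows = []
    for cancer_type, grp in candidates.groupby("cancer_type"):
        covered: set = set()
        for ids in grp["expressed_sample_ids"]:
            covered.update(ids)
        cohort_samples = tumor_cohort.tissue_of[
            tumor_cohort.tissue_of == cancer_type
        ].index
        rows.append(
            {
                "cancer_type": cancer_type,
                "n_covered": len(covered),
                "n_samples": len(cohort_samples),
                "coverage": len(covered) / max(len(cohort_samples), 1),
            }
        )
    return pd.DataFrame(rows)
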