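"""Chromatin-state reference standards and benchmarking protocols.

The reference standard labels genes active/inactive from a 15-state
chromHMM-style segmentation. A gene is **active** when all three hold:

1. at least one active promoter or promoter-flanking segment (states 1-2)
   overlaps its exons;
2. at least one active transcription segment (states 3-5) overlaps its
   gene body (optionally its exons);
3. no repressed-state segment (states 9-15) overlaps it anywhere.

A gene is **inactive** when it has no state 1-5 overlap at all and at
least one state 9-15 overlap. Genes satisfying neither conjunction are
ambiguous and excluded from all metrics.

Two evaluation protocols are provided: per-sample precision/recall for
both the non-expressed and expressed classes (mean and SD across
samples), and a tissue-level precision-recall curve swept over the
non-expressed-ratio threshold, with AUPRC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import AnnotationError, EvaluationError, FormatError
from .mixture import StateCallSet

__all__ = [
    "ChromatinAnnotation",
    "PRCurve",
    "EvaluationReport",
    "annotate_from_segmentation",
    "build_reference_standard",
    "evaluate_per_sample",
    "tissue_pr_curve",
]

log = logging.getLogger(__name__)

PROMOTER_STATES = frozenset({1, 2})
TRANSCRIPTION_STATES = frozenset({3, 4, 5})
REPRESSED_STATES = frozenset(range(9, 16))

ACTIVE, INACTIVE, AMBIGUOUS = "active", "inactive", "ambiguous"


@dataclass(frozen=True)
class ChromatinAnnotation:
    """Chromatin-state overlaps for one gene.

    Intervals are 0-based half-open; state labels are integers 1..15.
    ``exon_states`` / ``body_states`` are the sets of segmentation states
    overlapping the exons / the whole gene body.
    """

    gene_id: str
    exon_states: frozenset
    body_states: frozenset

    def __post_init__(self):
        all_states = self.exon_states | self.body_states
        if any(s not in range(1, 16) for s in all_states):
            raise FormatError(
                f"gene {self.gene_id!r}: chromatin states must be in 1..15, "
                f"got {sorted(all_states)}"
            )


def _parse_state_label(label) -> int:
    s = str(label)
    if s.upper().startswith("E"):
        s = s[1:]
    # chromHMM mnemonic labels like "1_TssA" keep the leading number
    s = s.split("_")[0]
    try:
        state = int(s)
    except ValueError as exc:
        raise FormatError(f"unparseable chromatin state label {label!r}") from exc
    if state not in range(1, 16):
        raise FormatError(f"chromatin state {state} outside 1..15")
    return state


def annotate_from_segmentation(
    genes: pd.DataFrame, segmentation: pd.DataFrame
) -> list[ChromatinAnnotation]:
    """Intersect gene models with a chromatin-state segmentation.

    Parameters
    ----------
    genes
        One row per gene: ``gene_id, chrom, start, end, exon_starts,
        exon_ends`` where the exon columns hold lists of 0-based
        half-open coordinates.
    segmentation
        BED4-style table: ``chrom, start, end, state`` with state labels
        "1".."15" or "E1".."E15".
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in segmentation.groupby("chrom"):
        tree = IntervalTree()
        for start, end, state in zip(grp["start"], grp["end"], grp["state"]):
            if end > start:
                tree.addi(int(start), int(end), _parse_state_label(state))
        trees[chrom] = tree

    annotations = []
    for row in genes.itertuples(index=False):
        tree = trees.get(row.chrom, IntervalTree())
        exon_pairs = list(zip(row.exon_starts, row.exon_ends))
        if not exon_pairs or row.end <= row.start:
            raise AnnotationError(f"gene {row.gene_id!r} has no intervals")
        exon_states = set()
        for s, e in exon_pairs:
            exon_states.update(iv.data for iv in tree.overlap(int(s), int(e)))
        body_states = {
            iv.data for iv in tree.overlap(int(row.start), int(row.end))
        }
        annotations.append(
            ChromatinAnnotation(
                gene_id=row.gene_id,
                exon_states=frozenset(exon_states),
                body_states=frozenset(body_states | exon_states),
            )
        )
    return annotations


def build_reference_standard(
    annotations: list[ChromatinAnnotation],
    transcription_span: str = "body",
) -> pd.DataFrame:
    """Label genes active/inactive/ambiguous from chromatin-state overlaps.

    ``transcription_span`` selects the region the transcription-mark
    requirement (states 3-5) is checked against: the whole gene
    ``"body"`` (default) or the ``"exons"`` only.

    Returns a DataFrame with columns ``gene_id, label``.
    """
    if transcription_span not in ("body", "exons"):
        raise ValueError("transcription_span must be 'body' or 'exons'")
    rows = []
    for ann in annotations:
        if not (ann.exon_states or ann.body_states):
            raise AnnotationError(f"gene {ann.gene_id!r} has no state overlaps")
        span_states = (
            ann.body_states if transcription_span == "body" else ann.exon_states
        )
        all_states = ann.body_states | ann.exon_states
        has_promoter = bool(ann.exon_states & PROMOTER_STATES)
        has_transcription = bool(span_states & TRANSCRIPTION_STATES)
        has_repressed = bool(all_states & REPRESSED_STATES)
        has_active_any = bool(all_states & (PROMOTER_STATES | TRANSCRIPTION_STATES))
        if has_promoter and has_transcription and not has_repressed:
            label = ACTIVE
        elif not has_active_any and has_repressed:
            label = INACTIVE
        else:
            label = AMBIGUOUS
        rows.append({"gene_id": ann.gene_id, "label": label})
    return pd.DataFrame(rows)


def _confusion(pred: np.ndarray, truth: np.ndarray):
    """(precision, recall) with the positive class coded 1 in both arrays;
    precision is NaN when there are no predicted positives."""
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    return precision, recall


@dataclass
class EvaluationReport:
    """Per-sample precision/recall for both classes, with mean and SD.

    ``per_sample`` has one row per sample with columns
    ``sample_id, precision_non_expressed, recall_non_expressed,
    precision_expressed, recall_expressed``; ``summary`` maps each of
    those metrics to (mean, sd) across samples (sample SD, n-1
    denominator), with undefined (NaN) values excluded and counted in
    ``n_undefined``.
    """

    method_name: str
    per_sample: pd.DataFrame
    summary: dict = field(default_factory=dict)
    n_undefined: dict = field(default_factory=dict)

    def summarize(self) -> "EvaluationReport":
        self.summary, self.n_undefined = {}, {}
        for col in self.per_sample.columns:
            if col == "sample_id":
                continue
            vals = self.per_sample[col].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            n_undef = int(np.isnan(vals).sum())
            self.n_undefined[col] = n_undef
            if n_undef:
                log.info(
                    "%s: %d sample(s) with undefined %s excluded from "
                    "mean/SD", self.method_name, n_undef, col,
                )
            mean = float(np.mean(defined)) if defined.size else np.nan
            sd = (
                float(np.std(defined, ddof=1)) if defined.size > 1 else 0.0
            )
            self.summary[col] = (mean, sd)
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "mean": v[0], "sd": v[1],
             "n_undefined": self.n_undefined.get(k, 0)}
            for k, v in self.summary.items()
        ]
        return pd.DataFrame(rows)


def evaluate_per_sample(
    calls: list[StateCallSet],
    ref: pd.DataFrame,
    method_name: str = "",
) -> EvaluationReport:
    """Score per-sample state calls against a reference standard.

    For the non-expressed class, reference-inactive genes are the
    positives and a prediction of state 0 is a positive call; for the
    expressed class, reference-active genes are the positives. Ambiguous
    reference genes are excluded. Precision/recall are computed per
    sample, then averaged; samples with no predicted positives in a class
    have undefined precision there and are excluded from that metric's
    mean/SD (with a logged count).
    """
    if not calls:
        raise EvaluationError("no samples to evaluate")
    ref = ref[ref["label"].isin((ACTIVE, INACTIVE))]
    ref_map = dict(zip(ref["gene_id"], ref["label"]))
    rows = []
    for cs in calls:
        mask = np.fromiter(
            (g in ref_map for g in cs.gene_ids), dtype=bool, count=len(cs)
        )
        if not mask.any():
            raise EvaluationError(
                f"sample {cs.sample_id!r} shares no unambiguous genes "
                "with the reference"
            )
        truth_active = np.fromiter(
            (ref_map[g] == ACTIVE for g in cs.gene_ids[mask]),
            dtype=bool, count=int(mask.sum()),
        )
        state = cs.state[mask]
        p_ne, r_ne = _confusion((state == 0).astype(int), (~truth_active).astype(int))
        p_e, r_e = _confusion((state == 1).astype(int), truth_active.astype(int))
        rows.append(
            {
                "sample_id": cs.sample_id,
                "precision_non_expressed": p_ne,
                "recall_non_expressed": r_ne,
                "precision_expressed": p_e,
                "recall_expressed": r_e,
            }
        )
    report = EvaluationReport(
        method_name=method_name, per_sample=pd.DataFrame(rows)
    )
    return report.summarize()


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall curve over the non-expressed-ratio threshold.

    ``points`` holds (threshold, recall, precision) rows ordered by
    descending threshold, so recall is non-decreasing along the sweep.
    ``auprc`` integrates precision over recall by the trapezoidal rule
    with an anchor at recall 0 carrying the precision of the
    highest-threshold prediction set. ``precision_at_09`` is the
    precision at the fixed ratio threshold 0.9, the dormancy operating
    point.
    """

    points: pd.DataFrame
    auprc: float
    precision_at_09: float


def tissue_pr_curve(
    ratios: pd.DataFrame,
    ref: pd.DataFrame,
    operating_threshold: float = 0.9,
) -> PRCurve:
    """Tissue-level PR curve of the non-expressed ratio as a score for
    reference-inactive genes.

    ``ratios`` is a TissueSummary table restricted to one tissue (columns
    ``gene_id`` and ``non_expressed_ratio``); ``ref`` a reference
    standard. At each distinct ratio value t, genes with ratio >= t are
    predicted non-expressed and scored with reference-inactive as the
    positive class.
    """
    if "tissue" in ratios.columns and ratios["tissue"].nunique() > 1:
        raise EvaluationError("ratios must cover exactly one tissue")
    ref = ref[ref["label"].isin((ACTIVE, INACTIVE))]
    merged = ratios.merge(ref, on="gene_id", how="inner")
    if len(merged) < 10:
        raise EvaluationError(
            f"only {len(merged)} unambiguous genes shared between ratios "
            "and reference (need >= 10)"
        )
    scores = merged["non_expressed_ratio"].to_numpy(dtype=float)
    truth = (merged["label"] == INACTIVE).to_numpy()
    thresholds = np.unique(scores)[::-1]
    recs, precs, rows = [], [], []
    for t in thresholds:
        pred = scores >= t
        p, r = _confusion(pred.astype(int), truth.astype(int))
        rows.append({"threshold": t, "recall": r, "precision": p})
        recs.append(r)
        precs.append(p)
    points = pd.DataFrame(rows)
    auprc = _auprc(np.asarray(recs, dtype=float), np.asarray(precs, dtype=float))
    p_at, _ = _confusion(
        (scores >= operating_threshold).astype(int), truth.astype(int)
    )
    return PRCurve(points=points, auprc=float(auprc), precision_at_09=float(p_at))


def _auprc(recalls: np.ndarray, precisions: np.ndarray) -> float:
    """Trapezoidal area over recall, anchored at (0, precision of the
    top-ranked prediction set). Points must be in sweep order (recall
    non-decreasing)."""
    ok = ~np.isnan(precisions)
    recalls, precisions = recalls[ok], precisions[ok]
    if recalls.size == 0:
        return np.nan
    r = np.concatenate([[0.0], recalls])
    p = np.concatenate([[precisions[0]], precisions])
    return float(np.trapezoid(p, r))
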