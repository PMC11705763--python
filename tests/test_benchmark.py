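"""Reference-standard construction and the two evaluation protocols."""

import numpy as np
import pandas as pd
import pytest

from statecall import (
    ChromatinAnnotation,
    StateCallSet,
    annotate_from_segmentation,
    build_reference_standard,
    evaluate_per_sample,
    tissue_pr_curve,
)
from statecall.errors import AnnotationError, EvaluationError, FormatError


def ann(gene_id, exon_states, body_states):
    return ChromatinAnnotation(
        gene_id=gene_id,
        exon_states=frozenset(exon_states),
        body_states=frozenset(body_states) | frozenset(exon_states),
    )


def call_set(sample_id, gene_ids, states):
    states = np.asarray(states, dtype=np.int8)
    return StateCallSet(
        sample_id=sample_id,
        gene_ids=np.asarray(gene_ids, dtype=object),
        tpm=states.astype(float),
        posterior=states.astype(float),
        state=states,
    )


class TestReferenceStandard:
    def test_three_feature_active_rule(self):
        # state-1 on exons, state-4 in the body, nothing repressed
        ref = build_reference_standard([ann("g", {1}, {4})])
        assert ref.iloc[0]["label"] == "active"

    def test_repressed_only_is_inactive(self):
        ref = build_reference_standard([ann("g", set(), {13})])
        assert ref.iloc[0]["label"] == "inactive"

    def test_conflicting_marks_are_ambiguous(self):
        ref = build_reference_standard([ann("g", {1}, {10})])
        assert ref.iloc[0]["label"] == "ambiguous"

    def test_promoter_without_transcription_is_ambiguous(self):
        ref = build_reference_standard([ann("g", {1}, set())])
        assert ref.iloc[0]["label"] == "ambiguous"

    def test_transcription_span_switch(self):
        # state 4 overlaps the body but not the exons
        a = ChromatinAnnotation(
            gene_id="g", exon_states=frozenset({1}),
            body_states=frozenset({1, 4}),
        )
        assert build_reference_standard([a], "body").iloc[0]["label"] == "active"
        assert (
            build_reference_standard([a], "exons").iloc[0]["label"]
            == "ambiguous"
        )

    def test_state_labels_validated(self):
        with pytest.raises(FormatError):
            ann("g", {16}, set())

    def test_interval_intersection(self):
        genes = pd.DataFrame(
            [
                {"gene_id": "gA", "chrom": "chr1", "start": 0, "end": 1000,
                 "exon_starts": [0, 800], "exon_ends": [200, 1000]},
                {"gene_id": "gB", "chrom": "chr1", "start": 2000, "end": 3000,
                 "exon_starts": [2000], "exon_ends": [2200]},
            ]
        )
        seg = pd.DataFrame(
            [
                ("chr1", 0, 150, "E1"),
                ("chr1", 300, 700, "E4"),   # body-only overlap for gA
                ("chr1", 2000, 3000, "E13"),
            ],
            columns=["chrom", "start", "end", "state"],
        )
        anns = {a.gene_id: a for a in annotate_from_segmentation(genes, seg)}
        assert anns["gA"].exon_states == frozenset({1})
        assert anns["gA"].body_states == frozenset({1, 4})
        assert anns["gB"].body_states == frozenset({13})
        ref = build_reference_standard(list(anns.values()))
        assert dict(zip(ref["gene_id"], ref["label"])) == {
            "gA": "active", "gB": "inactive",
        }

    def test_gene_without_intervals_rejected(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "start": 10, "end": 10,
              "exon_starts": [], "exon_ends": []}]
        )
        with pytest.raises(AnnotationError):
            annotate_from_segmentation(genes, pd.DataFrame(
                [("chr1", 0, 5, "E1")],
                columns=["chrom", "start", "end", "state"],
            ))


REF8 = pd.DataFrame(
    {
        "gene_id": [f"g{i}" for i in range(8)],
        "label": ["active"] * 4 + ["inactive"] * 4,
    }
)


class TestEvaluatePerSample:
    def test_perfect_predictions(self):
        genes = REF8["gene_id"].tolist()
        calls = [
            call_set(s, genes, [1, 1, 1, 1, 0, 0, 0, 0]) for s in ("a", "b")
        ]
        report = evaluate_per_sample(calls, REF8)
        for metric, (mean, sd) in report.summary.items():
            assert mean == 1.0
            assert sd == 0.0

    def test_single_flip_confusion_arithmetic(self):
        genes = REF8["gene_id"].tolist()
        # one active called off, one inactive called on
        calls = [call_set("a", genes, [0, 1, 1, 1, 1, 0, 0, 0])]
        report = evaluate_per_sample(calls, REF8)
        row = report.per_sample.iloc[0]
        assert row["precision_expressed"] == 3 / 4
        assert row["recall_expressed"] == 3 / 4
        assert row["precision_non_expressed"] == 3 / 4
        assert row["recall_non_expressed"] == 3 / 4

    def test_mean_and_sample_sd(self):
        genes = REF8["gene_id"].tolist()
        calls = [
            # expressed precision 0.8: 4 of 5 predicted-expressed are active
            call_set("a", genes, [1, 1, 1, 1, 1, 0, 0, 0]),
            call_set("b", genes, [1, 1, 1, 1, 0, 0, 0, 0]),
        ]
        report = evaluate_per_sample(calls, REF8)
        mean, sd = report.summary["precision_expressed"]
        assert mean == pytest.approx(0.9)
        assert sd == pytest.approx(np.std([0.8, 1.0], ddof=1))

    def test_undefined_precision_excluded_with_count(self):
        genes = REF8["gene_id"].tolist()
        calls = [
            call_set("a", genes, [0] * 8),  # no predicted expressed
            call_set("b", genes, [1, 1, 1, 1, 0, 0, 0, 0]),
        ]
        report = evaluate_per_sample(calls, REF8)
        assert report.n_undefined["precision_expressed"] == 1
        mean, sd = report.summary["precision_expressed"]
        assert mean == 1.0 and sd == 0.0

    def test_ambiguous_genes_excluded(self):
        ref = pd.concat(
            [REF8, pd.DataFrame({"gene_id": ["g8"], "label": ["ambiguous"]})],
            ignore_index=True,
        )
        genes = ref["gene_id"].tolist()
        calls = [call_set("a", genes, [1, 1, 1, 1, 0, 0, 0, 0, 1])]
        report = evaluate_per_sample(calls, ref)
        assert report.summary["precision_expressed"][0] == 1.0

    def test_gene_and_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        genes = REF8["gene_id"].tolist()
        states = [list(rng.integers(0, 2, 8)) for _ in range(3)]
        calls = [call_set(f"s{i}", genes, st) for i, st in enumerate(states)]
        base = evaluate_per_sample(calls, REF8).summary
        perm = rng.permutation(8)
        calls_p = [
            call_set(f"s{i}", [genes[j] for j in perm],
                     [st[j] for j in perm])
            for i, st in enumerate(states)
        ]
        shuffled = evaluate_per_sample(calls_p[::-1], REF8).summary
        for k in base:
            assert base[k] == pytest.approx(shuffled[k])


def ratios_frame(gene_ids, ratios, tissue="liver"):
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "tissue": tissue,
            "m": 10,
            "non_expressed_ratio": ratios,
            "expressed_ratio": [1 - r for r in ratios],
        }
    )


class TestTissuePRCurve:
    def test_perfect_separation_gives_auprc_one(self):
        genes = [f"g{i}" for i in range(12)]
        ref = pd.DataFrame(
            {"gene_id": genes, "label": ["inactive"] * 6 + ["active"] * 6}
        )
        curve = tissue_pr_curve(
            ratios_frame(genes, [1.0] * 6 + [0.0] * 6), ref
        )
        assert curve.auprc == pytest.approx(1.0, abs=1e-12)
        assert curve.precision_at_09 == 1.0

    def test_constant_scores_give_prevalence_precision(self):
        genes = [f"g{i}" for i in range(12)]
        ref = pd.DataFrame(
            {"gene_id": genes, "label": ["inactive"] * 3 + ["active"] * 9}
        )
        curve = tissue_pr_curve(ratios_frame(genes, [0.4] * 12), ref)
        assert (curve.points["precision"] == 3 / 12).all()

    def test_six_gene_toy_matches_brute_force(self):
        # brute-force enumeration over all distinct thresholds, computed
        # independently of the implementation's vectorized path
        genes = [f"g{i}" for i in range(6)]
        scores = [1.0, 0.9, 0.8, 0.6, 0.3, 0.1]
        labels = ["inactive", "inactive", "active", "inactive", "active",
                  "active"]
        truth = [lab == "inactive" for lab in labels]
        pts = []
        for t in sorted(set(scores), reverse=True):
            pred = [s >= t for s in scores]
            tp = sum(p and tr for p, tr in zip(pred, truth))
            fp = sum(p and not tr for p, tr in zip(pred, truth))
            fn = sum((not p) and tr for p, tr in zip(pred, truth))
            pts.append((tp / (tp + fn), tp / (tp + fp)))
        # trapezoid with the (0, first precision) anchor
        recalls = [0.0] + [r for r, _ in pts]
        precs = [pts[0][1]] + [p for _, p in pts]
        expected = sum(
            0.5 * (precs[i] + precs[i + 1]) * (recalls[i + 1] - recalls[i])
            for i in range(len(pts))
        )
        ref = pd.DataFrame({"gene_id": genes, "label": labels})
        # pad with extra unambiguous genes to satisfy the >=10 overlap
        genes_pad = genes + [f"h{i}" for i in range(6)]
        scores_pad = scores + [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        ref_pad = pd.concat(
            [ref, pd.DataFrame({"gene_id": [f"h{i}" for i in range(6)],
                                "label": ["inactive"] * 3 + ["active"] * 3})],
            ignore_index=True,
        )
        curve6 = tissue_pr_curve(ratios_frame(genes_pad, scores_pad), ref_pad)
        # oracle for the padded problem, same enumeration
        truth_pad = truth + [True] * 3 + [False] * 3
        pts = []
        for t in sorted(set(scores_pad), reverse=True):
            pred = [s >= t for s in scores_pad]
            tp = sum(p and tr for p, tr in zip(pred, truth_pad))
            fp = sum(p and not tr for p, tr in zip(pred, truth_pad))
            fn = sum((not p) and tr for p, tr in zip(pred, truth_pad))
            pts.append((tp / (tp + fn), tp / (tp + fp)))
        recalls = [0.0] + [r for r, _ in pts]
        precs = [pts[0][1]] + [p for _, p in pts]
        expected_pad = sum(
            0.5 * (precs[i] + precs[i + 1]) * (recalls[i + 1] - recalls[i])
            for i in range(len(pts))
        )
        assert curve6.auprc == pytest.approx(expected_pad, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        scores = rng.random(40)
        labels = np.where(rng.random(40) < 0.5, "inactive", "active")
        ref = pd.DataFrame({"gene_id": genes, "label": labels})
        base = tissue_pr_curve(ratios_frame(genes, list(scores)), ref).auprc
        transformed = tissue_pr_curve(
            ratios_frame(genes, list(scores ** 3)), ref
        ).auprc
        assert base == pytest.approx(transformed, abs=1e-12)

    def test_recall_non_decreasing_along_sweep(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        scores = list(rng.random(30).round(2))
        labels = np.where(rng.random(30) < 0.4, "inactive", "active")
        ref = pd.DataFrame({"gene_id": genes, "label": labels})
        curve = tissue_pr_curve(ratios_frame(genes, scores), ref)
        rec = curve.points["recall"].to_numpy()
        assert np.all(np.diff(rec) >= 0)
        assert 0.0 <= curve.auprc <= 1.0

    def test_insufficient_overlap_rejected(self):
        genes = [f"g{i}" for i in range(6)]
        ref = pd.DataFrame({"gene_id": genes, "label": ["ambiguous"] * 6})
        with pytest.raises(EvaluationError):
            tissue_pr_curve(ratios_frame(genes, [0.5] * 6), ref)
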