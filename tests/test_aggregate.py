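"""Tissue aggregation, dormancy calling and TAA prediction."""

import numpy as np
import pandas as pd
import pytest

from statecall import (
    CohortStateMatrix,
    annotate_candidates,
    cutoff_sweep,
    identify_dormant_genes,
    patient_coverage,
    predict_taas,
    tissue_ratios,
)
from statecall.errors import (
    IncompleteAtlasError,
    MappingError,
    ParameterError,
    ShapeError,
)


def make_cohort(states: dict, tissue_of: dict) -> CohortStateMatrix:
    df = pd.DataFrame(states).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return CohortStateMatrix(
        states=df,
        tissue_of=pd.Series({f"s{i}": t for i, t in enumerate(tissue_of)}),
    )


def summaries_from(rows) -> pd.DataFrame:
    df = pd.DataFrame(
        rows, columns=["gene_id", "tissue", "non_expressed_ratio"]
    )
    df["m"] = 10
    df["expressed_ratio"] = 1.0 - df["non_expressed_ratio"]
    return df


class TestTissueRatios:
    @pytest.mark.parametrize(
        "states,expected_ne",
        [
            ([0] * 9 + [1], 0.9),
            ([1] * 10, 0.0),
            ([0, 0, 0, 1, 1, 1, 1], 3 / 7),
        ],
    )
    def test_hand_computed_fractions(self, states, expected_ne):
        cohort = make_cohort({"g1": states}, ["liver"] * len(states))
        out = tissue_ratios(cohort)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["m"] == len(states)
        m = len(states)
        assert row["non_expressed_ratio"] == expected_ne
        assert row["expressed_ratio"] == sum(states) / m
        assert abs(
            row["non_expressed_ratio"] + row["expressed_ratio"] - 1.0
        ) <= 1e-12

    def test_unknown_sample_label_rejected(self):
        df = pd.DataFrame({"s0": [0], "s1": [1]}, index=["g1"])
        with pytest.raises(MappingError, match="s1"):
            CohortStateMatrix(
                states=df, tissue_of=pd.Series({"s0": "liver"})
            )

    def test_non_binary_states_rejected(self):
        df = pd.DataFrame({"s0": [0.5]}, index=["g1"])
        with pytest.raises(ShapeError):
            CohortStateMatrix(states=df, tissue_of=pd.Series({"s0": "liver"}))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, size=(20, 12))
        df = pd.DataFrame(
            states, index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(12)],
        )
        tissue_of = pd.Series(
            ["liver"] * 6 + ["lung"] * 6, index=df.columns
        )
        base = tissue_ratios(CohortStateMatrix(df, tissue_of))
        perm = rng.permutation(df.columns)
        shuffled = tissue_ratios(CohortStateMatrix(df[perm], tissue_of[perm]))
        key = ["gene_id", "tissue"]
        pd.testing.assert_frame_equal(
            base.sort_values(key).reset_index(drop=True),
            shuffled.sort_values(key).reset_index(drop=True),
        )


class TestDormantGenes:
    def test_testis_exclusive_category(self):
        rows = [
            ("g1", "liver", 1.0), ("g1", "lung", 0.95), ("g1", "testis", 0.0),
        ]
        out = identify_dormant_genes(summaries_from(rows))
        assert list(out["gene_id"]) == ["g1"]
        assert out.iloc[0]["category"] == "testis_exclusive"
        assert out.iloc[0]["testis_expressed_ratio"] == 1.0

    def test_silent_everywhere_category(self):
        rows = [
            ("g1", "liver", 1.0), ("g1", "lung", 1.0), ("g1", "testis", 1.0),
        ]
        out = identify_dormant_genes(summaries_from(rows))
        assert out.iloc[0]["category"] == "silent_everywhere"

    def test_testis_cutoff_is_strict(self):
        # expressed ratio exactly 0.10 is NOT testis-exclusive (> rule)
        rows = [("g1", "liver", 0.95), ("g1", "testis", 0.90)]
        out = identify_dormant_genes(summaries_from(rows))
        assert out.iloc[0]["category"] == "silent_everywhere"
        rows = [("g1", "liver", 0.95), ("g1", "testis", 0.89)]
        out = identify_dormant_genes(summaries_from(rows))
        assert out.iloc[0]["category"] == "testis_exclusive"

    def test_boundary_inclusive_at_090(self):
        rows = [("g1", "liver", 0.9), ("g1", "lung", 1.0)]
        out = identify_dormant_genes(summaries_from(rows))
        assert list(out["gene_id"]) == ["g1"]
        rows = [("g1", "liver", 0.89), ("g1", "lung", 1.0)]
        out = identify_dormant_genes(summaries_from(rows))
        assert out.empty

    def test_missing_tissue_summary_named(self):
        rows = [
            ("g1", "liver", 1.0), ("g1", "lung", 1.0),
            ("g2", "liver", 1.0),
        ]
        with pytest.raises(IncompleteAtlasError, match="g2.*lung"):
            identify_dormant_genes(summaries_from(rows))

    def test_no_testis_in_atlas_degrades_gracefully(self):
        rows = [("g1", "liver", 1.0), ("g1", "lung", 0.92)]
        out = identify_dormant_genes(summaries_from(rows))
        assert out.iloc[0]["category"] == "silent_everywhere"
        assert np.isnan(out.iloc[0]["testis_expressed_ratio"])

    def test_nesting_across_cutoffs(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"g{i}", t, round(float(rng.uniform(0.7, 1.0)), 3))
            for i in range(50)
            for t in ("liver", "lung", "brain")
        ]
        s = summaries_from(rows)
        sets = {
            c: set(identify_dormant_genes(s, ratio_cutoff=c)["gene_id"])
            for c in (0.95, 0.90, 0.80)
        }
        assert sets[0.95] <= sets[0.90] <= sets[0.80]


DORMANT = pd.DataFrame(
    {"gene_id": ["d1", "d2"], "category": ["testis_exclusive"] * 2}
)


class TestPredictTaas:
    def test_boundary_at_five_percent(self):
        states = {
            "d1": [1] * 5 + [0] * 95,   # exactly 5% -> candidate
            "d2": [1] * 4 + [0] * 96,   # 4% -> excluded
            "o1": [1] * 50 + [0] * 50,  # not dormant -> excluded
        }
        cohort = make_cohort(states, ["LIHC"] * 100)
        out = predict_taas(cohort, DORMANT, expressed_cutoff=0.05)
        assert list(out["gene_id"]) == ["d1"]
        assert out.iloc[0]["tumor_expressed_ratio"] == 0.05
        assert out.iloc[0]["expressed_sample_ids"] == [f"s{i}" for i in range(5)]

    def test_cutoff_domain(self):
        cohort = make_cohort({"d1": [1, 0]}, ["LIHC"] * 2)
        with pytest.raises(ParameterError):
            predict_taas(cohort, DORMANT, expressed_cutoff=0.0)
        with pytest.raises(ParameterError):
            predict_taas(cohort, DORMANT, expressed_cutoff=1.5)
        with pytest.raises(ParameterError):
            predict_taas(cohort, DORMANT.iloc[:0], expressed_cutoff=0.05)

    def test_per_cohort_separation(self):
        states = {"d1": [1, 1, 0, 0], "d2": [0, 0, 1, 1]}
        cohort = make_cohort(states, ["A", "A", "B", "B"])
        out = predict_taas(cohort, DORMANT, expressed_cutoff=0.5)
        got = set(zip(out["cancer_type"], out["gene_id"]))
        assert got == {("A", "d1"), ("B", "d2")}

    def test_patient_coverage_is_union_over_candidates(self):
        states = {"d1": [1, 1, 0, 0, 0], "d2": [0, 1, 1, 0, 0]}
        cohort = make_cohort(states, ["A"] * 5)
        cands = predict_taas(cohort, DORMANT, expressed_cutoff=0.05)
        cov = patient_coverage(cands, cohort)
        assert cov.iloc[0]["n_covered"] == 3
        assert cov.iloc[0]["coverage"] == 3 / 5


class TestAnnotateAndSweep:
    def test_membership_flags(self):
        cands = pd.DataFrame(
            {"gene_id": ["d1", "d2"], "cancer_type": ["A", "A"],
             "tumor_expressed_ratio": [0.2, 0.1],
             "expressed_sample_ids": [["s0"], ["s1"]]}
        )
        out = annotate_candidates(
            cands, membrane=["d1"], cta=["d1", "d2"], testis_specific=["d2"]
        )
        assert out["membrane"].tolist() == [True, False]
        assert out["known_CTA"].tolist() == [True, True]
        assert out["testis_specific"].tolist() == [False, True]
        empty = annotate_candidates(cands)
        assert not empty[["membrane", "known_CTA", "testis_specific"]].any().any()

    def test_sweep_counts_non_increasing(self):
        rng = np.random.default_rng(1)
        states = {
            f"d{i}": list(rng.integers(0, 2, size=40)) for i in range(30)
        }
        cohort = make_cohort(states, ["A"] * 40)
        dormant = pd.DataFrame({"gene_id": list(states)})
        table = cutoff_sweep(cohort, dormant, [0.01, 0.05, 0.5, 1.0])
        counts = table["candidate_count"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_sweep_parameter_validation(self):
        cohort = make_cohort({"d1": [1, 0]}, ["A"] * 2)
        dormant = pd.DataFrame({"gene_id": ["d1"]})
        with pytest.raises(ParameterError):
            cutoff_sweep(cohort, dormant, [0.5, 0.1])
        with pytest.raises(ParameterError):
            cutoff_sweep(cohort, dormant, [0.0, 0.5])

    def test_sweep_at_cutoff_one(self):
        cohort = make_cohort({"d1": [1, 0], "d2": [1, 1]}, ["A"] * 2)
        dormant = pd.DataFrame({"gene_id": ["d1", "d2"]})
        table = cutoff_sweep(cohort, dormant, [1.0])
        assert table["candidate_count"].tolist() == [1]
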