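"""Cohort summaries: frequencies, categories, carrier groups, census, sample size."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mlpacnv import datasets
from mlpacnv.cohort import (
    CATEGORY_BY_CLASS_SET,
    GENOTYPE_ORDER,
    allele_frequencies,
    assign_categories,
    carrier_groups,
    categorize_individual,
    gene_cnv_census,
    genotype_frequencies,
    round_half_up,
    sample_size,
)
from mlpacnv.simulate import calls_from_truth, simulate_from_genotype_table

LABEL_TO_CLASS = {
    "Del/Del": "HOM_DEL",
    "Del/Wt": "HET_DEL",
    "Wt/Wt": "NORMAL",
    "Dup/Wt": "HET_DUP",
    "Dup/Dup": "HOM_DUP",
}


def _calls(rows):
    """rows: (sample_id, gene, genotype_label) -> calls-shaped frame."""
    return pd.DataFrame(
        [
            {
                "sample_id": s,
                "gene": g,
                "cnv_class": LABEL_TO_CLASS.get(l, "AMBIGUOUS"),
                "genotype_label": l,
                "discordant": False,
                "n_probes_called": 1,
            }
            for s, g, l in rows
        ]
    )


@pytest.fixture(scope="module")
def reconstructed_calls():
    """Per-sample calls drawn deterministically from the published cohort table."""
    truth = simulate_from_genotype_table(
        datasets.cohort_genotype_percent(), n=datasets.COHORT_N, exact=True
    )
    return calls_from_truth(truth)


class TestGenotypeFrequencies:
    def test_published_gstm1_fractions(self, reconstructed_calls):
        gt = genotype_frequencies(reconstructed_calls)
        got = gt.percent(1)["GSTM1"]
        assert got["Del/Del"] == 44.7
        assert got["Del/Wt"] == 5.7
        assert got["Wt/Wt"] == 33.3
        assert got["Dup/Wt"] == 1.6
        assert got["Dup/Dup"] == 14.6
        assert gt.n_called["GSTM1"] == 123

    def test_all_wild_type(self):
        gt = genotype_frequencies(_calls([(f"S{i}", "CYP1A2", "Wt/Wt") for i in range(5)]))
        frac = gt.fractions["CYP1A2"]
        assert frac["Wt/Wt"] == 1.0 and frac.drop("Wt/Wt").eq(0).all()

    def test_single_sample(self):
        gt = genotype_frequencies(_calls([("S1", "GSTM1", "Del/Del")]))
        assert gt.fractions["GSTM1"]["Del/Del"] == 1.0

    def test_unknown_excluded_from_both_sides(self):
        gt = genotype_frequencies(
            _calls([("S1", "GSTM1", "Del/Del"), ("S2", "GSTM1", "Unknown")])
        )
        assert gt.n_called["GSTM1"] == 1
        assert gt.n_excluded["GSTM1"] == 1
        assert gt.fractions["GSTM1"]["Del/Del"] == 1.0

    def test_fractions_sum_to_one_per_gene(self, reconstructed_calls):
        gt = genotype_frequencies(reconstructed_calls)
        assert np.allclose(gt.fractions.sum(axis=0), 1.0, atol=1e-9)

    def test_sample_order_permutation_invariance(self, reconstructed_calls):
        shuffled = reconstructed_calls.sample(frac=1.0, random_state=1)
        a = genotype_frequencies(reconstructed_calls).fractions
        b = genotype_frequencies(shuffled).fractions
        pd.testing.assert_frame_equal(a, b[a.columns])


class TestAlleleFrequencies:
    def test_published_gstm1_column(self, reconstructed_calls):
        af = allele_frequencies(genotype_frequencies(reconstructed_calls))
        col = (af["GSTM1"] * 100).map(lambda v: round_half_up(v, 1))
        assert col["Deletion"] == 47.6
        assert col["Duplication"] == 15.4
        assert col["No CNV"] == 37.0

    def test_published_gstt1_column(self, reconstructed_calls):
        af = allele_frequencies(genotype_frequencies(reconstructed_calls))
        col = (af["GSTT1"] * 100).map(lambda v: round_half_up(v, 1))
        assert col["Deletion"] == 27.2
        assert col["Duplication"] == 17.5

    def test_full_table_matches_published_at_one_decimal(self, reconstructed_calls):
        af = allele_frequencies(genotype_frequencies(reconstructed_calls))
        got = (af * 100).map(lambda v: round_half_up(v, 1))
        expected = datasets.cohort_allele_percent()
        pd.testing.assert_frame_equal(
            got[expected.columns], expected, check_dtype=False
        )

    def test_columns_sum_to_one(self, reconstructed_calls):
        af = allele_frequencies(genotype_frequencies(reconstructed_calls))
        assert np.allclose(af.sum(axis=0), 1.0, atol=1e-9)

    def test_all_wild_type(self):
        af = allele_frequencies(
            genotype_frequencies(_calls([("S1", "CYP1A2", "Wt/Wt")]))
        )
        assert af["CYP1A2"].tolist() == [0.0, 0.0, 1.0]


class TestCategories:
    @pytest.mark.parametrize(
        "class_set,category",
        [
            (frozenset(), 1),
            (frozenset({"HOM_DEL"}), 2),
            (frozenset({"HET_DEL"}), 3),
            (frozenset({"HET_DEL", "HOM_DEL"}), 4),
            (frozenset({"HOM_DUP"}), 5),
            (frozenset({"HET_DUP"}), 6),
            (frozenset({"HET_DUP", "HOM_DEL"}), 8),
            (frozenset({"HOM_DUP", "HET_DEL"}), 9),
            (frozenset({"HOM_DUP", "HOM_DEL"}), 10),
            (frozenset({"HOM_DUP", "HET_DUP"}), 11),
            (frozenset({"HET_DUP", "HOM_DEL", "HET_DEL"}), 12),
            (frozenset({"HET_DEL", "HET_DUP", "HOM_DUP"}), 13),
            (frozenset({"HET_DUP", "HOM_DUP", "HOM_DEL"}), 14),
            # combinations with no defined category -> 0
            (frozenset({"HET_DEL", "HET_DUP"}), 0),
            (frozenset({"HOM_DUP", "HOM_DEL", "HET_DEL"}), 0),
            (frozenset({"HOM_DUP", "HOM_DEL", "HET_DEL", "HET_DUP"}), 0),
        ],
    )
    def test_category_mapping(self, class_set, category):
        assert categorize_individual(class_set) == category

    def test_every_class_subset_gets_exactly_one_category(self):
        classes = ("HOM_DEL", "HET_DEL", "HOM_DUP", "HET_DUP")
        seen = []
        for r in range(5):
            for combo in itertools.combinations(classes, r):
                seen.append(categorize_individual(frozenset(combo)))
        assert len(seen) == 16
        assert all(0 <= c <= 14 for c in seen)
        # category 7 is textually indistinguishable from 4 and unreachable
        assert 7 not in seen
        assert 7 not in CATEGORY_BY_CLASS_SET.values()

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            categorize_individual({"NORMAL"})

    def test_assignment_is_a_partition(self, reconstructed_calls):
        cats = assign_categories(reconstructed_calls)
        assert len(cats) == cats["sample_id"].nunique() == 123
        assert cats["category"].between(0, 14).all()


class TestCarrierGroups:
    def test_examples(self):
        calls = _calls(
            [
                ("S1", "GSTM1", "Del/Wt"),
                ("S1", "CYP2D6", "Wt/Wt"),
                ("S2", "GSTM1", "Dup/Dup"),
                ("S2", "CYP2D6", "Del/Del"),
                ("S3", "GSTM1", "Wt/Wt"),
                ("S3", "CYP2D6", "Wt/Wt"),
                ("S4", "GSTM1", "Dup/Wt"),
                ("S4", "CYP2D6", "Wt/Wt"),
            ]
        )
        per_sample, fracs = carrier_groups(calls)
        groups = per_sample.set_index("sample_id")["group"]
        assert groups["S1"] == "deletions_only"
        assert groups["S2"] == "both"
        assert groups["S3"] == "none"
        assert groups["S4"] == "duplications_only"
        assert abs(sum(fracs.values()) - 1.0) < 1e-12

    def test_none_fraction_equals_wild_type_category(self, reconstructed_calls):
        _, fracs = carrier_groups(reconstructed_calls)
        cats = assign_categories(reconstructed_calls)
        cat1 = (cats["category"] == 1).mean()
        assert fracs["none"] == pytest.approx(cat1)


class TestGeneCnvCensus:
    def test_published_census(self, reconstructed_calls):
        census = gene_cnv_census(genotype_frequencies(reconstructed_calls))
        assert census["n_genes"] == 14
        assert census["pct_with_any"] == 92.9
        assert census["n_with_both"] == 5
        assert census["pct_with_both"] == 35.7
        assert census["n_with_either"] == 8
        assert census["pct_with_either"] == 57.1
        assert census["genes_with_both"] == [
            "CYP2A6",
            "CYP2C9",
            "CYP2D6",
            "GSTM1",
            "GSTT1",
        ]
        assert census["genes_without_cnv"] == ["CYP1A2"]

    def test_all_wild_type_cohort(self):
        calls = _calls(
            [(f"S{i}", g, "Wt/Wt") for i in range(4) for g in ("GSTM1", "GSTT1")]
        )
        census = gene_cnv_census(genotype_frequencies(calls))
        assert census["n_with_any"] == 0
        assert census["pct_with_any"] == 0.0


class TestSampleSize:
    def test_survey_design_value(self):
        assert sample_size(p=0.03, e=0.03, z=1.96) == 125

    def test_textbook_half_proportion(self):
        # ceil(1.96^2 * 0.25 / 0.05^2) = ceil(384.16)
        assert sample_size(p=0.5, e=0.05, z=1.96) == 385

    @pytest.mark.parametrize("N", [50, 125, 1000, 10**6])
    def test_finite_population_correction_never_increases_n(self, N):
        n0 = sample_size(p=0.03, e=0.03)
        assert sample_size(p=0.03, e=0.03, N=N) <= n0

    @given(st.floats(0.01, 0.99), st.floats(0.005, 0.2))
    def test_positive_and_monotone_in_margin(self, p, e):
        n = sample_size(p=p, e=e)
        assert n >= 1
        assert sample_size(p=p, e=e / 2) >= n

    @pytest.mark.parametrize("kw", [{"p": 0.0}, {"p": 1.0}, {"e": 0.0}, {"z": -1.0}])
    def test_invalid_spec_rejected(self, kw):
        spec = {"p": 0.03, "e": 0.03, "z": 1.96, **kw}
        with pytest.raises(ValueError):
            sample_size(**spec)
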