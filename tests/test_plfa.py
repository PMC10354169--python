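"""PLFA quantification, grouping, relative abundance and allocation."""
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cryotrace import (
    label_allocation,
    load_marker_table,
    quantify_markers,
    relative_abundance,
    total_plfa,
)
from cryotrace.errors import DomainError, QuantificationError
from cryotrace.plfa import INTERNAL_STANDARD, PRIMARY_GROUPS, is_unsaturated


@pytest.fixture(scope="module")
def table():
    return load_marker_table()


class TestMarkerTable:
    def test_primary_partition_is_disjoint_and_exhaustive(self, table):
        assert set(table["primary_group"]) <= set(PRIMARY_GROUPS)
        assert table["primary_group"].notna().all()

    def test_published_group_memberships(self, table):
        assert set(table.index[table["fungal"]]) == {"18:1ω9cis", "18:2ω6,9"}
        assert set(table.index[table["gram_positive"]]) == {
            "a15:0", "i16:0", "16:1ω7", "10Me16:0", "a17:0", "cy17:0", "10Me18:0",
        }
        assert set(table.index[table["bacterial"]]) == {"16:1ω7", "cy17:0", "cy19:0"}
        # the disjoint allocation partition merges the overlapping lists
        bacterial = set(table.index[table["primary_group"] == "bacterial"])
        assert bacterial == {
            "a15:0", "i16:0", "16:1ω7", "10Me16:0", "a17:0", "cy17:0",
            "10Me18:0", "cy19:0",
        }

    def test_saturation_classifier_matches_table(self, table):
        for marker, row in table.iterrows():
            assert is_unsaturated(marker) == row["unsaturated"]

    @pytest.mark.parametrize(
        "marker,expected",
        [("16:1ω7", True), ("18:2ω6,9", True), ("cy19:0", False), ("10Me16:0", False)],
    )
    def test_cyclopropane_and_methyl_are_saturated(self, marker, expected):
        assert is_unsaturated(marker) is expected


class TestQuantification:
    def test_identity_response(self):
        amounts = quantify_markers(pd.Series({"16:0": 1000.0}), 1000.0, 5.0, 1.0)
        assert amounts["16:0"] == pytest.approx(5.0)

    def test_all_zero_areas_give_empty_amounts(self):
        amounts = quantify_markers(pd.Series({"16:0": 0.0, "17:0": 0.0}), 1000.0, 5.0, 1.0)
        assert (amounts == 0).all()

    def test_linearity_in_areas(self):
        areas = pd.Series({"16:0": 500.0, "17:0": 250.0})
        a1 = quantify_markers(areas, 1000.0, 5.0, 1.0)
        a2 = quantify_markers(2 * areas, 1000.0, 5.0, 1.0)
        assert a2.values == pytest.approx(2 * a1.values)

    def test_internal_standard_excluded(self):
        areas = pd.Series({"16:0": 500.0, INTERNAL_STANDARD: 1000.0})
        amounts = quantify_markers(areas, 1000.0, 5.0, 1.0)
        assert INTERNAL_STANDARD not in amounts.index

    def test_missing_internal_standard_rejected(self):
        with pytest.raises(QuantificationError):
            quantify_markers(pd.Series({"16:0": 500.0}), 0.0, 5.0, 1.0)


class TestRelativeAbundance:
    def test_two_marker_fractions(self):
        rel = relative_abundance(pd.Series({"16:0": 3.0, "17:0": 1.0}))
        assert rel["16:0"] == pytest.approx(0.75)
        assert rel["17:0"] == pytest.approx(0.25)

    def test_single_marker(self):
        assert relative_abundance(pd.Series({"16:0": 4.2}))["16:0"] == 1.0

    def test_permutation_invariance(self):
        a = pd.Series({"16:0": 3.0, "17:0": 1.0, "15:0": 2.0})
        rel1 = relative_abundance(a)
        rel2 = relative_abundance(a.iloc[::-1])
        assert (rel1.sort_index() == rel2.sort_index()).all()

    def test_all_zero_profile_rejected(self):
        with pytest.raises(DomainError):
            relative_abundance(pd.Series({"16:0": 0.0}))

    @given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=10))
    def test_simplex_valued(self, values):
        amounts = pd.Series(values, index=[f"m{i}:0" for i in range(len(values))])
        rel = relative_abundance(amounts)
        assert rel.sum() == pytest.approx(1.0, abs=1e-12)
        assert ((rel >= 0) & (rel <= 1)).all()

    def test_invariant_to_internal_standard_amount(self):
        areas = pd.Series({"16:0": 500.0, "17:0": 250.0})
        rel1 = relative_abundance(quantify_markers(areas, 1000.0, 5.0, 1.0))
        rel2 = relative_abundance(quantify_markers(areas, 1000.0, 50.0, 1.0))
        assert rel1.values == pytest.approx(rel2.values)


class TestLabelAllocation:
    def _ap(self, f):
        return 1.08 + f * (10.0 - 1.08)

    def test_all_label_in_fungal_markers(self, table):
        amounts = pd.Series({"18:1ω9cis": 10.0, "16:0": 10.0})
        ap = pd.Series({"18:1ω9cis": self._ap(0.2), "16:0": self._ap(0.0)})
        alloc = label_allocation(amounts, ap, 1.08, table=table)
        assert alloc["fungal"] == pytest.approx(1.0)
        assert alloc["bacterial"] == 0.0

    def test_saturation_symmetry(self, table):
        # equal label-C in one saturated and one unsaturated marker
        amounts = pd.Series({"16:0": 10.0, "16:1ω7": 10.0})
        ap = pd.Series({"16:0": self._ap(0.1), "16:1ω7": self._ap(0.1)})
        alloc = label_allocation(amounts, ap, 1.08, table=table, grouping="saturation")
        assert alloc["saturated"] == pytest.approx(0.5)
        assert alloc["unsaturated"] == pytest.approx(0.5)

    def test_no_label_is_undefined(self, table):
        amounts = pd.Series({"16:0": 10.0})
        ap = pd.Series({"16:0": 1.08})
        assert label_allocation(amounts, ap, 1.08, table=table) is None

    def test_both_groupings_sum_to_one(self, table, zero_noise_experiment):
        plfa = zero_noise_experiment.tables["plfa"]
        grp = plfa[plfa["amendment"] == "glucose"].groupby("sample_id")
        for _, sub in list(grp)[:4]:
            sub = sub.set_index("marker")
            amounts = sub["area"] / 1e6 * 100.0 / sub["dry_soil_g"]
            for grouping in ("primary_groups", "saturation"):
                alloc = label_allocation(
                    amounts, sub["c13_at_percent"], 1.08, table=table, grouping=grouping
                )
                assert alloc.sum() == pytest.approx(1.0, abs=1e-9)
                assert ((alloc >= 0) & (alloc <= 1)).all()


class TestTotalPlfa:
    def test_sum_and_zero_marker_invariance(self):
        amounts = pd.Series({"a": 10.0, "b": 20.0, "c": 30.0})
        assert total_plfa(amounts) == pytest.approx(60.0)
        amounts["d"] = 0.0
        assert total_plfa(amounts) == pytest.approx(60.0)

    def test_published_site_totals_ratio(self):
        from cryotrace import reference_site_summary

        ref = reference_site_summary().set_index("parameter")
        ratio = (
            ref.loc["total_plfa", "forest_mean"]
            / ref.loc["total_plfa", "agricultural_mean"]
        )
        assert round(ratio, 1) == 13.6
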