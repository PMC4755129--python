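import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biodisagg.regions import UnitLevel
from biodisagg.species import (
    ASSESSED_CATEGORIES,
    MissingAssessmentError,
    category_counts,
    filter_occurrences,
    species_endemic,
    species_occurring,
    tabulate_units,
    threat_bounds,
)
from biodisagg.synth import WorldSpec, generate_world

# ---------------------------------------------------------------------------
# independent brute-force oracle: re-derives occurrence/endemism/counts from
# first principles with plain nested loops, no calls into the module under test

EXCLUDED = {"vagrant", "uncertain", "introduced"}


def brute_force_table(scheme, level, assessments, occurrences, mode):
    occ_units = {}
    for r in occurrences.itertuples():
        if r.origin not in EXCLUDED:
            occ_units.setdefault(r.species_id, set()).add(r.unit_code)
    cat = dict(zip(assessments.species_id, assessments.category))
    grp = dict(zip(assessments.species_id, assessments.group))
    groups = list(dict.fromkeys(assessments.group))
    rows = []
    for unit in scheme.units(level):
        members = (
            {unit} if unit in scheme.special_units else set(scheme.members(unit, level))
        )
        if mode == "occurring":
            chosen = {s for s, us in occ_units.items() if us & members}
        else:
            chosen = {s for s, us in occ_units.items() if us and us <= members}
            if unit == "ABNJ":
                chosen = set()
        for g in ["all"] + groups:
            sub = chosen if g == "all" else {s for s in chosen if grp[s] == g}
            counts = {}
            for s in sub:
                counts[cat[s]] = counts.get(cat[s], 0) + 1
            total = sum(counts.get(c, 0) for c in ASSESSED_CATEGORIES)
            rows.append({"unit": unit, "group": g, "total": total, **counts})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


class TestThreatBounds:
    def test_printed_formulas_hand_fixture(self):
        # 10 species: threatened=3, DD=1, EX=1 =>
        # lower 3/9, best 3/8, upper 4/9
        counts = {"CR": 1, "EN": 1, "VU": 1, "DD": 1, "LC": 5, "EX": 1}
        lower, best, upper = threat_bounds(counts)
        assert lower == pytest.approx(100 * 3 / 9)
        assert best == pytest.approx(37.5)
        assert upper == pytest.approx(100 * 4 / 9)

    def test_no_dd_collapses_bounds(self):
        counts = {"CR": 2, "EN": 1, "LC": 7}
        lower, best, upper = threat_bounds(counts)
        assert lower == best == upper == pytest.approx(30.0)

    def test_all_extinct_undefined(self):
        assert threat_bounds({"EX": 4}) == (None, None, None)

    def test_ew_stays_in_denominator(self):
        # 1 threatened of (assessed 4 - EX 1) = 3 extant incl. EW
        counts = {"VU": 1, "EW": 1, "LC": 1, "EX": 1}
        lower, _, _ = threat_bounds(counts)
        assert lower == pytest.approx(100 / 3)

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=8, max_size=8)
    )
    def test_ordering_property(self, vec):
        counts = dict(zip(("EX", "EW", "CR", "EN", "VU", "NT", "LC", "DD"), vec))
        lower, best, upper = threat_bounds(counts)
        for v in (lower, best, upper):
            assert v is None or 0.0 <= v <= 100.0
        if None not in (lower, best, upper):
            assert lower <= best + 1e-12
            assert best <= upper + 1e-12


class TestOccurrenceAndEndemism:
    def occ(self, *rows):
        return pd.DataFrame(rows, columns=["species_id", "unit_code", "origin"])

    def test_native_in_one_member_country(self, geo):
        occ = self.occ(("S", "AFG", "native"))
        assert "S" in species_occurring(occ, geo, "Asia+Pacific", "region")

    def test_vagrant_only_never_occurs(self, geo):
        occ = self.occ(("S", "AFG", "vagrant"), ("S", "IND", "vagrant"))
        assert species_occurring(occ, geo, "Asia+Pacific", "region") == set()

    def test_empty_records(self, geo):
        assert species_occurring(self.occ(), geo, "Europe", "region") == set()

    def test_endemic_to_subregion(self, geo):
        occ = self.occ(("S", "AFG", "native"), ("S", "IND", "native"))
        assert "S" in species_endemic(occ, geo, "South Asia", "subregion")
        assert species_endemic(occ, geo, "South East Asia", "subregion") == set()
        assert species_occurring(occ, geo, "South East Asia", "subregion") == set()

    def test_introduced_record_does_not_break_endemism(self, geo):
        occ = self.occ(("S", "AFG", "native"), ("S", "FRA", "introduced"))
        assert "S" in species_endemic(occ, geo, "Asia+Pacific", "region")

    def test_abnj_endemism_rejected(self, geo, caplog):
        occ = self.occ(("S", "ABNJ", "native"))
        with caplog.at_level("WARNING"):
            assert species_endemic(occ, geo, "ABNJ", "region") == set()
        assert "ABNJ" in caplog.text

    def test_unknown_origin_defaults_native_with_warning(self, caplog):
        occ = self.occ(("S", "AFG", "Seasonal non-breeding"))
        with caplog.at_level("WARNING"):
            kept = filter_occurrences(occ)
        assert len(kept) == 1
        assert "unknown origin" in caplog.text

    def test_origin_alias_normalization(self, geo):
        occ = self.occ(("S", "AFG", "Origin Uncertain"))
        assert species_occurring(occ, geo, "Asia+Pacific", "region") == set()


class TestCategoryCounts:
    def test_direct_count(self):
        assess = pd.DataFrame(
            {
                "species_id": ["a", "b", "c"],
                "group": ["g"] * 3,
                "category": ["CR", "LC", "DD"],
            }
        )
        counts = category_counts({"a", "b", "c"}, assess)
        assert counts["CR"] == counts["LC"] == counts["DD"] == 1
        assert sum(counts.values()) == 3

    def test_empty_set(self):
        assess = pd.DataFrame(columns=["species_id", "group", "category"])
        assert all(v == 0 for v in category_counts(set(), assess).values())

    def test_missing_assessment_raises(self):
        assess = pd.DataFrame(
            {"species_id": ["a"], "group": ["g"], "category": ["LC"]}
        )
        with pytest.raises(MissingAssessmentError, match="b"):
            category_counts({"a", "b"}, assess)


class TestTabulation:
    def test_matches_brute_force_on_synthetic_world(self, world):
        scheme = world.schemes["GEO"]
        for level in ("region", "subregion"):
            for mode in ("occurring", "endemic"):
                got = tabulate_units(
                    scheme, level, world.assessments, world.occurrences, mode
                )
                want = brute_force_table(
                    scheme, level, world.assessments, world.occurrences, mode
                )
                m = got.merge(want, on=["unit", "group"], suffixes=("", "_bf"))
                assert len(m) == len(got)
                assert (m["total"] == m["total_bf"]).all()
                for c in ("CR", "LC", "DD", "EX"):
                    bf = m[c + "_bf"] if c + "_bf" in m else pd.Series(0, index=m.index)
                    assert (m[c] == bf.fillna(0).astype(int)).all()

    def test_endemic_counts_bounded_by_occurring(self, world):
        scheme = world.schemes["IPBES"]
        occ = tabulate_units(
            scheme, "region", world.assessments, world.occurrences, "occurring"
        )
        end = tabulate_units(
            scheme, "region", world.assessments, world.occurrences, "endemic"
        )
        m = occ.merge(end, on=["unit", "group"], suffixes=("_o", "_e"))
        assert (m["total_e"] <= m["total_o"]).all()

    def test_each_species_endemic_to_at_most_one_unit(self, world):
        scheme = world.schemes["GEO"]
        total_endemics = 0
        for unit in scheme.units("region"):
            total_endemics += len(
                species_endemic(world.occurrences, scheme, unit, "region")
            )
        assert total_endemics <= world.assessments.species_id.nunique()

    def test_permutation_invariance(self, world):
        scheme = world.schemes["GEO"]
        shuffled = world.occurrences.sample(frac=1.0, random_state=3).reset_index(
            drop=True
        )
        a = tabulate_units(scheme, "region", world.assessments, shuffled, "occurring")
        b = tabulate_units(
            scheme, "region", world.assessments, world.occurrences, "occurring"
        )
        pd.testing.assert_frame_equal(a, b)

    def test_matches_generator_truth_exactly(self, world):
        for (sname, level, mode), want in world.truth.species_tables.items():
            got = tabulate_units(
                world.schemes[sname], level, world.assessments, world.occurrences, mode
            )
            m = got.merge(want, on=["unit", "level", "group"], suffixes=("", "_t"))
            assert len(m) == len(got) == len(want)
            for c in ("EX", "EW", "CR", "EN", "VU", "NT", "LC", "DD", "total"):
                assert (m[c] == m[c + "_t"]).all(), (sname, level, mode, c)
            for c in ("pct_lower", "pct_best", "pct_upper"):
                np.testing.assert_allclose(
                    m[c].astype(float), m[c + "_t"].astype(float), atol=1e-9
                )

    def test_subregion_endemic_is_region_endemic(self, world):
        """A species endemic to a subregion is endemic to its parent region."""
        scheme = world.schemes["GEO"]
        for sub in scheme.units(UnitLevel.SUBREGION, include_special=False):
            parent = scheme.region_of_subregion(sub)
            sub_end = species_endemic(world.occurrences, scheme, sub, "subregion")
            reg_end = species_endemic(world.occurrences, scheme, parent, "region")
            assert sub_end <= reg_end
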