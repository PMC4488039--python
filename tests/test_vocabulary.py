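"""Controlled vocabulary, unit conversion, and harmonization."""

import numpy as np
import pandas as pd
import pytest

from limnodb.models import Observation, Provenance
from limnodb.vocabulary import (
    AggregatedDataError,
    DimensionError,
    MappingError,
    SourceMapping,
    UnitRegistry,
    VocabularyError,
    apply_detection_limit_policy,
    convert_units,
    harmonize_table,
    load_vocabulary,
    normalize_term,
)


class TestVocabulary:
    def test_packaged_vocabulary_has_seventeen_wq_variables_plus_depth(self, vocab):
        assert len(vocab.water_quality_variables) == 17
        assert len(vocab.depth_variables) >= 1
        categories = {v.category for v in vocab.water_quality_variables}
        assert {"nutrient", "clarity", "chlorophyll", "carbon"} <= categories

    def test_threshold_ordering_holds_for_every_variable(self, vocab):
        for v in vocab.variables.values():
            assert v.valid_min <= v.valid_max <= v.egregious_max

    def test_case_folded_terms_resolve_to_one_canonical(self, vocab):
        assert vocab.resolve("tp") == vocab.resolve("TP") == "total_phosphorus"
        assert vocab.resolve("Tot. Phosphorus") == "total_phosphorus"
        assert normalize_term("NO3-NO2") == "no3 no2"

    def test_synonym_bound_to_two_canonicals_is_rejected(self, tmp_path):
        doc = """
variables:
  - {canonical_name: a, long_name: A, canonical_units: m, category: clarity,
     valid_min: 0, valid_max: 1, egregious_max: 2, synonyms: [total phos]}
  - {canonical_name: b, long_name: B, canonical_units: m, category: clarity,
     valid_min: 0, valid_max: 1, egregious_max: 2, synonyms: [total phos]}
units:
  - {symbol: m, dimension: length, factor: 1.0}
"""
        p = tmp_path / "v.yaml"
        p.write_text(doc)
        with pytest.raises(VocabularyError, match="total phos"):
            load_vocabulary(p)

    def test_duplicate_canonical_after_casefold_is_rejected(self, tmp_path):
        doc = """
variables:
  - {canonical_name: tp, long_name: A, canonical_units: m, category: clarity,
     valid_min: 0, valid_max: 1, egregious_max: 2}
  - {canonical_name: TP, long_name: B, canonical_units: m, category: clarity,
     valid_min: 0, valid_max: 1, egregious_max: 2}
units:
  - {symbol: m, dimension: length, factor: 1.0}
"""
        p = tmp_path / "v.yaml"
        p.write_text(doc)
        with pytest.raises(VocabularyError):
            load_vocabulary(p)


class TestUnits:
    @pytest.mark.parametrize(
        "value,src,dst,expected",
        [
            (3.7, "µg/L", "µg/L", 3.7),          # identity, exact
            (1.0, "mg/L", "µg/L", 1000.0),       # SI prefix
            (2.5, "µmol P/L", "µg P/L", 77.425),  # 2.5 x 30.97 (P molar mass)
            (10.0, "ft", "m", 3.048),
        ],
    )
    def test_conversions(self, vocab, value, src, dst, expected):
        got = convert_units(value, src, dst, vocab.units)
        if src == dst:
            assert got == expected  # identity must be exact
        else:
            assert got == pytest.approx(expected, rel=1e-12)

    def test_incompatible_dimensions_raise(self, vocab):
        with pytest.raises(DimensionError):
            convert_units(1.0, "m", "µg/L", vocab.units)

    def test_composition_and_identity_properties(self, vocab, rng):
        units = ["ug/L", "mg/L", "g/L", "umol P/L"]
        for _ in range(50):
            x = float(rng.uniform(0.001, 1e4))
            a, b, c = rng.choice(units, size=3)
            ab_c = vocab.units.convert(vocab.units.convert(x, a, b), b, c)
            a_c = vocab.units.convert(x, a, c)
            assert ab_c == pytest.approx(a_c, rel=1e-9)
            assert vocab.units.convert(x, a, a) == x

    def test_nonpositive_factor_rejected(self):
        reg = UnitRegistry()
        with pytest.raises(VocabularyError):
            reg.register("bad", "length", -1.0)


def _wide_mapping(**kw):
    base = dict(
        source_id="s1",
        orientation="wide",
        site_id_column="site",
        date_column="date",
        date_format="%Y-%m-%d",
        variable_columns={
            "TP mg/L": {"variable": "total_phosphorus", "unit": "mg/L"},
            "secchi m": {"variable": "secchi_depth", "unit": "m"},
        },
    )
    base.update(kw)
    return SourceMapping(**base)


class TestHarmonize:
    def test_empty_table_yields_nothing(self, vocab):
        table = pd.DataFrame(columns=["site", "date", "TP mg/L", "secchi m"])
        obs, issues = harmonize_table(table, _wide_mapping(), vocab)
        assert obs == [] and issues == []

    def test_two_row_wide_table_transposes_and_converts(self, vocab):
        table = pd.DataFrame(
            {
                "site": ["A", "B"],
                "date": ["2010-06-01", "2010-06-02"],
                "TP mg/L": ["0.012", "0.030"],
                "secchi m": ["2.5", "1.1"],
            }
        )
        obs, issues = harmonize_table(table, _wide_mapping(), vocab)
        assert len(obs) == 4 and not issues
        tp = {o.site_ref: o.value for o in obs if o.variable == "total_phosphorus"}
        # hand conversion: mg/L -> ug/L multiplies by 1000
        assert tp == {"A": pytest.approx(12.0), "B": pytest.approx(30.0)}
        secchi = [o for o in obs if o.variable == "secchi_depth"]
        assert all(o.value in (2.5, 1.1) for o in secchi)

    def test_below_detection_convention_translates(self, vocab):
        table = pd.DataFrame(
            {
                "lake": ["L1"],
                "date": ["2011-07-04"],
                "param": ["tp"],
                "reading": ["<0.005"],
                "units": ["mg/L"],
            }
        )
        mapping = SourceMapping(
            source_id="s2", orientation="long", site_id_column="lake",
            date_column="date", variable_name_column="param",
            value_column="reading", unit_column="units",
            censor_conventions={"<": "below_detection"},
        )
        obs, issues = harmonize_table(table, mapping, vocab)
        assert len(obs) == 1 and not issues
        o = obs[0]
        assert o.censor_code == "below_detection"
        assert o.value is None
        assert o.detection_limit == pytest.approx(5.0)  # 0.005 mg/L in ug/L

    def test_aggregated_source_is_refused(self, vocab):
        with pytest.raises(AggregatedDataError, match="minimum dataset"):
            harmonize_table(
                pd.DataFrame({"site": [], "date": []}),
                _wide_mapping(aggregated=True),
                vocab,
            )

    def test_unknown_variable_term_becomes_issue_not_observation(self, vocab):
        table = pd.DataFrame(
            {
                "lake": ["L1", "L1"],
                "date": ["2011-07-04", "2011-07-05"],
                "param": ["tp", "mystery analyte"],
                "reading": ["12", "7"],
            }
        )
        mapping = SourceMapping(
            source_id="s2", orientation="long", site_id_column="lake",
            date_column="date", variable_name_column="param",
            value_column="reading",
        )
        obs, issues = harmonize_table(table, mapping, vocab)
        assert len(obs) == 1
        assert len(issues) == 1 and "mystery analyte" in issues[0]["reason"]

    def test_mapping_referencing_absent_column_is_refused(self, vocab):
        table = pd.DataFrame({"site": ["A"], "date": ["2010-06-01"]})
        with pytest.raises(MappingError, match="absent columns"):
            harmonize_table(table, _wide_mapping(), vocab)

    def test_unparseable_values_are_issues_never_coerced(self, vocab):
        table = pd.DataFrame(
            {
                "site": ["A", "B"],
                "date": ["2010-06-01", "not-a-date"],
                "TP mg/L": ["oops", "0.02"],
                "secchi m": ["2.0", None],
            }
        )
        obs, issues = harmonize_table(table, _wide_mapping(), vocab)
        # row A: TP unparseable (issue), secchi fine; row B: bad date -> issue
        assert len(obs) == 1 and obs[0].variable == "secchi_depth"
        reasons = sorted(i["reason"] for i in issues)
        assert reasons == ["bad_date", "unparseable_value"]

    def test_cell_conservation_on_wide_tables(self, vocab, rng):
        """observations + cell issues == non-null bound value cells."""
        n = 40
        cells = []
        for col in ["TP mg/L", "secchi m"]:
            vals = []
            for _ in range(n):
                r = rng.random()
                if r < 0.15:
                    vals.append(None)
                elif r < 0.3:
                    vals.append("junk")
                else:
                    vals.append(f"{rng.uniform(0.01, 2):.3f}")
            cells.append(vals)
        table = pd.DataFrame(
            {
                "site": [f"S{i}" for i in range(n)],
                "date": ["2010-06-01"] * n,
                "TP mg/L": cells[0],
                "secchi m": cells[1],
            }
        )
        obs, issues = harmonize_table(table, _wide_mapping(), vocab)
        non_null = int(table[["TP mg/L", "secchi m"]].notna().sum().sum())
        cell_issues = sum(1 for i in issues if i["cell_attributable"])
        assert len(obs) + cell_issues == non_null

    def test_harmonization_deterministic_under_row_permutation(self, vocab, rng):
        table = pd.DataFrame(
            {
                "site": [f"S{i}" for i in range(10)],
                "date": ["2010-06-01"] * 10,
                "TP mg/L": [f"{v:.3f}" for v in rng.uniform(0.01, 1, 10)],
                "secchi m": [f"{v:.2f}" for v in rng.uniform(0.5, 8, 10)],
            }
        )
        obs1, _ = harmonize_table(table, _wide_mapping(), vocab)
        perm = rng.permutation(10)
        shuffled = table.iloc[perm].reset_index(drop=True)
        obs2, _ = harmonize_table(shuffled, _wide_mapping(), vocab)
        key = lambda o: (o.site_ref, o.variable)
        vals1 = {key(o): o.value for o in obs1}
        vals2 = {key(o): o.value for o in obs2}
        assert vals1 == vals2

    def test_provenance_round_trip(self, vocab):
        table = pd.DataFrame(
            {
                "site": ["A", "B"],
                "date": ["2010-06-01", "2010-06-02"],
                "TP mg/L": ["0.012", "0.030"],
                "secchi m": ["2.5", "1.1"],
            }
        )
        obs, _ = harmonize_table(table, _wide_mapping(), vocab)
        for o in obs:
            p = o.provenance
            cell = table.iloc[int(p.source_row_ref)][p.source_column_ref]
            assert p.original_value_text == str(cell)


class TestDetectionLimitPolicy:
    def _censored(self):
        return Observation(
            variable="total_phosphorus", value=None, sample_date="2010-06-01",
            censor_code="below_detection", detection_limit=0.005,
            provenance=Provenance("s", "0", "c", "<0.005", "mg/L"),
        )

    def test_uncensored_passes_through(self, vocab):
        o = Observation(
            variable="total_phosphorus", value=5.0, sample_date="2010-06-01",
            provenance=Provenance("s", "0", "c", "5", "ug/L"),
        )
        out, flag = apply_detection_limit_policy(o, "retain")
        assert out is o and flag is None

    def test_retain_policy_keeps_limit_without_value(self):
        out, flag = apply_detection_limit_policy(self._censored(), "retain")
        assert out.value is None and out.detection_limit == 0.005
        assert flag is None

    def test_half_limit_policy_substitutes_and_flags(self):
        out, flag = apply_detection_limit_policy(self._censored(), "half_limit")
        assert out.value == pytest.approx(0.0025)  # limit / 2
        assert flag is not None and flag.disposition == "flagged"

    def test_substitution_without_limit_errors(self):
        o = Observation(
            variable="tp", value=1.0, sample_date="2010-06-01",
            censor_code="above_detection",
            provenance=Provenance("s", "0", "c", ">1", "ug/L"),
        )
        with pytest.raises(ValueError):
            apply_detection_limit_policy(o, "half_limit")
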