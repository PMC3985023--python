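"""E.C. parsing, wildcard expansion, status filtering and descriptor translation."""

import pytest

from ppma import ec_translate as ect
from ppma.ec_translate import (
    DescriptorMapping,
    ECNumber,
    ECParseError,
    expand_and_filter,
    parse_ec,
    parse_ec_list,
    parse_ec_table,
    translate,
)
from ppma.synthetic_fixtures import mapping_to_flatfiles


@pytest.mark.parametrize(
    "token,expected",
    [
        ("1.1.1.*", ECNumber(1, 1, 1, None)),
        ("1.3.1.26", ECNumber(1, 3, 1, 26)),
        ("7.2.4.3", ECNumber(7, 2, 4, 3)),
        ("1.1.1.n5", ECNumber(1, 1, 1, 5, preliminary=True)),
    ],
)
def test_parse_valid_tokens(token, expected):
    assert parse_ec(token) == expected
    assert str(expected) == token


@pytest.mark.parametrize(
    "token", ["1.*.1.1", "*.1.1.1", "1.1.*.2", "1.1.1", "1.1.1.1.1", "a.1.1.1", "8.1.1.1"]
)
def test_parse_rejects_malformed_tokens(token):
    with pytest.raises(ECParseError):
        parse_ec(token)


def test_parse_error_names_line_number():
    with pytest.raises(ECParseError, match="line 3"):
        parse_ec_list("1.1.1.1\n# comment\n1.*.1.1\n")


def test_parse_list_preserves_order_duplicates_and_groups():
    pairs = parse_ec_table("1.1.1.1\tADH\n1.1.1.1\tADH\n2.7.7.7\n")
    assert [str(e) for e, _ in pairs] == ["1.1.1.1", "1.1.1.1", "2.7.7.7"]
    assert [g for _, g in pairs] == ["ADH", "ADH", None]


@pytest.fixture()
def small_mapping():
    m = DescriptorMapping(low_specificity_ids=("PS00198",))
    m.add_enzyme_record(ECNumber(1, 1, 1, 1), "active", ("PS00001", "PS00198"))
    m.add_go(ECNumber(1, 1, 1, 1), ["GO:0000001", "GO:0000002"])
    m.add_enzyme_record(ECNumber(1, 1, 1, 2), "active", ("PS00002",))
    m.add_go(ECNumber(1, 1, 1, 2), ["GO:0000002"])
    m.add_enzyme_record(ECNumber(1, 1, 1, 3), "transferred")
    m.add_enzyme_record(ECNumber(1, 1, 2, 1), "deleted")
    return m


class TestExpandAndFilter:
    def test_dedup_preserves_first_occurrence(self, small_mapping):
        res = expand_and_filter(parse_ec_list("1.1.1.1\n1.1.1.1\n"), small_mapping)
        assert [str(e) for e in res.nonredundant_ecs] == ["1.1.1.1"]

    def test_wildcard_expansion_covers_concrete_members(self, small_mapping):
        res = expand_and_filter([ECNumber(1, 1, 1, None)], small_mapping)
        expanded = set(res.nonredundant_ecs) | set(
            ECNumber(e.ec_class, e.subclass, e.subsubclass, e.serial)
            for e in res.dropped_by_status
        )
        concrete = expand_and_filter([ECNumber(1, 1, 1, 1)], small_mapping)
        assert set(concrete.nonredundant_ecs) <= expanded

    def test_empty_wildcard_expansion_warns(self, small_mapping):
        with pytest.warns(UserWarning, match="matches no entry"):
            res = expand_and_filter([ECNumber(7, 9, 9, None)], small_mapping)
        assert res.nonredundant_ecs == ()

    def test_status_filter_moves_inactive_entries(self, small_mapping):
        res = expand_and_filter(
            parse_ec_list("1.1.1.1\n1.1.1.3\n1.1.2.1\n"), small_mapping
        )
        assert {str(e) for e in res.dropped_by_status} == {"1.1.1.3", "1.1.2.1"}
        assert {e.status for e in res.dropped_by_status} == {"transferred", "deleted"}
        assert set(res.nonredundant_ecs).isdisjoint(res.dropped_by_status)

    def test_preliminary_entries_dropped_from_n_suffix(self, small_mapping):
        res = expand_and_filter([ECNumber(1, 1, 1, 9, preliminary=True)], small_mapping)
        assert res.nonredundant_ecs == ()
        assert res.dropped_by_status[0].status == "preliminary"

    def test_unmapped_concrete_ec_is_recorded_not_an_error(self, small_mapping):
        res = expand_and_filter([ECNumber(6, 6, 6, 6)], small_mapping)
        assert res.unmapped == res.nonredundant_ecs

    def test_idempotent(self, small_mapping):
        once = expand_and_filter(parse_ec_list("1.1.1.*\n1.1.1.1\n"), small_mapping)
        twice = expand_and_filter(list(once.nonredundant_ecs), small_mapping)
        assert twice.nonredundant_ecs == once.nonredundant_ecs


class TestTranslate:
    def test_union_and_low_specificity_removal(self, small_mapping):
        res = expand_and_filter(parse_ec_list("1.1.1.1\n1.1.1.2\n"), small_mapping)
        res = translate(res, small_mapping)
        assert res.go_profile == ("GO:0000001", "GO:0000002")  # shared term once
        assert res.prosite_pattern_list == ("PS00001", "PS00002")
        assert res.dropped_low_specificity == ("PS00198",)

    def test_empty_input_gives_empty_lists(self, small_mapping):
        res = translate(expand_and_filter([], small_mapping), small_mapping)
        assert res.go_profile == () and res.prosite_pattern_list == ()

    def test_supplemental_descriptors_appended(self, small_mapping):
        res = expand_and_filter([ECNumber(1, 1, 1, 1)], small_mapping)
        res = translate(res, small_mapping, supplemental_go=["GO:0099999"])
        assert res.go_profile[-1] == "GO:0099999"


class TestTranslationReplay:
    """Stepwise translation arithmetic of the study's worked conversion table."""

    def test_stepwise_counts(self, translation_fx):
        pairs = parse_ec_table(translation_fx.ec_list_text)
        res = expand_and_filter(
            [e for e, _ in pairs], translation_fx.mapping, [g for _, g in pairs]
        )
        res = translate(
            res,
            translation_fx.mapping,
            translation_fx.supplemental_go,
            translation_fx.supplemental_prosite,
            translation_fx.supplemental_group,
        )
        man = translation_fx.manifest
        assert res.input_count == man["ec_total"] == 2576
        assert (
            len(res.nonredundant_ecs) + len(res.dropped_by_status)
            == man["ec_nonredundant"]
            == 433
        )
        assert len(res.nonredundant_ecs) == man["ec_surviving"] == 264
        assert len(res.go_profile) == man["go_terms"] == 171
        assert len(res.prosite_pattern_list) == man["prosite_ids"] == 49
        assert len(res.dropped_low_specificity) == 3

    def test_per_group_counts_match_manifest_rows(self, translation_fx):
        from ppma.synthetic_fixtures import TRANSLATION_ROWS

        pairs = parse_ec_table(translation_fx.ec_list_text)
        res = expand_and_filter(
            [e for e, _ in pairs], translation_fx.mapping, [g for _, g in pairs]
        )
        res = translate(
            res,
            translation_fx.mapping,
            translation_fx.supplemental_go,
            translation_fx.supplemental_prosite,
            translation_fx.supplemental_group,
        )
        by_group = res.per_group_counts.set_index("group")
        for name, total, nr, surviving, n_go, n_ps in TRANSLATION_ROWS:
            row = by_group.loc[name]
            assert (row.total, row.nonredundant, row.surviving) == (total, nr, surviving)
            assert (row.go_terms, row.prosite_ids) == (n_go, n_ps)

    def test_flatfile_dialect_round_trip(self, translation_fx, tmp_path):
        enzyme_text, ec2go_text = mapping_to_flatfiles(translation_fx.mapping)
        (tmp_path / "enzyme.dat").write_text(enzyme_text)
        (tmp_path / "ec2go.txt").write_text(ec2go_text)
        reloaded = DescriptorMapping.from_files(
            tmp_path / "enzyme.dat",
            tmp_path / "ec2go.txt",
            low_specificity=translation_fx.mapping.low_specificity_ids,
        )
        pairs = parse_ec_table(translation_fx.ec_list_text)
        for mapping in (translation_fx.mapping, reloaded):
            res = translate(
                expand_and_filter([e for e, _ in pairs], mapping),
                mapping,
            )
            assert len(res.go_profile) == 169  # without the supplemental pair
            assert len(res.prosite_pattern_list) == 48


def test_emit_and_load_round_trip(small_mapping, tmp_path):
    res = expand_and_filter(parse_ec_list("1.1.1.1\n1.1.1.2\n"), small_mapping)
    res = translate(res, small_mapping)
    profile, pattern = ect.emit_filter_lists(res, tmp_path)
    assert ect.load_filter_list(profile) == ("go_term", res.go_profile)
    assert ect.load_filter_list(pattern) == ("prosite_id", res.prosite_pattern_list)


def test_emit_empty_result_round_trips(small_mapping, tmp_path):
    res = translate(expand_and_filter([], small_mapping), small_mapping)
    profile, pattern = ect.emit_filter_lists(res, tmp_path)
    assert ect.load_filter_list(profile) == ("go_term", ())
    assert ect.load_filter_list(pattern) == ("prosite_id", ())
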