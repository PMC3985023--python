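"""Descriptor filters, de-duplication, set building/ranking and condensation."""

import json

import numpy as np
import pytest

from ppma.gene_store import GeneCollection, GeneRecord, gene_fragment_filter
from ppma.ppm_core import (
    Hit,
    build_ppm_sets,
    condense_meta_sets,
    dedupe_hits,
    filter_hits,
    load_family_map,
    pattern_filter,
    profile_filter,
    report,
)
from ppma.synthetic_fixtures import make_random_collection, make_replay_collection


def gene(gid, go=(), ps=(), nt=600, complete=True):
    return GeneRecord(
        gene_id=gid, nt_length=nt, complete=complete,
        go_terms=frozenset(go), prosite_ids=frozenset(ps),
    )


class TestFilters:
    def test_gene_matching_k_terms_yields_k_hits(self):
        c = GeneCollection([gene("g", go=["GO:0004665", "GO:0008977"])])
        hits = profile_filter(c, ["GO:0004665", "GO:0008977", "GO:0000001"])
        assert len(hits) == 2

    def test_annotation_mode_pattern_pairs(self):
        c = GeneCollection([gene("g", ps=["PS00136", "PS00137"])])
        assert len(pattern_filter(c, ["PS00136", "PS00137"])) == 2

    def test_no_overlap_is_empty(self):
        c = GeneCollection([gene("g", go=["GO:0000009"])])
        assert profile_filter(c, ["GO:0000001"]) == []
        assert profile_filter(c, []) == []

    def test_scan_mode_equals_annotation_mode_on_planted_fixture(self):
        from ppma.synthetic_fixtures import make_planted_proteins
        from ppma.prosite_engine import parse_pattern

        collection, _ = make_planted_proteins(
            ["H-x(3)-H", "W-x(2)-[DE]"],
            n_genes=30,
            plant_plan={"H-x(3)-H": 6, "W-x(2)-[DE]": 4},
            seed=21,
        )
        ids = ["PLANT01", "PLANT02"]
        patterns = [
            parse_pattern("H-x(3)-H", "PLANT01"),
            parse_pattern("W-x(2)-[DE]", "PLANT02"),
        ]
        scan = pattern_filter(collection, ids, mode="scan", patterns=patterns)
        annot = pattern_filter(collection, ids, mode="annotation")
        assert sorted((h.gene_id, h.descriptor_id) for h in scan) == sorted(
            (h.gene_id, h.descriptor_id) for h in annot
        )

    def test_scan_mode_without_sequences_lists_missing_genes(self):
        c = GeneCollection([gene("naked", ps=["PS00001"])])
        with pytest.raises(ValueError, match="naked"):
            pattern_filter(c, ["PS00001"], mode="scan", patterns=[])


class TestDedupe:
    def test_multiset_collapses_to_combined_combo(self):
        hits = [
            Hit("g", "GO:0000001", "profile"),
            Hit("g", "PS00001", "pattern"),
            Hit("g", "GO:0000001", "profile"),
            Hit("g", "GO:0000002", "profile"),
        ]
        deduped = dedupe_hits(hits)
        assert deduped == {"g": (("GO:0000001", "GO:0000002"), ("PS00001",))}

    def test_brute_force_grouping_oracle(self):
        rng = np.random.default_rng(5)
        hits = [
            Hit(f"g{rng.integers(0, 20)}", f"GO:00000{rng.integers(10, 30)}", "profile")
            for _ in range(300)
        ]
        deduped = dedupe_hits(hits)
        # naive recount
        expected: dict[str, set[str]] = {}
        for h in hits:
            expected.setdefault(h.gene_id, set()).add(h.descriptor_id)
        assert {g: set(go) for g, (go, _) in deduped.items()} == expected

    def test_pattern_trajectory_on_replay_fixture(self, replay):
        filtered = gene_fragment_filter(replay.collection)
        kept = filter_hits(replay.pattern_hits, filtered)
        assert (len(replay.pattern_hits), len(kept)) == (1617, 1078)
        assert len(dedupe_hits(kept)) == 142


class TestBuildSets:
    def test_single_gene_with_both_kinds_is_reliable_pp_set(self):
        sets = build_ppm_sets({"g": (("GO:0000001",), ("PS00001",))})
        (s,) = sets
        assert s.ppm_class == "profile_and_pattern"
        assert s.reliable and s.set_id == "PP 1"

    def test_class_partition_and_counting_identity(self):
        c, go_pool, ps_pool = make_random_collection(seed=3, n_genes=60)
        hits = profile_filter(c, go_pool) + pattern_filter(c, ps_pool)
        deduped = dedupe_hits(hits)
        sets = build_ppm_sets(deduped)
        all_members = [g for s in sets for g in s.members]
        assert sorted(all_members) == sorted(deduped)  # partition, no duplicates
        assert len(hits) >= len(deduped)
        for s in sets:
            has_go, has_ps = bool(s.go_combo), bool(s.prosite_combo)
            expected = (
                "profile_and_pattern" if has_go and has_ps
                else "profile" if has_go else "pattern"
            )
            assert s.ppm_class == expected

    def test_rank_is_monotone_in_descriptor_count(self):
        c, go_pool, ps_pool = make_random_collection(seed=9, n_genes=80)
        sets = build_ppm_sets(
            dedupe_hits(profile_filter(c, go_pool) + pattern_filter(c, ps_pool))
        )
        for earlier, later in zip(sets, sets[1:]):
            assert earlier.n_descriptors >= later.n_descriptors

    def test_input_permutation_leaves_sets_unchanged(self):
        c, go_pool, ps_pool = make_random_collection(seed=13, n_genes=40)
        hits = profile_filter(c, go_pool) + pattern_filter(c, ps_pool)
        rng = np.random.default_rng(1)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        a = build_ppm_sets(dedupe_hits(hits))
        b = build_ppm_sets(dedupe_hits(shuffled))
        assert [(s.set_id, s.go_combo, s.prosite_combo, s.members) for s in a] == [
            (s.set_id, s.go_combo, s.prosite_combo, s.members) for s in b
        ]

    def test_replay_set_structure(self, replay):
        filtered = gene_fragment_filter(replay.collection)
        hits = filter_hits(replay.profile_hits + replay.pattern_hits, filtered)
        sets = build_ppm_sets(dedupe_hits(hits))
        by_class = {}
        for s in sets:
            by_class.setdefault(s.ppm_class, []).append(s)
        assert len(by_class["profile"]) == 5
        assert len(by_class["pattern"]) == 17
        (pp,) = by_class["profile_and_pattern"]
        assert pp.go_combo == ("GO:0008839",)
        assert pp.prosite_combo == ("PS01298",)
        assert len(pp.members) == 14
        profile_genes = sum(len(s.members) for s in by_class["profile"])
        assert profile_genes == 92


class TestCondense:
    def test_identity_map_keeps_sets_apart(self):
        sets = build_ppm_sets(
            {"a": (("GO:0000001",), ()), "b": (("GO:0000002",), ())}
        )
        metas = condense_meta_sets(sets, {})
        assert len(metas) == 2

    def test_subtilisin_style_merge_unions_members(self, replay):
        filtered = gene_fragment_filter(replay.collection)
        sets = build_ppm_sets(
            dedupe_hits(filter_hits(replay.pattern_hits, filtered))
        )
        subtilase = [
            s for s in sets
            if set(s.prosite_combo) in ({"PS00136", "PS00137"},
                                        {"PS00136", "PS00138"},
                                        {"PS00137", "PS00138"})
        ]
        metas = condense_meta_sets(subtilase, replay.family_map)
        (m,) = metas
        assert len(m.members) == 2 + 4 + 1
        assert len(m.member_sets) == 3

    def test_replay_reliable_sets_condense_to_nine_families(self, replay):
        filtered = gene_fragment_filter(replay.collection)
        sets = build_ppm_sets(
            dedupe_hits(filter_hits(replay.profile_hits + replay.pattern_hits, filtered))
        )
        reliable = [s for s in sets if s.reliable]
        assert len(reliable) == 12
        metas = condense_meta_sets(reliable, replay.family_map)
        assert len(metas) == 9
        assert sum(len(m.members) for m in metas) == 117


class TestReport:
    def test_report_counts_and_json_tsv_consistency(self, replay, tmp_path):
        import pandas as pd

        filtered = gene_fragment_filter(replay.collection)
        sets = build_ppm_sets(
            dedupe_hits(filter_hits(replay.profile_hits + replay.pattern_hits, filtered))
        )
        metas = condense_meta_sets([s for s in sets if s.reliable], replay.family_map)
        summary = report(sets, metas, tmp_path)
        assert summary["n_reliable_genes"] == 117
        tsv = pd.read_csv(tmp_path / "sets.tsv", sep="\t")
        payload = json.loads((tmp_path / "sets.json").read_text())
        assert len(tsv) == len(payload["sets"]) == summary["n_sets"]
        assert tsv["n_members"].sum() == summary["n_genes"]
        members = pd.read_csv(tmp_path / "members.tsv", sep="\t")
        assert len(members) == summary["n_genes"]

    def test_empty_input_gives_header_only_report(self, tmp_path):
        summary = report([], [], tmp_path)
        assert summary["n_sets"] == 0
        assert (tmp_path / "sets.tsv").read_text().startswith("set_id\t")


def test_family_map_round_trip(tmp_path, replay):
    path = tmp_path / "fam.tsv"
    lines = ["combo\tfamily"] + [
        f"{combo}\t{label}" for combo, label in replay.family_map.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    assert load_family_map(path) == replay.family_map


def test_fragment_filter_commutes_with_descriptor_filters():
    for seed in range(20):
        c, go_pool, ps_pool = make_random_collection(seed=seed, n_genes=50)
        filtered = gene_fragment_filter(c)
        before = filter_hits(profile_filter(c, go_pool), filtered)
        after = profile_filter(filtered, go_pool)
        assert before == after
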