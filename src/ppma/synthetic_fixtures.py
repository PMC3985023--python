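"""Seeded generators for every test surface of the pipeline.

All fixtures are synthetic: gene collections shaped like an annotated SAG
(single amplified genome) database, descriptor mapping tables replaying the
study-scale translation arithmetic, proteins with planted pattern
occurrences, planted-cluster alignments, and the gamma-carbonic-anhydrase
derivation scenario.  A fixture's seed fully determines its output; changing
the seed changes identifiers and background residues but never the counts a
test asserts on.

The replay fixture deserves a note: warehouse exports list the same
gene–descriptor evidence repeatedly (one row per annotation source), so the
generator emits *raw hit tables with duplicate multiplicities* alongside the
gene collection; the recorded trajectory is raw hits → hits on complete
genes → non-redundant genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .ec_translate import DescriptorMapping, ECNumber
from .gene_store import GeneCollection, GeneRecord
from .ppm_core import Hit
from .pattern_derivation import DerivationSpec, FunctionalPosition
from .prosite_engine import AA20, PrositePattern, match, parse_pattern

__all__ = [
    "ReplayFixture",
    "TranslationFixture",
    "GammaCAFixture",
    "make_replay_collection",
    "make_translation_fixture",
    "make_planted_proteins",
    "make_cluster_alignment",
    "make_gamma_ca_fixture",
    "make_random_collection",
]

_AA_LIST = sorted(AA20)

# ---------------------------------------------------------------------------
# the study-scale worked example (descriptor combinations and member counts)

PROFILE_COMBOS: tuple[tuple[tuple[str, ...], int], ...] = (
    (("GO:0008839",), 3),
    (("GO:0009326",), 25),
    (("GO:0018492",), 17),
    (("GO:0043115",), 31),
    (("GO:0004665", "GO:0008977"), 16),
)

PATTERN_COMBOS: tuple[tuple[tuple[str, ...], int], ...] = (
    (("PS00059",), 15),
    (("PS00061",), 3),
    (("PS00136",), 3),
    (("PS00137",), 1),
    (("PS00138",), 2),
    (("PS00141",), 11),
    (("PS00501",), 6),
    (("PS00060", "PS00913"), 4),
    (("PS00062", "PS00063", "PS00798"), 19),
    (("PS00065", "PS00670", "PS00671"), 27),
    (("PS00381", "PS00382"), 2),
    (("PS00490", "PS00551", "PS00932"), 11),
    (("PS00090", "PS00699"), 10),
    (("PS00692", "PS00746"), 7),
    (("PS00136", "PS00137"), 2),
    (("PS00136", "PS00138"), 4),
    (("PS00137", "PS00138"), 1),
)

PP_COMBOS: tuple[tuple[tuple[str, ...], tuple[str, ...], int], ...] = (
    (("GO:0008839",), ("PS01298",), 14),
)

#: Curated enzyme-family labels for every multi-descriptor combination.
FAMILY_MAP: dict[str, str] = {
    "GO:0004665;GO:0008977": "Prephenate DH [1.3.1.13]",
    "PS00060;PS00913": "Fe-ADH [1.1.1.1]",
    "PS00062;PS00063;PS00798": "dkgA [1.1.1.274]",
    "PS00065;PS00670;PS00671": "Glyoxylate reductase [1.1.1.26]",
    "PS00381;PS00382": "Clp protease [3.4.21.92]",
    "PS00490;PS00551;PS00932": "Molybdopterin OR [1.2.2.1]",
    "PS00090;PS00699": "Nitrogenase [1.18.6.1]",
    "PS00692;PS00746": "Nitrogenase [1.18.6.1]",
    "PS00136;PS00137": "Subtilisin [3.4.21.*]",
    "PS00136;PS00138": "Subtilisin [3.4.21.*]",
    "PS00137;PS00138": "Subtilisin [3.4.21.*]",
    "GO:0008839;PS01298": "DHPR [1.3.1.26]",
}

#: Raw-export trajectory targets: (raw hits, hits on complete genes).
PROFILE_TRAJECTORY = (520, 352)
PATTERN_TRAJECTORY = (1617, 1078)

_SAGS = ("AtlantisII_SAG01", "Discovery_SAG07", "Kebrit_SAG03")
_TAXA = ("MSBL1", "MBGE", "UMSBL6")


@dataclass
class ReplayFixture:
    collection: GeneCollection
    profile_hits: list[Hit]
    pattern_hits: list[Hit]
    go_profile: tuple[str, ...]
    prosite_list: tuple[str, ...]
    family_map: dict[str, str]
    manifest: dict


def _duplicate(hits: list[Hit], extra: int) -> list[Hit]:
    """Append *extra* duplicate rows, round-robin over the distinct pairs."""
    out = list(hits)
    for i in range(extra):
        out.append(hits[i % len(hits)])
    return out


def make_replay_collection(seed: int = 0) -> ReplayFixture:
    """Gene collection and raw hit tables replaying the worked example.

    Complete genes carry exactly the descriptor combinations of the
    published set table; additional fragmentary genes (short or incomplete)
    carry one descriptor each, and duplicate evidence rows inflate the raw
    hit tables so the full trajectory — 520→352→106 profile hits and
    1617→1078→142 pattern hits — is reproduced from generated data.
    """
    rng = np.random.default_rng(seed)
    tag = rng.integers(0, 10**6)
    genes: list[GeneRecord] = []
    counter = 0

    def new_gene(
        go: tuple[str, ...] = (),
        ps: tuple[str, ...] = (),
        complete: bool = True,
        nt: Optional[int] = None,
    ) -> GeneRecord:
        nonlocal counter
        counter += 1
        g = GeneRecord(
            gene_id=f"g{tag:06d}_{counter:05d}",
            genome_id=_SAGS[counter % len(_SAGS)],
            taxon=_TAXA[counter % len(_TAXA)],
            nt_length=nt if nt is not None else int(rng.integers(350, 2000)),
            complete=complete,
            product="hypothetical protein",
            go_terms=frozenset(go),
            prosite_ids=frozenset(ps),
        )
        genes.append(g)
        return g

    profile_pairs: list[Hit] = []
    pattern_pairs: list[Hit] = []

    for combo, count in PROFILE_COMBOS:
        for _ in range(count):
            g = new_gene(go=combo)
            profile_pairs.extend(Hit(g.gene_id, go, "profile") for go in combo)
    for combo, count in PATTERN_COMBOS:
        for _ in range(count):
            g = new_gene(ps=combo)
            pattern_pairs.extend(Hit(g.gene_id, ps, "pattern") for ps in combo)
    for go_combo, ps_combo, count in PP_COMBOS:
        for _ in range(count):
            g = new_gene(go=go_combo, ps=ps_combo)
            profile_pairs.extend(Hit(g.gene_id, go, "profile") for go in go_combo)
            pattern_pairs.extend(Hit(g.gene_id, ps, "pattern") for ps in ps_combo)

    go_profile = tuple(
        dict.fromkeys(
            [g for combo, _ in PROFILE_COMBOS for g in combo]
            + [g for go_combo, _, _ in PP_COMBOS for g in go_combo]
        )
    )
    prosite_list = tuple(
        dict.fromkeys(
            [p for combo, _ in PATTERN_COMBOS for p in combo]
            + [p for _, ps_combo, _ in PP_COMBOS for p in ps_combo]
        )
    )

    profile_hits = _duplicate(
        profile_pairs, PROFILE_TRAJECTORY[1] - len(profile_pairs)
    )
    pattern_hits = _duplicate(
        pattern_pairs, PATTERN_TRAJECTORY[1] - len(pattern_pairs)
    )

    # fragmentary genes contribute the raw-minus-complete remainder, one hit each
    n_frag_profile = PROFILE_TRAJECTORY[0] - PROFILE_TRAJECTORY[1]
    n_frag_pattern = PATTERN_TRAJECTORY[0] - PATTERN_TRAJECTORY[1]
    for i in range(n_frag_profile):
        short = i % 2 == 0  # short fragments vs. full-length but incomplete genes
        g = new_gene(
            go=(go_profile[i % len(go_profile)],),
            complete=short,
            nt=int(rng.integers(60, 300)) if short else None,
        )
        profile_hits.append(Hit(g.gene_id, go_profile[i % len(go_profile)], "profile"))
    for i in range(n_frag_pattern):
        short = i % 2 == 0
        g = new_gene(
            ps=(prosite_list[i % len(prosite_list)],),
            complete=short,
            nt=int(rng.integers(60, 300)) if short else None,
        )
        pattern_hits.append(Hit(g.gene_id, prosite_list[i % len(prosite_list)], "pattern"))

    n_profile_nr = sum(c for _, c in PROFILE_COMBOS) + sum(c for *_, c in PP_COMBOS)
    n_pattern_nr = sum(c for _, c in PATTERN_COMBOS) + sum(c for *_, c in PP_COMBOS)
    manifest = {
        "n_genes": len(genes),
        "profile_raw_hits": len(profile_hits),
        "pattern_raw_hits": len(pattern_hits),
        "profile_complete_hits": PROFILE_TRAJECTORY[1],
        "pattern_complete_hits": PATTERN_TRAJECTORY[1],
        "profile_nonredundant": n_profile_nr,
        "pattern_nonredundant": n_pattern_nr,
        "n_profile_sets": len(PROFILE_COMBOS),
        "n_pattern_sets": len(PATTERN_COMBOS),
        "n_pp_sets": len(PP_COMBOS),
        "multi_pattern_genes": sum(
            c for combo, c in PATTERN_COMBOS if len(combo) >= 2
        ),
        "reliable_genes": (
            sum(c for combo, c in PROFILE_COMBOS if len(combo) >= 2)
            + sum(c for combo, c in PATTERN_COMBOS if len(combo) >= 2)
            + sum(c for *_, c in PP_COMBOS)
        ),
        "n_meta_families": len(set(FAMILY_MAP.values())),
    }
    collection = GeneCollection(genes, {"fixture": "replay", "seed": seed})
    return ReplayFixture(
        collection=collection,
        profile_hits=profile_hits,
        pattern_hits=pattern_hits,
        go_profile=go_profile,
        prosite_list=prosite_list,
        family_map=dict(FAMILY_MAP),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# translation-table replay

# (group, EC total, EC non-redundant, EC surviving, GO NR, PROSITE NR)
TRANSLATION_ROWS: tuple[tuple[str, int, int, int, int, int], ...] = (
    ("Alcohol DH", 101, 32, 25, 20, 8),
    ("Formate DH", 29, 6, 6, 4, 6),
    ("Formaldehyde DH", 23, 9, 4, 2, 0),
    ("Carbon monoxide DH", 19, 4, 4, 4, 0),
    ("Ene reductase", 1162, 107, 65, 61, 1),
    ("Protease", 741, 217, 111, 39, 20),
    ("Terpene synthase", 35, 23, 17, 9, 0),
    ("Nitrogenase", 18, 4, 2, 2, 4),
    ("Lipase", 380, 26, 25, 24, 6),
    ("Carbonic anhydrase", 58, 1, 1, 1, 3),
    ("Acetylene hydratase", 2, 1, 1, 1, 0),
    ("Acetyl-CoA synthetase", 8, 3, 3, 2, 0),
)

#: The aquaporin group has no E.C. number; its descriptors are supplemental.
TRANSLATION_SUPPLEMENTAL = ("Aquaporin", 2, 1)

LOW_SPECIFICITY_IDS = ("PS00198", "PS00455", "PS00143")


@dataclass
class TranslationFixture:
    ec_list_text: str
    groups: list[str]
    mapping: DescriptorMapping
    supplemental_go: tuple[str, ...]
    supplemental_prosite: tuple[str, ...]
    supplemental_group: str
    manifest: dict


def make_translation_fixture(seed: int = 0) -> TranslationFixture:
    """An E.C. list plus mapping replaying the stepwise translation counts.

    Per group: the stated number of raw (duplicated) E.C. tokens collapsing
    to the stated non-redundant count; the non-surviving entries are marked
    transferred or deleted in the enzyme table; surviving entries map onto
    group-disjoint GO and PROSITE identifier blocks sized to the stated
    non-redundant descriptor counts.  The three low-specificity PROSITE IDs
    are attached to the protease group so the pattern list shrinks by
    exactly three at translation.
    """
    del seed  # identifiers are structural here; kept for API symmetry
    mapping = DescriptorMapping(low_specificity_ids=LOW_SPECIFICITY_IDS)
    lines: list[str] = []
    groups: list[str] = []
    for gi, (name, total, nr, surviving, n_go, n_ps) in enumerate(TRANSLATION_ROWS):
        ec_class = (gi % 7) + 1
        ecs = [ECNumber(ec_class, gi + 1, 1, serial) for serial in range(1, nr + 1)]
        go_ids = tuple(f"GO:{gi:03d}{k:04d}" for k in range(1, n_go + 1))
        ps_ids = tuple(f"PS9{gi:02d}{k:02d}" for k in range(1, n_ps + 1))
        for k, ec in enumerate(ecs):
            if k < surviving:
                mapping.add_enzyme_record(ec, "active", ps_ids if k == 0 else ())
                if go_ids:
                    mapping.add_go(ec, go_ids)
            else:
                status = "transferred" if k % 2 == 0 else "deleted"
                mapping.add_enzyme_record(ec, status)
        if name == "Protease" and surviving > 0:
            mapping.add_enzyme_record(ecs[0], "active", LOW_SPECIFICITY_IDS)
        for i in range(total):
            lines.append(f"{ecs[i % nr]}\t{name}")
            groups.append(name)

    supp_name, n_supp_go, n_supp_ps = TRANSLATION_SUPPLEMENTAL
    supplemental_go = tuple(f"GO:999{k:04d}" for k in range(1, n_supp_go + 1))
    supplemental_prosite = tuple(f"PS999{k:02d}" for k in range(1, n_supp_ps + 1))

    manifest = {
        "ec_total": sum(r[1] for r in TRANSLATION_ROWS),
        "ec_nonredundant": sum(r[2] for r in TRANSLATION_ROWS),
        "ec_surviving": sum(r[3] for r in TRANSLATION_ROWS),
        "go_terms": sum(r[4] for r in TRANSLATION_ROWS) + n_supp_go,
        "prosite_ids": sum(r[5] for r in TRANSLATION_ROWS) + n_supp_ps,
        "low_specificity_removed": len(LOW_SPECIFICITY_IDS),
    }
    return TranslationFixture(
        ec_list_text="\n".join(lines) + "\n",
        groups=groups,
        mapping=mapping,
        supplemental_go=supplemental_go,
        supplemental_prosite=supplemental_prosite,
        supplemental_group=supp_name,
        manifest=manifest,
    )


def mapping_to_flatfiles(mapping: DescriptorMapping) -> tuple[str, str]:
    """Render a mapping in the two flat-file dialects (round-trip support)."""
    enzyme_records = []
    ec2go_lines = []
    for ec in mapping.known():
        status = mapping.status_of(ec)
        if status == "transferred":
            de = "Transferred entry: elsewhere."
        elif status == "deleted":
            de = "Deleted entry."
        else:
            de = "Synthetic enzyme."
        block = [f"ID   {ec}", f"DE   {de}"]
        for ps in mapping.ec_to_prosite.get(ec, ()):
            block.append(f"PR   PROSITE; {ps};")
        enzyme_records.append("\n".join(block) + "\n//")
        for go in mapping.ec_to_go.get(ec, ()):
            ec2go_lines.append(f"EC:{ec} > GO:synthetic term ; {go}")
    return "\n".join(enzyme_records) + "\n", "\n".join(ec2go_lines) + "\n"


# ---------------------------------------------------------------------------
# planted pattern occurrences


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_LIST, size=length))


def _pattern_instance(rng: np.random.Generator, pattern: PrositePattern) -> str:
    """A minimal-length sequence matching *pattern*, elements at min repeat."""
    out: list[str] = []
    for el in pattern.elements:
        if el.kind == "fixed":
            choices = list(el.residues)
        elif el.kind == "any_of":
            choices = list(el.residues)
        elif el.kind == "none_of":
            choices = sorted(AA20 - set(el.residues))
        else:
            choices = _AA_LIST
        out.extend(rng.choice(choices) for _ in range(el.min_repeat))
    return "".join(out)


def make_planted_proteins(
    pattern_texts: Sequence[str],
    n_genes: int = 50,
    plant_plan: Optional[Mapping[str, int]] = None,
    length: int = 120,
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[GeneCollection, dict[str, set[str]]]:
    """Proteins with planted pattern sites and a clean background.

    *plant_plan* maps pattern text → number of genes carrying a planted
    site (defaults to 5 per pattern, in distinct genes).  Background genes
    are rejection-sampled against the matcher so they match no pattern, and
    planted genes match exactly their planted patterns — the returned truth
    table is exact by construction.
    """
    rng = np.random.default_rng(seed)
    patterns = [parse_pattern(t, pattern_id=f"PLANT{i+1:02d}") for i, t in enumerate(pattern_texts)]
    for p in patterns:
        if p.min_span > length:
            raise ValueError(f"pattern {p.render()} cannot fit in length {length}")
    if plant_plan is None:
        plant_plan = {t: 5 for t in pattern_texts}
    by_text = dict(zip(pattern_texts, patterns))

    assignments: list[set[str]] = [set() for _ in range(n_genes)]
    cursor = 0
    for text, count in plant_plan.items():
        if count > n_genes:
            raise ValueError("more plants than genes")
        for _ in range(count):
            assignments[cursor % n_genes].add(by_text[text].id)
            cursor += 1

    genes: list[GeneRecord] = []
    truth: dict[str, set[str]] = {}
    for i, planted_ids in enumerate(assignments):
        gene_id = f"p{seed}_{i:03d}"
        for _ in range(max_tries):
            seq = _random_seq(rng, length)
            for pid in planted_ids:
                pat = next(p for p in patterns if p.id == pid)
                inst = _pattern_instance(rng, pat)
                if pat.n_anchored:
                    pos = 0
                elif pat.c_anchored:
                    pos = length - len(inst)
                else:
                    pos = int(rng.integers(0, length - len(inst) + 1))
                seq = seq[:pos] + inst + seq[pos + len(inst):]
            matched = {p.id for p in patterns if match(p, seq)}
            if matched == planted_ids:
                break
        else:
            raise RuntimeError("could not sample a clean background sequence")
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id="planted",
                complete=True,
                protein_seq=seq,
                prosite_ids=frozenset(planted_ids),
            )
        )
        truth[gene_id] = set(planted_ids)
    return GeneCollection(genes, {"fixture": "planted", "seed": seed}), truth


# ---------------------------------------------------------------------------
# planted-cluster alignments


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            alternatives = [a for a in _AA_LIST if a != ch]
            out[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


def make_cluster_alignment(
    sizes: Sequence[int] = (5, 4, 3, 2),
    length: int = 200,
    within_rate: float = 0.02,
    between_rate: float = 0.4,
    seed: int = 0,
) -> tuple[dict[str, str], list[list[str]]]:
    """Gap-free alignment with planted phylogenetic clusters.

    Each cluster descends from an ancestor mutated from a common root at
    *between_rate* per site; members mutate from their ancestor at
    *within_rate*.  Requires within < between (otherwise the planted
    partition is not recoverable even in expectation).
    """
    if within_rate >= between_rate:
        raise ValueError("within_rate must be smaller than between_rate")
    if min(sizes) < 1:
        raise ValueError("cluster sizes must be positive")
    rng = np.random.default_rng(seed)
    root = _random_seq(rng, length)
    alignment: dict[str, str] = {}
    partition: list[list[str]] = []
    for ci, size in enumerate(sizes, start=1):
        ancestor = _mutate(rng, root, between_rate)
        block = []
        for k in range(1, size + 1):
            name = f"C{ci}_{k:02d}"
            alignment[name] = _mutate(rng, ancestor, within_rate)
            block.append(name)
        partition.append(block)
    return alignment, partition


# ---------------------------------------------------------------------------
# gamma-carbonic-anhydrase derivation scenario


@dataclass
class GammaCAFixture:
    spec: DerivationSpec
    manifest: dict


def make_gamma_ca_fixture(seed: int = 0, n_candidates: int = 6) -> GammaCAFixture:
    """Synthetic archetype-plus-candidates alignment for pattern derivation.

    Emulates the gamma-carbonic-anhydrase situation: an archetype with nine
    functional residues in two segments, and candidate homologs where the
    long spacer is shortened by one residue, one hydrogen-bonding position
    tolerates N→C, another Q→K, the terminal acidic position tolerates E→D,
    and one catalytic position is hypervariable (degrading to ``x``).  The
    metal-binding histidines and the structural Arg/Asp are conserved.
    """
    if n_candidates < 2:
        raise ValueError("need at least two candidates to observe variation")
    rng = np.random.default_rng(seed)
    length = 130
    arch = list(_random_seq(rng, length))

    fixed = {
        59: "R",
        61: "D",
        62: "E",
        73: "N",
        75: "Q",
        81: "H",
        84: "E",
        117: "H",
        121: "H",
    }
    for idx, res in fixed.items():
        arch[idx - 1] = res
    archetype = "".join(arch)

    gap_col = 67 - 1  # a spacer residue between positions 62 and 73
    hyper = ["A", "S", "T", "G", "P", "K", "V", "I"]

    alignment: dict[str, str] = {"CAM_ARCHETYPE": archetype}
    candidate_ids = []
    for c in range(n_candidates):
        row = list(_mutate(rng, archetype, 0.10))
        for idx, res in fixed.items():
            row[idx - 1] = res
        row[62 - 1] = hyper[c % len(hyper)]  # hypervariable catalytic position
        row[73 - 1] = "C" if c < n_candidates // 2 else "N"
        row[75 - 1] = "K" if c % 2 == 0 else "Q"
        row[84 - 1] = "D" if c < max(n_candidates - 2, 1) else "E"
        row[gap_col] = "-"  # every candidate lost one spacer residue
        name = f"GCA_CAND{c+1}"
        alignment[name] = "".join(row)
        candidate_ids.append(name)

    positions = [
        FunctionalPosition(59, "structural", "R"),
        FunctionalPosition(61, "structural", "D"),
        FunctionalPosition(62, "catalytic", "E"),
        FunctionalPosition(73, "catalytic", "N"),
        FunctionalPosition(75, "catalytic", "Q"),
        FunctionalPosition(81, "metal_binding", "H"),
        FunctionalPosition(84, "catalytic", "E"),
        FunctionalPosition(117, "metal_binding", "H"),
        FunctionalPosition(121, "metal_binding", "H"),
    ]
    spec = DerivationSpec(
        archetype_id="CAM_ARCHETYPE",
        candidate_ids=candidate_ids,
        alignment=alignment,
        positions=positions,
        segments=[(59, 84), (117, 121)],
    )
    manifest = {
        "n_sequences": 1 + n_candidates,
        "segments": 2,
        "hypervariable_positions": [62],
        "spacer_shortened": True,
    }
    return GammaCAFixture(spec=spec, manifest=manifest)


# ---------------------------------------------------------------------------
# additive distance matrices for tree-inference checks


def make_additive_matrix(
    n_leaves: int, seed: int = 0
) -> tuple[tuple[str, ...], "np.ndarray"]:
    """A random tree's exact leaf-to-leaf path-length matrix.

    Branch lengths are drawn uniformly; the returned matrix is additive by
    construction, so a correct distance-based tree builder must reproduce
    every pairwise path length exactly.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    G = nx.Graph()
    labels = [f"L{i}" for i in range(3)]
    for l in labels:
        G.add_edge(l, "I0", weight=float(rng.uniform(0.1, 1.0)))
    nxt = 1
    for i in range(3, n_leaves):
        edges = list(G.edges())
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = G[u][v]["weight"]
        G.remove_edge(u, v)
        mid = f"I{nxt}"
        nxt += 1
        a = float(rng.uniform(0.05, 0.95))
        G.add_edge(u, mid, weight=w * a)
        G.add_edge(mid, v, weight=w * (1 - a))
        leaf = f"L{i}"
        labels.append(leaf)
        G.add_edge(leaf, mid, weight=float(rng.uniform(0.1, 1.0)))
    d = np.zeros((n_leaves, n_leaves))
    sp = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[i, j] = sp[a][b]
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return tuple(labels), d


# ---------------------------------------------------------------------------
# random collections for property tests


def make_random_collection(
    seed: int = 0,
    n_genes: int = 30,
    go_pool: Sequence[str] = tuple(f"GO:00000{k:02d}" for k in range(1, 7)),
    ps_pool: Sequence[str] = tuple(f"PS000{k:02d}" for k in range(1, 7)),
) -> tuple[GeneCollection, tuple[str, ...], tuple[str, ...]]:
    """A random annotated collection (lengths straddling 300 nt, mixed flags)."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        n_go = int(rng.integers(0, 3))
        n_ps = int(rng.integers(0, 3))
        genes.append(
            GeneRecord(
                gene_id=f"r{seed}_{i:03d}",
                genome_id="random",
                nt_length=int(rng.integers(100, 900)),
                complete=bool(rng.random() < 0.7),
                go_terms=frozenset(rng.choice(go_pool, size=n_go, replace=False)),
                prosite_ids=frozenset(rng.choice(ps_pool, size=n_ps, replace=False)),
            )
        )
    return (
        GeneCollection(genes, {"fixture": "random", "seed": seed}),
        tuple(go_pool),
        tuple(ps_pool),
    )
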