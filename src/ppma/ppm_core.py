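"""The PPM processor: descriptor filtering, set building, ranking, condensation.

Genes are matched independently against the GO-term profile list and the
PROSITE pattern list.  Warehouse exports may list the same gene–descriptor
evidence several times, so hit de-duplication collapses an arbitrary multiset
of hits into one entry per gene carrying the full sorted combination of
matched descriptors.  Genes sharing an exact combination form a PPM set,
classified as

* ``profile`` — only GO terms matched,
* ``pattern`` — only PROSITE IDs matched,
* ``profile_and_pattern`` — at least one of each (such genes belong to this
  class only; they are removed from the pure classes).

A set is *reliable* when it is backed by at least two descriptors.  Sets
whose combinations point at the same enzyme family can be condensed into a
meta-set under an explicit, curator-supplied family map — condensation is
deliberately not guessed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .gene_store import GeneCollection
from .prosite_engine import PrositePattern, scan_genes
from .ec_translate import load_filter_list

__all__ = [
    "Hit",
    "PPMSet",
    "MetaSet",
    "profile_filter",
    "pattern_filter",
    "filter_hits",
    "dedupe_hits",
    "build_ppm_sets",
    "condense_meta_sets",
    "report",
    "load_family_map",
    "load_filter_list",
]


@dataclass(frozen=True)
class Hit:
    """One piece of gene–descriptor evidence (possibly duplicated upstream)."""

    gene_id: str
    descriptor_id: str
    descriptor_kind: str  # 'profile' | 'pattern'

    def __post_init__(self) -> None:
        if self.descriptor_kind not in ("profile", "pattern"):
            raise ValueError(f"unknown descriptor kind {self.descriptor_kind!r}")


@dataclass
class PPMSet:
    """Genes sharing one exact descriptor combination."""

    set_id: str
    go_combo: tuple[str, ...]
    prosite_combo: tuple[str, ...]
    ppm_class: str  # 'profile' | 'pattern' | 'profile_and_pattern'
    members: tuple[str, ...]

    @property
    def n_descriptors(self) -> int:
        return len(self.go_combo) + len(self.prosite_combo)

    @property
    def reliable(self) -> bool:
        return self.n_descriptors >= 2

    @property
    def combo_key(self) -> str:
        return ";".join(sorted(self.go_combo) + sorted(self.prosite_combo))


@dataclass
class MetaSet:
    """Union of PPM sets indicating the same enzyme family."""

    family_label: str
    member_sets: list[PPMSet]
    members: tuple[str, ...]


# ---------------------------------------------------------------------------
# filters


def profile_filter(
    collection: GeneCollection, go_profile: Sequence[str]
) -> list[Hit]:
    """One hit per (gene, matching GO term) pair, in collection order."""
    wanted = list(dict.fromkeys(go_profile))
    hits: list[Hit] = []
    for gene in collection:
        for go in wanted:
            if go in gene.go_terms:
                hits.append(Hit(gene.gene_id, go, "profile"))
    return hits


def pattern_filter(
    collection: GeneCollection,
    prosite_list: Sequence[str],
    mode: str = "annotation",
    patterns: Optional[Sequence[PrositePattern]] = None,
) -> list[Hit]:
    """One hit per (gene, matching PROSITE ID) pair.

    ``annotation`` mode trusts the annotated ``prosite_ids`` field; ``scan``
    mode recomputes the flags by matching the supplied pattern definitions
    against the protein sequences (error if any gene lacks one).
    """
    wanted = list(dict.fromkeys(prosite_list))
    if mode == "annotation":
        hits: list[Hit] = []
        for gene in collection:
            for ps in wanted:
                if ps in gene.prosite_ids:
                    hits.append(Hit(gene.gene_id, ps, "pattern"))
        return hits
    if mode != "scan":
        raise ValueError(f"unknown pattern filter mode {mode!r}")
    if patterns is None:
        raise ValueError("scan mode requires parsed pattern definitions")
    missing = [g.gene_id for g in collection if g.protein_seq is None]
    if missing:
        raise ValueError(
            f"scan mode requires protein sequences; missing for: {missing[:10]}"
        )
    by_id = {p.id: p for p in patterns}
    absent = [ps for ps in wanted if ps not in by_id]
    if absent:
        raise ValueError(f"no pattern definition for: {absent}")
    flagged, _ = scan_genes([by_id[ps] for ps in wanted], collection)
    hits = []
    for gene in collection:
        for ps in wanted:
            if ps in flagged.get(gene.gene_id, set()):
                hits.append(Hit(gene.gene_id, ps, "pattern"))
    return hits


def filter_hits(hits: Iterable[Hit], collection: GeneCollection) -> list[Hit]:
    """Keep only hits whose gene survives in *collection* (e.g. post fragment filter)."""
    return [h for h in hits if h.gene_id in collection]


# ---------------------------------------------------------------------------
# de-duplication and set building


def dedupe_hits(
    hits: Iterable[Hit],
) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Collapse a hit multiset to one entry per gene.

    Returns an ordered mapping gene_id → (sorted GO combo, sorted PROSITE
    combo); first-appearance order of genes is preserved.
    """
    go: dict[str, set[str]] = {}
    ps: dict[str, set[str]] = {}
    order: dict[str, None] = {}
    for h in hits:
        order.setdefault(h.gene_id, None)
        bucket = go if h.descriptor_kind == "profile" else ps
        bucket.setdefault(h.gene_id, set()).add(h.descriptor_id)
    return {
        g: (tuple(sorted(go.get(g, ()))), tuple(sorted(ps.get(g, ()))))
        for g in order
    }


_CLASS_PREFIX = {"profile": "Pro", "pattern": "Pat", "profile_and_pattern": "PP"}


def build_ppm_sets(
    deduped: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]],
) -> list[PPMSet]:
    """Group genes by exact descriptor combination, classify and rank.

    Ranking: descriptor count descending, then member count descending, then
    lexicographic combination.  Set ids are assigned per class in rank order
    ("Pro 1", "Pat 1", "PP 1", ...).  The output is independent of the input
    gene order up to member ordering within a set.
    """
    groups: dict[tuple[tuple[str, ...], tuple[str, ...]], list[str]] = {}
    for gene_id, (go_combo, ps_combo) in deduped.items():
        if not go_combo and not ps_combo:
            continue
        groups.setdefault((go_combo, ps_combo), []).append(gene_id)

    sets: list[PPMSet] = []
    for (go_combo, ps_combo), members in groups.items():
        if go_combo and ps_combo:
            ppm_class = "profile_and_pattern"
        elif go_combo:
            ppm_class = "profile"
        else:
            ppm_class = "pattern"
        sets.append(
            PPMSet(
                set_id="",
                go_combo=go_combo,
                prosite_combo=ps_combo,
                ppm_class=ppm_class,
                members=tuple(sorted(members)),
            )
        )

    sets.sort(
        key=lambda s: (
            -s.n_descriptors,
            -len(s.members),
            s.go_combo + s.prosite_combo,
        )
    )
    counters = {k: 0 for k in _CLASS_PREFIX}
    for s in sets:
        counters[s.ppm_class] += 1
        s.set_id = f"{_CLASS_PREFIX[s.ppm_class]} {counters[s.ppm_class]}"
    return sets


def load_family_map(path: str | Path) -> dict[str, str]:
    """Read a family map TSV: columns ``combo`` (';'-joined descriptors), ``family``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("combo", "family"):
        if col not in df.columns:
            raise ValueError(f"family map missing column {col!r}")
    return {
        ";".join(sorted(str(row.combo).split(";"))): str(row.family)
        for row in df.itertuples(index=False)
    }


def condense_meta_sets(
    sets: Sequence[PPMSet], family_map: Mapping[str, str]
) -> list[MetaSet]:
    """Merge sets sharing a curated enzyme-family label.

    Sets whose combination is not in the map pass through as singleton
    meta-sets labeled by their own combination.  Meta-sets are ordered by
    total member count descending, then label.
    """
    buckets: dict[str, list[PPMSet]] = {}
    for s in sets:
        label = family_map.get(s.combo_key, s.combo_key)
        buckets.setdefault(label, []).append(s)
    metas = []
    for label, members in buckets.items():
        union = tuple(dict.fromkeys(g for s in members for g in s.members))
        metas.append(MetaSet(label, members, union))
    metas.sort(key=lambda m: (-len(m.members), m.family_label))
    return metas


# ---------------------------------------------------------------------------
# reporting


def report(
    sets: Sequence[PPMSet],
    meta_sets: Sequence[MetaSet],
    dest: str | Path,
) -> dict:
    """Write the ranked set report (TSV + JSON mirror) and return a summary."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)

    set_rows = [
        {
            "set_id": s.set_id,
            "class": s.ppm_class,
            "go_combo": ";".join(s.go_combo),
            "prosite_combo": ";".join(s.prosite_combo),
            "n_descriptors": s.n_descriptors,
            "reliable": s.reliable,
            "n_members": len(s.members),
        }
        for s in sets
    ]
    pd.DataFrame(
        set_rows,
        columns=[
            "set_id",
            "class",
            "go_combo",
            "prosite_combo",
            "n_descriptors",
            "reliable",
            "n_members",
        ],
    ).to_csv(dest / "sets.tsv", sep="\t", index=False)

    member_rows = [
        {"set_id": s.set_id, "gene_id": g} for s in sets for g in s.members
    ]
    pd.DataFrame(member_rows, columns=["set_id", "gene_id"]).to_csv(
        dest / "members.tsv", sep="\t", index=False
    )

    meta_rows = [
        {
            "family": m.family_label,
            "sets": ";".join(s.set_id for s in m.member_sets),
            "n_members": len(m.members),
        }
        for m in meta_sets
    ]
    pd.DataFrame(meta_rows, columns=["family", "sets", "n_members"]).to_csv(
        dest / "meta_sets.tsv", sep="\t", index=False
    )

    summary = {
        "n_sets": len(sets),
        "n_profile_sets": sum(1 for s in sets if s.ppm_class == "profile"),
        "n_pattern_sets": sum(1 for s in sets if s.ppm_class == "pattern"),
        "n_profile_and_pattern_sets": sum(
            1 for s in sets if s.ppm_class == "profile_and_pattern"
        ),
        "n_genes": sum(len(s.members) for s in sets),
        "n_reliable_genes": sum(len(s.members) for s in sets if s.reliable),
        "n_meta_sets": len(meta_sets),
    }
    payload = {
        "summary": summary,
        "sets": [
            {**row, "members": list(s.members)}
            for row, s in zip(set_rows, sets)
        ],
        "meta_sets": meta_rows,
    }
    (dest / "sets.json").write_text(json.dumps(payload, indent=2) + "\n")
    return summary
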