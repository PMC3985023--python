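"""Derive relaxed consensus patterns from an archetype's functional residues.

When a protein family has no public GO term or PROSITE signature (the
gamma-class carbonic anhydrases are the motivating case), a custom pattern
can be built from structurally characterized functional residues of an
archetype sequence and a set of candidate homologs:

1. anchor each functional residue (metal binding, catalytic, structural)
   at its archetype position through a multiple alignment;
2. at each position, collect the residues observed across archetype and
   candidates — a singleton becomes a fixed element, a small set an
   ``[...]`` class, and a hypervariable position (more residues than the
   breadth threshold) degrades to the arbitrary ``x``;
3. the spacing between surviving positions becomes ``x(n)`` when constant
   across sequences and ``x(n,m)`` with the observed minimum/maximum
   otherwise (candidate gaps shorten spacers naturally).

Every derived pattern is verified to match the archetype and every
candidate via the pattern engine; derivation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .prosite_engine import (
    AA20,
    PatternElement,
    PrositePattern,
    match,
)

__all__ = [
    "ROLES",
    "FunctionalPosition",
    "DerivationSpec",
    "DerivedPattern",
    "derive_pattern",
    "relax_pattern",
    "load_alignment_fasta",
    "load_derivation_spec",
    "write_derivation_report",
]

ROLES = ("metal_binding", "catalytic", "structural")

_GAPS = {"-", ".", "?"}


@dataclass(frozen=True)
class FunctionalPosition:
    """A functionally relevant residue, numbered in archetype coordinates."""

    archetype_index: int  # 1-based residue number in the ungapped archetype
    role: str
    archetype_residue: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.archetype_residue not in AA20:
            raise ValueError(f"bad archetype residue {self.archetype_residue!r}")


@dataclass
class DerivationSpec:
    """Inputs of a derivation: archetype, candidates, alignment, positions, segments."""

    archetype_id: str
    candidate_ids: list[str]
    alignment: dict[str, str]  # id -> aligned sequence (gaps as '-')
    positions: list[FunctionalPosition]
    segments: list[tuple[int, int]]  # archetype-index span of each pattern

    def __post_init__(self) -> None:
        idx = [p.archetype_index for p in self.positions]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("functional positions must be strictly increasing")
        for p in self.positions:
            if sum(first <= p.archetype_index <= last for first, last in self.segments) != 1:
                raise ValueError(
                    f"position {p.archetype_index} must lie inside exactly one segment"
                )


@dataclass
class DerivedPattern:
    """A derived pattern plus its per-position evidence."""

    pattern: PrositePattern
    per_position_classes: dict[int, tuple[str, ...]]
    gap_ranges: list[tuple[int, int]]
    degraded_positions: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# alignment plumbing


def load_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered id → row mapping."""
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    return rows


def _archetype_columns(row: str) -> dict[int, int]:
    """Map 1-based archetype residue numbers to 0-based alignment columns."""
    cols: dict[int, int] = {}
    i = 0
    for c, ch in enumerate(row):
        if ch not in _GAPS:
            i += 1
            cols[i] = c
    return cols


def _ungapped(row: str) -> str:
    return "".join(ch for ch in row if ch not in _GAPS)


# ---------------------------------------------------------------------------
# derivation


def derive_pattern(
    spec: DerivationSpec, breadth: int = 4, pattern_prefix: str = "DERIVED"
) -> list[DerivedPattern]:
    """Derive one relaxed consensus pattern per segment (see module docstring).

    *breadth* is the residue-class cutoff: a position whose observed residue
    set exceeds it is judged not generally important and degrades to ``x``
    (folded into the neighbouring spacer); degradations are reported.
    """
    arch_row = spec.alignment.get(spec.archetype_id)
    if arch_row is None:
        raise ValueError(f"archetype {spec.archetype_id} missing from alignment")
    missing = [c for c in spec.candidate_ids if c not in spec.alignment]
    if missing:
        raise ValueError(f"candidates missing from alignment: {missing}")
    seq_ids = [spec.archetype_id, *spec.candidate_ids]
    cols = _archetype_columns(arch_row)

    for p in spec.positions:
        col = cols.get(p.archetype_index)
        if col is None:
            raise ValueError(f"archetype has no residue {p.archetype_index}")
        if arch_row[col] != p.archetype_residue:
            raise ValueError(
                f"archetype residue {p.archetype_index} is {arch_row[col]}, "
                f"spec says {p.archetype_residue}"
            )

    derived: list[DerivedPattern] = []
    for seg_no, (first, last) in enumerate(spec.segments, start=1):
        seg_positions = [
            p for p in spec.positions if first <= p.archetype_index <= last
        ]
        if not seg_positions:
            raise ValueError(f"segment {first}-{last} contains no functional position")

        observed: dict[int, tuple[str, ...]] = {}
        kept: list[FunctionalPosition] = []
        degraded: list[int] = []
        for p in seg_positions:
            col = cols[p.archetype_index]
            residues: dict[str, None] = {}
            for sid in seq_ids:
                ch = spec.alignment[sid][col]
                if ch in _GAPS:
                    continue
                residues[ch] = None
            if not residues:
                raise ValueError(
                    f"position {p.archetype_index} falls in an all-gap column"
                )
            observed[p.archetype_index] = tuple(residues)
            if len(residues) > breadth:
                degraded.append(p.archetype_index)
            else:
                kept.append(p)
        if not kept:
            raise ValueError(
                f"segment {first}-{last}: every position degraded to 'x'"
            )

        elements: list[PatternElement] = []
        gap_ranges: list[tuple[int, int]] = []
        for i, p in enumerate(kept):
            if i > 0:
                prev_col = cols[kept[i - 1].archetype_index]
                col = cols[p.archetype_index]
                spacers = []
                for sid in seq_ids:
                    row = spec.alignment[sid]
                    spacers.append(
                        sum(
                            1
                            for c in range(prev_col + 1, col)
                            if row[c] not in _GAPS
                        )
                    )
                lo, hi = min(spacers), max(spacers)
                if hi > 0 and lo == 0:
                    raise ValueError(
                        f"spacer before position {p.archetype_index} varies "
                        "between zero and nonzero; not expressible in pattern syntax"
                    )
                if hi > 0:
                    gap_ranges.append((lo, hi))
                    elements.append(PatternElement("any", (), lo, hi))
                # lo == hi == 0: adjacent positions, no spacer element
            res = observed[p.archetype_index]
            if len(res) == 1:
                elements.append(PatternElement("fixed", res))
            else:
                elements.append(PatternElement("any_of", res))

        pattern = PrositePattern(
            id=f"{pattern_prefix}_{seg_no}", elements=tuple(elements)
        )
        dp = DerivedPattern(pattern, observed, gap_ranges, degraded)
        for sid in seq_ids:
            if not match(pattern, _ungapped(spec.alignment[sid])):
                raise AssertionError(
                    f"derived pattern {pattern.render()} fails to match {sid}"
                )
        derived.append(dp)
    return derived


def relax_pattern(
    pattern: PrositePattern,
    observed_exceptions: Sequence[tuple[int, object]],
) -> PrositePattern:
    """Widen a pattern minimally to admit observed exceptions.

    Each exception is ``(element_index, residue)`` — the residue joins the
    element's allowed set — or ``(element_index, spacer_length)`` — the
    repeat range widens to include that length.  Element indices are
    0-based.  The result matches a superset of what the input matched.
    """
    elements = list(pattern.elements)
    for idx, obs in observed_exceptions:
        if not 0 <= idx < len(elements):
            raise ValueError(f"element index {idx} out of range")
        el = elements[idx]
        if isinstance(obs, int) and not isinstance(obs, bool):
            lo = min(el.min_repeat, obs)
            hi = max(el.max_repeat, obs)
            if lo < 1:
                raise ValueError("spacer lengths must be >= 1")
            elements[idx] = replace(el, min_repeat=lo, max_repeat=hi)
        elif isinstance(obs, str):
            if obs not in AA20:
                raise ValueError(f"not a standard amino acid: {obs!r}")
            if el.kind == "any":
                continue  # already maximally permissive
            if el.kind == "none_of":
                residues = tuple(r for r in el.residues if r != obs)
                if not residues:
                    elements[idx] = replace(el, kind="any", residues=())
                else:
                    elements[idx] = replace(el, residues=residues)
            elif obs not in el.residues:
                elements[idx] = replace(
                    el, kind="any_of", residues=el.residues + (obs,)
                )
        else:
            raise TypeError(f"exception must be residue or spacer length: {obs!r}")
    return replace(pattern, elements=tuple(elements), source_text="")


# ---------------------------------------------------------------------------
# spec file I/O


def load_derivation_spec(
    positions_path: str | Path,
    alignment_path: str | Path,
    archetype_id: str,
    candidate_ids: Optional[Sequence[str]] = None,
) -> DerivationSpec:
    """Build a spec from a positions TSV and an aligned FASTA.

    The TSV has columns ``index``, ``role``, ``residue`` for functional
    positions plus rows with role ``segment`` whose index column holds
    ``first-last``.
    """
    df = pd.read_csv(positions_path, sep="\t", dtype=str)
    for col in ("index", "role", "residue"):
        if col not in df.columns:
            raise ValueError(f"positions table missing column {col!r}")
    positions: list[FunctionalPosition] = []
    segments: list[tuple[int, int]] = []
    for row in df.itertuples(index=False):
        if row.role == "segment":
            first, _, last = str(row.index).partition("-")
            segments.append((int(first), int(last)))
        else:
            positions.append(
                FunctionalPosition(int(row.index), row.role, str(row.residue))
            )
    alignment = load_alignment_fasta(alignment_path)
    if candidate_ids is None:
        candidate_ids = [k for k in alignment if k != archetype_id]
    return DerivationSpec(
        archetype_id=archetype_id,
        candidate_ids=list(candidate_ids),
        alignment=alignment,
        positions=sorted(positions, key=lambda p: p.archetype_index),
        segments=segments,
    )


def write_derivation_report(
    derived: Sequence[DerivedPattern],
    spec: DerivationSpec,
    dest: str | Path,
) -> None:
    """Write PROSITE-format PA entries plus the per-position evidence table."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    entries = []
    for dp in derived:
        entries.append(
            f"ID   {dp.pattern.id}; PATTERN.\nPA   {dp.pattern.render()}.\n//"
        )
    (dest / "derived_patterns.prosite").write_text("\n".join(entries) + "\n")

    role_of = {p.archetype_index: p.role for p in spec.positions}
    rows = []
    for dp in derived:
        for idx, residues in dp.per_position_classes.items():
            rows.append(
                {
                    "pattern_id": dp.pattern.id,
                    "archetype_index": idx,
                    "role": role_of.get(idx, ""),
                    "observed_residues": "".join(residues),
                    "degraded_to_x": idx in dp.degraded_positions,
                }
            )
    pd.DataFrame(rows).to_csv(dest / "derivation_report.tsv", sep="\t", index=False)
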