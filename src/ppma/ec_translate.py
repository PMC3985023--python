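"""Translate Enzyme Commission number lists into GO-term and PROSITE descriptor lists.

An enzyme search starts from a list of four-field E.C. numbers (the fourth
field may be the wildcard ``*``).  This module normalizes that list —
wildcard expansion, de-duplication, removal of preliminary / transferred /
deleted entries — and translates the surviving numbers into two non-redundant
descriptor lists: GO terms (the *profile* filter) and PROSITE IDs (the
*pattern* filter).  Mapping data come from two public flat-file dialects:

* ENZYME-release style records (``ID`` / ``DE`` / ``PR`` lines, ``//``
  separators) providing entry status and PROSITE cross-references;
* ``ec2go`` style mapping lines (``EC:1.1.1.1 > GO:... ; GO:0004022``).

A handful of PROSITE patterns are too unspecific to be useful as function
evidence and are removed from the pattern list (logged, never silently).
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "ECNumber",
    "DescriptorMapping",
    "TranslationResult",
    "ECParseError",
    "DEFAULT_LOW_SPECIFICITY",
    "parse_ec",
    "parse_ec_list",
    "parse_ec_table",
    "expand_and_filter",
    "translate",
    "emit_filter_lists",
    "load_filter_list",
]

#: PROSITE patterns excluded from pattern lists because of low specificity.
DEFAULT_LOW_SPECIFICITY = ("PS00198", "PS00455", "PS00143")

_EC_TOKEN = re.compile(r"^(\d+)\.(\d+)\.(\d+)\.(\*|n?\d+)$")
_GO_ID = re.compile(r"GO:\d{7}$")
_PS_ID = re.compile(r"PS\d{5}$")


class ECParseError(ValueError):
    """Raised for malformed E.C. tokens; message names the offending line."""


@dataclass(frozen=True)
class ECNumber:
    """A four-field Enzyme Commission identifier.

    The first three fields are always concrete integers; only the serial
    (fourth) field may be a wildcard (``serial is None``).  Entries whose
    serial carries the ENZYME ``n`` prefix (e.g. ``1.1.1.n5``) are
    preliminary.  ``status`` is informational (resolved against the enzyme
    table) and does not take part in identity.
    """

    ec_class: int
    subclass: int
    subsubclass: int
    serial: Optional[int]
    preliminary: bool = False
    status: str = field(default="active", compare=False)

    def __post_init__(self) -> None:
        if not 1 <= self.ec_class <= 7:
            raise ECParseError(f"E.C. class must be 1-7, got {self.ec_class}")

    @property
    def is_wildcard(self) -> bool:
        return self.serial is None

    def matches(self, other: "ECNumber") -> bool:
        """True if *other* is covered by this number (wildcard-aware)."""
        if (self.ec_class, self.subclass, self.subsubclass) != (
            other.ec_class,
            other.subclass,
            other.subsubclass,
        ):
            return False
        return self.is_wildcard or (
            self.serial == other.serial and self.preliminary == other.preliminary
        )

    def __str__(self) -> str:
        if self.serial is None:
            tail = "*"
        else:
            tail = f"n{self.serial}" if self.preliminary else str(self.serial)
        return f"{self.ec_class}.{self.subclass}.{self.subsubclass}.{tail}"


def parse_ec(token: str, line_no: Optional[int] = None) -> ECNumber:
    """Parse one E.C. token; the wildcard is legal only in the fourth field."""
    where = f" (line {line_no})" if line_no is not None else ""
    m = _EC_TOKEN.match(token.strip())
    if m is None:
        if re.search(r"^(\*|\d+\.\*|\d+\.\d+\.\*)", token.strip()):
            raise ECParseError(
                f"wildcard allowed only in the fourth E.C. field: {token!r}{where}"
            )
        raise ECParseError(f"malformed E.C. number {token!r}{where}")
    a, b, c, tail = m.groups()
    if tail == "*":
        return ECNumber(int(a), int(b), int(c), None)
    if tail.startswith("n"):
        return ECNumber(int(a), int(b), int(c), int(tail[1:]), preliminary=True)
    return ECNumber(int(a), int(b), int(c), int(tail))


def parse_ec_table(text: str) -> list[tuple[ECNumber, Optional[str]]]:
    """Parse a line-oriented E.C. list with optional tab-separated group labels.

    ``#`` starts a comment; blank lines are skipped; input order and
    duplicates are preserved.
    """
    out: list[tuple[ECNumber, Optional[str]]] = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split("\t")]
        group = fields[1] if len(fields) > 1 and fields[1] else None
        out.append((parse_ec(fields[0], i), group))
    return out


def parse_ec_list(text: str) -> list[ECNumber]:
    """Parse an E.C. list, discarding any group labels."""
    return [ec for ec, _ in parse_ec_table(text)]


# ---------------------------------------------------------------------------
# mapping tables


@dataclass
class DescriptorMapping:
    """Concrete-E.C. → descriptor lookup built from flat mapping files."""

    ec_to_go: dict[ECNumber, tuple[str, ...]] = field(default_factory=dict)
    ec_to_prosite: dict[ECNumber, tuple[str, ...]] = field(default_factory=dict)
    ec_status: dict[ECNumber, str] = field(default_factory=dict)
    low_specificity_ids: tuple[str, ...] = DEFAULT_LOW_SPECIFICITY
    known_order: list[ECNumber] = field(default_factory=list)

    def _register(self, ec: ECNumber) -> None:
        if ec not in self.ec_status:
            self.ec_status[ec] = "preliminary" if ec.preliminary else "active"
            self.known_order.append(ec)

    def known(self) -> list[ECNumber]:
        return list(self.known_order)

    def status_of(self, ec: ECNumber) -> str:
        if ec in self.ec_status:
            return self.ec_status[ec]
        return "preliminary" if ec.preliminary else "active"

    def add_enzyme_record(
        self, ec: ECNumber, status: str, prosite_ids: Sequence[str] = ()
    ) -> None:
        self._register(ec)
        self.ec_status[ec] = status
        if prosite_ids:
            merged = dict.fromkeys(self.ec_to_prosite.get(ec, ()) + tuple(prosite_ids))
            self.ec_to_prosite[ec] = tuple(merged)

    def add_go(self, ec: ECNumber, go_ids: Sequence[str]) -> None:
        for go in go_ids:
            if not _GO_ID.match(go):
                raise ValueError(f"not a GO identifier: {go!r}")
        self._register(ec)
        merged = dict.fromkeys(self.ec_to_go.get(ec, ()) + tuple(go_ids))
        self.ec_to_go[ec] = tuple(merged)

    # -- flat-file loaders ---------------------------------------------------

    def load_enzyme_flatfile(self, text: str) -> None:
        """ENZYME-release dialect: ``ID``/``DE``/``PR`` lines, ``//`` separators.

        Status is derived from the standard DE-line phrases ("Transferred
        entry", "Deleted entry"); ``n``-suffixed serials are preliminary.
        """
        for record in text.split("//"):
            ec: Optional[ECNumber] = None
            de_lines: list[str] = []
            prosite: list[str] = []
            for line in record.splitlines():
                tag, _, body = line.partition("   ")
                body = body.strip()
                if tag == "ID":
                    ec = parse_ec(body)
                elif tag == "DE":
                    de_lines.append(body)
                elif tag == "PR":
                    for part in body.split(";"):
                        part = part.strip().rstrip(".")
                        if _PS_ID.match(part):
                            prosite.append(part)
            if ec is None:
                continue
            de = " ".join(de_lines)
            if de.startswith("Transferred entry"):
                status = "transferred"
            elif de.startswith("Deleted entry"):
                status = "deleted"
            elif ec.preliminary:
                status = "preliminary"
            else:
                status = "active"
            self.add_enzyme_record(ec, status, prosite)

    def load_ec2go(self, text: str) -> None:
        """ec2go dialect: ``EC:1.1.1.1 > GO:name ; GO:0004022`` lines."""
        pat = re.compile(r"^EC:(\S+)\s*>\s*GO:.*?;\s*(GO:\d{7})\s*$")
        for line in text.splitlines():
            if line.startswith("!"):
                continue
            m = pat.match(line.strip())
            if m is None:
                continue
            token, go = m.groups()
            if not _EC_TOKEN.match(token):
                continue  # class-level entries like EC:1.1.1 are not POI keys
            ec = parse_ec(token)
            if ec.is_wildcard:
                continue
            self.add_go(ec, [go])

    @classmethod
    def from_files(
        cls,
        enzyme_path: str | Path,
        ec2go_path: str | Path,
        low_specificity: Sequence[str] = DEFAULT_LOW_SPECIFICITY,
    ) -> "DescriptorMapping":
        m = cls(low_specificity_ids=tuple(low_specificity))
        m.load_enzyme_flatfile(Path(enzyme_path).read_text())
        m.load_ec2go(Path(ec2go_path).read_text())
        return m


# ---------------------------------------------------------------------------
# translation


@dataclass
class TranslationResult:
    """Stepwise outcome of E.C. → descriptor translation."""

    input_count: int = 0
    nonredundant_ecs: tuple[ECNumber, ...] = ()
    dropped_by_status: tuple[ECNumber, ...] = ()
    unmapped: tuple[ECNumber, ...] = ()
    go_profile: tuple[str, ...] = ()
    prosite_pattern_list: tuple[str, ...] = ()
    dropped_low_specificity: tuple[str, ...] = ()
    per_group_counts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["group", "total", "nonredundant", "surviving"]
        )
    )
    group_of: dict[ECNumber, str] = field(default_factory=dict)


def expand_and_filter(
    ecs: Sequence[ECNumber],
    mapping: DescriptorMapping,
    groups: Optional[Sequence[Optional[str]]] = None,
) -> TranslationResult:
    """Expand wildcards, drop duplicates and inactive entries.

    Wildcards expand to every concrete E.C. number in the mapping sharing the
    first three fields (empty expansions warn).  Duplicates are removed
    preserving first occurrence; entries whose status is not ``active`` move
    to ``dropped_by_status``.  Concrete numbers absent from the mapping are
    kept but recorded as unmapped.
    """
    if groups is None:
        groups = [None] * len(ecs)
    if len(groups) != len(ecs):
        raise ValueError("groups must parallel the E.C. list")

    expanded: list[ECNumber] = []
    exp_groups: list[Optional[str]] = []
    known = mapping.known()
    for ec, grp in zip(ecs, groups):
        if ec.is_wildcard:
            members = sorted(
                (k for k in known if ec.matches(k)),
                key=lambda k: (k.serial, k.preliminary),
            )
            if not members:
                warnings.warn(f"wildcard {ec} matches no entry in the mapping")
            expanded.extend(members)
            exp_groups.extend([grp] * len(members))
        else:
            expanded.append(ec)
            exp_groups.append(grp)

    seen: dict[ECNumber, None] = {}
    group_of: dict[ECNumber, str] = {}
    surviving: list[ECNumber] = []
    dropped: list[ECNumber] = []
    unmapped: list[ECNumber] = []
    for ec, grp in zip(expanded, exp_groups):
        if ec in seen:
            continue
        seen[ec] = None
        if grp is not None:
            group_of[ec] = grp
        status = mapping.status_of(ec)
        if status != "active":
            dropped.append(dataclasses.replace(ec, status=status))
            continue
        surviving.append(ec)
        if ec not in mapping.ec_to_go and ec not in mapping.ec_to_prosite:
            unmapped.append(ec)

    rows = []
    labels = dict.fromkeys(g for g in exp_groups if g is not None) or {None: None}
    for grp in labels:
        idx = [i for i, g in enumerate(exp_groups) if g == grp]
        toks = [expanded[i] for i in idx]
        nr = list(dict.fromkeys(toks))
        surv = [t for t in nr if mapping.status_of(t) == "active"]
        rows.append(
            {
                "group": grp if grp is not None else "all",
                "total": len(toks),
                "nonredundant": len(nr),
                "surviving": len(surv),
            }
        )

    return TranslationResult(
        input_count=len(ecs),
        nonredundant_ecs=tuple(surviving),
        dropped_by_status=tuple(dropped),
        unmapped=tuple(unmapped),
        per_group_counts=pd.DataFrame(rows),
        group_of=group_of,
    )


def translate(
    result: TranslationResult,
    mapping: DescriptorMapping,
    supplemental_go: Sequence[str] = (),
    supplemental_prosite: Sequence[str] = (),
    supplemental_group: str = "supplemental",
) -> TranslationResult:
    """Complete a translation: union the descriptors of the surviving E.C.s.

    GO and PROSITE lists are de-duplicated preserving first occurrence; the
    low-specificity PROSITE IDs are removed (and logged).  Supplemental
    descriptors cover proteins of interest without an enzymatic E.C. number
    (e.g. aquaporins) and are appended after the mapped ones.
    """
    go: dict[str, None] = {}
    ps: dict[str, None] = {}
    go_by_group: dict[str, set[str]] = {}
    ps_by_group: dict[str, set[str]] = {}
    for ec in result.nonredundant_ecs:
        grp = result.group_of.get(ec, "all")
        for g in mapping.ec_to_go.get(ec, ()):
            go[g] = None
            go_by_group.setdefault(grp, set()).add(g)
        for p in mapping.ec_to_prosite.get(ec, ()):
            ps[p] = None
            ps_by_group.setdefault(grp, set()).add(p)
    for g in supplemental_go:
        if not _GO_ID.match(g):
            raise ValueError(f"not a GO identifier: {g!r}")
        go[g] = None
        go_by_group.setdefault(supplemental_group, set()).add(g)
    for p in supplemental_prosite:
        if not _PS_ID.match(p):
            raise ValueError(f"not a PROSITE identifier: {p!r}")
        ps[p] = None
        ps_by_group.setdefault(supplemental_group, set()).add(p)

    dropped_low = tuple(p for p in ps if p in mapping.low_specificity_ids)
    pattern_list = tuple(p for p in ps if p not in mapping.low_specificity_ids)

    counts = result.per_group_counts.copy()
    if not counts.empty:
        low = set(mapping.low_specificity_ids)
        counts["go_terms"] = [
            len(go_by_group.get(g, ())) for g in counts["group"]
        ]
        counts["prosite_ids"] = [
            len(ps_by_group.get(g, set()) - low) for g in counts["group"]
        ]
        if supplemental_group in go_by_group or supplemental_group in ps_by_group:
            counts = pd.concat(
                [
                    counts,
                    pd.DataFrame(
                        [
                            {
                                "group": supplemental_group,
                                "total": 0,
                                "nonredundant": 0,
                                "surviving": 0,
                                "go_terms": len(
                                    go_by_group.get(supplemental_group, ())
                                ),
                                "prosite_ids": len(
                                    ps_by_group.get(supplemental_group, set()) - low
                                ),
                            }
                        ]
                    ),
                ],
                ignore_index=True,
            )

    return dataclasses.replace(
        result,
        go_profile=tuple(go),
        prosite_pattern_list=pattern_list,
        dropped_low_specificity=dropped_low,
        per_group_counts=counts,
    )


# ---------------------------------------------------------------------------
# filter-list documents


def emit_filter_lists(
    result: TranslationResult, dest: str | Path
) -> tuple[Path, Path]:
    """Write the profile (GO) and pattern (PROSITE) lists as TSV documents.

    Each document is a flat, one-ID-per-line list whose single header names
    the descriptor kind; both round-trip through :func:`load_filter_list`.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    profile = dest / "profile_go.tsv"
    pattern = dest / "pattern_prosite.tsv"
    profile.write_text("\n".join(["go_term", *result.go_profile]) + "\n")
    pattern.write_text(
        "\n".join(["prosite_id", *result.prosite_pattern_list]) + "\n"
    )
    return profile, pattern


def load_filter_list(path: str | Path) -> tuple[str, tuple[str, ...]]:
    """Read a descriptor-list document; returns (descriptor kind, ordered IDs)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty descriptor list document: {path}")
    kind, ids = lines[0], lines[1:]
    if kind not in ("go_term", "prosite_id"):
        raise ValueError(f"unknown descriptor kind {kind!r} in {path}")
    return kind, tuple(dict.fromkeys(ids))
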