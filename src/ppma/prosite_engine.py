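"""PROSITE consensus-pattern parsing, matching and reliability bookkeeping.

A PROSITE pattern such as ``R-x-D-x(10,11)-[NC]-x-[QK]-x(5)-H-x(2)-[ED]``
describes a short amino-acid signature: dash-separated elements that are a
fixed residue, an allowed set ``[...]``, a forbidden set ``{...}`` or the
arbitrary residue ``x``, each optionally repeated ``(n)`` or ``(n,m)`` times.
``<`` anchors the pattern at the N-terminus and ``>`` at the C-terminus.

The matcher reports *every* distinct (start, end) span admitted by some
assignment of per-element repeat lengths — downstream filtering only consumes
presence/absence, and exhaustive reporting keeps the matcher checkable
against a brute-force oracle.  Ambiguity handling is deliberately
conservative (a false positive costs an expression campaign, a false negative
does not): ``X`` in a sequence satisfies only ``x`` elements, and ``B``/``Z``
satisfy neither fixed nor bracketed elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AA20",
    "PatternElement",
    "PrositePattern",
    "PatternMatch",
    "PatternReliability",
    "PatternParseError",
    "parse_pattern",
    "parse_prosite_flatfile",
    "match",
    "scan_genes",
    "evaluate_reliability",
    "write_matches_tsv",
]

#: The 20 standard amino-acid letters.
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


class PatternParseError(ValueError):
    """Raised on malformed pattern syntax; message carries the element index."""


@dataclass(frozen=True)
class PatternElement:
    """One pattern element with its repeat bounds.

    ``residues`` is an ordered tuple (rendering preserves source order);
    membership tests use the set view.  For ``kind='fixed'`` it has exactly
    one letter and for ``kind='any'`` it is empty.
    """

    kind: str  # 'fixed' | 'any_of' | 'none_of' | 'any'
    residues: tuple[str, ...] = ()
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "any_of", "none_of", "any"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "fixed" and len(self.residues) != 1:
            raise ValueError("fixed element needs exactly one residue")
        if self.kind == "any" and self.residues:
            raise ValueError("'x' element carries no residues")
        if not 1 <= self.min_repeat <= self.max_repeat:
            raise ValueError("repeat bounds must satisfy 1 <= min <= max")
        for r in self.residues:
            if r not in AA20:
                raise ValueError(f"not a standard amino acid: {r!r}")

    def accepts(self, residue: str) -> bool:
        """Conservative residue test (see module docstring for B/Z/X rules)."""
        if self.kind == "any":
            return residue.isalpha() and residue.isupper()
        if residue not in AA20:
            return False
        if self.kind == "none_of":
            return residue not in self.residues
        return residue in self.residues

    def render(self) -> str:
        if self.kind == "fixed":
            core = self.residues[0]
        elif self.kind == "any_of":
            core = "[" + "".join(self.residues) + "]"
        elif self.kind == "none_of":
            core = "{" + "".join(self.residues) + "}"
        else:
            core = "x"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return core
        if self.min_repeat == self.max_repeat:
            return f"{core}({self.min_repeat})"
        return f"{core}({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class PrositePattern:
    """A parsed consensus pattern."""

    id: str
    elements: tuple[PatternElement, ...]
    n_anchored: bool = False
    c_anchored: bool = False
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern needs at least one element")

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    def render(self) -> str:
        body = "-".join(e.render() for e in self.elements)
        return ("<" if self.n_anchored else "") + body + (">" if self.c_anchored else "")


@dataclass(frozen=True)
class PatternMatch:
    """One matched span; coordinates are 1-based inclusive (PROSITE convention)."""

    gene_id: str
    pattern_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("match coordinates must satisfy 1 <= start <= end")


@dataclass(frozen=True)
class PatternReliability:
    """Confusion-matrix rates for one pattern over a labeled gene collection.

    Rates are percentages; ``None`` marks undefined rates (no flagged genes /
    no labeled genes) rather than a misleading zero.
    """

    pattern_id: str
    hits: int
    true_positive_rate: Optional[float]
    false_positive_rate: Optional[float]
    false_negatives: int
    false_negative_rate: Optional[float]


# ---------------------------------------------------------------------------
# parsing


def _parse_core(token: str, idx: int) -> tuple[str, tuple[str, ...]]:
    if token == "x":
        return "any", ()
    if token.startswith("["):
        if not token.endswith("]"):
            raise PatternParseError(f"unbalanced '[' in element {idx}: {token!r}")
        body = token[1:-1]
        if ">" in body:
            raise PatternParseError(
                f"element {idx}: the '[...>]' C-terminal-or-residue idiom is unsupported"
            )
        kind = "any_of"
    elif token.startswith("{"):
        if not token.endswith("}"):
            raise PatternParseError(f"unbalanced '{{' in element {idx}: {token!r}")
        body = token[1:-1]
        kind = "none_of"
    else:
        if len(token) != 1:
            raise PatternParseError(f"malformed element {idx}: {token!r}")
        body = token
        kind = "fixed"
    if not body:
        raise PatternParseError(f"empty element {idx}")
    residues = tuple(dict.fromkeys(body))
    for r in residues:
        if r not in AA20:
            raise PatternParseError(
                f"element {idx}: not a standard amino-acid letter: {r!r}"
            )
    return kind, residues


def parse_pattern(text: str, pattern_id: Optional[str] = None) -> PrositePattern:
    """Parse PROSITE pattern syntax into a :class:`PrositePattern`.

    Grammar: dash-separated elements; ``x`` any residue; ``[...]`` allowed
    set; ``{...}`` forbidden set; ``(n)``/``(n,m)`` repetition of the
    preceding element; optional leading ``<``, trailing ``>`` and terminal
    ``.``.
    """
    source = text.strip()
    body = source
    if body.endswith("."):
        body = body[:-1]
    n_anchored = body.startswith("<")
    if n_anchored:
        body = body[1:]
    c_anchored = body.endswith(">")
    if c_anchored:
        body = body[:-1]
    if not body:
        raise PatternParseError("empty pattern")

    elements: list[PatternElement] = []
    for idx, token in enumerate(body.split("-"), start=1):
        token = token.strip()
        lo, hi = 1, 1
        if "(" in token:
            core, _, rep = token.partition("(")
            if not rep.endswith(")"):
                raise PatternParseError(f"unbalanced '(' in element {idx}: {token!r}")
            rep = rep[:-1]
            parts = rep.split(",")
            try:
                if len(parts) == 1:
                    lo = hi = int(parts[0])
                elif len(parts) == 2:
                    lo, hi = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise PatternParseError(
                    f"malformed repeat in element {idx}: {token!r}"
                ) from None
            if lo < 1 or hi < lo:
                raise PatternParseError(
                    f"element {idx}: repeat bounds must satisfy 1 <= n <= m: {token!r}"
                )
        else:
            core = token
        kind, residues = _parse_core(core, idx)
        elements.append(PatternElement(kind, residues, lo, hi))

    return PrositePattern(
        id=pattern_id or source,
        elements=tuple(elements),
        n_anchored=n_anchored,
        c_anchored=c_anchored,
        source_text=source,
    )


def parse_prosite_flatfile(text: str) -> list[PrositePattern]:
    """Parse PROSITE-release-style entries (ID / AC / PA lines).

    Multi-line ``PA`` bodies are concatenated; the accession (``PSxxxxx``)
    becomes the pattern id, falling back to the ID-line name.
    """
    patterns: list[PrositePattern] = []
    for record in text.split("//"):
        name = accession = None
        pa_parts: list[str] = []
        for line in record.splitlines():
            tag, _, payload = line.partition("   ")
            payload = payload.strip()
            if tag == "ID":
                name = payload.split(";")[0].strip()
            elif tag == "AC":
                accession = payload.split(";")[0].strip()
            elif tag == "PA":
                pa_parts.append(payload)
        if not pa_parts:
            continue
        pattern_text = "".join(pa_parts)
        patterns.append(parse_pattern(pattern_text, pattern_id=accession or name))
    return patterns


# ---------------------------------------------------------------------------
# matching


def match(pattern: PrositePattern, sequence: str) -> list[PatternMatch]:
    """Return every distinct matched span of *pattern* in *sequence*.

    Implemented as a per-start dynamic program over element reach sets;
    overlapping and nested spans are all reported.  Anchors pin the start to
    1 and/or the end to the sequence length.
    """
    return _match_spans(pattern, sequence, gene_id="")


def _match_spans(
    pattern: PrositePattern, sequence: str, gene_id: str
) -> list[PatternMatch]:
    n = len(sequence)
    if n == 0 or pattern.min_span > n:
        return []

    # run[e][i] = length of the longest acceptable run of element e starting at i
    runs: list[list[int]] = []
    for el in pattern.elements:
        ok = [el.accepts(c) for c in sequence]
        run = [0] * (n + 1)
        for i in range(n - 1, -1, -1):
            run[i] = run[i + 1] + 1 if ok[i] else 0
        runs.append(run)

    starts = [0] if pattern.n_anchored else range(n - pattern.min_span + 1)
    spans: list[PatternMatch] = []
    for s in starts:
        positions = {s}
        for el, run in zip(pattern.elements, runs):
            nxt: set[int] = set()
            for p in positions:
                reach = min(run[p] if p < n else 0, el.max_repeat)
                for k in range(el.min_repeat, reach + 1):
                    nxt.add(p + k)
            if not nxt:
                positions = nxt
                break
            positions = nxt
        for e in positions:
            if pattern.c_anchored and e != n:
                continue
            spans.append(PatternMatch(gene_id, pattern.id, s + 1, e))
    spans.sort(key=lambda m: (m.start, m.end))
    return spans


def scan_genes(
    patterns: Sequence[PrositePattern], genes: Iterable
) -> tuple[dict[str, set[str]], list[PatternMatch]]:
    """Scan protein sequences of a gene collection against patterns.

    *genes* is any iterable of records with ``gene_id`` and ``protein_seq``
    attributes (a :class:`ppma.gene_store.GeneCollection` qualifies).  A gene
    is flagged for a pattern iff at least one span matches.  Genes lacking a
    sequence are skipped with a warning.
    """
    flagged: dict[str, set[str]] = {}
    all_matches: list[PatternMatch] = []
    for gene in genes:
        if gene.protein_seq is None:
            warnings.warn(f"gene {gene.gene_id} has no protein sequence; skipped")
            continue
        hits: set[str] = set()
        for pat in patterns:
            spans = _match_spans(pat, gene.protein_seq, gene.gene_id)
            if spans:
                hits.add(pat.id)
                all_matches.extend(spans)
        flagged[gene.gene_id] = hits
    return flagged, all_matches


def write_matches_tsv(
    matches: Sequence[PatternMatch],
    sequences: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write matches as TSV: gene, pattern, 1-based span, matched subsequence."""
    lines = ["gene_id\tpattern_id\tstart\tend\tmatched"]
    for m in matches:
        sub = sequences.get(m.gene_id, "")[m.start - 1 : m.end]
        lines.append(f"{m.gene_id}\t{m.pattern_id}\t{m.start}\t{m.end}\t{sub}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reliability


def evaluate_reliability(
    flagged: Mapping[str, set[str]],
    truth: Mapping[str, set[str]],
    pattern_to_label: Mapping[str, str],
) -> list[PatternReliability]:
    """Book-keep per-pattern TP/FP/FN reliability over labeled genes.

    For each pattern with function label L: hits are the flagged genes;
    TP% = flagged genes carrying L / hits × 100 and FP% = 100 − TP%;
    FN counts genes carrying L but not flagged; FN% = FN / (FN + TP) × 100.
    Truth must cover every gene in *flagged*.
    """
    missing = set(flagged) - set(truth)
    if missing:
        raise ValueError(f"truth labels missing for genes: {sorted(missing)[:5]}")
    out: list[PatternReliability] = []
    for pattern_id, label in pattern_to_label.items():
        flagged_genes = {g for g, ps in flagged.items() if pattern_id in ps}
        tp = sum(1 for g in flagged_genes if label in truth.get(g, set()))
        hits = len(flagged_genes)
        fn = sum(
            1
            for g, labels in truth.items()
            if label in labels and g not in flagged_genes
        )
        tp_rate = 100.0 * tp / hits if hits else None
        fp_rate = 100.0 - tp_rate if tp_rate is not None else None
        fn_rate = 100.0 * fn / (fn + tp) if (fn + tp) else None
        out.append(
            PatternReliability(pattern_id, hits, tp_rate, fp_rate, fn, fn_rate)
        )
    return out
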