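"""Independent oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, closed
forms, graph path lengths — so it shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np

from ppma.prosite_engine import AA20, PatternElement, PrositePattern

_AA_LIST = sorted(AA20)


def brute_force_spans(pattern: PrositePattern, seq: str) -> list[tuple[int, int]]:
    """All matched (start, end) spans by exhaustive repeat-assignment enumeration."""
    n = len(seq)
    spans: set[tuple[int, int]] = set()
    starts = [0] if pattern.n_anchored else range(n)
    rep_ranges = [
        range(e.min_repeat, e.max_repeat + 1) for e in pattern.elements
    ]
    for s in starts:
        for assign in product(*rep_ranges):
            pos = s
            ok = True
            for el, k in zip(pattern.elements, assign):
                for _ in range(k):
                    if pos >= n or not el.accepts(seq[pos]):
                        ok = False
                        break
                    pos += 1
                if not ok:
                    break
            if ok and (not pattern.c_anchored or pos == n):
                spans.add((s + 1, pos))
    return sorted(spans)


def random_pattern(rng: np.random.Generator, max_elements: int = 6) -> PrositePattern:
    """A random small pattern (bounded repeats keep the oracle enumerable)."""
    n_el = int(rng.integers(1, max_elements + 1))
    elements = []
    for _ in range(n_el):
        kind = str(rng.choice(["fixed", "any_of", "none_of", "any"], p=[0.3, 0.3, 0.1, 0.3]))
        if kind == "fixed":
            residues = (str(rng.choice(_AA_LIST)),)
        elif kind in ("any_of", "none_of"):
            size = int(rng.integers(1, 5))
            residues = tuple(
                str(r) for r in rng.choice(_AA_LIST, size=size, replace=False)
            )
        else:
            residues = ()
        lo = int(rng.integers(1, 4))
        hi = lo + int(rng.integers(0, 3))
        elements.append(PatternElement(kind, residues, lo, hi))
    return PrositePattern(
        id="RND",
        elements=tuple(elements),
        n_anchored=bool(rng.random() < 0.15),
        c_anchored=bool(rng.random() < 0.15),
    )


def random_sequence(rng: np.random.Generator, max_len: int = 40) -> str:
    length = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(_AA_LIST, size=length))


def random_additive_tree(
    rng: np.random.Generator, n_leaves: int
) -> tuple[tuple[str, ...], np.ndarray]:
    """A random tree with random branch lengths and its exact leaf distance matrix."""
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
    d = (d + d.T) / 2.0  # remove floating asymmetry from path summation
    np.fill_diagonal(d, 0.0)
    return tuple(labels), d


def pdist_by_column_tally(rows: list[str]) -> tuple[np.ndarray, int]:
    """Recompute complete-deletion p-distances by an explicit per-column tally."""
    aa = set(_AA_LIST)
    length = len(rows[0])
    cols = [
        j for j in range(length) if all(r[j].upper() in aa for r in rows)
    ]
    n = len(rows)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(1 for c in cols if rows[i][c].upper() != rows[j][c].upper())
            p[i, j] = p[j, i] = diff / len(cols)
    return p, len(cols)
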