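"""Within-set phylogenetics: Poisson-corrected distances, NJ, clusters, representatives.

Members of a PPM set are isoenzyme candidates; before expression, each set is
clustered phylogenetically and one representative per cluster is picked.
Distances come from the aligned protein sequences under complete deletion
(every column containing a gap or missing symbol in any sequence is dropped),
giving the proportion of differing sites p, Poisson-corrected to
d = −ln(1 − p) substitutions per site.  Trees are built with Neighbor-Joining
(deterministic tie-breaks, negative branch lengths clamped to zero) and
clusters are the leaf components left after cutting branches longer than a
threshold.  Representative selection cascades through (1) containment —
one member's aligned residues cover all others —, (2) an injected external
similarity score (e.g. from a BLASTp run supplied as a table), and (3) the
count of functional-side-chain residues.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import TreeNode

__all__ = [
    "DistanceMatrix",
    "RepresentativeChoice",
    "FUNCTIONAL_SIDE_CHAINS",
    "DEFAULT_CLUSTER_CUT",
    "pairwise_distances",
    "neighbor_joining",
    "extract_clusters",
    "select_representative",
    "tree_to_newick",
    "tip_distances",
]

log = logging.getLogger(__name__)

#: Residues whose side chains carry chemical functionality (hydrogen bonding,
#: metal complexation, acid/base chemistry).
FUNCTIONAL_SIDE_CHAINS = frozenset("CDEHKNQRSTWY")

#: Default branch-length cut for cluster extraction, substitutions per site.
DEFAULT_CLUSTER_CUT = 0.1

_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class DistanceMatrix:
    """Pairwise p-distances and Poisson-corrected distances over labels."""

    labels: tuple[str, ...]
    p: np.ndarray
    d: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.p.shape != (n, n) or self.d.shape != (n, n):
            raise ValueError("matrix shapes must match the label count")


def pairwise_distances(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Poisson-corrected distances under complete deletion.

    Columns where any sequence carries a gap (``-``, ``.``), ``?`` or an
    ambiguous letter outside the 20-letter alphabet are removed globally;
    p is the per-pair mismatch proportion over the retained columns and
    d = −ln(1 − p).  A saturated pair (p = 1) has no finite correction and
    is an error, as is an empty post-deletion alignment.
    """
    labels = tuple(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    rows = [alignment[l] for l in labels]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows have unequal lengths")

    arr = np.array([list(r.upper()) for r in rows])
    good = np.ones(length, dtype=bool)
    for j in range(length):
        if any(arr[i, j] not in _AA for i in range(len(labels))):
            good[j] = False
    kept = arr[:, good]
    n_sites = kept.shape[1]
    if n_sites == 0:
        raise ValueError("no columns retained after complete deletion")

    n = len(labels)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = np.mean(kept[i] != kept[j])
    if np.any(p >= 1.0):
        raise ValueError("saturated pair (p = 1): Poisson correction undefined")
    d = -np.log(1.0 - p)
    return DistanceMatrix(labels, p, d, n_sites)


# ---------------------------------------------------------------------------
# Neighbor-Joining


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Saitou–Nei Neighbor-Joining on the corrected distances.

    Agglomerates by the Q criterion with standard branch-length formulas.
    Ties break deterministically on the smallest pair of node keys (a node's
    key is its smallest descendant leaf label).  Negative branch lengths are
    clamped to zero with the deficit logged.  Returns an unrooted tree
    represented with a trifurcating root (skbio ``TreeNode``).
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa; handle pairs directly")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in m.labels]
    keys: list[str] = list(m.labels)
    dist = m.d.astype(float).copy()

    def clamp(length: float) -> float:
        if length < 0:
            log.info("clamping negative branch length %.3g to 0", length)
            return 0.0
        return length

    while len(nodes) > 3:
        k = len(nodes)
        r = dist.sum(axis=1)
        best: Optional[tuple] = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * dist[i, j] - r[i] - r[j]
                key = (q, min(keys[i], keys[j]), max(keys[i], keys[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = dist[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)

        new_row = np.array(
            [
                0.5 * (dist[i, t] + dist[j, t] - dist[i, j])
                for t in range(k)
                if t not in (i, j)
            ]
        )
        keep = [t for t in range(k) if t not in (i, j)]
        dist = dist[np.ix_(keep, keep)]
        dist = np.vstack([dist, new_row])
        dist = np.hstack([dist, np.append(new_row, 0.0)[:, None]])
        nodes = [nodes[t] for t in keep] + [parent]
        keys = [keys[t] for t in keep] + [min(keys[i], keys[j])]

    # resolve the final three nodes around the unrooted central vertex
    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    root = TreeNode(children=list(nodes))
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
    return root


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tip_distances(tree: TreeNode) -> dict[frozenset[str], float]:
    """Path lengths between every pair of tips."""
    dm = tree.tip_tip_distances()
    out: dict[frozenset[str], float] = {}
    ids = list(dm.ids)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            out[frozenset((ids[a], ids[b]))] = float(dm[a, b])
    return out


# ---------------------------------------------------------------------------
# clusters and representatives


def extract_clusters(
    tree: TreeNode, threshold: float = DEFAULT_CLUSTER_CUT
) -> list[list[str]]:
    """Partition leaves by removing branches longer than *threshold*.

    Connected leaf components of the remaining tree become clusters,
    ordered (and internally sorted) by their smallest member label.
    """
    comp_of: dict[int, int] = {}
    next_comp = 0

    def walk(node: TreeNode, comp: int) -> None:
        nonlocal next_comp
        comp_of[id(node)] = comp
        for child in node.children:
            length = child.length or 0.0
            if length > threshold:
                next_comp += 1
                walk(child, next_comp)
            else:
                walk(child, comp)

    walk(tree, 0)
    groups: dict[int, list[str]] = {}
    for tip in tree.tips():
        groups.setdefault(comp_of[id(tip)], []).append(tip.name)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda c: c[0])
    return clusters


@dataclass(frozen=True)
class RepresentativeChoice:
    """The picked gene and the cascade rule that decided it."""

    gene_id: str
    criterion: str  # 'containment' | 'external_score' | 'side_chains' | 'singleton'


def _contains(a: str, b: str) -> bool:
    """True if aligned row *a* covers row *b*: wherever b has a residue, a agrees."""
    return all(cb in "-.?" or ca == cb for ca, cb in zip(a, b))


def select_representative(
    cluster: Sequence[str],
    alignment: Mapping[str, str],
    external_scores: Optional[Mapping[str, float]] = None,
) -> RepresentativeChoice:
    """Pick one expression candidate from a cluster.

    Cascade: (1) the unique member whose aligned residues contain every
    other member's; else (2) the highest external similarity score, when
    scores are supplied and discriminate; else (3) the member with the most
    functional-side-chain residues.  Final ties break on the lexicographically
    smallest gene id.
    """
    members = list(cluster)
    if not members:
        raise ValueError("cluster is empty")
    missing = [g for g in members if g not in alignment]
    if missing:
        raise ValueError(f"cluster members missing from alignment: {missing}")
    if len(members) == 1:
        return RepresentativeChoice(members[0], "singleton")

    containers = [
        g
        for g in members
        if all(_contains(alignment[g], alignment[h]) for h in members if h != g)
    ]
    if len(containers) == 1:
        return RepresentativeChoice(containers[0], "containment")

    if external_scores is not None:
        scored = [(external_scores.get(g, float("-inf")), g) for g in members]
        best = max(s for s, _ in scored)
        top = sorted(g for s, g in scored if s == best)
        if best > float("-inf") and len(top) == 1:
            return RepresentativeChoice(top[0], "external_score")
        if best > float("-inf") and len(top) < len(members):
            members = top  # score narrowed the field; fall through to rule 3

    counts = {
        g: sum(1 for ch in alignment[g] if ch in FUNCTIONAL_SIDE_CHAINS)
        for g in members
    }
    best_count = max(counts.values())
    winner = min(g for g, c in counts.items() if c == best_count)
    return RepresentativeChoice(winner, "side_chains")
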