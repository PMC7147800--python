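"""Substitution-pattern estimation, NJ trees and gene/species reconciliation.

Substitution patterns follow the Tamura-Nei (TN93) model — distinct purine
(k1) and pyrimidine (k2) transition/transversion ratios with unequal base
frequencies — estimated composite-likelihood style from pair counts pooled
over every sequence pair, with pairwise deletion of gap/ambiguous columns.
The fitted pattern is reported as a 4x4 table of substitution percentages
(off-diagonal sum 100), plus k1, k2 and the overall transition/transversion
bias R.

Trees are built with Saitou-Nei neighbour joining on p- or TN93 distances,
with deterministic tie-breaks and bootstrap support by column resampling.
Duplication/loss censuses come from standard LCA reconciliation of a rooted
gene tree against a rooted binary species tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np

from .sequence_io import SequenceRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
A, C, G, T = 0, 1, 2, 3
_PURINES = (A, G)
_PYRIMIDINES = (C, T)
_TRANSITION_PAIRS = {(A, G), (G, A), (C, T), (T, C)}

__all__ = [
    "PairCounts",
    "SubstitutionPattern",
    "ReconciliationResult",
    "pair_counts",
    "estimate_pattern",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "reconcile",
    "midpoint_root",
    "min_duplication_rooting",
    "leaf_map_from_prefix",
]


@dataclass
class PairCounts:
    """Aligned base-pair counts for one (or a pool of) sequence pair(s).

    ``matrix[i, j]`` counts columns with base i in the first sequence and j
    in the second; columns containing a gap or N in either sequence are
    excluded (pairwise deletion).  ``base_freqs`` are the empirical
    frequencies over the counted pairs (symmetrized).
    """

    sites_compared: int
    matrix: np.ndarray
    base_freqs: np.ndarray


def _encode_dna(residues: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in residues.upper()])


def pair_counts(a: SequenceRecord | str, b: SequenceRecord | str) -> PairCounts:
    """Tally aligned base pairs of two equal-length aligned sequences."""
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError(f"aligned lengths differ: {len(sa)} vs {len(sb)}")
    ea, eb = _encode_dna(sa), _encode_dna(sb)
    keep = (ea >= 0) & (eb >= 0)
    ea, eb = ea[keep], eb[keep]
    matrix = np.zeros((4, 4))
    np.add.at(matrix, (ea, eb), 1)
    n = int(keep.sum())
    if n:
        freqs = (matrix.sum(axis=0) + matrix.sum(axis=1)) / (2 * n)
    else:
        freqs = np.full(4, 0.25)
    return PairCounts(sites_compared=n, matrix=matrix, base_freqs=freqs)


@dataclass
class SubstitutionPattern:
    """TN93 substitution pattern.

    ``rates``: 4x4 table (A,C,G,T order), off-diagonal entries are
    substitution percentages summing to 100 for diverged data (all zero when
    the sequences are identical); diagonal is zero.  ``k1``/``k2``: purine /
    pyrimidine transition-to-transversion rate ratios (inf when no
    transversions were observed); ``R``: overall transition/transversion
    bias.  ``undefined`` flags a degenerate estimate (no divergence, or no
    transversions for the ratios).
    """

    rates: np.ndarray
    k1: float
    k2: float
    R: float
    undefined: bool = False


def _pooled_counts(alignment: Sequence[SequenceRecord | str]) -> PairCounts:
    seqs = [s.residues if isinstance(s, SequenceRecord) else s for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    matrix = np.zeros((4, 4))
    sites = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            pc = pair_counts(seqs[i], seqs[j])
            matrix += pc.matrix
            sites += pc.sites_compared
    if sites == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    freqs = (matrix.sum(axis=0) + matrix.sum(axis=1)) / (2 * sites)
    return PairCounts(sites_compared=sites, matrix=matrix, base_freqs=freqs)


def _tn93_components(
    matrix: np.ndarray, sites: int, freqs: np.ndarray
) -> tuple[float, float, float] | None:
    """TN93 branch-length components (alpha1*t, alpha2*t, beta*t) from
    pooled pair proportions; None when a log argument is non-positive
    (saturation)."""
    sym = (matrix + matrix.T) / 2
    p1 = (sym[A, G] + sym[G, A]) / sites
    p2 = (sym[C, T] + sym[T, C]) / sites
    q = sum(
        sym[i, j]
        for i in range(4)
        for j in range(4)
        if i != j and (i, j) not in _TRANSITION_PAIRS
    ) / sites
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    if min(pa, pc, pg, pt) <= 0:
        return None
    w1 = 1 - pr * p1 / (2 * pa * pg) - q / (2 * pr)
    w2 = 1 - py * p2 / (2 * pc * pt) - q / (2 * py)
    w3 = 1 - q / (2 * pr * py)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return None
    beta_t = -0.5 * math.log(w3)
    alpha1_t = (-0.5 * math.log(w1) - py * beta_t) / pr
    alpha2_t = (-0.5 * math.log(w2) - pr * beta_t) / py
    return alpha1_t, alpha2_t, beta_t


def estimate_pattern(alignment: Sequence[SequenceRecord | str]) -> SubstitutionPattern:
    """Estimate the TN93 substitution pattern from a multiple alignment.

    Pair counts are pooled over all sequence pairs (composite); identical
    sequences give an all-zero table with undefined ratios, and absent
    transversions give infinite k1/k2/R rather than an error.
    """
    pooled = _pooled_counts(alignment)
    comps = _tn93_components(pooled.matrix, pooled.sites_compared, pooled.base_freqs)
    if comps is None:
        raise ValueError("substitution pattern not estimable (saturation or "
                         "degenerate base frequencies)")
    a1t, a2t, bt = comps
    pa, pc, pg, pt = pooled.base_freqs
    pr, py = pa + pg, pc + pt
    rate_factor = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            if (i, j) in _TRANSITION_PAIRS:
                rate_factor[i, j] = a1t if i in _PURINES else a2t
            else:
                rate_factor[i, j] = bt
    rates = rate_factor * pooled.base_freqs[np.newaxis, :]
    total = rates.sum()
    if total > 0:
        rates = rates / total * 100.0
    if a1t == 0 and a2t == 0 and bt == 0:
        return SubstitutionPattern(
            rates=rates, k1=float("nan"), k2=float("nan"), R=float("nan"),
            undefined=True,
        )
    if bt == 0:
        return SubstitutionPattern(
            rates=rates, k1=float("inf"), k2=float("inf"), R=float("inf"),
            undefined=True,
        )
    k1, k2 = a1t / bt, a2t / bt
    R = (pa * pg * k1 + pc * pt * k2) / (pr * py)
    return SubstitutionPattern(rates=rates, k1=k1, k2=k2, R=R)


def distance_matrix(
    alignment: Sequence[SequenceRecord | str], model: str = "p"
) -> np.ndarray:
    """Pairwise distances (symmetric, zero diagonal).

    ``p``: mismatch proportion; ``tn93``: Tamura-Nei correction with
    alignment-wide base frequencies.  Saturated pairs (log of a non-positive
    value) are reported as NaN.
    """
    seqs = [s.residues if isinstance(s, SequenceRecord) else s for s in alignment]
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if model not in ("p", "tn93"):
        raise ValueError(f"unknown distance model {model!r}")
    freqs = _pooled_counts(seqs).base_freqs if model == "tn93" else None
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pc = pair_counts(seqs[i], seqs[j])
            if pc.sites_compared == 0:
                d = float("nan")
            elif model == "p":
                d = (pc.sites_compared - np.trace(pc.matrix)) / pc.sites_compared
            else:
                d = _tn93_distance(pc, freqs)
            dist[i, j] = dist[j, i] = d
    return dist


def _tn93_distance(pc: PairCounts, freqs: np.ndarray) -> float:
    comps = _tn93_components(pc.matrix, pc.sites_compared, freqs)
    if comps is None:
        return float("nan")
    a1t, a2t, bt = comps
    pa, pc_, pg, pt = freqs
    pr, py = pa + pg, pc_ + pt
    # expected substitutions per site; equals the standard TN93 closed form
    # -(2*pA*pG/pR) ln w1 - (2*pC*pT/pY) ln w2
    # - 2(pR*pY - pA*pG*pY/pR - pC*pT*pR/pY) ln w3
    return 4 * (pa * pg * a1t + pc_ * pt * a2t + pr * py * bt)


def nj_tree(
    dist: np.ndarray, labels: Sequence[str], namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou-Nei neighbour joining.

    Deterministic: ties in the Q criterion break toward the smallest (i, j)
    index pair in the current node order.  Negative limb lengths are clamped
    to zero with the deficit moved to the sibling limb.  Returns an unrooted
    dendropy tree (trifurcating seed node).
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T, equal_nan=True):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if namespace is None:
        namespace = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=namespace)
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node(taxon=namespace.get_taxon(label))
        nodes.append(node)
    d = dist.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple[float, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                qv = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]
    # final trifurcation
    i, j, k = active
    la = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lb = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lc = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = tree.seed_node
    for node, length in ((nodes[i], la), (nodes[j], lb), (nodes[k], lc)):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def _internal_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (the side not
    containing the alphabetically first label)."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    all_set = frozenset(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(labels) - 1:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: Sequence[SequenceRecord],
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree of the full alignment with per-split bootstrap support.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal split of the full-data tree is the fraction of replicate
    trees containing it.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = [s.id for s in alignment]
    cols = np.array([list(s.residues.upper()) for s in alignment])
    full_tree = nj_tree(distance_matrix(alignment, model), labels)
    targets = _internal_splits(full_tree)
    hits = {split: 0 for split in targets}
    rng = np.random.default_rng(seed)
    length = cols.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        boot = ["".join(row) for row in cols[:, idx]]
        try:
            rep_tree = nj_tree(distance_matrix(boot, model), labels)
        except ValueError:
            continue  # unestimable replicate distances
        rep_splits = _internal_splits(rep_tree)
        for split in targets:
            if split in rep_splits:
                hits[split] += 1
    support = {split: hits[split] / n_reps for split in targets}
    for node in full_tree.preorder_node_iter():
        if node.is_leaf() or node is full_tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        labels_all = frozenset(labels)
        ref = min(labels)
        key = labels_all - side if ref in side else side
        if key in support:
            node.label = f"{support[key]:.3f}"
    return full_tree, support


@dataclass
class ReconciliationResult:
    duplications: int
    losses: int
    paralog_gene_count: int
    node_events: dict[int, str] = field(default_factory=dict)  # node id -> event


def _check_binary(tree: dendropy.Tree, what: str) -> None:
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if n_children not in (0, 2):
            raise ValueError(
                f"{what} tree is not binary: node with {n_children} children"
            )


def leaf_map_from_prefix(gene_tree: dendropy.Tree, sep: str = "|") -> dict[str, str]:
    """Default species mapping: gene id prefix up to the first separator."""
    return {
        leaf.taxon.label: leaf.taxon.label.split(sep, 1)[0]
        for leaf in gene_tree.leaf_node_iter()
    }


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: dict[str, str] | None = None,
) -> ReconciliationResult:
    """LCA reconciliation of a rooted gene tree with a rooted species tree.

    Each gene node v maps to M(v), the species-tree LCA of its leaf species;
    v is a duplication when M(v) equals M(child) for some child.  Losses are
    counted from the species-path lengths between M(v) and M(children):
    path-1 edges for a speciation node, path edges for a duplication node.
    Paralogs are gene leaves descending from at least one duplication.
    """
    _check_binary(species_tree, "species")
    _check_binary(gene_tree, "gene")
    if leaf_map is None:
        leaf_map = leaf_map_from_prefix(gene_tree)
    sp_by_label = {
        leaf.taxon.label: leaf for leaf in species_tree.leaf_node_iter()
    }
    depth: dict[int, int] = {}
    parent: dict[int, dendropy.Node | None] = {}
    for node in species_tree.preorder_node_iter():
        parent[id(node)] = node.parent_node
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1

    def species_lca(u: dendropy.Node, v: dendropy.Node) -> dendropy.Node:
        while u is not v:
            if depth[id(u)] >= depth[id(v)]:
                u = parent[id(u)]
            else:
                v = parent[id(v)]
        return u

    mapping: dict[int, dendropy.Node] = {}
    events: dict[int, str] = {}
    duplications = 0
    losses = 0
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_map:
                raise ValueError(f"gene leaf {label!r} has no species mapping")
            sp = leaf_map[label]
            if sp not in sp_by_label:
                raise ValueError(f"species {sp!r} absent from species tree")
            mapping[id(node)] = sp_by_label[sp]
            continue
        c1, c2 = node.child_nodes()
        m1, m2 = mapping[id(c1)], mapping[id(c2)]
        m = species_lca(m1, m2)
        mapping[id(node)] = m
        is_dup = m is m1 or m is m2
        events[id(node)] = "duplication" if is_dup else "speciation"
        if is_dup:
            duplications += 1
        for mc in (m1, m2):
            path = depth[id(mc)] - depth[id(m)]
            losses += path if is_dup else max(path - 1, 0)
    paralogs = 0
    dup_flag: dict[int, bool] = {}
    for node in gene_tree.preorder_node_iter():
        above = dup_flag.get(id(node.parent_node), False) if node.parent_node else False
        here = above or events.get(id(node)) == "duplication"
        dup_flag[id(node)] = here
        if node.is_leaf() and here:
            paralogs += 1
    return ReconciliationResult(
        duplications=duplications,
        losses=losses,
        paralog_gene_count=paralogs,
        node_events=events,
    )


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a copy of an (unrooted) tree."""
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    _binarize_root(rooted)
    return rooted


def _binarize_root(tree: dendropy.Tree) -> None:
    """Resolve a trifurcating seed node into a binary root (deterministic:
    the last two children are grouped)."""
    root = tree.seed_node
    children = root.child_nodes()
    if len(children) <= 2:
        return
    new_node = dendropy.Node()
    for child in children[1:]:
        root.remove_child(child)
        new_node.add_child(child)
    new_node.edge.length = 0.0
    root.add_child(new_node)


def min_duplication_rooting(
    unrooted: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: dict[str, str] | None = None,
) -> tuple[ReconciliationResult, dendropy.Tree]:
    """Exhaustive root search minimizing the duplication count.

    Tries rooting on every edge of the gene tree and returns the
    reconciliation with the fewest duplications (ties: fewest losses, first
    encountered).  Intended for small trees.
    """
    best: tuple[ReconciliationResult, dendropy.Tree] | None = None
    n_edges = sum(1 for _ in unrooted.preorder_edge_iter())
    for edge_idx in range(n_edges):
        work = unrooted.clone(depth=1)
        edges = [
            e for e in work.preorder_edge_iter()
            if e.head_node is not work.seed_node
        ]
        if edge_idx >= len(edges):
            continue
        edge = edges[edge_idx]
        length = edge.length or 0.0
        work.reroot_at_edge(edge, length1=length / 2, length2=length / 2,
                            update_bipartitions=False)
        work.is_rooted = True
        _binarize_root(work)
        try:
            res = reconcile(work, species_tree, leaf_map)
        except ValueError:
            continue
        if best is None or (res.duplications, res.losses) < (
            best[0].duplications, best[0].losses
        ):
            best = (res, work)
    if best is None:
        raise ValueError("no valid rooting found")
    return best
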