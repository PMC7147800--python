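"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the structure of a plant NAC transcription-factor
census: proteomes in which NAC proteins carry exact instances of the domain
signature-motif catalog in canonical order (1-4 tandem domains, optionally a
non-NAC partner motif making the protein chimeric), planted nuclear
localization signals of each taxonomy class at recorded coordinates, and
23-residue hydrophobic transmembrane stretches; composition-matched shuffled
decoys; coding sequences back-translated under a controlled codon-usage
profile; alignments evolved site-independently under TN93 with known k1/k2;
and gene families grown on a known species tree with a known number of
duplications.

Everything is a pure function of its spec plus a seed.  Each record draws
from its own child generator (seeded by record index), so inserting a record
never reshuffles the others.  Truth tables are emitted as DataFrames and are
the only ground-truth interface the rest of the package reads.

Deliberate simplifications: planted motifs are exact (no mutation), linkers
avoid P so that planted cluster-geometry classes can never collide with the
pattern-defined non-canonical classes, and domain evolution (indels inside
motifs) is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .codon_usage import FAMILIES
from .motif_scan import Catalog, Pattern, default_catalog
from .motif_scan import _AnyOf, _Fixed, _NoneOf, _Wildcard  # element types
from .sequence_io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
# linker/background letters that can never form a basic cluster or a
# non-canonical NLS pattern (no K, R, P)
SAFE_LINKER = "AGSTQN"
_HYDROPHOBIC = "LIVF"
NLS_CLASSES = ("mono_I", "mono_II", "bipartite", "multipartite",
               "class_III", "class_IV")

__all__ = [
    "ProteomeSpec",
    "EvolutionSpec",
    "NLS_CLASSES",
    "make_proteome",
    "make_nls_segment",
    "make_cds",
    "evolve_alignment",
    "make_gene_family",
    "instantiate_pattern",
]


def _rng_for(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index)])


def instantiate_pattern(pattern: Pattern, rng: np.random.Generator) -> str:
    """One concrete sequence matching ``pattern`` (wildcards from the safe
    linker alphabet)."""
    out = []
    for el in pattern.elements:
        if isinstance(el, _Fixed):
            out.append(el.residue)
        elif isinstance(el, _AnyOf):
            out.append(el.residues[rng.integers(len(el.residues))])
        elif isinstance(el, _NoneOf):
            choices = [a for a in AA20 if a not in el.residues]
            out.append(choices[rng.integers(len(choices))])
        elif isinstance(el, _Wildcard):
            n = int(rng.integers(el.min_rep, el.max_rep + 1))
            out.append("".join(rng.choice(list(SAFE_LINKER), size=n)))
    return "".join(out)


def _linker(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SAFE_LINKER), size=n))


def make_nls_segment(nls_class: str, rng: np.random.Generator) -> str:
    """A segment guaranteed to classify as ``nls_class`` under defaults.

    Basic runs use a single letter (all-K or all-R) so the segment can never
    contain the K-R adjacency required by the non-canonical patterns unless
    the class itself plants one.
    """
    basic = "K" if rng.random() < 0.7 else "R"
    run = lambda lo, hi: basic * int(rng.integers(lo, hi + 1))
    if nls_class == "mono_I":
        return run(4, 9)
    if nls_class == "mono_II":
        second = "K" if rng.random() < 0.5 else "R"
        last = "K" if rng.random() < 0.5 else "R"
        return "K" + second + _linker(rng, 1) + last
    if nls_class == "bipartite":
        return run(2, 3) + _linker(rng, int(rng.integers(8, 25))) + run(3, 5)
    if nls_class == "multipartite":
        n_clusters = int(rng.integers(3, 5))
        parts = [run(2, 4)]
        for _ in range(n_clusters - 1):
            parts.append(_linker(rng, int(rng.integers(5, 8))))
            parts.append(run(2, 4))
        return "".join(parts)
    if nls_class == "class_III":
        aromatic = "WFY"[rng.integers(3)]
        return "KR" + _linker(rng, 1) + aromatic + _linker(rng, 2) + "AF"
    if nls_class == "class_IV":
        first = "P" if rng.random() < 0.5 else "R"
        last = "K" if rng.random() < 0.5 else "R"
        return first + _linker(rng, 2) + "KR" + last
    raise ValueError(f"unknown NLS class {nls_class!r}")


@dataclass
class ProteomeSpec:
    """Study conditions for a synthetic proteome.

    Defaults describe a small but census-shaped proteome: mostly
    single-domain NAC proteins with a tail of multi-domain architectures,
    every taxonomy class of NLS represented, and a minority of
    membrane-anchored proteins.
    """

    n_nac: int = 50
    n_decoys: int = 50
    domain_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.85, 2: 0.09, 3: 0.04, 4: 0.02}
    )
    nls_plan: list[tuple[str, int]] = field(
        default_factory=lambda: [(c, 8) for c in NLS_CLASSES]
    )
    tm_fraction: float = 0.09
    length_range: tuple[int, int] = (280, 650)
    chimeric_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nac < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        total = sum(self.domain_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("domain count weights must sum to 1")


def _domain_block(catalog: Catalog, rng: np.random.Generator) -> str:
    parts = []
    for i, (_, pattern) in enumerate(catalog.core):
        if i:
            parts.append(_linker(rng, int(rng.integers(3, 9))))
        parts.append(instantiate_pattern(pattern, rng))
    return "".join(parts)


def make_proteome(
    spec: ProteomeSpec, catalog: Catalog | None = None
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate a proteome with planted features and its truth table.

    Truth table columns: protein_id, feature (nac_domain | nls | tm |
    chimeric), nls_class (empty for non-NLS features), start, end (1-based
    inclusive), segment.  Identical seed implies byte-identical output.
    """
    if catalog is None:
        catalog = default_catalog()
    domain_counts = sorted(spec.domain_count_distribution)
    domain_weights = [spec.domain_count_distribution[k] for k in domain_counts]
    # round-robin assignment of planted NLS over NAC proteins
    nls_queue: list[str] = []
    for cls, count in spec.nls_plan:
        nls_queue.extend([cls] * count)
    if spec.n_nac == 0 and nls_queue:
        raise ValueError("NLS plan requires at least one NAC protein")
    assignments: dict[int, list[str]] = {i: [] for i in range(spec.n_nac)}
    for k, cls in enumerate(nls_queue):
        assignments[k % spec.n_nac].append(cls)

    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    partner_pattern = catalog.partners[0] if catalog.partners else None

    for i in range(spec.n_nac):
        rng = _rng_for(spec.seed, i)
        pid = f"nac_{i:04d}"
        n_domains = int(rng.choice(domain_counts, p=domain_weights))
        pieces: list[tuple[str, str, str]] = []  # (feature, class, sequence)
        for _ in range(n_domains):
            pieces.append(("nac_domain", "", _domain_block(catalog, rng)))
        for cls in assignments[i]:
            pieces.append(("nls", cls, make_nls_segment(cls, rng)))
        if rng.random() < spec.tm_fraction:
            tm = "".join(rng.choice(list(_HYDROPHOBIC), size=23))
            pieces.append(("tm", "", tm))
        if partner_pattern is not None and rng.random() < spec.chimeric_fraction:
            pieces.append(
                ("chimeric", partner_pattern[0],
                 instantiate_pattern(partner_pattern[1], rng))
            )
        seq_parts: list[str] = []
        pos = 0
        lead = int(rng.integers(10, 30))
        seq_parts.append(_linker(rng, lead))
        pos += lead
        for feature, cls, segment in pieces:
            start = pos + 1
            seq_parts.append(segment)
            pos += len(segment)
            truth_rows.append(
                {
                    "protein_id": pid,
                    "feature": feature,
                    "nls_class": cls,
                    "start": start,
                    "end": pos,
                    "segment": segment,
                }
            )
            gap = int(rng.integers(12, 40))
            seq_parts.append(_linker(rng, gap))
            pos += gap
        target_len = int(rng.integers(*spec.length_range))
        if pos < target_len:
            seq_parts.append(_linker(rng, target_len - pos))
        residues = "".join(seq_parts)
        records.append(SequenceRecord(id=pid, residues=residues))

    for i in range(spec.n_decoys):
        rng = _rng_for(spec.seed, spec.n_nac + i)
        pid = f"decoy_{i:04d}"
        if spec.n_nac:  # composition-matched shuffle of a NAC protein
            template = records[int(rng.integers(spec.n_nac))].residues
            residues = "".join(rng.permutation(list(template)))
        else:
            residues = "".join(
                rng.choice(list(AA20), size=int(rng.integers(*spec.length_range)))
            )
        records.append(SequenceRecord(id=pid, residues=residues))

    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "feature", "nls_class", "start", "end", "segment"],
    )
    return records, truth


def make_cds(
    proteins: list[SequenceRecord],
    rscu_target: dict[str, float] | None = None,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Back-translate proteins, sampling synonymous codons with the target
    weights (uniform within each family by default); a terminal stop codon
    is appended.  ``rscu_target`` maps codons (DNA or RNA labels) to
    non-negative weights."""
    weights: dict[str, dict[str, float]] = {}
    target = {
        k.upper().replace("U", "T"): float(v) for k, v in (rscu_target or {}).items()
    }
    for aa, codons in FAMILIES.items():
        w = np.array([target.get(c, 1.0) for c in codons], dtype=float)
        if (w < 0).any():
            raise ValueError(f"negative codon weight in family {aa}")
        if w.sum() == 0:
            raise ValueError(f"all-zero codon weights for amino acid {aa}")
        weights[aa] = dict(zip(codons, w / w.sum()))
    out = []
    for idx, rec in enumerate(proteins):
        rng = _rng_for(seed, idx)
        bad = set(rec.residues) - set(weights)
        if bad:
            raise ValueError(
                f"{rec.id}: cannot back-translate residue {sorted(bad)[0]!r}"
            )
        codons = np.empty(len(rec.residues), dtype=object)
        residues = np.array(list(rec.residues))
        for aa in sorted(set(rec.residues)):  # sample per family, vectorized
            positions = np.nonzero(residues == aa)[0]
            fam = weights[aa]
            keys = np.array(list(fam), dtype=object)
            draws = rng.choice(len(keys), size=len(positions),
                               p=list(fam.values()))
            codons[positions] = keys[draws]
        out.append(
            SequenceRecord(
                id=rec.id, residues="".join(codons) + "TAA", alphabet="dna"
            )
        )
    return out


@dataclass
class EvolutionSpec:
    """TN93 simulation conditions: a rooted tree with branch lengths in
    expected substitutions per site, transition/transversion ratios k1
    (purine) and k2 (pyrimidine), base frequencies (A, C, G, T) and the
    alignment length in sites."""

    tree: str | dendropy.Tree
    k1: float = 4.0
    k2: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    length: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1, k2 must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


def tn93_rate_matrix(
    k1: float, k2: float, base_freqs: tuple[float, float, float, float]
) -> np.ndarray:
    """TN93 generator matrix (A,C,G,T), normalized to one expected
    substitution per unit branch length."""
    pi = np.asarray(base_freqs, dtype=float)
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            if (i, j) in ((0, 2), (2, 0)):
                q[i, j] = k1 * pi[j]
            elif (i, j) in ((1, 3), (3, 1)):
                q[i, j] = k2 * pi[j]
            else:
                q[i, j] = pi[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def evolve_alignment(
    spec: EvolutionSpec,
) -> tuple[list[SequenceRecord], str]:
    """Evolve an alignment down the tree under TN93.

    Sites evolve independently; per-branch substitution probabilities are
    the matrix exponential of the normalized TN93 generator.  Returns the
    leaf alignment (ungapped, tree leaf order) and the root sequence.
    """
    tree = (
        spec.tree
        if isinstance(spec.tree, dendropy.Tree)
        else dendropy.Tree.get(data=spec.tree, schema="newick",
                               preserve_underscores=True)
    )
    q = tn93_rate_matrix(spec.k1, spec.k2, spec.base_freqs)
    rng = _rng_for(spec.seed, 0)
    pi = np.asarray(spec.base_freqs)
    root_states = rng.choice(4, size=spec.length, p=pi)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    transition_cache: dict[float, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        if t not in transition_cache:
            transition_cache[t] = expm(q * t) if t > 0 else np.eye(4)
        p = transition_cache[t]
        cum = np.cumsum(p, axis=1)
        parent_states = states[id(node.parent_node)]
        u = rng.random(spec.length)
        states[id(node)] = (u[:, None] > cum[parent_states]).sum(axis=1)
    bases = np.array(list("ACGT"))
    leaves = []
    for i, leaf in enumerate(tree.leaf_node_iter()):
        label = leaf.taxon.label if leaf.taxon else f"leaf_{i}"
        leaves.append(
            SequenceRecord(
                id=label.replace(" ", "_"),
                residues="".join(bases[states[id(leaf)]]),
                alphabet="dna",
            )
        )
    root_seq = "".join(bases[root_states])
    return leaves, root_seq


class _GNode:
    __slots__ = ("children", "species", "is_dup", "name")

    def __init__(self, species: str | None = None):
        self.children: list[_GNode] = []
        self.species = species
        self.is_dup = False
        self.name: str | None = None


def _gnodes(root: _GNode) -> list[_GNode]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _newick(node: _GNode) -> str:
    if not node.children:
        return node.name
    return "(" + ",".join(_newick(c) for c in node.children) + ")"


def make_gene_family(
    species_tree: dendropy.Tree | str,
    n_duplications: int = 0,
    loss_prob: float = 0.0,
    seed: int = 0,
    max_retries: int = 20,
) -> tuple[dendropy.Tree, dict[str, str], dict[str, int]]:
    """Grow a gene family on a binary species tree with known history.

    Duplication events are inserted at uniformly chosen nodes of the growing
    gene tree (the subtree below the point is copied); leaves are then lost
    independently with ``loss_prob`` and unary nodes suppressed.  Returns
    the observable (pruned) rooted gene tree, the gene->species leaf map,
    and the truth dict {"duplications": surviving duplication count,
    "losses": number of pruned gene leaves}.  Degenerate all-lost draws are
    resampled with fresh sub-seeds (bounded retries).
    """
    sp_tree = (
        species_tree
        if isinstance(species_tree, dendropy.Tree)
        else dendropy.Tree.get(data=species_tree, schema="newick",
                               preserve_underscores=True)
    )
    sp_nodes = list(sp_tree.preorder_node_iter())
    for node in sp_nodes:
        if len(node.child_nodes()) not in (0, 2):
            raise ValueError("species tree must be binary")
    for attempt in range(max_retries):
        rng = _rng_for(seed, attempt)
        # forward simulation: each event happens on a uniformly chosen
        # species-tree edge (the edge above a uniformly chosen node), on a
        # uniformly chosen gene lineage traversing that edge
        events = {id(n): 0 for n in sp_nodes}
        for _ in range(n_duplications):
            events[id(sp_nodes[int(rng.integers(len(sp_nodes)))])] += 1

        root = _GNode()
        incoming: dict[int, list[_GNode]] = {id(sp_tree.seed_node): [root]}
        for sp_node in sp_nodes:  # preorder: parent edges processed first
            tips = incoming.pop(id(sp_node))
            for _ in range(events[id(sp_node)]):
                target = tips.pop(int(rng.integers(len(tips))))
                target.is_dup = True
                a, b = _GNode(), _GNode()
                target.children = [a, b]
                tips.extend([a, b])
            if sp_node.is_leaf():
                for tip in tips:
                    tip.species = sp_node.taxon.label
            else:
                children = sp_node.child_nodes()
                for child in children:
                    incoming.setdefault(id(child), [])
                for tip in tips:  # speciation: one copy into each child edge
                    for child in children:
                        g = _GNode()
                        incoming[id(child)].append(g)
                        tip.children.append(g)
        leaves = [n for n in _gnodes(root) if not n.children]
        lost = rng.random(len(leaves)) < loss_prob
        survivors = [lf for lf, dead in zip(leaves, lost) if not dead]
        if not survivors:
            continue
        kept = set(map(id, survivors))

        def prune(node: _GNode) -> _GNode | None:
            if not node.children:
                return node if id(node) in kept else None
            new_children = [c for c in (prune(ch) for ch in node.children) if c]
            if not new_children:
                return None
            if len(new_children) == 1:
                return new_children[0]
            node.children = new_children
            return node

        root = prune(root)
        if root is None or not root.children:
            continue
        counters: dict[str, int] = {}
        leaf_map: dict[str, str] = {}
        for leaf in [n for n in _gnodes(root) if not n.children]:
            counters[leaf.species] = counters.get(leaf.species, 0) + 1
            leaf.name = f"{leaf.species}|g{counters[leaf.species]}"
            leaf_map[leaf.name] = leaf.species
        surviving_dups = sum(
            1 for n in _gnodes(root) if n.is_dup and len(n.children) == 2
        )
        truth = {"duplications": surviving_dups, "losses": int(lost.sum())}
        gene_tree = dendropy.Tree.get(
            data=_newick(root) + ";", schema="newick", preserve_underscores=True
        )
        gene_tree.is_rooted = True
        return gene_tree, leaf_map, truth
    raise RuntimeError("all gene-family draws were degenerate (all genes lost)")
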