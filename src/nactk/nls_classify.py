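"""Taxonomy of nuclear localization signals and linker-collapsed signatures.

Classes, decided in this fixed order (first match wins):

* ``class_III``     — non-canonical importin-beta2 pattern K-R-x-[WFY]-x(2)-A-F
* ``class_IV``      — non-canonical pattern [PR]-x(2)-K-R-[KR]
* ``multipartite``  — three or more clusters of basic residues
* ``bipartite``     — two clusters separated by a linker of 8-24 residues
* ``mono_I``        — a single run of >= 4 consecutive basic residues
* ``mono_II``       — the K-(K/R)-x-(K/R) pattern
* ``unclassified``  — anything else

The non-canonical pattern classes are tested first because they are defined
by sequence, not geometry, and would otherwise be absorbed by cluster
counting.

Cluster model.  Basic clusters start as maximal K/R runs of length >=
``min_run`` (default 2).  A run is merged into an adjacent run when they are
separated by at most ``merge_gap`` (default 4) non-basic residues *and* at
least one of the two runs is an anchor of length >= 3 — two lone pairs never
seed a merge.  This reproduces the canonical bipartite exemplar
K-R-P-A-A-T-K-K-A-G-Q-A-K-K-K-K as two clusters (KR | KK+KKKK): the embedded
KK pair is absorbed into the adjacent KKKK anchor, while KR and KK, both
lone pairs separated by the same 4-residue gap, stay apart.  The bipartite
linker is measured between the *core* runs (longest constituent run) of the
two clusters, which scores the exemplar's linker as the classical 10
residues.

Signatures collapse the linkers: delete every non-K/R residue and keep the
basic residues in order (the paper-style "remove the x's" view of NLS
diversity).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .motif_scan import Pattern, compile_pattern, match_at
from .nls_detect import NlsInterval

BASIC = frozenset("KR")

__all__ = [
    "BasicCluster",
    "NlsCall",
    "NlsSignature",
    "CensusSummary",
    "find_basic_clusters",
    "merge_clusters",
    "classify_nls",
    "collapse_linkers",
    "assign_terminal",
    "signature_census",
]

_CLASS_III: Pattern = compile_pattern("K-R-x-[WFY]-x(2)-A-F")
_CLASS_IV: Pattern = compile_pattern("[PR]-x(2)-K-R-[KR]")
_MONO_II: Pattern = compile_pattern("K-[KR]-x-[KR]")


@dataclass(frozen=True)
class BasicCluster:
    """A cluster of basic residues; 1-based inclusive within the segment.

    ``core_start``/``core_end`` delimit the longest constituent maximal run
    (the cluster "core"); for an unmerged cluster they equal start/end.
    ``n_basic`` counts the basic residues in the cluster span.
    """

    start: int
    end: int
    core_start: int
    core_end: int
    n_basic: int

    @property
    def max_run(self) -> int:
        return self.core_end - self.core_start + 1


def _maximal_runs(segment: str, min_run: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(segment)
    while i < n:
        if segment[i] in BASIC:
            j = i
            while j + 1 < n and segment[j + 1] in BASIC:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i + 1, j + 1))  # 1-based inclusive
            i = j + 1
        else:
            i += 1
    return runs


def find_basic_clusters(segment: str, min_run: int = 2) -> list[BasicCluster]:
    """Maximal K/R runs of length >= ``min_run``, left to right, unmerged."""
    return [
        BasicCluster(start=s, end=e, core_start=s, core_end=e, n_basic=e - s + 1)
        for s, e in _maximal_runs(segment, min_run)
    ]


def merge_clusters(
    clusters: list[BasicCluster],
    segment: str,
    merge_gap: int = 4,
    anchor_len: int = 3,
) -> list[BasicCluster]:
    """Merge adjacent clusters separated by <= ``merge_gap`` non-basic
    residues when at least one of the pair is an anchor (max run >=
    ``anchor_len``).  Single left-to-right pass over the original runs."""
    if not clusters:
        return []
    merged = [clusters[0]]
    for nxt in clusters[1:]:
        cur = merged[-1]
        gap = nxt.start - cur.end - 1
        if gap <= merge_gap and (
            cur.max_run >= anchor_len or nxt.max_run >= anchor_len
        ):
            core = max(
                (cur.core_start, cur.core_end),
                (nxt.core_start, nxt.core_end),
                key=lambda c: (c[1] - c[0], c[0]),
            )
            merged[-1] = BasicCluster(
                start=cur.start,
                end=nxt.end,
                core_start=core[0],
                core_end=core[1],
                n_basic=cur.n_basic + nxt.n_basic,
            )
        else:
            merged.append(nxt)
    return merged


def _matches(pattern: Pattern, segment: str) -> bool:
    return any(match_at(pattern, segment, i) is not None for i in range(len(segment)))


def classify_nls(
    segment: str,
    min_run: int = 2,
    merge_gap: int = 4,
    bipartite_linker: tuple[int, int] = (8, 24),
    mono_i_min_run: int = 4,
    multipartite_min_clusters: int = 3,
) -> str:
    """Assign the NLS taxonomy class of a candidate segment.

    See the module docstring for the decision order and cluster model.
    Segments shorter than 3 residues are ``unclassified``.
    """
    segment = segment.upper()
    if len(segment) < 3:
        return "unclassified"
    if _matches(_CLASS_III, segment):
        return "class_III"
    if _matches(_CLASS_IV, segment):
        return "class_IV"
    clusters = merge_clusters(
        find_basic_clusters(segment, min_run), segment, merge_gap
    )
    if len(clusters) >= multipartite_min_clusters:
        return "multipartite"
    if len(clusters) == 2:
        linker = clusters[1].core_start - clusters[0].core_end - 1
        if bipartite_linker[0] <= linker <= bipartite_linker[1]:
            return "bipartite"
    if len(clusters) == 1 and clusters[0].max_run >= mono_i_min_run:
        return "mono_I"
    if _matches(_MONO_II, segment):
        return "mono_II"
    return "unclassified"


def collapse_linkers(segment: str) -> str:
    """Delete every non-K/R residue, preserving order (idempotent)."""
    return "".join(c for c in segment.upper() if c in BASIC)


@dataclass
class NlsCall:
    """A detected NLS with its class, terminal region and signature."""

    protein_id: str
    interval: NlsInterval
    segment: str
    nls_class: str
    clusters: list[BasicCluster]
    terminal: str  # 'N' or 'C'
    signature: str = ""

    def __post_init__(self) -> None:
        if not self.signature:
            self.signature = collapse_linkers(self.segment)


def assign_terminal(start: int, end: int, protein_length: int) -> str:
    """'N' iff the interval midpoint falls in the N-terminal half.

    Midpoint = (start + end) / 2 on 1-based inclusive coordinates; exactly
    half-way counts as N-terminal.
    """
    if not 1 <= start <= end <= protein_length:
        raise ValueError(
            f"interval {start}-{end} outside protein of length {protein_length}"
        )
    return "N" if (start + end) / 2 <= protein_length / 2 else "C"


def make_call(
    protein_id: str,
    interval: NlsInterval,
    protein_residues: str,
) -> NlsCall:
    """Build a classified NlsCall from a detector interval."""
    segment = protein_residues[interval.start - 1 : interval.end]
    clusters = merge_clusters(find_basic_clusters(segment), segment)
    return NlsCall(
        protein_id=protein_id,
        interval=interval,
        segment=segment,
        nls_class=classify_nls(segment),
        clusters=clusters,
        terminal=assign_terminal(interval.start, interval.end, len(protein_residues)),
    )


@dataclass(frozen=True)
class NlsSignature:
    signature: str
    count_n_terminal: int
    count_c_terminal: int


@dataclass(frozen=True)
class CensusSummary:
    n_unique_n: int
    n_unique_c: int
    n_shared: int
    n_only_n: int
    n_only_c: int


def signature_census(calls: list[NlsCall]) -> tuple[list[NlsSignature], CensusSummary]:
    """Count linker-collapsed signatures per terminal region.

    Returns per-signature occurrence counts (sorted by total count then
    signature) and the unique/shared summary across the N and C sets.
    """
    n_counts: Counter[str] = Counter()
    c_counts: Counter[str] = Counter()
    for call in calls:
        if not call.signature:
            continue
        (n_counts if call.terminal == "N" else c_counts)[call.signature] += 1
    signatures = [
        NlsSignature(
            signature=sig,
            count_n_terminal=n_counts.get(sig, 0),
            count_c_terminal=c_counts.get(sig, 0),
        )
        for sig in set(n_counts) | set(c_counts)
    ]
    signatures.sort(
        key=lambda s: (-(s.count_n_terminal + s.count_c_terminal), s.signature)
    )
    n_set, c_set = set(n_counts), set(c_counts)
    summary = CensusSummary(
        n_unique_n=len(n_set),
        n_unique_c=len(c_set),
        n_shared=len(n_set & c_set),
        n_only_n=len(n_set - c_set),
        n_only_c=len(c_set - n_set),
    )
    return signatures, summary
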