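"""PROSITE-style pattern engine and NAC domain architecture calls.

The NAC DNA-binding domain is recognized here the way large plant-TF surveys
confirm it: by co-occurrence of short consensus signature motifs (e.g.
``E-W-Y-F-F``, ``T-x-W-x-M-H-E-Y``) in their canonical N->C order, rather than
by a profile HMM.  A domain instance is called when at least
``min_core_motifs`` distinct core motifs from the shipped catalog co-occur, in
order, within a fixed residue window.  Proteins with two or more instances are
multi-domain; non-NAC catalog patterns matching outside called instances flag
chimeric architectures.  The hydrophobic L-V-F-Y nuclear export signal (with
the L-V/I-F-M substitution class) is detected separately.

Pattern grammar (PROSITE-flavoured): elements separated by ``-``; ``x``
wildcard with optional ``x(n)`` / ``x(n,m)`` repeats; ``[AB]`` any-of;
``{AB}`` none-of; the ``A/B`` shorthand is normalized to ``[AB]``.  An ``X``
in a *sequence* matches any fixed-residue element (unknown residue wildcard).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "PatternError",
    "Pattern",
    "MotifHit",
    "DomainSummary",
    "Catalog",
    "compile_pattern",
    "scan",
    "match_at",
    "detect_nes",
    "count_nac_domains",
    "load_catalog",
    "default_catalog",
]


class PatternError(ValueError):
    """Malformed PROSITE-style pattern."""


@dataclass(frozen=True)
class _Fixed:
    residue: str

    def token(self) -> str:
        return self.residue


@dataclass(frozen=True)
class _AnyOf:
    residues: str  # sorted, deduplicated

    def token(self) -> str:
        return f"[{self.residues}]"


@dataclass(frozen=True)
class _NoneOf:
    residues: str

    def token(self) -> str:
        return "{%s}" % self.residues


@dataclass(frozen=True)
class _Wildcard:
    min_rep: int
    max_rep: int

    def token(self) -> str:
        if (self.min_rep, self.max_rep) == (1, 1):
            return "x"
        if self.min_rep == self.max_rep:
            return f"x({self.min_rep})"
        return f"x({self.min_rep},{self.max_rep})"


_Element = _Fixed | _AnyOf | _NoneOf | _Wildcard


@dataclass(frozen=True)
class Pattern:
    """A compiled pattern; equality is structural on the element list."""

    source: str
    elements: tuple[_Element, ...]
    _regex: re.Pattern = field(compare=False, repr=False, hash=False, default=None)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pattern) and self.elements == other.elements

    def __hash__(self) -> int:
        return hash(self.elements)

    def decompile(self) -> str:
        """Canonical PROSITE string; ``compile_pattern`` round-trips it."""
        return "-".join(el.token() for el in self.elements)


_WILDCARD_RE = re.compile(r"^x(?:\((\d+)(?:,(\d+))?\))?$")


def _check_residues(letters: str, token: str) -> str:
    for c in letters:
        if c not in AA20:
            raise PatternError(f"unknown residue letter {c!r} in {token!r}")
    return "".join(sorted(set(letters)))


def _parse_token(token: str) -> _Element:
    m = _WILDCARD_RE.match(token)
    if m:
        lo = int(m.group(1)) if m.group(1) else 1
        hi = int(m.group(2)) if m.group(2) else lo
        if lo > hi:
            raise PatternError(f"malformed repeat range in {token!r} ({lo} > {hi})")
        return _Wildcard(lo, hi)
    if token.startswith("[") and token.endswith("]"):
        inner = token[1:-1]
        if not inner:
            raise PatternError(f"empty residue class in {token!r}")
        return _AnyOf(_check_residues(inner, token))
    if token.startswith("{") and token.endswith("}"):
        inner = token[1:-1]
        if not inner:
            raise PatternError(f"empty excluded class in {token!r}")
        return _NoneOf(_check_residues(inner, token))
    if "/" in token:  # A/B shorthand -> [AB]
        letters = token.split("/")
        if any(len(p) != 1 for p in letters):
            raise PatternError(f"malformed alternative {token!r}")
        return _AnyOf(_check_residues("".join(letters), token))
    if len(token) == 1:
        _check_residues(token, token)
        return _Fixed(token)
    raise PatternError(f"cannot parse pattern token {token!r}")


def _element_regex(el: _Element) -> str:
    if isinstance(el, _Fixed):
        return f"[{el.residue}X]"  # sequence X matches any fixed element
    if isinstance(el, _AnyOf):
        return f"[{el.residues}]"
    if isinstance(el, _NoneOf):
        return f"[^{el.residues}]"
    return ".{%d,%d}" % (el.min_rep, el.max_rep)


def compile_pattern(prosite: str) -> Pattern:
    """Compile a PROSITE-style pattern to its matcher.

    The match semantics equal the corresponding regular expression on the
    20-letter alphabet (greedy wildcard repeats, backtracking).
    """
    tokens = [t for t in prosite.strip().rstrip(".").split("-") if t]
    if not tokens:
        raise PatternError("empty pattern")
    elements = tuple(_parse_token(t) for t in tokens)
    regex = re.compile("".join(_element_regex(el) for el in elements))
    return Pattern(source=prosite.strip(), elements=elements, _regex=regex)


@dataclass(frozen=True)
class MotifHit:
    """A located pattern match; positions are 1-based inclusive."""

    protein_id: str
    pattern_name: str
    start: int
    end: int
    matched: str


@dataclass
class DomainSummary:
    protein_id: str
    nac_domain_count: int
    is_nac: bool
    is_multi_domain: bool
    chimeric_partners: list[str]
    nes_hits: list[MotifHit]
    domain_intervals: list[tuple[int, int]] = field(default_factory=list)


def match_at(pattern: Pattern, residues: str, pos: int) -> int | None:
    """Greedy match of ``pattern`` anchored at 0-based ``pos``; returns the
    0-based exclusive end of the match, or None."""
    m = pattern._regex.match(residues, pos)
    return m.end() if m else None


def scan(
    seq: SequenceRecord,
    pattern: Pattern,
    pattern_name: str = "pattern",
    overlapping: bool = True,
) -> list[MotifHit]:
    """All (greedy, one per start position) hits of ``pattern`` in ``seq``.

    With ``overlapping=False`` a greedy left-to-right non-overlapping subset
    is returned.  Nucleotide input is rejected.
    """
    if seq.alphabet != "protein":
        raise ValueError(f"{seq.id}: motif scan requires protein input")
    hits: list[MotifHit] = []
    for pos in range(len(seq.residues)):
        end = match_at(pattern, seq.residues, pos)
        if end is not None and end > pos:
            hits.append(
                MotifHit(
                    protein_id=seq.id,
                    pattern_name=pattern_name,
                    start=pos + 1,
                    end=end,
                    matched=seq.residues[pos:end],
                )
            )
    if overlapping:
        return hits
    selected: list[MotifHit] = []
    last_end = 0
    for hit in hits:  # already sorted by start
        if hit.start > last_end:
            selected.append(hit)
            last_end = hit.end
    return selected


_NES_PATTERNS = [("nes_class", "L-[VI]-[FM]-[YM]"), ("nes_exact", "L-V-F-Y")]


def detect_nes(seq: SequenceRecord) -> list[MotifHit]:
    """Hydrophobic nuclear-export-signal motifs (L-V-F-Y and its
    L-V/I-F-M substitution class); duplicate intervals merged."""
    seen: set[tuple[int, int]] = set()
    merged: list[MotifHit] = []
    for _, pat_str in _NES_PATTERNS:
        for hit in scan(seq, compile_pattern(pat_str), pattern_name="nes_lvfy"):
            key = (hit.start, hit.end)
            if key not in seen:
                seen.add(key)
                merged.append(hit)
    merged.sort(key=lambda h: (h.start, h.end))
    return merged


@dataclass
class Catalog:
    """Named pattern set: NAC core motifs (canonical order = file order),
    NES motifs, and optional non-NAC partner patterns."""

    core: list[tuple[str, Pattern]]
    nes: list[tuple[str, Pattern]]
    partners: list[tuple[str, Pattern]]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.core + self.nes + self.partners]


def load_catalog(path: str | Path) -> Catalog:
    """Load a catalog TSV: ``name<TAB>role<TAB>prosite`` (role optional,
    default ``core``); ``#`` lines are comments."""
    core, nes, partners = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                name, role, pat = parts[0], "core", parts[1]
            else:
                name, role, pat = parts[0], parts[1], parts[2]
            entry = (name, compile_pattern(pat))
            {"core": core, "nes": nes, "partner": partners}[role].append(entry)
    if not (core or nes or partners):
        raise PatternError(f"{path}: empty catalog")
    return Catalog(core=core, nes=nes, partners=partners)


def default_catalog() -> Catalog:
    with resources.as_file(
        resources.files("nactk.data") / "nac_motifs.tsv"
    ) as path:
        return load_catalog(path)


def _best_chain(
    hits: list[tuple[int, int, int]], window: int
) -> list[tuple[int, int, int]] | None:
    """Longest chain of motif hits (start, end, core_index) with strictly
    increasing core index and non-overlapping positions, anchored at the
    first hit, all starts within ``window`` of the anchor."""
    if not hits:
        return None
    anchor_start = hits[0][0]
    pool = [h for h in hits if h[0] - anchor_start < window]
    # DP over pool (sorted by start): longest increasing-core-index chain of
    # non-overlapping hits that begins with the anchor hit pool[0].
    best: list[list[tuple[int, int, int]] | None] = [None] * len(pool)
    best[0] = [pool[0]]
    for i in range(1, len(pool)):
        h = pool[i]
        for j in range(i):
            prev = best[j]
            if prev is None:
                continue
            last = prev[-1]
            if h[2] > last[2] and h[0] >= last[1]:
                cand = prev + [h]
                if (
                    best[i] is None
                    or len(cand) > len(best[i])
                    or (len(cand) == len(best[i]) and cand[-1][1] > best[i][-1][1])
                ):
                    best[i] = cand
    chains = [c for c in best if c is not None]
    return max(chains, key=lambda c: (len(c), c[-1][1]))


def count_nac_domains(
    seq: SequenceRecord,
    catalog: Catalog | None = None,
    min_core_motifs: int = 3,
    window: int = 200,
) -> DomainSummary:
    """Call NAC domain instances and summarize the protein's architecture.

    A domain instance requires ``min_core_motifs`` distinct core motifs in
    canonical order within ``window`` residues; instances are selected
    greedily left to right (leftmost start, then longest) and never overlap.
    """
    if catalog is None:
        catalog = default_catalog()
    if not catalog.core:
        raise PatternError("catalog has no core motifs")
    all_hits: list[tuple[int, int, int]] = []  # (start0, end0_excl, core_idx)
    for idx, (name, pattern) in enumerate(catalog.core):
        for hit in scan(seq, pattern, pattern_name=name):
            all_hits.append((hit.start - 1, hit.end, idx))
    all_hits.sort()
    intervals: list[tuple[int, int]] = []
    pos = 0
    remaining = all_hits
    while remaining:
        remaining = [h for h in remaining if h[0] >= pos]
        called = False
        for i, anchor in enumerate(remaining):
            chain = _best_chain(remaining[i:], window)
            if chain is not None and len(chain) >= min_core_motifs:
                start0, end0 = chain[0][0], chain[-1][1]
                intervals.append((start0 + 1, end0))  # 1-based inclusive
                pos = end0
                called = True
                break
        if not called:
            break
    count = len(intervals)
    partners: set[str] = set()
    for name, pattern in catalog.partners:
        for hit in scan(seq, pattern, pattern_name=name):
            inside = any(hit.start >= s and hit.end <= e for s, e in intervals)
            if not inside:
                partners.add(name)
    return DomainSummary(
        protein_id=seq.id,
        nac_domain_count=count,
        is_nac=count >= 1,
        is_multi_domain=count >= 2,
        chimeric_partners=sorted(partners),
        nes_hits=detect_nes(seq),
        domain_intervals=intervals,
    )
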