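"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nactk.motif_scan import _AnyOf, _Fixed, _NoneOf, _Wildcard, Pattern
from nactk.synthetic_data import ProteomeSpec, make_proteome

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def small_proteome():
    """A small synthetic proteome with its truth table (fixed seed)."""
    spec = ProteomeSpec(n_nac=12, n_decoys=8, seed=11)
    return make_proteome(spec)


# ------------------------------------------------------------------ oracles


def brute_force_match(pattern: Pattern, seq: str, pos: int) -> int | None:
    """Naive position-by-position backtracking matcher (greedy repeats),
    independent of the regex-based engine; returns the 0-based exclusive
    match end or None."""
    elements = pattern.elements

    def rec(ei: int, p: int) -> int | None:
        if ei == len(elements):
            return p
        el = elements[ei]
        if isinstance(el, _Wildcard):
            for n in range(el.max_rep, el.min_rep - 1, -1):  # greedy first
                if p + n <= len(seq):
                    r = rec(ei + 1, p + n)
                    if r is not None:
                        return r
            return None
        if p >= len(seq):
            return None
        c = seq[p]
        if isinstance(el, _Fixed):
            ok = c == el.residue or c == "X"
        elif isinstance(el, _AnyOf):
            ok = c in el.residues
        else:
            ok = c not in el.residues
        return rec(ei + 1, p + 1) if ok else None

    return rec(0, pos)


def random_pattern_string(rng: np.random.Generator) -> str:
    """Random PROSITE-style pattern over the supported grammar."""
    n = int(rng.integers(2, 7))
    tokens = []
    for _ in range(n):
        kind = rng.integers(5)
        if kind == 0:
            tokens.append(AA20[rng.integers(20)])
        elif kind == 1:
            k = int(rng.integers(2, 4))
            tokens.append("[" + "".join(rng.choice(list(AA20), k, replace=False)) + "]")
        elif kind == 2:
            k = int(rng.integers(1, 4))
            tokens.append("{" + "".join(rng.choice(list(AA20), k, replace=False)) + "}")
        elif kind == 3:
            tokens.append("x")
        else:
            lo = int(rng.integers(1, 3))
            hi = lo + int(rng.integers(0, 3))
            tokens.append(f"x({lo},{hi})" if hi > lo else f"x({lo})")
    return "-".join(tokens)


def random_protein(rng: np.random.Generator, lo: int = 10, hi: int = 41,
                   x_prob: float = 0.02) -> str:
    length = int(rng.integers(lo, hi))
    letters = rng.choice(list(AA20), length)
    if x_prob:
        mask = rng.random(length) < x_prob
        letters[mask] = "X"
    return "".join(letters)


def enumerate_hmm(symbols: list[int], params) -> tuple[float, np.ndarray]:
    """Exhaustive path enumeration over the 2-state HMM.

    Returns (max path probability, per-position marginal P(state=1)).
    Symbols index the emission columns; -1 means uninformative.
    """
    n = len(symbols)
    best = 0.0
    marg = np.zeros(n)
    total = 0.0
    for code in range(2 ** n):
        path = [(code >> t) & 1 for t in range(n)]
        p = params.initial[path[0]]
        p *= params.emission[path[0], symbols[0]] if symbols[0] >= 0 else 1.0
        for t in range(1, n):
            p *= params.transition[path[t - 1], path[t]]
            p *= params.emission[path[t], symbols[t]] if symbols[t] >= 0 else 1.0
        best = max(best, p)
        total += p
        for t in range(n):
            if path[t]:
                marg[t] += p
    return best, marg / total if total > 0 else marg
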