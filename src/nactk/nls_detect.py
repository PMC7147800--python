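"""Two-state hidden Markov model detection of nuclear localization signals.

A static (untrained) 2-state HMM — background (BG) vs NLS — decoded by
Viterbi or by posterior (forward-backward) with a per-position probability
cutoff, the configuration used by NLStradamus-style NLS predictors.  The
shipped default parameters make the NLS state strongly prefer the basic
residues K and R; they live in an editable TSV and any parameter file with
the same (section, key, value) layout can be loaded.

Viterbi runs in log space; forward-backward uses per-position scaling, so
arbitrarily long proteins decode without underflow.  Decoding is
deterministic: ties in the Viterbi recursion break toward BG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

BG, NLS = 0, 1  # state order: ties break toward the lower (BG) index

__all__ = [
    "HmmParams",
    "NlsInterval",
    "load_hmm_params",
    "default_hmm_params",
    "viterbi",
    "posterior",
    "call_nls",
    "intervals_from_mask",
    "forward_backward",
    "ZeroProbabilityError",
]


class ZeroProbabilityError(ValueError):
    """All state paths for the sequence have probability zero."""


@dataclass(frozen=True)
class HmmParams:
    """Initial, transition and emission probabilities of the 2-state HMM.

    ``initial``: shape (2,); ``transition``: shape (2, 2) row-stochastic;
    ``emission``: shape (2, 20) over the amino acids in alphabetical
    one-letter order.  State 0 is BG, state 1 is NLS.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        init = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        emit = np.asarray(self.emission, dtype=float)
        object.__setattr__(self, "initial", init)
        object.__setattr__(self, "transition", trans)
        object.__setattr__(self, "emission", emit)
        if init.shape != (2,) or trans.shape != (2, 2) or emit.shape != (2, 20):
            raise ValueError("HmmParams shapes must be (2,), (2,2), (2,20)")
        if (init < 0).any() or (trans < 0).any() or (emit < 0).any():
            raise ValueError("probabilities must be non-negative")
        for name, row_sums in [
            ("initial", [init.sum()]),
            ("transition", trans.sum(axis=1)),
            ("emission", emit.sum(axis=1)),
        ]:
            for s in row_sums:
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(f"{name} row sums to {s}, not 1")


def load_hmm_params(path: str | Path) -> HmmParams:
    """Load parameters from a (section, key, value) TSV.

    Sections: ``initial`` (key = state), ``transition`` (key = "from,to"),
    ``emission`` (key = "state,residue").  States are named BG and NLS.
    """
    state_idx = {"BG": BG, "NLS": NLS}
    initial = np.zeros(2)
    transition = np.zeros((2, 2))
    emission = np.zeros((2, 20))
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            section, key, value = line.split("\t")
            v = float(value)
            if section == "initial":
                initial[state_idx[key]] = v
            elif section == "transition":
                a, b = key.split(",")
                transition[state_idx[a], state_idx[b]] = v
            elif section == "emission":
                s, res = key.split(",")
                emission[state_idx[s], _AA_INDEX[res]] = v
            else:
                raise ValueError(f"unknown section {section!r}")
    return HmmParams(initial=initial, transition=transition, emission=emission)


def default_hmm_params() -> HmmParams:
    with resources.as_file(
        resources.files("nactk.data") / "nls_hmm_default.tsv"
    ) as path:
        return load_hmm_params(path)


def _encode(seq: SequenceRecord) -> np.ndarray:
    if seq.alphabet != "protein":
        raise ValueError(f"{seq.id}: NLS detection requires protein input")
    # X carries no emission information: treated as missing (uniform evidence)
    return np.array([_AA_INDEX.get(res, -1) for res in seq.residues])


def _emission_column(params: HmmParams, symbol: int) -> np.ndarray:
    if symbol < 0:  # X: uninformative
        return np.ones(2)
    return params.emission[:, symbol]


def viterbi(seq: SequenceRecord, params: HmmParams) -> list[int]:
    """Maximum-probability state path (log space); ties toward BG."""
    symbols = _encode(seq)
    n = len(symbols)
    with np.errstate(divide="ignore"):
        log_init = np.log(params.initial)
        log_trans = np.log(params.transition)
        log_emit = np.log(params.emission)
    score = np.full((n, 2), -np.inf)
    back = np.zeros((n, 2), dtype=int)
    with np.errstate(divide="ignore"):
        e0 = np.log(_emission_column(params, symbols[0]))
    score[0] = log_init + e0
    for t in range(1, n):
        with np.errstate(divide="ignore"):
            e = np.log(_emission_column(params, symbols[t]))
        for j in (BG, NLS):
            cand = score[t - 1] + log_trans[:, j]
            # argmax with ties toward BG (index 0)
            best = BG if cand[BG] >= cand[NLS] else NLS
            score[t, j] = cand[best] + e[j]
            back[t, j] = best
    if not np.isfinite(score[n - 1].max()):
        raise ZeroProbabilityError(f"{seq.id}: no state path has positive probability")
    last = BG if score[n - 1, BG] >= score[n - 1, NLS] else NLS
    path = [last]
    for t in range(n - 1, 0, -1):
        last = back[t, last]
        path.append(last)
    path.reverse()
    return path


def forward_backward(
    seq: SequenceRecord, params: HmmParams
) -> tuple[np.ndarray, float]:
    """Scaled forward-backward.

    Returns (posteriors over states, shape (L, 2)) and the log-likelihood
    of the sequence.
    """
    symbols = _encode(seq)
    n = len(symbols)
    alpha = np.zeros((n, 2))
    beta = np.zeros((n, 2))
    scale = np.zeros(n)
    alpha[0] = params.initial * _emission_column(params, symbols[0])
    scale[0] = alpha[0].sum()
    if scale[0] == 0:
        raise ZeroProbabilityError(f"{seq.id}: zero-probability sequence")
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ params.transition) * _emission_column(
            params, symbols[t]
        )
        scale[t] = alpha[t].sum()
        if scale[t] == 0:
            raise ZeroProbabilityError(f"{seq.id}: zero-probability sequence")
        alpha[t] /= scale[t]
    beta[n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (
            params.transition
            @ (_emission_column(params, symbols[t + 1]) * beta[t + 1])
        ) / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.log(scale).sum())


def posterior(seq: SequenceRecord, params: HmmParams) -> np.ndarray:
    """Per-position posterior probability of the NLS state."""
    post, _ = forward_backward(seq, params)
    return post[:, NLS]


@dataclass(frozen=True)
class NlsInterval:
    """A called NLS; positions are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    decoder: str
    mean_posterior: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def intervals_from_mask(mask, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal True runs of length >= ``min_len`` as 1-based inclusive
    intervals — the run rule shared by both decoders."""
    return [(i + 1, j + 1) for i, j in _runs(np.asarray(mask, dtype=bool))
            if j - i + 1 >= min_len]


def call_nls(
    seq: SequenceRecord,
    params: HmmParams | None = None,
    cutoff: float = 0.4,
    decoder: str = "posterior",
    min_len: int = 4,
) -> list[NlsInterval]:
    """Call NLS intervals with the chosen decoder.

    ``posterior``: maximal runs of positions with P(NLS) >= cutoff;
    ``viterbi``: maximal runs of the NLS state.  Runs shorter than
    ``min_len`` are dropped.  The reported ``mean_posterior`` is always the
    posterior mean over the interval.
    """
    if params is None:
        params = default_hmm_params()
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    if decoder not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decoder {decoder!r}")
    post = posterior(seq, params)
    if decoder == "posterior":
        mask = post >= cutoff
    else:
        mask = np.array(viterbi(seq, params)) == NLS
    return [
        NlsInterval(
            protein_id=seq.id,
            start=start,
            end=end,
            decoder=decoder,
            mean_posterior=float(post[start - 1 : end].mean()),
        )
        for start, end in intervals_from_mask(mask, min_len)
    ]
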