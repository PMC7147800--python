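"""Molecular weight, isoelectric point and hydropathy-based membrane profiling.

MW uses standard average residue masses (condensation polymer plus one water).
The isoelectric point is the bisection root of the Henderson-Hasselbalch net
charge over the N-/C-termini and the seven ionizable side chains; pKa tables
are shipped as named data (``emboss`` default, ``sillero`` alternative)
because published pI calculators differ only in that table.

Transmembrane segments are called with a documented Kyte-Doolittle sliding
window rather than a trained topology model: maximal runs of windows whose
mean hydropathy clears a threshold.  The output column is named
``tm_segments_hydropathy`` to make the method explicit; externally computed
TM calls can be supplied via TSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .sequence_io import SequenceRecord

__all__ = [
    "PhyschemProfile",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "classify_pi",
    "tm_scan",
    "load_pka_table",
    "WATER_MASS",
]

# Spec'd condensation water mass; the MW additivity identity
# mw(a+b) == mw(a) + mw(b) - WATER_MASS holds exactly.
WATER_MASS = 18.02

_POSITIVE = "KRH"  # plus N-terminus
_NEGATIVE = "DECY"  # plus C-terminus


def _load_table(name: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with resources.as_file(resources.files("nactk.data") / name) as path:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                out["\t".join(parts[:-1])] = float(parts[-1])
    return out


def _residue_masses() -> dict[str, float]:
    return _load_table("residue_masses.tsv")


def load_pka_table(name: str = "emboss") -> dict[str, float]:
    """Named pKa table: keys are 'nterm', 'cterm' and the ionizable residues."""
    raw = _load_table("pka_tables.tsv")
    table = {
        key.split("\t")[1]: val
        for key, val in raw.items()
        if key.split("\t")[0] == name
    }
    if not table:
        known = sorted({k.split("\t")[0] for k in raw})
        raise KeyError(f"unknown pKa table {name!r}; available: {known}")
    return table


def _hydropathy() -> dict[str, float]:
    return _load_table("hydropathy_kd.tsv")


_MASSES = _residue_masses()
_KD = _hydropathy()


@dataclass
class PhyschemProfile:
    protein_id: str
    length: int
    mw_da: float
    pi: float
    charge_class: str
    tm_segments: list[tuple[int, int]]
    is_membrane_bound: bool


def molecular_weight(seq: SequenceRecord) -> float:
    """Average-isotopic molecular weight in daltons.

    X (unknown residue) has no defined mass and raises, naming the position.
    """
    if seq.alphabet != "protein":
        raise ValueError(f"{seq.id}: molecular weight requires protein input")
    total = WATER_MASS
    for pos, res in enumerate(seq.residues):
        if res not in _MASSES:
            raise ValueError(
                f"{seq.id}: residue {res!r} at position {pos + 1} has no mass"
            )
        total += _MASSES[res]
    return total


def net_charge(
    seq: SequenceRecord, ph: float, pka_table: str | dict[str, float] = "emboss"
) -> float:
    """Henderson-Hasselbalch net charge at ``ph`` (elementary charges)."""
    if not 0 <= ph <= 14:
        raise ValueError(f"pH {ph} outside [0, 14]")
    table = load_pka_table(pka_table) if isinstance(pka_table, str) else pka_table
    charge = 1.0 / (1.0 + 10 ** (ph - table["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (table["cterm"] - ph))
    for res in seq.residues:
        if res in "KRH":
            charge += 1.0 / (1.0 + 10 ** (ph - table[res]))
        elif res in "DECY":
            charge -= 1.0 / (1.0 + 10 ** (table[res] - ph))
    return charge


def isoelectric_point(
    seq: SequenceRecord, pka_table: str | dict[str, float] = "emboss"
) -> float:
    """pH at which the net charge vanishes (bisection on [0, 14]).

    The charge is strictly decreasing in pH and positive at 0, negative at
    14, so the root always exists and is unique.  Converged well below the
    reported 1e-4 pH tolerance.
    """
    table = load_pka_table(pka_table) if isinstance(pka_table, str) else pka_table
    lo, hi = 0.0, 14.0
    for _ in range(60):  # 14 / 2^60 << 1e-4
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_pi(pi: float, threshold: float = 7.0) -> str:
    """``acidic`` iff pi < threshold (default 7.0), else ``basic``."""
    return "acidic" if pi < threshold else "basic"


def tm_scan(
    seq: SequenceRecord, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Candidate transmembrane segments from mean Kyte-Doolittle hydropathy.

    Maximal unions of overlapping ``window``-length windows whose mean
    hydropathy is >= ``threshold``; 1-based inclusive intervals, each at
    least ``window`` residues long.  A sequence shorter than the window
    yields no calls.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(seq.residues)
    if n < window:
        return []
    values = np.array([_KD[res] for res in seq.residues])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    above = means >= threshold
    segments: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            segments.append((i + 1, j + window))  # 1-based inclusive
            i = j + 1
        else:
            i += 1
    return segments


def profile(
    seq: SequenceRecord,
    pka_table: str = "emboss",
    pi_threshold: float = 7.0,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
) -> PhyschemProfile:
    """Full physicochemical profile for one protein.

    Proteins containing X get ``mw_da = nan`` (mass undefined) but still
    receive a pI and TM profile.
    """
    try:
        mw = molecular_weight(seq)
    except ValueError:
        mw = float("nan")
    pi = isoelectric_point(seq, pka_table)
    tm = tm_scan(seq, window=tm_window, threshold=tm_threshold)
    return PhyschemProfile(
        protein_id=seq.id,
        length=len(seq.residues),
        mw_da=mw,
        pi=pi,
        charge_class=classify_pi(pi, pi_threshold),
        tm_segments=tm,
        is_membrane_bound=bool(tm),
    )
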