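"""Molecular formulae, element constraints and CHNOSP formula enumeration.

Everything downstream works on neutral molecular formulae over the elements
C, H, N, O, S and P, the composition space used for negative-mode ESI
FTICR-MS analysis of natural organic matter. Peaks are singly deprotonated
ions ([M-H]-), so a measured m/z maps to a neutral monoisotopic mass by
adding one proton mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, NamedTuple

import numpy as np

# Exact monoisotopic masses (Da)
MASS_C = 12.0
MASS_H = 1.00782503
MASS_N = 14.00307401
MASS_O = 15.99491462
MASS_S = 31.97207069
MASS_P = 30.97376200

#: mass added to m/z of an [M-H]- ion to recover the neutral mass
PROTON_MASS = 1.00727646
#: mass difference between 13C and 12C
C13_DELTA = 1.0033548
#: natural 13C/12C abundance ratio per carbon atom
C13_ABUNDANCE = 0.0107

ELEMENT_MASSES = (MASS_C, MASS_H, MASS_N, MASS_O, MASS_S, MASS_P)

#: homologous-series building blocks as (composition delta, mass delta / Da)
SERIES_BLOCKS: dict[str, tuple[tuple[int, int, int, int, int, int], float]] = {
    "CH2": ((1, 2, 0, 0, 0, 0), 14.015650),
    "CO2": ((1, 0, 0, 2, 0, 0), 43.989830),
    "H2": ((0, 2, 0, 0, 0, 0), 2.015650),
    "H2O": ((0, 2, 0, 1, 0, 0), 18.010565),
    "O": ((0, 0, 0, 1, 0, 0), 15.994915),
}


class MolecularFormula(NamedTuple):
    """Neutral CHNOSP molecular formula with integer element counts."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return (
            MASS_C * self.c
            + MASS_H * self.h
            + MASS_N * self.n
            + MASS_O * self.o
            + MASS_S * self.s
            + MASS_P * self.p
        )

    @property
    def mz_neg(self) -> float:
        """Theoretical m/z of the singly charged [M-H]- ion."""
        return self.mass - PROTON_MASS

    @property
    def dbe(self) -> float:
        """Double-bond equivalents, 1 + (2C - H + N + P)/2."""
        return 1.0 + (2 * self.c - self.h + self.n + self.p) / 2.0

    @property
    def heteroatoms(self) -> int:
        return self.n + self.s + self.p

    def is_valid(self) -> bool:
        """Integer DBE >= 0 and at least one carbon."""
        if self.c < 1 or min(self) < 0:
            return False
        dbe2 = 2 * self.c - self.h + self.n + self.p + 2
        return dbe2 >= 0 and dbe2 % 2 == 0

    def hill(self) -> str:
        """Hill-order string with explicit counts, e.g. ``C6H10O5``."""
        parts = []
        for sym, count in (
            ("C", self.c), ("H", self.h), ("N", self.n),
            ("O", self.o), ("P", self.p), ("S", self.s),
        ):
            if count > 0:
                parts.append(f"{sym}{count}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a formula string such as ``C6H10O5`` or ``CH4``."""
        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0, "P": 0}
        pos = 0
        for m in re.finditer(r"([CHNOSP])(\d*)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula string {text!r}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(text) or pos == 0:
            raise ValueError(f"cannot parse formula string {text!r}")
        return cls(counts["C"], counts["H"], counts["N"],
                   counts["O"], counts["S"], counts["P"])

    def shift(self, delta: tuple[int, int, int, int, int, int],
              sign: int = 1) -> "MolecularFormula":
        """Composition shifted by a series block (sign +1 or -1)."""
        return MolecularFormula(*(a + sign * d for a, d in zip(self, delta)))


@dataclass(frozen=True)
class ElementConstraints:
    """Element count bounds and validity screens for formula assignment.

    Defaults follow common practice for natural DOM: C 1-100, H 0-200,
    N 0-4, O 0-50, S 0-2, P 0-1, with elemental-ratio screens
    (H/C in [0.3, 2.5], O/C <= 1.2) that suppress chemically implausible
    candidates at high mass. The screens can be disabled.
    """

    c_min: int = 1
    c_max: int = 100
    h_min: int = 0
    h_max: int = 200
    n_min: int = 0
    n_max: int = 4
    o_min: int = 0
    o_max: int = 50
    s_min: int = 0
    s_max: int = 2
    p_min: int = 0
    p_max: int = 1
    mass_min: float = 100.0
    mass_max: float = 1000.0
    ratio_screens: bool = True
    hc_min: float = 0.3
    hc_max: float = 2.5
    oc_max: float = 1.2

    def __post_init__(self) -> None:
        for el in "chnosp":
            lo = getattr(self, f"{el}_min")
            hi = getattr(self, f"{el}_max")
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid bounds for element {el.upper()}: "
                                 f"[{lo}, {hi}]")
        if self.mass_min <= 0 or self.mass_min > self.mass_max:
            raise ValueError("invalid mass window")

    def admits(self, f: MolecularFormula) -> bool:
        """Whether a formula satisfies the box, screens and validity rules."""
        if not f.is_valid():
            return False
        for el, count in zip("chnosp", f):
            if not getattr(self, f"{el}_min") <= count <= getattr(self, f"{el}_max"):
                return False
        if not self.mass_min <= f.mass <= self.mass_max:
            return False
        if self.ratio_screens:
            hc = f.h / f.c
            if not (self.hc_min <= hc <= self.hc_max):
                return False
            if f.o / f.c > self.oc_max:
                return False
        return True


class FormulaTable(NamedTuple):
    """All formulae admitted by a constraint set, sorted by neutral mass."""

    counts: np.ndarray  # (n, 6) int16, columns c,h,n,o,s,p
    masses: np.ndarray  # (n,) float64, ascending

    def __len__(self) -> int:
        return len(self.masses)

    def formula(self, i: int) -> MolecularFormula:
        return MolecularFormula(*(int(x) for x in self.counts[i]))


@lru_cache(maxsize=8)
def build_formula_table(constraints: ElementConstraints) -> FormulaTable:
    """Enumerate every admissible formula in the constraint box.

    Vectorized over the (C, O) grid for each (N, S, P) combination; the
    hydrogen count range for each cell is derived in closed form from the
    mass window, the integer-DBE parity requirement, DBE >= 0 and the
    elemental-ratio screens, then expanded.
    """
    cs = constraints
    all_counts: list[np.ndarray] = []

    c = np.arange(max(cs.c_min, 1), cs.c_max + 1, dtype=np.int64)
    o = np.arange(cs.o_min, cs.o_max + 1, dtype=np.int64)
    C, O = (a.ravel() for a in np.meshgrid(c, o, indexing="ij"))
    if cs.ratio_screens:
        keep = O <= cs.oc_max * C
        C, O = C[keep], O[keep]

    for n in range(cs.n_min, cs.n_max + 1):
        for s in range(cs.s_min, cs.s_max + 1):
            for p in range(cs.p_min, cs.p_max + 1):
                base = (MASS_C * C + MASS_O * O
                        + MASS_N * n + MASS_S * s + MASS_P * p)
                h_lo = np.ceil((cs.mass_min - base) / MASS_H - 1e-9)
                h_hi = np.floor((cs.mass_max - base) / MASS_H + 1e-9)
                h_lo = np.maximum(h_lo, cs.h_min)
                h_hi = np.minimum(h_hi, cs.h_max)
                # DBE >= 0  <=>  H <= 2C + 2 + N + P
                h_hi = np.minimum(h_hi, 2 * C + 2 + n + p)
                if cs.ratio_screens:
                    h_lo = np.maximum(h_lo, np.ceil(cs.hc_min * C - 1e-9))
                    h_hi = np.minimum(h_hi, np.floor(cs.hc_max * C + 1e-9))
                h_lo = h_lo.astype(np.int64)
                h_hi = h_hi.astype(np.int64)
                # integer DBE  <=>  H + N + P even
                parity = (n + p) % 2
                h_lo = h_lo + ((h_lo + parity) % 2)
                counts = (h_hi - h_lo) // 2 + 1
                counts = np.maximum(counts, 0)
                total = int(counts.sum())
                if total == 0:
                    continue
                idx = np.repeat(np.arange(len(C)), counts)
                offsets = np.arange(total) - np.repeat(
                    np.cumsum(counts) - counts, counts)
                h = h_lo[idx] + 2 * offsets
                block = np.empty((total, 6), dtype=np.int16)
                block[:, 0] = C[idx]
                block[:, 1] = h
                block[:, 2] = n
                block[:, 3] = O[idx]
                block[:, 4] = s
                block[:, 5] = p
                all_counts.append(block)

    if not all_counts:
        return FormulaTable(np.empty((0, 6), dtype=np.int16),
                            np.empty(0, dtype=np.float64))
    counts = np.concatenate(all_counts)
    masses = counts.astype(np.float64) @ np.array(ELEMENT_MASSES)
    order = np.argsort(masses, kind="stable")
    return FormulaTable(counts[order], masses[order])


#: slack (ppm) added to tolerance comparisons so that a tolerance of zero
#: still accepts float round-trip error of the m/z <-> neutral conversion
PPM_SLACK = 1e-6


def candidate_indices(table: FormulaTable, neutral_mass: float,
                      tolerance_ppm: float) -> np.ndarray:
    """Indices of table formulae within a ppm tolerance of a neutral mass."""
    half = neutral_mass * (tolerance_ppm + PPM_SLACK) * 1e-6
    lo = np.searchsorted(table.masses, neutral_mass - half, side="left")
    hi = np.searchsorted(table.masses, neutral_mass + half, side="right")
    idx = np.arange(lo, hi)
    if len(idx):
        err = np.abs(table.masses[idx] - neutral_mass) / neutral_mass * 1e6
        idx = idx[err <= tolerance_ppm + PPM_SLACK]
    return idx


def enumerate_formulas(neutral_mass: float, tolerance_ppm: float,
                       constraints: ElementConstraints | None = None,
                       ) -> set[MolecularFormula]:
    """All admissible formulae within ``tolerance_ppm`` of a neutral mass.

    Equivalent to exhaustively enumerating the constraint box and keeping
    formulae with relative mass error at most ``tolerance_ppm`` that pass
    the validity rules (integer DBE >= 0 and, when enabled, the H/C and
    O/C screens).
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if tolerance_ppm < 0:
        raise ValueError("tolerance_ppm must be non-negative")
    cs = constraints or ElementConstraints()
    table = build_formula_table(cs)
    idx = candidate_indices(table, neutral_mass, tolerance_ppm)
    out = {table.formula(i) for i in idx}
    # the cached table is windowed on cs.mass_min/max; a query mass near the
    # window edge still only returns formulae inside the window, which is the
    # documented contract
    return out


def neutral_mass_from_mz(mz: float | np.ndarray) -> float | np.ndarray:
    """Neutral mass of a singly deprotonated ([M-H]-) ion."""
    return mz + PROTON_MASS


def degeneracy_key(comp: tuple[int, int, int, int, int, int],
                   ) -> tuple[int, tuple[int, ...]]:
    """Preference order among mass-degenerate formulae: fewest heteroatoms
    (N+S+P), then lexicographically smallest composition."""
    return (comp[2] + comp[4] + comp[5], tuple(comp))


def is_mass_identifiable(f: MolecularFormula, table: FormulaTable,
                         degeneracy_ppm: float = 0.2) -> bool:
    """Whether ``f`` would win the deterministic preference among all
    admissible formulae within ``degeneracy_ppm`` of its mass.

    Formula pairs closer in mass than the measurement error (fractions of
    a mDa are common in the CHNOSP space above ~500 Da) cannot be told
    apart by mass; assignment resolves such clusters by
    :func:`degeneracy_key`, so only the preferred member of a cluster is
    recoverable by name.
    """
    m = f.mass
    idx = candidate_indices(table, m, degeneracy_ppm)
    mine = degeneracy_key(tuple(f))
    for i in idx:
        comp = tuple(int(x) for x in table.counts[i])
        if comp != tuple(f) and degeneracy_key(comp) < mine:
            return False
    return True
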