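"""Molecular descriptors and compound-category classification.

Per-formula descriptors follow the standard conventions of ultrahigh
resolution organic-matter studies:

* ``AImod``: modified aromaticity index,
  (1 + C - 0.5 O - S - 0.5 (H + N + P)) / (C - 0.5 O - S - N - P),
  clamped to 0 when the numerator is negative or the denominator is <= 0.
* ``NOSC``: nominal oxidation state of carbon,
  4 - (4 C + H - 3 N - 2 O - 2 S) / C.
* ``DBE``: double-bond equivalents, 1 + (2 C - H + N + P) / 2, and
  ``DBE - O`` which discounts carboxyl-type oxygen.

Formulae are mapped to exactly one of five van Krevelen categories
(saturated, unsaturated aliphatic, highly unsaturated, aromatic,
condensed aromatic) by ordered AImod / H/C windows, plus independent
flags for carboxyl-rich alicyclic molecules (CRAM, DBE-ratio windows)
and oxy-aromatic phytochemicals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formulas import MolecularFormula

CATEGORIES = (
    "condensed_aromatic",
    "aromatic",
    "highly_unsaturated",
    "unsaturated_aliphatic",
    "saturated",
)

ELEMENTAL_CLASSES = ("CHO", "CHON", "CHOS", "CHOP")


@dataclass(frozen=True)
class Descriptors:
    """Derived molecular descriptors of one formula."""

    hc: float
    oc: float
    dbe: float
    dbe_o: float
    aimod: float
    nosc: float
    mass: float


@dataclass(frozen=True)
class CategoryWindows:
    """Numeric cuts of the ordered category scheme and the optional flags.

    Categories are evaluated first-match in the order: condensed aromatic
    (AImod >= ``aimod_condensed``), aromatic (AImod >= ``aimod_aromatic``),
    highly unsaturated (H/C <= ``hc_aliphatic``), unsaturated aliphatic
    (H/C < ``hc_saturated``), saturated.
    """

    aimod_condensed: float = 0.67
    aimod_aromatic: float = 0.50
    hc_aliphatic: float = 1.5
    hc_saturated: float = 2.0
    # CRAM: DBE-ratio windows from the carboxyl-rich alicyclic literature
    cram_dbe_c: tuple[float, float] = (0.30, 0.68)
    cram_dbe_h: tuple[float, float] = (0.20, 0.95)
    cram_dbe_o: tuple[float, float] = (0.77, 1.75)
    # oxy-aromatic phytochemical box (configurable placeholder window)
    phyto_oc: tuple[float, float] = (0.1, 0.85)
    phyto_aimod_min: float = 0.5
    phyto_mass_max: float = 800.0

    def __post_init__(self) -> None:
        if not 0 < self.aimod_aromatic < self.aimod_condensed:
            raise ValueError(
                "category windows overlap: require 0 < aimod_aromatic < "
                f"aimod_condensed, got {self.aimod_aromatic} / "
                f"{self.aimod_condensed}")
        if not 0 < self.hc_aliphatic < self.hc_saturated:
            raise ValueError(
                "category windows overlap: require 0 < hc_aliphatic < "
                f"hc_saturated, got {self.hc_aliphatic} / {self.hc_saturated}")
        for name in ("cram_dbe_c", "cram_dbe_h", "cram_dbe_o", "phyto_oc"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"window {name} is empty: [{lo}, {hi}]")


@dataclass(frozen=True)
class CategoryLabel:
    elemental_class: str
    category: str
    cram: bool
    phytochemical: bool
    aliphatic_with_nitrogen: bool


def compute_descriptors(f: MolecularFormula) -> Descriptors:
    """Descriptors of a single formula; requires at least one carbon."""
    if f.c < 1:
        raise ValueError("carbon-free formulae carry no descriptors; "
                         "they are excluded upstream")
    c, h, n, o, s, p = f
    numer = 1 + c - 0.5 * o - s - 0.5 * (h + n + p)
    denom = c - 0.5 * o - s - n - p
    # clamped into [0, 1]: negative or undefined values mean "no aromatic
    # character"; the rare low-hydrogen heteroatom formulae that push the
    # index above 1 are capped at full condensed-aromatic character
    aimod = 0.0 if (numer < 0 or denom <= 0) else min(numer / denom, 1.0)
    nosc = 4 - (4 * c + h - 3 * n - 2 * o - 2 * s) / c
    dbe = 1 + (2 * c - h + n + p) / 2
    return Descriptors(
        hc=h / c,
        oc=o / c,
        dbe=dbe,
        dbe_o=dbe - o,
        aimod=aimod,
        nosc=nosc,
        mass=f.mass,
    )


def classify_elemental(f: MolecularFormula) -> str:
    """CHO / CHON / CHOS / CHOP with precedence P > S > N.

    The four classes are exclusive so that their shares sum to 100%; the
    precedence keeps the rarest heteroatom when several are present.
    """
    if f.p >= 1:
        return "CHOP"
    if f.s >= 1:
        return "CHOS"
    if f.n >= 1:
        return "CHON"
    return "CHO"


def classify_category(d: Descriptors, f: MolecularFormula,
                      windows: CategoryWindows | None = None) -> CategoryLabel:
    """One van Krevelen category plus CRAM / phytochemical / N-aliphatic flags."""
    w = windows or CategoryWindows()
    if d.aimod >= w.aimod_condensed:
        category = "condensed_aromatic"
    elif d.aimod >= w.aimod_aromatic:
        category = "aromatic"
    elif d.hc <= w.hc_aliphatic:
        category = "highly_unsaturated"
    elif d.hc < w.hc_saturated:
        category = "unsaturated_aliphatic"
    else:
        category = "saturated"

    cram = False
    if f.o >= 1 and f.h > 0:
        cram = (w.cram_dbe_c[0] <= d.dbe / f.c <= w.cram_dbe_c[1]
                and w.cram_dbe_h[0] <= d.dbe / f.h <= w.cram_dbe_h[1]
                and w.cram_dbe_o[0] <= d.dbe / f.o <= w.cram_dbe_o[1])
    phyto = (w.phyto_oc[0] <= d.oc <= w.phyto_oc[1]
             and d.aimod >= w.phyto_aimod_min
             and d.mass <= w.phyto_mass_max)
    aliph_n = category in ("unsaturated_aliphatic", "saturated") and f.n >= 1
    return CategoryLabel(
        elemental_class=classify_elemental(f),
        category=category,
        cram=cram,
        phytochemical=phyto,
        aliphatic_with_nitrogen=aliph_n,
    )


def descriptor_table(formulas: Iterable[MolecularFormula],
                     windows: CategoryWindows | None = None) -> pd.DataFrame:
    """One row per formula: element counts, descriptors, class, category, flags."""
    rows = []
    for f in formulas:
        d = compute_descriptors(f)
        lab = classify_category(d, f, windows)
        rows.append({
            "formula": f.hill(),
            "c": f.c, "h": f.h, "n": f.n, "o": f.o, "s": f.s, "p": f.p,
            "mass": d.mass, "hc": d.hc, "oc": d.oc,
            "dbe": d.dbe, "dbe_o": d.dbe_o,
            "aimod": d.aimod, "nosc": d.nosc,
            "elemental_class": lab.elemental_class,
            "category": lab.category,
            "cram": lab.cram,
            "phytochemical": lab.phytochemical,
            "aliphatic_with_nitrogen": lab.aliphatic_with_nitrogen,
        })
    return pd.DataFrame(rows).set_index("formula")


def weighted_summary(matrix: pd.DataFrame, subset: Sequence[str],
                     sample: str,
                     windows: CategoryWindows | None = None,
                     weights: Mapping[str, float] | None = None,
                     ) -> dict[str, float]:
    """Intensity-weighted descriptor means and composition shares of a subset.

    ``matrix`` is a formula x sample intensity table (Hill strings as the
    row index). Weights are the sample's normalized intensities restricted
    to the subset and re-normalized; ``weights`` overrides them (used by
    process-pool reports that average a formula's intensity over several
    samples). Composition shares (elemental classes, categories, flags) are
    unweighted percentages of the subset, as in standard habitat tables.
    """
    subset = [f for f in subset if f in matrix.index]
    if not subset:
        raise ValueError(f"subset is empty in sample {sample!r}")
    if weights is None:
        w = matrix.loc[subset, sample].to_numpy(dtype=float)
    else:
        w = np.array([weights[f] for f in subset], dtype=float)
    present = w > 0
    if not present.any():
        raise ValueError(f"subset has no intensity in sample {sample!r}")
    subset = [f for f, keep in zip(subset, present) if keep]
    w = w[present]
    w = w / w.sum()

    table = descriptor_table(
        [MolecularFormula.from_string(f) for f in subset], windows)
    out: dict[str, float] = {"n_formulae": float(len(subset))}
    for col in ("mass", "hc", "oc", "aimod", "nosc", "dbe", "dbe_o"):
        out[f"{col}_wa"] = float(np.average(table[col].to_numpy(), weights=w))
    n = len(subset)
    for cls in ELEMENTAL_CLASSES:
        out[f"pct_{cls}"] = 100.0 * float((table["elemental_class"] == cls).sum()) / n
    for cat in CATEGORIES:
        out[f"pct_{cat}"] = 100.0 * float((table["category"] == cat).sum()) / n
    out["pct_cram"] = 100.0 * float(table["cram"].sum()) / n
    out["pct_phytochemical"] = 100.0 * float(table["phytochemical"].sum()) / n
    out["pct_aliphatic_with_nitrogen"] = (
        100.0 * float(table["aliphatic_with_nitrogen"].sum()) / n)
    return out
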