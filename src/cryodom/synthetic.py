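"""Synthetic incubation experiments with planted molecular dynamics.

Emulates the study design that the pipeline analyses: two algal habitats
(glacier ice-algae ``GIA``, red snow-algae ``RSA``), three organic-matter
pools (dissolved ``DOM``, hot-water particulate extract ``POM_HW``,
alkaline particulate extract ``POM_NAOH``), light and dark incubations
over a 0-24-day time series measured in duplicate, plus procedural
blanks. Every formula carries a planted trajectory class, so each
downstream stage can be scored against ground truth.

Design notes
------------
* Formula pools are generated as homologous-series families (chains of
  CH2 / CO2 / H2 / H2O / O steps), mimicking the series structure of
  natural organic matter, and trajectory classes are planted per family:
  structurally related compounds co-occur and behave alike, and every
  member keeps series-network support in every spectrum it occurs in.
* Degradation is exponential decay (optionally reaching zero at a planted
  extinction day), production a saturating logistic that starts at zero;
  both are smooth monotone shapes the classifier's rules must accept.
* Dissolved-pool per-sample totals are held constant over time: the
  unclassified background absorbs the intensity the dynamic classes lose
  or gain. Intensities are closed (columns are normalized downstream), so
  without this balancing every constant compound would drift in relative
  abundance and no exact recovery would exist.
* Noise is multiplicative lognormal (CV default 0.05), mass error
  Gaussian in ppm (sd default 0.1, clipped at 4 sd), and a small fraction
  of formulae is removed from one replicate of one sample to exercise the
  duplicate-presence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .formulas import (
    C13_ABUNDANCE,
    C13_DELTA,
    ElementConstraints,
    MolecularFormula,
    SERIES_BLOCKS,
    build_formula_table,
    is_mass_identifiable,
)

GIA = "GIA"
RSA = "RSA"

#: default mass window of the sampled pools (Da)
POOL_CONSTRAINTS = ElementConstraints(mass_min=100.0, mass_max=800.0)

_ZIG_AMP = 0.4          # deterministic fluctuation of "flat" series
_HUMP_DECAY = 0.72      # tail decline of the transfer appearance profile
_POM_LIGHT_DECAY = 0.08  # per-day leaching decline of particulate pools


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling layout of one synthetic incubation experiment."""

    habitats: tuple[str, ...] = (GIA, RSA)
    pools: tuple[str, ...] = (dyn.DOM, dyn.POM_HW, dyn.POM_NAOH)
    conditions: tuple[str, ...] = (dyn.LIGHT, dyn.DARK)
    timepoints_days: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 15.0, 22.0, 24.0)
    n_replicates: int = 2
    n_blanks: int = 6
    #: optional per-(habitat, pool) restriction of the measured timepoints
    pool_timepoints: Mapping[tuple[str, str], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        t = self.timepoints_days
        if len(t) < 1 or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing and "
                             "include 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_blanks < 0:
            raise ValueError("n_blanks must be >= 0")

    def times_for(self, habitat: str, pool: str) -> tuple[float, ...]:
        if self.pool_timepoints:
            return tuple(self.pool_timepoints.get((habitat, pool),
                                                  self.timepoints_days))
        return self.timepoints_days


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth parameters of the planted molecular dynamics."""

    n_formulae: int = 1000
    class_fractions: Mapping[str, float] = field(default_factory=lambda: {
        dyn.TRANSFERRED: 0.15,
        dyn.PHOTOPRODUCED: 0.10,
        dyn.PHOTO_DEGRADED: 0.05,
        dyn.HETERO_PRODUCED: 0.10,
        dyn.HETERO_DEGRADED: 0.25,
        dyn.REFRACTORY: 0.15,
    })
    #: (habitat-A only, habitat-B only, shared) split of the formula pool
    habitat_split: tuple[float, float, float] = (0.25, 0.25, 0.5)
    decay_rate: float = 0.2            # 1/day, exponential degradation
    extinction_day: float = 15.0       # day at which extinct series hit zero
    extinct_fraction: float = 0.5      # fraction of degraded families -> zero
    growth_rate: float = 0.25          # 1/day, logistic production
    growth_midpoint: float = 15.0      # day of the logistic midpoint
    noise_cv: float = 0.05             # multiplicative intensity noise
    mz_error_ppm_sd: float = 0.1       # Gaussian m/z error, clipped at 4 sd
    dropout_fraction: float = 0.02     # formulae dropped from one replicate
    n_contaminants: int = 30           # formulae present in blanks
    n_spiked_contaminants: int = 10    # of which also spiked into samples
    emit_isotopes: bool = True         # add 13C1 isotopologue peaks
    constraints: ElementConstraints = POOL_CONSTRAINTS

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError("class fractions must sum to <= 1 "
                             f"(got {total:.3f}); the remainder is "
                             "unclassified background")
        if any(not 0 <= v <= 1 for v in self.class_fractions.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if abs(sum(self.habitat_split) - 1) > 1e-9:
            raise ValueError("habitat_split must sum to 1")

    def zero_noise(self) -> "PlantedTruth":
        """Copy with every stochastic corruption disabled."""
        return replace(self, noise_cv=0.0, mz_error_ppm_sd=0.0,
                       dropout_fraction=0.0)


# ---------------------------------------------------------------------------
# formula pool sampling

def sample_formula_families(n: int, constraints: ElementConstraints,
                            rng: np.random.Generator,
                            family_size: tuple[int, int] = (4, 6),
                            exclude: set[MolecularFormula] | None = None,
                            identifiable_only: bool = True,
                            degeneracy_ppm: float = 0.2,
                            min_separation_ppm: float = 1.0,
                            ) -> list[list[MolecularFormula]]:
    """``n`` distinct admissible formulae grouped into homologous families.

    Families are grown by chained series-block steps from a random seed
    formula, so every member differs from some other member by exactly one
    block. Family sizes are drawn from ``family_size`` and the last family
    absorbs the remainder (total is exactly ``n``).

    With ``identifiable_only`` (default) the pool contains only formulae
    that are recoverable by exact mass: members of a mass-degenerate
    cluster that the assignment convention would report under another name
    are skipped (real spectra carry the same limitation; the preferred
    cluster member is what a formula list reports). Pool members (and any
    ``exclude`` formulae) are additionally kept at least
    ``min_separation_ppm`` apart in mass — ion pairs closer than the
    instrument's resolving power never appear as separate peaks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table = build_formula_table(constraints)
    excluded = set(exclude or ())
    capacity = len(table) - len(excluded)
    if n > capacity:
        raise ValueError(
            f"requested {n} formulae but only {capacity} distinct formulae "
            f"satisfy the constraints (short by {n - capacity})")

    import bisect
    masses: list[float] = sorted(f.mass for f in excluded)

    def well_separated(m: float) -> bool:
        i = bisect.bisect_left(masses, m)
        for j in (i - 1, i):
            if 0 <= j < len(masses):
                if abs(masses[j] - m) / m * 1e6 < min_separation_ppm:
                    return False
        return True

    def ok(f: MolecularFormula) -> bool:
        if f in used or not constraints.admits(f):
            return False
        if not well_separated(f.mass):
            return False
        return (not identifiable_only
                or is_mass_identifiable(f, table, degeneracy_ppm))

    blocks = [delta for delta, _ in SERIES_BLOCKS.values()]
    used: set[MolecularFormula] = set(excluded)
    families: list[list[MolecularFormula]] = []
    remaining = n
    stall = 0
    while remaining > 0:
        if remaining >= family_size[1] + 3:
            target = int(rng.integers(family_size[0], family_size[1] + 1))
        else:
            target = remaining
        seed_f = None
        seed_tries = 0
        while seed_f is None:
            seed_tries += 1
            if seed_tries > 10 * len(table):
                raise ValueError(
                    "could not find enough identifiable formulae under the "
                    f"given constraints (still needed: {remaining})")
            cand = table.formula(int(rng.integers(len(table))))
            if ok(cand):
                seed_f = cand
        family = [seed_f]
        used.add(seed_f)
        bisect.insort(masses, seed_f.mass)
        attempts = 0
        while len(family) < target and attempts < 200:
            attempts += 1
            anchor = family[int(rng.integers(len(family)))]
            delta = blocks[int(rng.integers(len(blocks)))]
            cand = anchor.shift(delta, int(rng.choice((-1, 1))))
            if not ok(cand):
                continue
            family.append(cand)
            used.add(cand)
            bisect.insort(masses, cand.mass)
        families.append(family)
        remaining -= len(family)
    return families


def sample_formula_pool(n: int, constraints: ElementConstraints | None = None,
                        seed: int = 0) -> list[MolecularFormula]:
    """``n`` distinct chemically plausible formulae (flat list), deterministic
    for a fixed seed."""
    cs = constraints or POOL_CONSTRAINTS
    rng = np.random.default_rng(seed)
    fams = sample_formula_families(n, cs, rng)
    return [f for fam in fams for f in fam]


# ---------------------------------------------------------------------------
# experiment assembly

@dataclass
class SimulatedExperiment:
    """Peak tables, manifest and planted truth of one synthetic experiment."""

    design: ExperimentDesign
    truth_params: PlantedTruth
    seed: int
    manifest: pd.DataFrame                      # one row per measurement
    peaks: dict[str, pd.DataFrame]              # measurement_id -> (mz, intensity)
    truth: pd.DataFrame                         # formula, habitat, label, ...
    noiseless: dict[str, pd.Series]             # base sample -> intensities
    contaminants: list[str]                     # Hill strings in blanks
    spiked_contaminants: list[str]
    dropped: list[tuple[str, str]]              # (formula, measurement_id)

    def base_id(self, habitat: str, pool: str, condition: str,
                time_days: float) -> str:
        return _base_id(habitat, pool, condition, time_days)


def _base_id(habitat: str, pool: str, condition: str, t: float) -> str:
    tt = f"{t:g}"
    return f"{habitat}_{pool}_{condition}_T{tt}"


def _logistic_from_zero(t: np.ndarray, k: float, t0: float,
                        t_end: float) -> np.ndarray:
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
    lo = sig(k * (0.0 - t0))
    hi = sig(k * (t_end - t0))
    return (sig(k * (t - t0)) - lo) / (hi - lo)


def _zig(i: int, phase: int) -> float:
    return 1.0 + _ZIG_AMP * (1.0 if (i + phase) % 2 == 0 else -1.0)


def _hump(pos: int) -> float:
    """Appearance profile of transferred formulae in dissolved light
    samples (pos counts t>0 timepoints from 1): rise then clear decline."""
    if pos <= 1:
        return 1.0
    if pos == 2:
        return 1.3
    return 1.3 * _HUMP_DECAY ** (pos - 2)


def _assign_classes(families: list[int], sizes: list[int],
                    fractions: Mapping[str, float], n_total: int,
                    rng: np.random.Generator) -> dict[int, str]:
    """Greedy family-level quota fill; remainder families are background."""
    order = list(rng.permutation(len(families)))
    assignment: dict[int, str] = {}
    targets = {lab: frac * n_total for lab, frac in fractions.items()}
    filled = {lab: 0 for lab in fractions}
    pos = 0
    for lab in fractions:
        while filled[lab] < targets[lab] - 1e-9 and pos < len(order):
            size = sizes[order[pos]]
            # stop when adding the family would overshoot the quota by more
            # than stopping short undershoots it
            if abs(filled[lab] + size - targets[lab]) > abs(
                    filled[lab] - targets[lab]):
                break
            fam = families[order[pos]]
            assignment[fam] = lab
            filled[lab] += size
            pos += 1
    for i in range(pos, len(order)):
        assignment[families[order[i]]] = dyn.UNCLASSIFIED
    return assignment


def simulate_experiment(design: ExperimentDesign, truth: PlantedTruth,
                        seed: int, validate: bool = True,
                        ) -> SimulatedExperiment:
    """Generate a complete synthetic experiment with ground truth.

    Deterministic for fixed ``(design, truth, seed)``. When ``validate`` is
    true the generator asserts its planted invariants on the noiseless
    series (degraded monotone down, produced monotone up, background and
    flat series classifiable as neither).
    """
    rng = np.random.default_rng(seed)
    cs = truth.constraints
    families = sample_formula_families(truth.n_formulae, cs, rng)
    pool_formulae = {f for fam in families for f in fam}
    contam_families = sample_formula_families(
        truth.n_contaminants, cs, rng, exclude=pool_formulae) \
        if truth.n_contaminants else []
    contaminants = [f for fam in contam_families for f in fam]
    # spike whole homologous families so spiked contaminants keep series
    # support in sample spectra as well as in blanks
    spiked: list[MolecularFormula] = []
    for fam in contam_families:
        if len(spiked) >= truth.n_spiked_contaminants:
            break
        spiked.extend(fam)

    # habitat split per family
    fam_order = list(rng.permutation(len(families)))
    sizes = [len(families[i]) for i in fam_order]
    cum = np.cumsum(sizes) / truth.n_formulae
    split_a, split_b, _ = truth.habitat_split
    groups: dict[int, str] = {}
    ha, hb = design.habitats[0], design.habitats[-1]
    for k, i in enumerate(fam_order):
        if cum[k] <= split_a + 1e-12:
            groups[i] = ha
        elif cum[k] <= split_a + split_b + 1e-12:
            groups[i] = hb
        else:
            groups[i] = "shared"
    if len(design.habitats) == 1:
        groups = {i: "shared" for i in range(len(families))}

    amplitudes: dict[tuple[str, str], float] = {}
    phases: dict[str, int] = {}
    for j, f in enumerate(sorted(pool_formulae | set(contaminants),
                                 key=lambda x: x.mass)):
        phases[f.hill()] = j % 2

    truth_rows: list[dict] = []
    noiseless: dict[str, pd.Series] = {}
    base_meta: dict[str, tuple[str, str, str, float]] = {}
    per_habitat_class: dict[str, dict[str, str]] = {}
    per_habitat_extract: dict[str, dict[str, str]] = {}
    per_habitat_zero: dict[str, dict[str, bool]] = {}
    per_habitat_bgfams: dict[str, list[list[str]]] = {}

    for habitat in design.habitats:
        fam_ids = [i for i in range(len(families))
                   if groups.get(i) in (habitat, "shared")]
        n_hab = sum(len(families[i]) for i in fam_ids)
        assignment = _assign_classes(
            fam_ids, [len(families[i]) for i in fam_ids],
            truth.class_fractions, n_hab, rng)

        class_of: dict[str, str] = {}
        extract_of: dict[str, str] = {}
        zero_of: dict[str, bool] = {}
        deg_idx = prod_idx = tr_idx = 0
        for i in fam_ids:
            lab = assignment[i]
            if lab in (dyn.HETERO_DEGRADED, dyn.PHOTO_DEGRADED):
                # deterministic thinning at the configured extinct fraction
                reaches = (int(truth.extinct_fraction * (deg_idx + 1))
                           > int(truth.extinct_fraction * deg_idx))
                deg_idx += 1
            else:
                reaches = False
            extract = ""
            if lab == dyn.TRANSFERRED:
                extract = dyn.POM_POOLS[tr_idx % 2]
                tr_idx += 1
            for f in families[i]:
                hill = f.hill()
                class_of[hill] = lab
                extract_of[hill] = extract
                zero_of[hill] = reaches
                amplitudes[(habitat, hill)] = float(
                    np.exp(rng.normal(np.log(1e5), 0.4)))
        per_habitat_class[habitat] = class_of
        per_habitat_extract[habitat] = extract_of
        per_habitat_zero[habitat] = zero_of
        per_habitat_bgfams[habitat] = [
            [f.hill() for f in families[i]] for i in fam_ids
            if assignment[i] == dyn.UNCLASSIFIED]

    # ---- noiseless intensity surfaces per (habitat, pool) ----------------
    for habitat in design.habitats:
        class_of = per_habitat_class[habitat]
        extract_of = per_habitat_extract[habitat]
        zero_of = per_habitat_zero[habitat]
        hills = sorted(class_of)
        bg = [h for h in hills if class_of[h] == dyn.UNCLASSIFIED]
        # structural absences of background formulae (break "always
        # present"); planted per family so no member ever loses its
        # homologous-series partners within a spectrum
        absence: dict[str, tuple[str, float]] = {}
        dom_times = design.times_for(habitat, dyn.DOM)
        later = [t for t in dom_times if t > 0]
        for j, fam in enumerate(per_habitat_bgfams[habitat]):
            cond = dyn.LIGHT if j % 2 == 0 else dyn.DARK
            slot = (cond, later[j % len(later)]) if later else ("", -1.0)
            for h in fam:
                absence[h] = slot

        # -- dissolved pool with constant-total closure --
        grid = [(dyn.INITIAL, 0.0)] + [(c, t) for c in (dyn.LIGHT, dyn.DARK)
                                       for t in later]
        t_end = dom_times[-1]
        dyn_profiles: dict[str, dict[tuple[str, float], float]] = {}
        for h in hills:
            lab = class_of[h]
            if lab == dyn.UNCLASSIFIED:
                continue
            A = amplitudes[(habitat, h)]
            prof: dict[tuple[str, float], float] = {}
            for cond, t in grid:
                ti = dom_times.index(t)
                if lab == dyn.REFRACTORY:
                    v = A
                elif lab == dyn.HETERO_DEGRADED:
                    v = 0.0 if (zero_of[h] and t >= truth.extinction_day) \
                        else A * np.exp(-truth.decay_rate * t)
                elif lab == dyn.HETERO_PRODUCED:
                    v = A * float(_logistic_from_zero(
                        np.array([t]), truth.growth_rate,
                        truth.growth_midpoint, t_end)[0])
                elif lab == dyn.PHOTOPRODUCED:
                    v = A * float(_logistic_from_zero(
                        np.array([t]), truth.growth_rate,
                        truth.growth_midpoint, t_end)[0]) \
                        if cond == dyn.LIGHT else 0.0
                elif lab == dyn.PHOTO_DEGRADED:
                    if cond == dyn.DARK:
                        v = A * _zig(ti, phases[h])
                    elif cond == dyn.INITIAL:
                        v = A
                    else:
                        v = 0.0 if (zero_of[h] and t >= truth.extinction_day) \
                            else A * np.exp(-truth.decay_rate * t)
                elif lab == dyn.TRANSFERRED:
                    v = A * _hump(later.index(t) + 1) \
                        if cond == dyn.LIGHT else 0.0
                else:  # pragma: no cover
                    raise AssertionError(lab)
                prof[(cond, t)] = v
            dyn_profiles[h] = prof

        nb_total = {key: sum(p[key] for p in dyn_profiles.values())
                    for key in grid}
        target = _closure_target(nb_total, grid)
        residual = {key: target - nb_total[key] for key in grid}
        for key in grid:
            if residual[key] <= 0:
                raise RuntimeError("closure target underflow; raise the "
                                   "background fraction")
        bg_profiles: dict[str, dict[tuple[str, float], float]] = {
            h: {} for h in bg}
        for cond, t in grid:
            ti = dom_times.index(t)
            raw = {}
            for h in bg:
                a_cond, a_t = absence[h]
                if cond != dyn.INITIAL and cond == a_cond and t == a_t:
                    raw[h] = 0.0
                else:
                    raw[h] = amplitudes[(habitat, h)] * _zig(ti, phases[h])
            z = sum(raw.values())
            if z <= 0 and bg:
                raise RuntimeError("background pool vanished at one sample; "
                                   "need more background formulae")
            for h in bg:
                bg_profiles[h][(cond, t)] = raw[h] / z * residual[(cond, t)] \
                    if bg else 0.0

        for cond, t in grid:
            vals = {}
            for h in hills:
                v = dyn_profiles.get(h, bg_profiles.get(h, {})).get((cond, t), 0.0)
                if v > 0:
                    vals[h] = v
            bid = _base_id(habitat, dyn.DOM, cond, t)
            noiseless[bid] = pd.Series(vals, dtype=float)
            base_meta[bid] = (habitat, dyn.DOM, cond, t)

        # -- particulate pools --
        for pool in design.pools:
            if pool == dyn.DOM:
                continue
            times = design.times_for(habitat, pool)
            p_later = [t for t in times if t > 0]
            p_grid = [(dyn.INITIAL, 0.0)] + [
                (c, t) for c in (dyn.LIGHT, dyn.DARK) for t in p_later]
            for cond, t in p_grid:
                ti = times.index(t)
                vals = {}
                for h in hills:
                    lab = class_of[h]
                    A = amplitudes[(habitat, h)]
                    if lab == dyn.REFRACTORY:
                        v = A
                    elif lab == dyn.UNCLASSIFIED:
                        v = A * _zig(ti, phases[h])
                    elif lab == dyn.TRANSFERRED and extract_of[h] == pool:
                        if cond == dyn.INITIAL:
                            v = A
                        elif cond == dyn.LIGHT:
                            v = A * np.exp(-_POM_LIGHT_DECAY * t)
                        else:
                            v = A * _zig(ti, phases[h])
                    else:
                        v = 0.0
                    if v > 0:
                        vals[h] = v
                bid = _base_id(habitat, pool, cond, t)
                noiseless[bid] = pd.Series(vals, dtype=float)
                base_meta[bid] = (habitat, pool, cond, t)

        for h in hills:
            truth_rows.append({
                "formula": h, "habitat": habitat,
                "label": class_of[h],
                "extract": extract_of[h],
                "reaches_zero": bool(zero_of[h]),
                "event_time": (
                    min((t for t in dom_times if t >= truth.extinction_day),
                        default=dom_times[-1])
                    if zero_of[h] else (
                        dom_times[-1]
                        if class_of[h] in (dyn.HETERO_DEGRADED,
                                           dyn.PHOTO_DEGRADED,
                                           dyn.HETERO_PRODUCED,
                                           dyn.PHOTOPRODUCED)
                        else np.nan)),
            })

    truth_df = pd.DataFrame(truth_rows)

    # ---- measurements: noise, m/z error, dropout, contaminants -----------
    mz_of = {f.hill(): f.mz_neg for f in pool_formulae | set(contaminants)}
    c_of = {f.hill(): f.c for f in pool_formulae | set(contaminants)}
    contam_amp = {f.hill(): float(np.exp(rng.normal(np.log(1e5), 0.4)))
                  for f in contaminants}
    sigma = float(np.sqrt(np.log(1 + truth.noise_cv ** 2)))

    manifest_rows = []
    peaks: dict[str, pd.DataFrame] = {}
    base_ids = sorted(noiseless)

    # dropout bookkeeping: fraction of each habitat's formulae, one
    # (sample, replicate) occurrence each
    dropped: list[tuple[str, str]] = []
    drop_map: dict[tuple[str, str], set[str]] = {}
    for habitat in design.habitats:
        hills = sorted(per_habitat_class[habitat])
        n_drop = int(round(truth.dropout_fraction * len(hills)))
        if n_drop:
            chosen = rng.choice(len(hills), size=n_drop, replace=False)
            for ci in chosen:
                h = hills[int(ci)]
                present = [b for b in base_ids
                           if b.startswith(f"{habitat}_")
                           and h in noiseless[b].index]
                if not present:
                    continue
                b = present[int(rng.integers(len(present)))]
                r = int(rng.integers(1, design.n_replicates + 1))
                mid = f"{b}_R{r}"
                drop_map.setdefault((b, f"R{r}"), set()).add(h)
                dropped.append((h, mid))

    def _emit(mid: str, series: pd.Series, spike: bool) -> pd.DataFrame:
        hills = list(series.index)
        inten = series.to_numpy(dtype=float)
        if spike:
            hills = hills + list(spiked_hills)
            inten = np.concatenate(
                [inten, [contam_amp[h] for h in spiked_hills]])
        if sigma > 0:
            inten = inten * np.exp(
                rng.normal(0.0, sigma, len(inten)) - sigma ** 2 / 2)
        mz = np.array([mz_of[h] for h in hills])
        if truth.mz_error_ppm_sd > 0:
            err = rng.normal(0.0, truth.mz_error_ppm_sd, len(mz))
            err = np.clip(err, -4 * truth.mz_error_ppm_sd,
                          4 * truth.mz_error_ppm_sd)
            mz = mz * (1 + err * 1e-6)
        df = pd.DataFrame({"mz": mz, "intensity": inten,
                           "_formula": hills})
        if truth.emit_isotopes:
            iso = pd.DataFrame({
                "mz": mz + C13_DELTA,
                "intensity": inten * C13_ABUNDANCE
                * np.array([c_of[h] for h in hills]),
                "_formula": [f"{h}+13C" for h in hills],
            })
            df = pd.concat([df, iso], ignore_index=True)
        return df.sort_values("mz", kind="stable").reset_index(drop=True)

    spiked_hills = [f.hill() for f in spiked]
    for b in base_ids:
        habitat, pool, cond, t = base_meta[b]
        for r in range(1, design.n_replicates + 1):
            mid = f"{b}_R{r}"
            series = noiseless[b]
            gone = drop_map.get((b, f"R{r}"))
            if gone:
                series = series[~series.index.isin(gone)]
            peaks[mid] = _emit(mid, series, spike=True)
            manifest_rows.append({
                "sample_id": mid, "habitat": habitat, "pool": pool,
                "condition": cond, "time_days": t, "replicate": r,
                "is_blank": False,
            })
    for bi in range(1, design.n_blanks + 1):
        b = f"BLANK{bi}_NA_{dyn.BLANK}_T0"
        series = pd.Series({f.hill(): contam_amp[f.hill()]
                            for f in contaminants})
        for r in range(1, design.n_replicates + 1):
            mid = f"{b}_R{r}"
            peaks[mid] = _emit(mid, series, spike=False)
            manifest_rows.append({
                "sample_id": mid, "habitat": f"BLANK{bi}", "pool": "NA",
                "condition": dyn.BLANK, "time_days": 0.0, "replicate": r,
                "is_blank": True,
            })

    manifest = pd.DataFrame(manifest_rows)
    exp = SimulatedExperiment(
        design=design, truth_params=truth, seed=seed, manifest=manifest,
        peaks=peaks, truth=truth_df, noiseless=noiseless,
        contaminants=[f.hill() for f in contaminants],
        spiked_contaminants=spiked_hills, dropped=dropped)
    if validate:
        validate_planted_dynamics(exp)
    return exp


def _closure_target(nb_total: Mapping[tuple[str, float], float],
                    grid: Sequence[tuple[str, float]]) -> float:
    """Smallest constant per-sample total such that the background residual
    stays positive and varies slowly (step ratios within [0.85, 1.18])."""
    max_nb = max(nb_total.values())
    target = 1.3 * max_nb
    by_cond: dict[str, list[float]] = {}
    init = nb_total[(dyn.INITIAL, 0.0)]
    for cond in (dyn.LIGHT, dyn.DARK):
        seq = [init] + [nb_total[k] for k in grid if k[0] == cond]
        for a, b in zip(seq, seq[1:]):
            # (C-b)/(C-a) <= 1.18 and >= 0.85
            if b < a:
                target = max(target, (1.18 * a - b) / 0.18)
            elif b > a:
                target = max(target, (b - 0.85 * a) / 0.15)
    return target


def validate_planted_dynamics(exp: SimulatedExperiment) -> None:
    """Assert planted invariants on the noiseless dissolved-pool series."""
    rule = dyn.MonotoneRule()
    for habitat in exp.design.habitats:
        sub = exp.truth[exp.truth["habitat"] == habitat]
        times = list(exp.design.times_for(habitat, dyn.DOM))
        for _, row in sub.iterrows():
            h, lab = row["formula"], row["label"]
            for cond in (dyn.LIGHT, dyn.DARK):
                t, x = _noiseless_series(exp, h, habitat, dyn.DOM, cond, times)
                dec, _, _ = dyn.is_consistent_decrease(t, x, rule)
                inc, _ = dyn.is_consistent_increase(t, x, rule)
                if lab == dyn.UNCLASSIFIED and (dec or inc):
                    raise RuntimeError(
                        f"background formula {h} is monotone in {cond}; "
                        "closure construction failed")
                if lab == dyn.REFRACTORY and (dec or inc):
                    raise RuntimeError(
                        f"refractory formula {h} drifts in {cond}")
                if lab == dyn.HETERO_DEGRADED and not dec:
                    raise RuntimeError(
                        f"planted degraded formula {h} not monotone ({cond})")
                if lab == dyn.HETERO_PRODUCED and not inc:
                    raise RuntimeError(
                        f"planted produced formula {h} not monotone ({cond})")


def _noiseless_series(exp: SimulatedExperiment, formula: str, habitat: str,
                      pool: str, condition: str, times: Sequence[float],
                      ) -> tuple[np.ndarray, np.ndarray]:
    ts, xs = [], []
    for t in times:
        cond = dyn.INITIAL if t == 0 else condition
        b = _base_id(habitat, pool, cond, t)
        if b in exp.noiseless:
            ts.append(t)
            xs.append(float(exp.noiseless[b].get(formula, 0.0)))
    return np.array(ts), np.array(xs)


# ---------------------------------------------------------------------------
# disk output

def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> Path:
    """Write peak tables (one TSV per measurement), the sample manifest and
    the truth table under ``outdir``."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    for mid, df in sorted(exp.peaks.items()):
        df[["mz", "intensity"]].to_csv(out / "peaks" / f"{mid}.tsv",
                                       sep="\t", index=False,
                                       float_format="%.8f")
    exp.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    exp.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out
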