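"""From raw peak lists to a blank-corrected, duplicate-merged intensity matrix.

The processing chain mirrors standard ultrahigh-resolution organic-matter
workflows: noise filtering against a method detection limit (MDL),
optional mass recalibration on known calibrants, CHNOSP formula
assignment validated by a homologous-series network, 13C-isotopologue
verification, removal of every formula seen in procedural blanks, and
merging of duplicate measurements (a compound counts as present only when
detected in all replicates; the mean normalized intensity is kept).

All peak tables are plain DataFrames with ``mz`` and ``intensity``
columns; assignments and audit trails are long-format DataFrames keyed by
measurement id; the final product is an :class:`IntensityMatrix` whose
columns each sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formulas import (
    C13_ABUNDANCE,
    C13_DELTA,
    ElementConstraints,
    FormulaTable,
    MolecularFormula,
    PROTON_MASS,
    SERIES_BLOCKS,
    build_formula_table,
    candidate_indices,
    degeneracy_key,
)

DEFAULT_SERIES_BLOCKS = tuple(SERIES_BLOCKS)


# ---------------------------------------------------------------------------
# I/O helpers

def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read one delimited peak table (columns ``mz``, ``intensity``)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = {"mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peak table lacks columns {sorted(missing)}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "habitat", "pool", "condition", "time_days",
                "replicate", "is_blank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# per-spectrum operations

def estimate_noise_level(intensities: np.ndarray) -> float:
    """Spectrum noise level: median intensity of the lowest-decile peaks.

    A simple monotone stand-in for instrument-specific detection-limit
    models; callers may supply a constant instead.
    """
    x = np.sort(np.asarray(intensities, dtype=float))
    if len(x) == 0:
        return 0.0
    k = max(1, len(x) // 10)
    return float(np.median(x[:k]))


def mdl_filter(peaks: pd.DataFrame, mdl_factor: float = 2.0,
               noise_level: float | None = None,
               ) -> tuple[pd.DataFrame, float]:
    """Retain peaks with intensity >= ``mdl_factor`` x noise level.

    Returns the filtered table and the MDL value used (factor x noise).
    """
    if mdl_factor <= 0:
        raise ValueError("mdl_factor must be positive")
    if peaks.empty:
        return peaks.copy(), 0.0
    noise = (estimate_noise_level(peaks["intensity"].to_numpy())
             if noise_level is None else float(noise_level))
    mdl = mdl_factor * noise
    return peaks[peaks["intensity"] >= mdl].copy(), mdl


def recalibrate(peaks: pd.DataFrame,
                calibrants: Sequence[tuple[MolecularFormula, float]],
                tolerance_ppm: float = 0.5,
                min_signal_ratio: float = 5.0,
                mdl: float | None = None) -> pd.DataFrame:
    """Correct a constant relative mass offset using known calibrants.

    Each calibrant (formula, expected m/z) is matched to the closest peak
    within ``tolerance_ppm``; matched peaks must additionally have
    signal-to-MDL ratio >= ``min_signal_ratio`` when ``mdl`` is given.
    The mean signed ppm error over >= 3 matched calibrants is subtracted
    multiplicatively from every m/z ("mean recalibration").
    """
    mz = peaks["mz"].to_numpy(dtype=float)
    intensity = peaks["intensity"].to_numpy(dtype=float)
    errors = []
    for _, expected in calibrants:
        if len(mz) == 0:
            break
        i = int(np.argmin(np.abs(mz - expected)))
        err_ppm = (mz[i] - expected) / expected * 1e6
        if abs(err_ppm) > tolerance_ppm:
            continue
        if mdl is not None and mdl > 0 and intensity[i] / mdl < min_signal_ratio:
            continue
        errors.append(err_ppm)
    if len(errors) < 3:
        raise ValueError(
            f"only {len(errors)} calibrants matched within "
            f"{tolerance_ppm} ppm (need >= 3); skip recalibration for this "
            "spectrum explicitly")
    mean_err = float(np.mean(errors))
    out = peaks.copy()
    out["mz"] = mz * (1 - mean_err * 1e-6)
    return out


#: width (ppm) of the aligned-ion mass buckets used for cross-sample
#: candidate consensus
ION_BUCKET_PPM = 0.5


def ion_bucket(neutral_mass: float) -> int:
    """Index of the aligned-ion mass bucket containing a neutral mass."""
    return int(np.log(neutral_mass) / (ION_BUCKET_PPM * 1e-6))


def aligned_ion_scores(neutral_masses: Sequence[np.ndarray],
                       table: FormulaTable,
                       tolerance_ppm: float = 0.5,
                       ) -> dict[tuple[int, tuple[int, ...]], float]:
    """|mean signed mass error| of every candidate per aligned ion.

    Peaks from all supplied spectra are aligned on a logarithmic mass grid
    (bucket width 0.5 ppm: occurrences of the same ion across samples fall
    into the same or adjacent buckets). For each (bucket, candidate
    composition) pair the signed ppm errors are averaged: the correct
    formula of an ion averages to the calibration accuracy (noise cancels
    across samples) while a near-isobaric alternative averages to its
    systematic mass offset. This is the desk-scale analogue of joining
    mass spectra across samples before deciding assignments.
    """
    sums: dict[tuple[int, tuple[int, ...]], float] = {}
    counts: dict[tuple[int, tuple[int, ...]], int] = {}
    for neutral in neutral_masses:
        for m in neutral:
            b = ion_bucket(m)
            for i in candidate_indices(table, m, tolerance_ppm):
                i = int(i)
                comp = tuple(int(x) for x in table.counts[i])
                err = (m - table.masses[i]) / table.masses[i] * 1e6
                # smear into adjacent buckets so an occurrence in a bucket
                # tail still sees its ion's evidence
                for bb in (b - 1, b, b + 1):
                    key = (bb, comp)
                    sums[key] = sums.get(key, 0.0) + err
                    counts[key] = counts.get(key, 0) + 1
    return {key: abs(sums[key] / counts[key]) for key in sums}


def winner_ion_scores(winners: Sequence[tuple[np.ndarray, pd.DataFrame]],
                      ) -> dict[tuple[int, tuple[int, ...]], float]:
    """Re-estimate aligned-ion scores from current assignment winners.

    ``winners`` pairs each spectrum's neutral-mass array with its
    assignment table. Only the winning formula of each peak contributes
    its signed error, so the mean per (bucket, composition) is no longer
    diluted by foreign-ion candidacies; iterating assignment against
    these scores lets a rare ion reclaim peaks that a more abundant
    near-isobaric neighbour captured in the first pass.
    """
    sums: dict[tuple[int, tuple[int, ...]], float] = {}
    counts: dict[tuple[int, tuple[int, ...]], int] = {}
    for neutral, assigned in winners:
        hills = assigned["formula"].to_numpy()
        errs = assigned["mass_error_ppm"].to_numpy(dtype=float)
        for m, hill, err in zip(neutral, hills, errs):
            if not hill:
                continue
            comp = tuple(MolecularFormula.from_string(hill))
            b = ion_bucket(m)
            for bb in (b - 1, b, b + 1):
                key = (bb, comp)
                sums[key] = sums.get(key, 0.0) + err
                counts[key] = counts.get(key, 0) + 1
    return {key: abs(sums[key] / counts[key]) for key in sums}


def assign_formulas(peaks: pd.DataFrame,
                    constraints: ElementConstraints | None = None,
                    tolerance_ppm: float = 0.5,
                    series_blocks: Sequence[str] = DEFAULT_SERIES_BLOCKS,
                    min_series_links: int = 1,
                    series_consensus: bool = True,
                    degeneracy_ppm: float = 0.2,
                    comp_score: Mapping[tuple[int, tuple[int, ...]], float]
                    | None = None,
                    support_pool: set[tuple[int, ...]] | None = None,
                    table: FormulaTable | None = None) -> pd.DataFrame:
    """Assign one molecular formula (or none) to every [M-H]- peak.

    Candidates within ``tolerance_ppm`` of the neutral mass are validated
    by a homologous-series network over all candidate formulae of the
    spectrum: a candidate survives only if it differs from at least
    ``min_series_links`` other candidates by exactly one series block
    (element-count deltas of CH2, CO2, H2, H2O, O by default). Among
    survivors the smallest |mass error| wins; ties fall to fewer
    heteroatoms, then to the lexicographically smallest composition.

    Near-isobaric candidate pairs (well below 1 mDa apart at high mass)
    cannot be separated reliably by one observation. With
    ``series_consensus`` enabled, candidates are ranked primarily by their
    aligned-ion consensus score (:func:`aligned_ion_scores`): the |mean
    signed error| of the candidate across every occurrence of the ion,
    pooled over all spectra passed via ``comp_score`` (the engine supplies
    experiment-wide scores; standalone calls pool only the one spectrum,
    where the score reduces to the peak's own |error|). The correct
    formula averages to the calibration accuracy while a wrong candidate
    averages to its systematic offset.

    Candidates of one peak closer to each other than ``degeneracy_ppm``
    cannot be told apart by mass at all; such clusters collapse
    deterministically onto the member with the fewest heteroatoms (then
    smallest composition), the convention assumed throughout the package
    for reporting mass-degenerate formulae.

    Returns one row per peak: ``mz``, ``intensity``, ``formula`` (Hill
    string or empty), ``mass_error_ppm``, ``series_support``.
    """
    cs = constraints or ElementConstraints()
    tab = table if table is not None else build_formula_table(cs)
    deltas = [SERIES_BLOCKS[name][0] for name in series_blocks]

    mz = peaks["mz"].to_numpy(dtype=float)
    neutral = mz + PROTON_MASS
    cand_idx: list[np.ndarray] = [
        candidate_indices(tab, m, tolerance_ppm) for m in neutral]

    # series network over the union of candidate compositions; a caller
    # processing a whole experiment may extend the union across samples
    # (``support_pool``) so that a replicate missing one series member
    # does not orphan its neighbours
    union = sorted({int(i) for idx in cand_idx for i in idx})
    comp_of = {i: tuple(int(x) for x in tab.counts[i]) for i in union}
    comp_set = set(comp_of.values())
    if support_pool:
        comp_set = comp_set | support_pool

    def neighbors(comp: tuple[int, ...]):
        for d in deltas:
            yield tuple(a + b for a, b in zip(comp, d))
            yield tuple(a - b for a, b in zip(comp, d))

    support = {i: sum(nb in comp_set for nb in neighbors(comp_of[i]))
               for i in union}

    err_of = {}
    for j in range(len(mz)):
        for i in cand_idx[j]:
            i = int(i)
            err_of[(j, i)] = (neutral[j] - tab.masses[i]) / tab.masses[i] * 1e6

    local_refine = series_consensus and comp_score is None
    if local_refine:
        comp_score = aligned_ion_scores([neutral], tab, tolerance_ppm)
    # score differences below a quarter of the degeneracy window carry no
    # information; binning lets |mass error| decide such near-ties
    score_bin = max(degeneracy_ppm / 4.0, 1e-9)

    pruned_of: list[list[int]] = []
    for j in range(len(mz)):
        eligible = [int(i) for i in cand_idx[j]
                    if support[int(i)] >= min_series_links]
        # mass-degenerate candidates (closer than the measurement can
        # resolve) collapse onto the chemically preferred member
        pruned = []
        for i in eligible:
            mine = degeneracy_key(comp_of[i])
            beaten = any(
                k != i
                and abs(tab.masses[k] - tab.masses[i])
                <= tab.masses[i] * degeneracy_ppm * 1e-6
                and degeneracy_key(comp_of[k]) < mine
                for k in eligible)
            if not beaten:
                pruned.append(i)
        pruned_of.append(pruned)

    def pick(lookup) -> list[tuple[int, float] | None]:
        out = []
        for j in range(len(mz)):
            best = None
            for i in pruned_of[j]:
                err = err_of[(j, i)]
                f = comp_of[i]
                hetero = f[2] + f[4] + f[5]
                if lookup is None:
                    key = (abs(err), hetero, f)
                else:
                    key = (round(lookup(j, f, err) / score_bin),
                           abs(err), hetero, f)
                if best is None or key < best[0]:
                    best = (key, i, err)
            out.append(None if best is None else (best[1], best[2]))
        return out

    if series_consensus:
        winners = pick(lambda j, f, err: comp_score.get(
            (ion_bucket(neutral[j]), f), abs(err)))
    else:
        winners = pick(None)

    if local_refine:
        # refinement passes: each winner's signed error, smoothed over its
        # series neighbourhood, re-calibrates the choice — members of a
        # homologous family share the spectrum's calibration, so a lone
        # near-miss cannot outvote a consistent family; iterate until the
        # assignment is stable
        for _ in range(5):
            win_err: dict[tuple[int, ...], float] = {}
            for w in winners:
                if w is not None:
                    win_err[comp_of[w[0]]] = w[1]

            def family_score(j, f, err):
                # relatives only — a candidate cannot vouch for itself
                errs = [win_err[nb] for nb in neighbors(f) if nb in win_err]
                if errs:
                    return abs(float(np.mean(errs)))
                # a candidate without assigned series relatives is
                # implausible in natural organic matter: two-bin penalty
                return abs(err) + 2 * score_bin

            new_winners = pick(family_score)
            if new_winners == winners:
                break
            winners = new_winners

    rows = []
    for j, w in enumerate(winners):
        if w is None:
            rows.append({"mz": mz[j],
                         "intensity": float(peaks["intensity"].iloc[j]),
                         "formula": "", "mass_error_ppm": np.nan,
                         "series_support": 0})
        else:
            i, err = w
            rows.append({"mz": mz[j],
                         "intensity": float(peaks["intensity"].iloc[j]),
                         "formula": tab.formula(i).hill(),
                         "mass_error_ppm": float(err),
                         "series_support": support[i]})
    return pd.DataFrame(rows)


def verify_isotopes(assignments: pd.DataFrame, peaks: pd.DataFrame,
                    ratio_tolerance_permil: float = 1000.0,
                    min_isotope_signal_ratio: float = 5.0,
                    mdl: float = 0.0,
                    mz_tolerance_ppm: float = 1.0) -> pd.DataFrame:
    """Check assigned formulae against their 13C1 isotopologue peaks.

    For every assignment the spectrum is searched at m/z + 1.0033548. When
    a peak is found there with signal-to-MDL ratio above
    ``min_isotope_signal_ratio``, the observed isotope intensity ratio is
    compared with the expected 0.0107 x C; assignments deviating by more
    than ``ratio_tolerance_permil`` (relative, in permil) are flagged
    removed. Assignments without a detectable isotope peak are retained.
    Peaks that are themselves the 13C satellite of another assigned peak
    are flagged ``isotopologue`` and excluded from downstream matrices.

    Returns the assignment table with added ``isotope_check`` column
    (``ok`` / ``no_isotope`` / ``mismatch`` / ``isotopologue``).
    """
    out = assignments.copy()
    out["isotope_check"] = "no_isotope"
    mz_all = peaks["mz"].to_numpy(dtype=float)
    int_all = peaks["intensity"].to_numpy(dtype=float)
    order = np.argsort(mz_all)
    mz_sorted, int_sorted = mz_all[order], int_all[order]

    assigned = out["formula"] != ""
    for idx in out.index[assigned]:
        row = out.loc[idx]
        f = MolecularFormula.from_string(row["formula"])
        target = row["mz"] + C13_DELTA
        half = target * mz_tolerance_ppm * 1e-6
        lo = np.searchsorted(mz_sorted, target - half)
        hi = np.searchsorted(mz_sorted, target + half)
        if lo >= hi:
            continue
        k = lo + int(np.argmin(np.abs(mz_sorted[lo:hi] - target)))
        iso_int = int_sorted[k]
        if mdl > 0 and iso_int / mdl <= min_isotope_signal_ratio:
            continue
        expected = C13_ABUNDANCE * f.c * row["intensity"]
        if expected <= 0:
            continue
        deviation_permil = abs(iso_int / expected - 1.0) * 1000.0
        out.loc[idx, "isotope_check"] = (
            "mismatch" if deviation_permil > ratio_tolerance_permil else "ok")

    # flag satellites of assigned monoisotopic peaks; only parents whose
    # own isotope pattern was positively confirmed can claim a satellite
    # (otherwise spectra without isotopologue peaks would lose ordinary
    # peaks to chance mass coincidences), and only the peak closest to
    # the exact satellite position is a satellite — a resolved neighbour
    # formula a fraction of a ppm away keeps its assignment
    out_mz = out["mz"].to_numpy(dtype=float)
    flagged: set[int] = set()
    # ascending m/z: a satellite is always heavier than its parent, so a
    # peak flagged as satellite can never claim a satellite of its own
    # (there is no 13C2 fine structure in this model)
    parents = out.index[assigned & (out["isotope_check"] == "ok")]
    for idx in sorted(parents, key=lambda i: out.at[i, "mz"]):
        if idx in flagged:
            continue
        f = MolecularFormula.from_string(out.loc[idx, "formula"])
        target = out.loc[idx, "mz"] + C13_DELTA
        half = target * mz_tolerance_ppm * 1e-6
        lo = np.searchsorted(mz_sorted, target - half)
        hi = np.searchsorted(mz_sorted, target + half)
        if lo >= hi:
            continue
        k = lo + int(np.argmin(np.abs(mz_sorted[lo:hi] - target)))
        expected = C13_ABUNDANCE * f.c * out.loc[idx, "intensity"]
        if expected > 0 and 1 / 3 < int_sorted[k] / expected < 3:
            # mark the matched peak itself (map back to table rows by m/z)
            for j in np.flatnonzero(np.isclose(out_mz, mz_sorted[k],
                                               rtol=0, atol=1e-12)):
                flagged.add(int(out.index[j]))
    for idx in flagged:
        if out.loc[idx, "formula"] != "":
            out.loc[idx, "isotope_check"] = "isotopologue"
    return out


# ---------------------------------------------------------------------------
# cross-sample operations

def remove_blank_peaks(long_table: pd.DataFrame,
                       blank_ids: Iterable[str]) -> tuple[pd.DataFrame, int]:
    """Drop every formula assigned in any blank measurement from all samples.

    ``long_table`` has columns ``sample_id``, ``formula``, ``intensity``.
    Returns the reduced table and the number of distinct formulae removed.
    """
    blank_ids = set(blank_ids)
    if not blank_ids:
        warnings.warn("no blank samples present; blank removal is a no-op")
        return long_table.copy(), 0
    contaminated = set(
        long_table.loc[long_table["sample_id"].isin(blank_ids), "formula"])
    contaminated.discard("")
    out = long_table[~long_table["formula"].isin(contaminated)]
    out = out[~out["sample_id"].isin(blank_ids)].copy()
    return out, len(contaminated)


@dataclass
class IntensityMatrix:
    """Blank-corrected, duplicate-merged normalized intensities.

    ``data`` holds formulae (rows, Hill strings) x merged samples
    (columns); every column sums to one. ``samples`` is one manifest row
    per merged sample. Provenance counters record what the engine removed.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    blank_removed: int = 0
    duplicate_dropped: int = 0

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=0).to_numpy()
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("merged matrix columns must each sum to 1")


def merged_sample_id(habitat: str, pool: str, condition: str,
                     time_days: float) -> str:
    return f"{habitat}_{pool}_{condition}_T{time_days:g}"


def merge_duplicates(long_table: pd.DataFrame, manifest: pd.DataFrame,
                     n_replicates: int = 2,
                     blank_removed: int = 0) -> IntensityMatrix:
    """Merge replicate measurements into one column per sample.

    Per replicate, intensities are normalized to sum 1; a formula is
    present only when detected in all replicates of the sample; the merged
    value is the mean of the normalized replicate intensities,
    re-normalized to sum 1.
    """
    man = manifest[manifest["is_blank"] != True].copy()  # noqa: E712
    man["merged_id"] = [
        merged_sample_id(r["habitat"], r["pool"], r["condition"],
                         r["time_days"]) for _, r in man.iterrows()]
    by_measurement = {
        sid: g.groupby("formula")["intensity"].sum()
        for sid, g in long_table[long_table["formula"] != ""].groupby("sample_id")}

    columns: dict[str, pd.Series] = {}
    merged_rows = []
    dropped = 0
    for merged_id, g in man.groupby("merged_id", sort=True):
        sids = sorted(g["sample_id"])
        if len(sids) != n_replicates:
            raise ValueError(
                f"sample {merged_id!r} has {len(sids)} replicates, "
                f"expected {n_replicates}")
        reps = []
        for sid in sids:
            s = by_measurement.get(sid, pd.Series(dtype=float))
            total = s.sum()
            if total <= 0:
                s = pd.Series(dtype=float)
            else:
                s = s / total
            reps.append(s)
        common = set(reps[0].index)
        union = set(reps[0].index)
        for s in reps[1:]:
            common &= set(s.index)
            union |= set(s.index)
        dropped += len(union) - len(common)
        common_list = sorted(common)
        if common_list:
            merged = pd.Series(
                np.mean([s.reindex(common_list).to_numpy() for s in reps],
                        axis=0),
                index=common_list)
            merged = merged / merged.sum()
        else:
            merged = pd.Series(dtype=float)
        columns[merged_id] = merged
        first = g.iloc[0]
        merged_rows.append({
            "sample_id": merged_id, "habitat": first["habitat"],
            "pool": first["pool"], "condition": first["condition"],
            "time_days": first["time_days"], "is_blank": False,
        })

    data = pd.DataFrame(columns).fillna(0.0).sort_index()
    return IntensityMatrix(data=data, samples=pd.DataFrame(merged_rows),
                           blank_removed=blank_removed,
                           duplicate_dropped=dropped)


# ---------------------------------------------------------------------------
# end-to-end engine run

@dataclass(frozen=True)
class EngineParams:
    """Tunables of the peak-to-matrix engine (defaults follow common
    ultrahigh-resolution organic-matter practice)."""

    constraints: ElementConstraints = ElementConstraints()
    tolerance_ppm: float = 0.5
    mdl_factor: float = 2.0
    noise_level: float | None = None   # None: estimate per spectrum
    series_blocks: tuple[str, ...] = DEFAULT_SERIES_BLOCKS
    min_series_links: int = 1
    series_consensus: bool = True
    consensus_iterations: int = 0
    degeneracy_ppm: float = 0.2
    verify_isotopes: bool = True
    ratio_tolerance_permil: float = 1000.0
    n_replicates: int = 2


def process_peaks(peaks: Mapping[str, pd.DataFrame], manifest: pd.DataFrame,
                  params: EngineParams | None = None,
                  calibrants: Sequence[tuple[MolecularFormula, float]] | None = None,
                  ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Run the full engine on per-measurement peak tables.

    Returns the merged intensity matrix and a per-peak audit table
    (measurement id, m/z, assigned formula, mass error, series support,
    isotope outcome).
    """
    params = params or EngineParams()
    table = build_formula_table(params.constraints)
    audit_parts = []
    long_rows = []
    filtered_specs: dict[str, tuple[pd.DataFrame, float]] = {}
    for sid in sorted(peaks):
        filtered, mdl = mdl_filter(peaks[sid], params.mdl_factor,
                                   params.noise_level)
        if calibrants:
            filtered = recalibrate(filtered, calibrants,
                                   params.tolerance_ppm, mdl=mdl)
        filtered_specs[sid] = (filtered, mdl)
    order = sorted(filtered_specs)
    neutrals = {sid: filtered_specs[sid][0]["mz"].to_numpy(dtype=float)
                + PROTON_MASS for sid in order}

    # experiment-wide candidate-composition pool: the series network spans
    # the aligned dataset, so one replicate missing a series member does
    # not orphan the rest of the family
    support_pool: set[tuple[int, ...]] = set()
    for sid in order:
        for m in neutrals[sid]:
            for i in candidate_indices(table, m, params.tolerance_ppm):
                support_pool.add(tuple(int(x) for x in table.counts[int(i)]))

    def assign_all(scores):
        return {sid: assign_formulas(
            filtered_specs[sid][0], params.constraints, params.tolerance_ppm,
            params.series_blocks, params.min_series_links,
            series_consensus=params.series_consensus,
            degeneracy_ppm=params.degeneracy_ppm,
            comp_score=scores, support_pool=support_pool,
            table=table) for sid in order}

    shared_scores = None
    if params.series_consensus:
        # join candidate evidence across all measurements: one aligned-ion
        # score table for the whole experiment, then refine it from the
        # assignment winners so close real ion pairs disentangle
        shared_scores = aligned_ion_scores(
            [neutrals[sid] for sid in order], table, params.tolerance_ppm)
        for _ in range(params.consensus_iterations):
            assignments = assign_all(shared_scores)
            shared_scores = winner_ion_scores(
                [(neutrals[sid], assignments[sid]) for sid in order])
    assignments = assign_all(shared_scores)

    for sid in order:
        filtered, mdl = filtered_specs[sid]
        assigned = assignments[sid]
        if params.verify_isotopes:
            assigned = verify_isotopes(
                assigned, filtered,
                ratio_tolerance_permil=params.ratio_tolerance_permil,
                mdl=mdl)
            ok = assigned["isotope_check"].isin(("ok", "no_isotope"))
        else:
            assigned["isotope_check"] = "skipped"
            ok = pd.Series(True, index=assigned.index)
        assigned.insert(0, "sample_id", sid)
        audit_parts.append(assigned)
        keep = assigned[(assigned["formula"] != "") & ok]
        long_rows.append(keep[["sample_id", "formula", "intensity"]])

    audit = pd.concat(audit_parts, ignore_index=True)
    long_table = pd.concat(long_rows, ignore_index=True)
    blank_ids = set(manifest.loc[manifest["is_blank"] == True, "sample_id"])  # noqa: E712
    long_table, n_blank = remove_blank_peaks(long_table, blank_ids)
    matrix = merge_duplicates(long_table, manifest, params.n_replicates,
                              blank_removed=n_blank)
    return matrix, audit
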