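"""Time-course classification of molecular formulae into process pools.

Each formula's relative-intensity trajectory in the merged matrix is
classified per habitat into the process pools of the incubation design:

* ``transferred`` — present in the particulate pool at T0 and appearing in
  the dissolved pool exclusively under light at later times (abiotic
  release / leaching from particles plus photosynthetic export).
* ``photoproduced`` / ``photo_degraded`` — consistent increase / decrease
  of the dissolved-pool series under light but not under dark (autotrophic
  photoproduction; photochemical degradation).
* ``hetero_produced`` / ``hetero_degraded`` — consistent increase /
  decrease under dark, light behaviour notwithstanding (heterotrophic
  microbial processes run in the dark bottles but not exclusively there).
* ``refractory`` — present in every measured sample of the habitat and
  never classified as degraded.

"Consistent" monotone change is operationalized by :class:`MonotoneRule`:
every consecutive step must move in the trend direction or counter-move by
at most ``tolerance_rel`` relative to the running extremum, and the net
change over the series must exceed ``min_net_change_rel`` — a trend that
is not resolvable beyond replicate noise is not a trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import descriptors as desc_mod
from .formulas import MolecularFormula

LIGHT = "light"
DARK = "dark"
INITIAL = "initial"
BLANK = "blank"

DOM = "DOM"
POM_HW = "POM_HW"
POM_NAOH = "POM_NAOH"
POM_POOLS = (POM_HW, POM_NAOH)

TRANSFERRED = "transferred"
PHOTOPRODUCED = "photoproduced"
PHOTO_DEGRADED = "photo_degraded"
HETERO_PRODUCED = "hetero_produced"
HETERO_DEGRADED = "hetero_degraded"
REFRACTORY = "refractory"
UNCLASSIFIED = "unclassified"

PROCESS_LABELS = (TRANSFERRED, PHOTOPRODUCED, PHOTO_DEGRADED,
                  HETERO_PRODUCED, HETERO_DEGRADED, REFRACTORY)


@dataclass(frozen=True)
class MonotoneRule:
    """Noise-tolerant monotonicity test for short time series.

    tolerance_rel
        Allowed relative counter-movement of one step against the running
        extremum (default 0.10).
    min_points
        Minimum number of observed timepoints (default 3).
    zero_eps
        Intensity at or below which a formula counts as absent (default 0).
    min_net_change_rel
        Required relative net change between the first and last point
        (default 0.20, about four times a typical measurement CV); a series
        whose overall change is smaller is neither an increase nor a
        decrease.
    """

    tolerance_rel: float = 0.10
    min_points: int = 3
    zero_eps: float = 0.0
    min_net_change_rel: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance_rel < 1:
            raise ValueError("tolerance_rel must be in [0, 1)")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


def is_consistent_decrease(times: Sequence[float], values: Sequence[float],
                           rule: MonotoneRule | None = None,
                           ) -> tuple[bool, bool, float | None]:
    """Whether a series decreases consistently; returns
    ``(ok, reached_zero, event_time)``.

    The series must start present (above ``zero_eps`` at the first point),
    every step must go down or counter-move by less than ``tolerance_rel``
    of the running minimum, and the final value must undercut the initial
    one by more than ``min_net_change_rel``. ``reached_zero`` is true when
    the series hits ``zero_eps`` and stays there; ``event_time`` is the
    first such time (otherwise the last observed time when ``ok``).
    """
    rule = rule or MonotoneRule()
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    if len(x) < rule.min_points:
        return False, False, None
    if x[0] <= rule.zero_eps:  # not present at T0: not eligible
        return False, False, None
    run_min = x[0]
    for prev, cur in zip(x[:-1], x[1:]):
        if not (cur <= prev or cur < (1 + rule.tolerance_rel) * run_min):
            return False, False, None
        run_min = min(run_min, cur)
    if not x[-1] < x[0] * (1 - rule.min_net_change_rel):
        return False, False, None
    reached_zero = False
    event_time: float | None = float(t[-1])
    below = x <= rule.zero_eps
    if below.any():
        first = int(np.argmax(below))
        if below[first:].all():
            reached_zero = True
            event_time = float(t[first])
    return True, reached_zero, event_time


def is_consistent_increase(times: Sequence[float], values: Sequence[float],
                           rule: MonotoneRule | None = None,
                           ) -> tuple[bool, float | None]:
    """Mirror of :func:`is_consistent_decrease`; returns ``(ok, max_time)``
    with ``max_time`` the time of the series maximum."""
    rule = rule or MonotoneRule()
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    if len(x) < rule.min_points:
        return False, None
    run_max = x[0]
    for prev, cur in zip(x[:-1], x[1:]):
        if not (cur >= prev or cur > (1 - rule.tolerance_rel) * run_max):
            return False, None
        run_max = max(run_max, cur)
    if not x[-1] > x[0] * (1 + rule.min_net_change_rel):
        return False, None
    return True, float(t[int(np.argmax(x))])


class TrajectoryClassifier:
    """Classifies formulae of a merged intensity matrix into process pools.

    Parameters
    ----------
    matrix
        Formula x sample intensity table (normalized columns); the column
        names must appear in ``manifest["sample_id"]``.
    manifest
        One row per merged sample with columns ``sample_id``, ``habitat``,
        ``pool``, ``condition`` (light / dark / initial) and ``time_days``.
    rule
        Monotonicity rule; defaults to :class:`MonotoneRule`.
    strict_transfer
        When true (default) transfer requires absence from dissolved dark
        samples at every t > 0; the relaxed mode requires absence in at
        least 80% of the dark timepoints.
    """

    def __init__(self, matrix: pd.DataFrame, manifest: pd.DataFrame,
                 rule: MonotoneRule | None = None,
                 strict_transfer: bool = True) -> None:
        self.matrix = matrix
        self.rule = rule or MonotoneRule()
        self.strict_transfer = strict_transfer
        man = manifest.drop_duplicates("sample_id").set_index("sample_id")
        man = man[man.get("is_blank", False) != True]  # noqa: E712
        self.manifest = man
        self._columns: dict[tuple[str, str, str], list[tuple[float, str]]] = {}
        for sid, row in man.iterrows():
            if sid not in matrix.columns:
                continue
            key = (row["habitat"], row["pool"],
                   INITIAL if row["condition"] == INITIAL else row["condition"])
            self._columns.setdefault(key, []).append((float(row["time_days"]), sid))
        for cols in self._columns.values():
            cols.sort()

    # -- series assembly ---------------------------------------------------

    def series(self, formula: str, habitat: str, pool: str, condition: str,
               ) -> tuple[np.ndarray, np.ndarray]:
        """(times, intensities) of one formula; the shared T0 sample of the
        pool opens both the light and the dark series; absent formulae or
        samples contribute zero / nothing."""
        cols = list(self._columns.get((habitat, pool, INITIAL), []))
        cols += self._columns.get((habitat, pool, condition), [])
        cols.sort(key=lambda c: c[0])
        times = np.array([t for t, _ in cols])
        if formula in self.matrix.index:
            vals = np.array([float(self.matrix.at[formula, sid]) for _, sid in cols])
        else:
            vals = np.zeros(len(cols))
        return times, vals

    def _habitat_formulae(self, habitat: str) -> pd.Index:
        sids = [sid for (h, _, _), cols in self._columns.items()
                for _, sid in cols if h == habitat]
        sub = self.matrix[sids]
        return self.matrix.index[(sub > 0).any(axis=1)]

    def _present_at_t0(self, formula: str, habitat: str, pool: str) -> bool:
        cols = self._columns.get((habitat, pool, INITIAL), [])
        if formula not in self.matrix.index:
            return False
        return any(self.matrix.at[formula, sid] > self.rule.zero_eps
                   for _, sid in cols)

    # -- the four decision families ---------------------------------------

    def classify_dark(self, formula: str, habitat: str) -> str | None:
        """Heterotrophic production/degradation from the dissolved dark series."""
        t, x = self.series(formula, habitat, DOM, DARK)
        if len(t) == 0:
            return None
        dec, _, _ = is_consistent_decrease(t, x, self.rule)
        if dec and self._present_at_t0(formula, habitat, DOM):
            return HETERO_DEGRADED
        inc, _ = is_consistent_increase(t, x, self.rule)
        if inc:
            return HETERO_PRODUCED
        return None

    def classify_light(self, formula: str, habitat: str) -> str | None:
        """Photoproduction/photodegradation: the light trend must be absent
        from the dark series (light-exclusive processes)."""
        tl, xl = self.series(formula, habitat, DOM, LIGHT)
        td, xd = self.series(formula, habitat, DOM, DARK)
        if len(tl) == 0:
            return None
        inc_l, _ = is_consistent_increase(tl, xl, self.rule)
        if inc_l:
            inc_d, _ = is_consistent_increase(td, xd, self.rule)
            if not inc_d:
                return PHOTOPRODUCED
        dec_l, _, _ = is_consistent_decrease(tl, xl, self.rule)
        if dec_l:
            dec_d, _, _ = is_consistent_decrease(td, xd, self.rule)
            if not dec_d:
                return PHOTO_DEGRADED
        return None

    def classify_transfer(self, formula: str, habitat: str,
                          ) -> tuple[str | None, str | None]:
        """(label, extract_of_origin): particulate-to-dissolved transfer
        under light. Requires membership in the particulate pool at T0 and
        light-exclusive appearance in the dissolved pool at t > 0."""
        extracts = [pool for pool in POM_POOLS
                    if self._present_at_t0(formula, habitat, pool)]
        if not extracts:
            return None, None
        tl, xl = self.series(formula, habitat, DOM, LIGHT)
        light_later = bool(((tl > 0) & (xl > self.rule.zero_eps)).any())
        if not light_later:
            return None, None
        td, xd = self.series(formula, habitat, DOM, DARK)
        later = td > 0
        dark_hits = int(((xd > self.rule.zero_eps) & later).sum())
        if self.strict_transfer:
            ok = dark_hits == 0
        else:
            ok = later.sum() > 0 and dark_hits <= 0.2 * later.sum()
        if not ok:
            return None, None
        return TRANSFERRED, "+".join(extracts)

    def classify_refractory(self, formula: str, habitat: str,
                            degraded: bool) -> str | None:
        """Always present — over every measured sample of every pool the
        formula occurs in at all — and not carrying a degraded label."""
        if degraded:
            return None
        if formula not in self.matrix.index:
            return None
        pools = []
        for pool in (DOM, *POM_POOLS):
            sids = [sid for cond in (INITIAL, LIGHT, DARK)
                    for _, sid in self._columns.get((habitat, pool, cond), [])]
            if any(self.matrix.at[formula, sid] > self.rule.zero_eps
                   for sid in sids):
                pools.append(pool)
        if not pools:
            return None
        for pool in pools:
            for cond in (INITIAL, LIGHT, DARK):
                for _, sid in self._columns.get((habitat, pool, cond), []):
                    if not (formula in self.matrix.index
                            and self.matrix.at[formula, sid] > self.rule.zero_eps):
                        return None
        return REFRACTORY

    # -- full run ----------------------------------------------------------

    def classify_all(self, habitats: Iterable[str] | None = None) -> pd.DataFrame:
        """Label every formula of every habitat.

        Returns one row per (formula, habitat) with the family columns
        (``transfer``, ``light``, ``dark``, ``refractory``), auxiliary
        degradation info and a single ``label`` column (first label in
        family order transfer > light > dark > refractory, else
        unclassified) for truth-table comparisons.
        """
        if habitats is None:
            habitats = sorted({h for (h, _, _) in self._columns})
        rows = []
        for habitat in habitats:
            for formula in self._habitat_formulae(habitat):
                transfer, extract = self.classify_transfer(formula, habitat)
                light = self.classify_light(formula, habitat)
                dark = self.classify_dark(formula, habitat)
                degraded = PHOTO_DEGRADED in (light,) or HETERO_DEGRADED in (dark,)
                refractory = self.classify_refractory(formula, habitat, degraded)
                reached_zero = False
                event_time = None
                if dark == HETERO_DEGRADED:
                    t, x = self.series(formula, habitat, DOM, DARK)
                    _, reached_zero, event_time = is_consistent_decrease(
                        t, x, self.rule)
                elif light == PHOTO_DEGRADED:
                    t, x = self.series(formula, habitat, DOM, LIGHT)
                    _, reached_zero, event_time = is_consistent_decrease(
                        t, x, self.rule)
                label = (transfer or light or dark or refractory
                         or UNCLASSIFIED)
                rows.append({
                    "formula": formula, "habitat": habitat,
                    "transfer": transfer, "extract": extract,
                    "light": light, "dark": dark,
                    "refractory": refractory == REFRACTORY,
                    "reached_zero": bool(reached_zero),
                    "event_time": event_time,
                    "label": label,
                })
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------

    def pool_percentages(self, labels: pd.DataFrame,
                         windows: "desc_mod.CategoryWindows | None" = None,
                         with_summaries: bool = True) -> dict[str, dict]:
        """Process-pool percentages per habitat with the denominators of the
        incubation design: transfer relative to the particulate T0 formula
        count, production/degradation relative to the dissolved T0 count,
        refractory relative to all habitat formulae. Each pool also carries
        an intensity-weighted descriptor summary (weights are the formula's
        mean normalized intensity over the habitat's samples)."""
        report: dict[str, dict] = {}
        for habitat, sub in labels.groupby("habitat", sort=True):
            pom_t0 = {f for f in self.matrix.index
                      for pool in POM_POOLS
                      if self._present_at_t0(f, habitat, pool)}
            dom_t0 = {f for f in self.matrix.index
                      if self._present_at_t0(f, habitat, DOM)}
            n_hab = len(self._habitat_formulae(habitat))
            if not pom_t0 or not dom_t0:
                raise ValueError(
                    f"habitat {habitat!r}: empty T0 denominator "
                    f"(POM-T0 {len(pom_t0)}, DOM-T0 {len(dom_t0)})")
            sets = {
                TRANSFERRED: set(sub.loc[sub["transfer"] == TRANSFERRED,
                                         "formula"]),
                PHOTOPRODUCED: set(sub.loc[sub["light"] == PHOTOPRODUCED,
                                           "formula"]),
                PHOTO_DEGRADED: set(sub.loc[sub["light"] == PHOTO_DEGRADED,
                                            "formula"]),
                HETERO_PRODUCED: set(sub.loc[sub["dark"] == HETERO_PRODUCED,
                                             "formula"]),
                HETERO_DEGRADED: set(sub.loc[sub["dark"] == HETERO_DEGRADED,
                                             "formula"]),
                REFRACTORY: set(sub.loc[sub["refractory"], "formula"]),
            }
            entry: dict[str, object] = {
                "n_formulae": n_hab,
                "n_pom_t0": len(pom_t0),
                "n_dom_t0": len(dom_t0),
                "transferred_pct": 100.0 * len(sets[TRANSFERRED]) / len(pom_t0),
                "photoproduced_pct": 100.0 * len(sets[PHOTOPRODUCED]) / len(dom_t0),
                "photo_degraded_pct": 100.0 * len(sets[PHOTO_DEGRADED]) / len(dom_t0),
                "hetero_produced_pct": 100.0 * len(sets[HETERO_PRODUCED]) / len(dom_t0),
                "hetero_degraded_pct": 100.0 * len(sets[HETERO_DEGRADED]) / len(dom_t0),
                "refractory_count": len(sets[REFRACTORY]),
                "refractory_pct": 100.0 * len(sets[REFRACTORY]) / n_hab,
            }
            if with_summaries:
                sids = [sid for (h, _, _), cols in self._columns.items()
                        for _, sid in cols if h == habitat]
                mean_int = self.matrix[sids].mean(axis=1)
                summaries = {}
                for name, fset in sets.items():
                    fs = sorted(fset)
                    if fs:
                        summaries[name] = desc_mod.weighted_summary(
                            self.matrix, fs, sids[0], windows,
                            weights=mean_int.to_dict())
                entry["summaries"] = summaries
            report[habitat] = entry
        return report
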