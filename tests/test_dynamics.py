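"""Monotone-trend rules and trajectory classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cryodom import dynamics as dyn
from cryodom.dynamics import (
    MonotoneRule,
    TrajectoryClassifier,
    is_consistent_decrease,
    is_consistent_increase,
)

T = [0.0, 3.0, 6.0, 9.0, 15.0]


class TestMonotoneRules:
    def test_strict_decrease_to_zero(self):
        ok, zero, t = is_consistent_decrease(T, [10, 8, 5, 0, 0])
        assert ok and zero and t == 9.0

    def test_backstep_above_tolerance_fails(self):
        # a 10% rise over the running minimum is not allowed (strictly)
        ok, _, _ = is_consistent_decrease([0, 1, 2, 3], [10, 11, 5, 1])
        assert not ok

    def test_small_backstep_within_tolerance_passes(self):
        ok, zero, _ = is_consistent_decrease([0, 1, 2, 3], [10, 6, 6.3, 2])
        assert ok and not zero

    def test_constant_series_is_no_trend(self):
        assert not is_consistent_decrease([0, 1, 2], [10, 10, 10])[0]
        assert not is_consistent_increase([0, 1, 2], [10, 10, 10])[0]

    def test_increase_from_zero(self):
        ok, tmax = is_consistent_increase([0, 1, 2, 3], [0, 2, 5, 9])
        assert ok and tmax == 3

    def test_decrease_requires_t0_presence(self):
        assert not is_consistent_decrease([0, 1, 2], [0, 5, 1])[0]

    def test_plain_decrease_is_not_an_increase(self):
        assert not is_consistent_increase([0, 1, 2], [5, 4, 3])[0]

    def test_short_series_not_eligible(self):
        assert not is_consistent_decrease([0, 1], [5, 1])[0]

    def test_net_change_requirement(self):
        # a decline smaller than the net-change threshold is noise, not trend
        assert not is_consistent_decrease([0, 1, 2], [10, 9.6, 9.2])[0]
        assert is_consistent_decrease([0, 1, 2], [10, 6, 2])[0]

    def test_mutually_exclusive_on_varying_series(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.random(6) * 10 + 0.1
            t = np.arange(6, dtype=float)
            dec = is_consistent_decrease(t, x)[0]
            inc = is_consistent_increase(t, x)[0]
            assert not (dec and inc)

    def test_noisy_logistic_detected(self):
        # planted production with 5% multiplicative noise must be accepted
        # in at least 95% of cases
        rng = np.random.default_rng(1)
        times = np.array([0.0, 3, 6, 9, 15, 22, 24])
        sig = 1 / (1 + np.exp(-0.25 * (times - 15.0)))
        base = (sig - sig[0]) / (sig[-1] - sig[0])
        sigma = np.sqrt(np.log(1 + 0.05 ** 2))
        hits = 0
        n = 400
        for _ in range(n):
            noisy = base * np.exp(rng.normal(0, sigma, len(base))
                                  - sigma ** 2 / 2)
            noisy[0] = 0.0
            hits += is_consistent_increase(times, noisy)[0]
        assert hits / n >= 0.95

    def test_flat_noisy_series_rarely_trends(self):
        # instrument noise alone must not create trends (this property is
        # what keeps the refractory pool recoverable)
        rng = np.random.default_rng(2)
        times = np.arange(7, dtype=float)
        sigma = np.sqrt(np.log(1 + 0.05 ** 2))
        false = 0
        n = 1000
        for _ in range(n):
            x = np.exp(rng.normal(0, sigma, 7))
            false += (is_consistent_decrease(times, x)[0]
                      or is_consistent_increase(times, x)[0])
        assert false / n <= 0.02

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            MonotoneRule(tolerance_rel=1.5)
        with pytest.raises(ValueError):
            MonotoneRule(min_points=1)


def _mini_matrix(series: dict[str, dict[str, list[float]]],
                 times=(0.0, 3.0, 6.0, 9.0)) -> TrajectoryClassifier:
    """Build a classifier from {formula: {pool_condition: values}} where the
    key is e.g. 'DOM_light'; T0 comes from '<pool>_initial' single value."""
    cols = {}
    rows = []
    for f, d in series.items():
        for key, vals in d.items():
            pool, cond = key.rsplit("_", 1)
            if cond == "initial":
                sid = f"H_{pool}_initial_T0"
                cols.setdefault(sid, {})[f] = vals[0]
                rows.append((sid, pool, "initial", 0.0))
            else:
                for t, v in zip(times[1:], vals):
                    sid = f"H_{pool}_{cond}_T{t:g}"
                    cols.setdefault(sid, {})[f] = v
                    rows.append((sid, pool, cond, t))
    matrix = pd.DataFrame(cols).fillna(0.0)
    manifest = pd.DataFrame(
        [{"sample_id": sid, "habitat": "H", "pool": pool,
          "condition": cond, "time_days": t, "is_blank": False}
         for sid, pool, cond, t in dict.fromkeys(rows)])
    manifest = manifest.drop_duplicates("sample_id")
    return TrajectoryClassifier(matrix, manifest)


class TestClassifierRules:
    def test_dark_decrease_with_t0_is_heterotrophic(self):
        clf = _mini_matrix({
            "C6H10O5": {"DOM_initial": [10], "DOM_dark": [6, 3, 1],
                        "DOM_light": [10, 10, 10]},
        })
        assert clf.classify_dark("C6H10O5", "H") == dyn.HETERO_DEGRADED

    def test_dark_rule_ignores_light_behaviour(self):
        # decreasing in both conditions: still heterotrophic ("not
        # exclusively" under dark)
        clf = _mini_matrix({
            "C6H10O5": {"DOM_initial": [10], "DOM_dark": [6, 3, 1],
                        "DOM_light": [6, 3, 1]},
        })
        assert clf.classify_dark("C6H10O5", "H") == dyn.HETERO_DEGRADED
        assert clf.classify_light("C6H10O5", "H") is None

    def test_light_exclusivity_for_photoproduction(self):
        rising = [2, 5, 9]
        clf = _mini_matrix({
            "A": {"DOM_initial": [0], "DOM_light": rising,
                  "DOM_dark": [0, 0, 0]},
            "B": {"DOM_initial": [0], "DOM_light": rising,
                  "DOM_dark": rising},
        })
        assert clf.classify_light("A", "H") == dyn.PHOTOPRODUCED
        assert clf.classify_light("B", "H") is None
        assert clf.classify_dark("B", "H") == dyn.HETERO_PRODUCED

    def test_light_only_decay_is_photodegradation(self):
        clf = _mini_matrix({
            "A": {"DOM_initial": [10], "DOM_light": [6, 3, 0],
                  "DOM_dark": [10, 10, 10]},
        })
        assert clf.classify_light("A", "H") == dyn.PHOTO_DEGRADED

    def test_transfer_requires_dark_absence(self):
        base = {"POM_HW_initial": [5]}
        clf = _mini_matrix({
            "A": dict(base, DOM_initial=[0], DOM_light=[1, 2, 1],
                      DOM_dark=[0, 0, 0]),
            "B": dict(base, DOM_initial=[0], DOM_light=[1, 2, 1],
                      DOM_dark=[0, 1, 0]),
            "C": {"DOM_initial": [0], "DOM_light": [1, 2, 1],
                  "DOM_dark": [0, 0, 0]},
        })
        label, extract = clf.classify_transfer("A", "H")
        assert label == dyn.TRANSFERRED and extract == dyn.POM_HW
        assert clf.classify_transfer("B", "H") == (None, None)  # dark hit
        assert clf.classify_transfer("C", "H") == (None, None)  # no POM-T0

    def test_refractory_needs_every_sample(self):
        always = {"DOM_initial": [5], "DOM_light": [5, 5, 5],
                  "DOM_dark": [5, 5, 5]}
        gap = {"DOM_initial": [5], "DOM_light": [5, 0, 5],
               "DOM_dark": [5, 5, 5]}
        clf = _mini_matrix({"A": always, "B": gap})
        assert clf.classify_refractory("A", "H", degraded=False) == \
            dyn.REFRACTORY
        assert clf.classify_refractory("B", "H", degraded=False) is None

    def test_degraded_label_vetoes_refractory(self):
        clf = _mini_matrix({
            "A": {"DOM_initial": [10], "DOM_dark": [7, 5, 4],
                  "DOM_light": [10, 10, 10]},
        })
        labels = clf.classify_all()
        row = labels.iloc[0]
        assert row["dark"] == dyn.HETERO_DEGRADED
        assert not row["refractory"]


class TestFullRunInvariants:
    def test_family_exclusivity(self, noisy_run):
        lab = noisy_run.labels
        assert not ((lab["dark"] == dyn.HETERO_PRODUCED)
                    & (lab["dark"] == dyn.HETERO_DEGRADED)).any()
        both = lab[(lab["light"] == dyn.PHOTOPRODUCED)
                   & (lab["dark"] == dyn.HETERO_PRODUCED)]
        assert len(both) == 0
        degraded = lab[(lab["light"] == dyn.PHOTO_DEGRADED)
                       | (lab["dark"] == dyn.HETERO_DEGRADED)]
        assert not degraded["refractory"].any()

    def test_percentages_are_bounded(self, noisy_run):
        for habitat, entry in noisy_run.report.items():
            for key, val in entry.items():
                if key.endswith("_pct"):
                    assert 0.0 <= val <= 100.0, (habitat, key, val)
            n_tr = entry["transferred_pct"] / 100 * entry["n_pom_t0"]
            assert n_tr <= entry["n_pom_t0"]

    def test_zero_percentage_when_nothing_planted(self):
        # all-refractory world: no production, degradation or transfer
        from cryodom import synthetic as syn
        from cryodom.engine import EngineParams, process_peaks
        truth = syn.PlantedTruth(
            n_formulae=40, class_fractions={dyn.REFRACTORY: 1.0},
            n_contaminants=5, n_spiked_contaminants=0).zero_noise()
        exp = syn.simulate_experiment(syn.ExperimentDesign(), truth, seed=5)
        matrix, _ = process_peaks(exp.peaks, exp.manifest,
                                  EngineParams(noise_level=1.0))
        clf = TrajectoryClassifier(matrix.data, matrix.samples)
        report = clf.pool_percentages(clf.classify_all(),
                                      with_summaries=False)
        for entry in report.values():
            assert entry["hetero_degraded_pct"] == 0.0
            assert entry["photoproduced_pct"] == 0.0
            assert entry["transferred_pct"] == 0.0
            assert entry["refractory_pct"] == 100.0
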