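"""Shared fixtures: synthetic experiments at the study's design scale.

The full-design runs (2 habitats x 3 pools x 7 timepoints x duplicates,
1000 formulae) are expensive enough to build once per session; several
test modules and the acceptance checks reuse them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cryodom import dynamics as dyn
from cryodom import synthetic as syn
from cryodom.engine import EngineParams, process_peaks

#: a constant noise floor well below every planted intensity; the spectra
#: carry no synthetic noise peaks, so the estimator has nothing to estimate
ENGINE_PARAMS = EngineParams(noise_level=1.0)


class PipelineRun:
    """One simulated experiment pushed through engine + classifier."""

    def __init__(self, truth: syn.PlantedTruth, seed: int):
        self.design = syn.ExperimentDesign()
        self.truth_params = truth
        self.exp = syn.simulate_experiment(self.design, truth, seed)
        self.matrix, self.audit = process_peaks(
            self.exp.peaks, self.exp.manifest, ENGINE_PARAMS)
        self.classifier = dyn.TrajectoryClassifier(
            self.matrix.data, self.matrix.samples)
        self.labels = self.classifier.classify_all()
        self.report = self.classifier.pool_percentages(
            self.labels, with_summaries=False)
        self.comparison = self.labels.merge(
            self.exp.truth, on=["formula", "habitat"],
            suffixes=("_rec", "_true"))

    def recovery(self, label: str) -> float:
        sub = self.comparison[self.comparison["label_true"] == label]
        return float((sub["label_rec"] == label).mean())


@pytest.fixture(scope="session")
def zero_noise_run() -> PipelineRun:
    """Full design, 1000 formulae, every stochastic corruption disabled."""
    return PipelineRun(syn.PlantedTruth(n_formulae=1000).zero_noise(), seed=42)


@pytest.fixture(scope="session")
def noisy_run() -> PipelineRun:
    """Full design, 1000 formulae, default noise (CV 0.05, 0.1 ppm mass
    error, 2% replicate dropout)."""
    return PipelineRun(syn.PlantedTruth(n_formulae=1000), seed=42)


@pytest.fixture(scope="session")
def small_experiment() -> syn.SimulatedExperiment:
    """A fast zero-noise experiment for structural tests."""
    return syn.simulate_experiment(
        syn.ExperimentDesign(),
        syn.PlantedTruth(n_formulae=120, n_contaminants=10,
                         n_spiked_contaminants=5).zero_noise(),
        seed=3)
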