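"""Compositional comparison of habitats: Bray-Curtis dissimilarity,
non-metric multidimensional scaling (NMDS) and habitat-signal extraction.

Samples are compared on their normalized formula intensities with the
Bray-Curtis dissimilarity and embedded in two dimensions by NMDS
(Kruskal stress-1, best of several seeded random restarts). Formula
loadings are intensity-weighted averages of the sample coordinates,
min-max aligned to the coordinate range; formulae with extreme loadings
on the first axis are the molecular signal of each habitat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity of an intensity matrix
    (formulae x samples, columns normalized)."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.to_numpy(dtype=float).T
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample column")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class OrdinationResult:
    """Two-dimensional NMDS embedding with formula loadings."""

    coordinates: pd.DataFrame   # samples x (NMDS1, NMDS2), centered
    stress: float               # Kruskal stress-1
    loadings: pd.DataFrame      # formulae x (NMDS1, NMDS2), min-max aligned
    seed: int
    n_restarts: int


def nmds(dissimilarity: pd.DataFrame, matrix: pd.DataFrame | None = None,
         k: int = 2, seed: int = 0, n_restarts: int = 50,
         max_iter: int = 300) -> OrdinationResult:
    """Best-of-restarts non-metric MDS of a dissimilarity matrix.

    ``matrix`` (formulae x samples) is required to compute formula
    loadings: each formula is placed at the intensity-weighted average of
    the sample coordinates, then min-max aligned to the coordinate range
    per axis. Deterministic for a fixed seed.
    """
    d = dissimilarity.to_numpy(dtype=float)
    import inspect
    kwargs = dict(n_components=k, n_init=n_restarts, max_iter=max_iter,
                  random_state=seed, normalized_stress=True, eps=1e-9)
    params = inspect.signature(MDS).parameters
    if "metric_mds" in params:  # scikit-learn >= 1.9
        kwargs.update(metric_mds=False, metric="precomputed")
        if "init" in params:
            kwargs.update(init="random")
    else:  # older API
        kwargs.update(metric=False, dissimilarity="precomputed")
    model = MDS(**kwargs)
    coords = model.fit_transform(d)
    if not np.isfinite(model.stress_):
        raise RuntimeError("NMDS failed to converge in all restarts; "
                           f"stress trace ended at {model.stress_}")
    coords = coords - coords.mean(axis=0, keepdims=True)
    # display convention: one global scale factor puts the configuration in
    # [-1, 1] so loading thresholds are comparable across runs (stress-1 is
    # scale-invariant)
    extent = np.abs(coords).max()
    if extent > 0:
        coords = coords / extent
    axes = [f"NMDS{i + 1}" for i in range(k)]
    coordinates = pd.DataFrame(coords, index=dissimilarity.index,
                               columns=axes)

    loadings = pd.DataFrame(columns=axes)
    if matrix is not None:
        w = matrix[dissimilarity.index].to_numpy(dtype=float)
        totals = w.sum(axis=1)
        present = totals > 0
        raw = np.full((matrix.shape[0], k), np.nan)
        raw[present] = (w[present] @ coords) / totals[present, None]
        aligned = raw.copy()
        for j in range(k):
            col = raw[present, j]
            lo, hi = col.min(), col.max()
            if hi > lo:
                aligned[present, j] = (
                    (col - lo) / (hi - lo)
                    * (coords[:, j].max() - coords[:, j].min())
                    + coords[:, j].min())
        loadings = pd.DataFrame(aligned, index=matrix.index, columns=axes)
        loadings = loadings.dropna()
    return OrdinationResult(coordinates=coordinates,
                            stress=float(model.stress_),
                            loadings=loadings, seed=seed,
                            n_restarts=n_restarts)


def habitat_signal(result: OrdinationResult, sample_habitats: pd.Series,
                   threshold: float = 0.45,
                   ) -> dict[str, set[str]]:
    """Habitat-characteristic formula sets by first-axis loading threshold.

    Formulae with NMDS1 loading <= -``threshold`` belong to the habitat
    whose sample centroid lies on the negative side, those >= +``threshold``
    to the habitat on the positive side. (The threshold is applied
    symmetrically with opposite signs; a one-signed reading cannot select
    opposite sides.)
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    axis = result.loadings["NMDS1"]
    if axis.nunique() <= 1:
        raise ValueError("degenerate first axis: all loadings equal")
    habs = sample_habitats.loc[result.coordinates.index]
    centroids = result.coordinates["NMDS1"].groupby(habs).mean()
    if len(centroids) < 2:
        raise ValueError("need two habitats for a habitat signal")
    neg_hab = centroids.idxmin()
    pos_hab = centroids.idxmax()
    return {
        str(neg_hab): set(axis.index[axis <= -threshold]),
        str(pos_hab): set(axis.index[axis >= threshold]),
    }
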