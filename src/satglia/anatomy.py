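"""Observed astrocyte-neuron proximity from 2D ROI coordinate tables.

Works on section tables as produced by confocal quantification: one row per
cell with a type label, x/y soma centre (um, maximum-projection convention)
and soma area (um^2).  Provides nearest-astrocyte distances, apposition
calls via the circle-intersection chord proxy, Gaussian fits to distance
histograms, astrocyte location-probability heatmaps around a reference
neuron, and the soma-size vs proximity correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._util import round_half_away
from .field import validate_section_table
from .spatial import SomaGeometry, apposition_chord_length

__all__ = [
    "GaussianFit",
    "LocationMap",
    "nearest_astrocyte",
    "call_appositions",
    "apposition_percentage",
    "fit_gaussian_to_distances",
    "location_probability_map",
    "correlate_size_proximity",
]


@dataclass(frozen=True)
class GaussianFit:
    """Normal fit to a distance sample (maximum likelihood)."""

    mu: float
    sigma_fit: float
    n: int


@dataclass(frozen=True)
class LocationMap:
    """Smoothed occupancy grid of astrocyte positions relative to a neuron.

    ``grid[i, j]`` is the probability mass at offset
    (x = xcenters[j], y = ycenters[i]); the grid sums to 1.
    """

    grid: np.ndarray
    pixel_size: float
    filter_sigma: float
    window: float

    @property
    def centers(self) -> np.ndarray:
        n = self.grid.shape[0]
        half = (n - 1) / 2.0
        return (np.arange(n) - half) * self.pixel_size

    def peak_offset(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.grid)), self.grid.shape)
        c = self.centers
        return float(c[j]), float(c[i])


def nearest_astrocyte(table: pd.DataFrame, neuron_type: str) -> pd.DataFrame:
    """For each neuron of ``neuron_type``, the nearest astrocyte by 2D
    Euclidean centre distance.

    Returns one row per neuron with columns ``neuron_id, astro_id,
    center_distance, neuron_soma_area, astro_soma_area``.  Ties are broken
    in favour of the lowest astrocyte ``cell_id``.
    """
    validate_section_table(table)
    astro = table[table["cell_type"] == "astrocyte"]
    neurons = table[table["cell_type"] == neuron_type]
    if astro.empty:
        raise ValueError("section table contains no astrocytes")
    if neurons.empty:
        raise ValueError(f"section table contains no {neuron_type!r} cells")

    astro = astro.sort_values("cell_id", kind="stable").reset_index(drop=True)
    apos = astro[["x_um", "y_um"]].to_numpy(float)
    npos = neurons[["x_um", "y_um"]].to_numpy(float)
    # argmin takes the first (lowest-id) astrocyte on exact ties
    d2 = ((npos[:, None, :] - apos[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return pd.DataFrame({
        "neuron_id": neurons["cell_id"].to_numpy(),
        "astro_id": astro["cell_id"].to_numpy()[idx],
        "center_distance": np.sqrt(d2[np.arange(len(neurons)), idx]),
        "neuron_soma_area": neurons["soma_area_um2"].to_numpy(float),
        "astro_soma_area": astro["soma_area_um2"].to_numpy(float)[idx],
    })


def call_appositions(records: pd.DataFrame,
                     geometry: SomaGeometry = SomaGeometry()) -> pd.DataFrame:
    """Flag records whose soma circles appose by more than the threshold.

    Radii are inferred from soma areas by circle equivalence
    ``r = sqrt(A / pi)``; a pair is apposed when the intersection chord of
    the two circles exceeds ``geometry.apposition_threshold``.
    """
    out = records.copy()
    if not ((out["neuron_soma_area"] > 0).all()
            and (out["astro_soma_area"] > 0).all()):
        raise ValueError("soma areas must be positive")
    rn = np.sqrt(out["neuron_soma_area"].to_numpy(float) / math.pi)
    ra = np.sqrt(out["astro_soma_area"].to_numpy(float) / math.pi)
    chords = np.array([
        apposition_chord_length(d, max(a, b), min(a, b))
        for d, a, b in zip(out["center_distance"].to_numpy(float), rn, ra)])
    out["chord_um"] = chords
    out["apposed"] = chords > geometry.apposition_threshold
    return out


def apposition_percentage(records: pd.DataFrame) -> int:
    """Percentage of records flagged apposed, to the nearest integer."""
    if records.empty:
        raise ValueError("no records")
    frac = records["apposed"].to_numpy(bool).mean()
    return round_half_away(100.0 * frac)


def fit_gaussian_to_distances(distances) -> GaussianFit:
    """Maximum-likelihood normal fit to a sample of distances (um)."""
    d = np.asarray(distances, float)
    if d.size < 3:
        raise ValueError("need at least 3 distances")
    if not (d > 0).all():
        raise ValueError("distances must be positive")
    mu, sigma = stats.norm.fit(d)
    if sigma == 0:
        raise ValueError("zero-variance sample")
    return GaussianFit(mu=float(mu), sigma_fit=float(sigma), n=int(d.size))


def location_probability_map(offsets, pixel_size: float = 1.0,
                             filter_sigma: float = 24.0,
                             window: float = 60.0) -> LocationMap:
    """Astrocyte location-probability heatmap around a reference neuron.

    ``offsets`` is an (n, 2) array of astrocyte positions relative to their
    reference neuron (um).  Offsets are binned on a square grid of
    ``pixel_size`` um/pixel spanning +/- ``window`` um, smoothed with an
    isotropic Gaussian of ``filter_sigma`` pixels, and normalised to total
    mass 1.
    """
    off = np.atleast_2d(np.asarray(offsets, float))
    if off.size == 0:
        raise ValueError("no offsets")
    if off.shape[1] != 2:
        raise ValueError("offsets must be (n, 2)")

    n_px = 2 * int(round(window / pixel_size)) + 1
    half = window + pixel_size / 2.0
    edges = np.linspace(-half, half, n_px + 1)
    # histogram2d's first axis is x; transpose so grid rows are y
    hist, _, _ = np.histogram2d(off[:, 0], off[:, 1], bins=[edges, edges])
    grid = ndimage.gaussian_filter(hist.T, sigma=filter_sigma,
                                   mode="constant")
    total = grid.sum()
    if total <= 0:
        raise ValueError("all offsets fall outside the map window")
    return LocationMap(grid=grid / total, pixel_size=pixel_size,
                       filter_sigma=filter_sigma, window=window)


def correlate_size_proximity(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between neuron soma area and nearest-astrocyte
    centre distance, with a two-sided p value."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    area = records["neuron_soma_area"].to_numpy(float)
    dist = records["center_distance"].to_numpy(float)
    if np.std(area) == 0 or np.std(dist) == 0:
        raise ValueError("zero variance in soma area or distance")
    res = stats.pearsonr(area, dist)
    return float(res.statistic), float(res.pvalue)
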