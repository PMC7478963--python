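"""Subclone detection: Gaussian KDE over prevalences, peak finding, purity.

The pooled candidate prevalences are smoothed with a Gaussian kernel density
estimate; every local maximum of the density marks a subclone and the largest
maximum location is the tumor purity (the founder clone is present in all
tumor cells, so its SNVs attain the highest prevalence).

Bandwidth follows Scott's rule for one-dimensional data: the dimensionless
factor ``n^(-1/(d+4))`` (``scott_bandwidth``) scaled by the sample standard
deviation.  The kernel is ``exp(-((x - x_j)/h)^2)`` with normalizing constant
``Z = h*sqrt(pi)`` per point, so the density integrates to one over the real
line.

Peak finding evaluates the density on a fixed grid (resolution 0.001),
collects strict local maxima (boundary points included when they exceed
their single neighbor), refines each with Nelder-Mead, merges refined peaks
closer than a tolerance and prunes peaks whose density is a negligible
fraction of the global maximum.  Everything here is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SubcloneModel",
    "GaussianKDE",
    "select_clustering_input",
    "scott_bandwidth",
    "kde_density",
    "find_peaks",
    "estimate_purity",
    "detect_subclones",
]

from .prevalence import Scenario, ScenarioCandidate

_NO_CNA_SCENARIOS = {Scenario.NO_CNA, Scenario.MALE_NO_CNA}


@dataclass
class SubcloneModel:
    """Detected subclone structure of one tumor sample.

    ``peaks`` holds the subclone prevalences sorted descending; the largest
    equals the tumor purity.  ``weights`` (mixture proportions) and
    ``snv_support`` (per-subclone SNV counts) are filled in later by the
    assignment step.
    """

    peaks: np.ndarray
    bandwidth: float
    weights: np.ndarray | None = field(default=None)
    snv_support: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.peaks.size < 1:
            raise ValueError("a subclone model needs at least one peak")
        if np.any(np.diff(self.peaks) >= 0):
            raise ValueError("peaks must be strictly decreasing")

    @property
    def n_subclones(self) -> int:
        return int(self.peaks.size)

    @property
    def purity(self) -> float:
        return float(min(self.peaks[0], 1.0))


def select_clustering_input(
    candidates: list[ScenarioCandidate], nocna_threshold: int = 100
) -> np.ndarray:
    """Choose which candidate prevalences feed the KDE.

    When strictly more than ``nocna_threshold`` distinct SNVs sit on regions
    without any copy-number event, their (unambiguous) prevalences alone are
    used.  Otherwise every scenario of every SNV votes, except candidates
    from multistate segments whose prevalence cannot be inferred.
    """
    if not candidates:
        raise ValueError("no usable SNVs")
    nocna_by_snv: dict[str, float] = {}
    for cand in candidates:
        if cand.scenario in _NO_CNA_SCENARIOS:
            nocna_by_snv.setdefault(cand.snv_id, cand.rho)
    if len(nocna_by_snv) > nocna_threshold:
        return np.fromiter(nocna_by_snv.values(), dtype=float)
    values = [c.rho for c in candidates if not c.from_multistate_segment]
    if not values:
        raise ValueError("no usable SNVs")
    return np.asarray(values, dtype=float)


def scott_bandwidth(n: int, d: int = 1) -> float:
    """Scott's dimensionless bandwidth factor ``n^(-1/(d+4))``.

    The full kernel bandwidth is this factor times the data scale (sample
    standard deviation); ``d`` is 1 for single-sample inference.
    """
    if n < 1:
        raise ValueError("bandwidth requires at least one observation")
    return float(n) ** (-1.0 / (d + 4))


class GaussianKDE:
    """Density ``f(x) = 1/(n h sqrt(pi)) * sum_j exp(-((x - x_j)/h)^2)``."""

    def __init__(self, values, bandwidth: float):
        self.values = np.asarray(values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("KDE requires at least one value")
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.bandwidth = float(bandwidth)
        self._norm = 1.0 / (self.values.size * self.bandwidth * math.sqrt(math.pi))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        grid = np.atleast_1d(x)
        z = (grid[:, None] - self.values[None, :]) / self.bandwidth
        density = np.exp(-(z**2)).sum(axis=1) * self._norm
        return float(density[0]) if scalar else density


def kde_density(values, h: float) -> GaussianKDE:
    """Build the Gaussian kernel density over candidate prevalences."""
    return GaussianKDE(values, h)


def find_peaks(
    density,
    *,
    resolution: float = 0.001,
    merge_tolerance: float = 0.01,
    prune_fraction: float = 0.01,
) -> list[float]:
    """Locate the subclone peaks of a density on [0, 1].

    Grid scan at ``resolution``, Nelder-Mead refinement of every strict local
    maximum, merge of refined peaks closer than ``merge_tolerance`` (the
    denser one wins) and pruning of peaks below ``prune_fraction`` of the
    global maximum density.  Returned sorted descending by location.
    """
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    values = np.asarray(density(grid), dtype=float)

    seeds = []
    interior = (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
    seeds.extend(grid[1:-1][interior])
    if values[0] > values[1]:
        seeds.append(grid[0])
    if values[-1] > values[-2]:
        seeds.append(grid[-1])
    if not seeds:
        # flat or monotone density: fall back to the grid argmax
        seeds.append(grid[int(np.argmax(values))])

    refined: list[tuple[float, float]] = []
    for seed in seeds:
        result = minimize(
            lambda x: -density(float(np.clip(x[0], 0.0, 1.0))),
            x0=[seed],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12},
        )
        location = float(np.clip(result.x[0], 0.0, 1.0))
        refined.append((location, float(density(location))))

    refined.sort(key=lambda p: -p[1])  # densest first so merges keep it
    kept: list[tuple[float, float]] = []
    for location, height in refined:
        if all(abs(location - k[0]) >= merge_tolerance for k in kept):
            kept.append((location, height))
    top = max(h for _, h in kept)
    kept = [(loc, h) for loc, h in kept if h >= prune_fraction * top]
    return sorted((loc for loc, _ in kept), reverse=True)


def estimate_purity(peaks) -> float:
    """Tumor purity: the largest peak prevalence (clonal SNVs exist in all
    tumor cells, so the founder peak marks the tumor cell fraction)."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("cannot estimate purity without peaks")
    return float(min(peaks.max(), 1.0))


def detect_subclones(
    values,
    *,
    resolution: float = 0.001,
    merge_tolerance: float = 0.01,
    prune_fraction: float = 0.01,
) -> SubcloneModel:
    """End-to-end subclone detection from pooled prevalence values."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no usable SNVs")
    sigma = float(values.std(ddof=1)) if values.size > 1 else 0.0
    # Scott's rule prescribes the kernel standard deviation (factor * data
    # scale); the kernel exp(-((x-xj)/h)^2) has sd h/sqrt(2), hence the sqrt(2).
    # Floor at the grid resolution so degenerate single-point inputs still
    # produce a resolvable peak.
    bandwidth = max(
        math.sqrt(2.0) * scott_bandwidth(values.size, d=1) * sigma, resolution
    )
    density = kde_density(values, bandwidth)
    peaks = find_peaks(
        density,
        resolution=resolution,
        merge_tolerance=merge_tolerance,
        prune_fraction=prune_fraction,
    )
    if not peaks:  # pragma: no cover - find_peaks always returns >= 1
        peaks = [float(np.median(values))]
    return SubcloneModel(peaks=np.asarray(peaks, dtype=float), bandwidth=bandwidth)
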