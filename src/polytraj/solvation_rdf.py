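"""Radial distribution functions, first-shell peak tracking and the
hydration-shell crossing temperature.

``g(bin) = <count> / (4 pi r_c^2 dr rho)`` with ``r_c`` the bin centre and
``rho`` the mean target count over the mean box volume, averaged over
reference atoms and frames.  Distances use the minimum-image convention, so
``r_max`` may not exceed half the smallest box edge.

The crossing temperature is the linear interpolation between the first
adjacent temperature pair whose first-shell peak intensity falls from at or
above the threshold (default ``g = 1.0``) to below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ._geometry import pair_distances
from .trajectory_io import Trajectory

__all__ = [
    "RDFResult",
    "PeakCurve",
    "TcrpResult",
    "rdf",
    "average_rdfs",
    "first_peak",
    "peak_intensity_curve",
    "crossing_temperature",
    "tcrp",
]

DEFAULT_PEAK_WINDOW = (2.0, 5.5)  # Å; brackets the ~3.6 Å first shell


@dataclass
class RDFResult:
    r_centers: np.ndarray
    g: np.ndarray
    raw_counts: np.ndarray  # total pair counts per bin over all refs and frames
    n_ref: int
    n_frames: int
    bulk_density: float  # Å^-3
    dr: float


@dataclass
class PeakCurve:
    """First-shell peak location and intensity per temperature (ascending T)."""

    temperatures: np.ndarray
    first_peak_r: np.ndarray  # NaN where no local maximum was detected
    first_peak_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.first_peak_r = np.asarray(self.first_peak_r, dtype=float)
        self.first_peak_intensity = np.asarray(self.first_peak_intensity, dtype=float)
        if self.temperatures.ndim != 1 or np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (
            len(self.temperatures)
            == len(self.first_peak_r)
            == len(self.first_peak_intensity)
        ):
            raise ValueError("curve arrays must have equal length")
        finite = self.first_peak_intensity[np.isfinite(self.first_peak_intensity)]
        if np.any(finite < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class TcrpResult:
    """Crossing temperature; ``temperature is None`` encodes 'no crossing'."""

    temperature: float | None
    bracket: tuple | None
    method: str = "linear_interpolation"

    def __post_init__(self) -> None:
        if self.temperature is not None and self.bracket is not None:
            lo, hi = self.bracket
            if not (lo <= self.temperature <= hi):
                raise ValueError("crossing temperature must lie inside its bracket")


def rdf(
    trajectory: Trajectory,
    ref_selection: np.ndarray,
    target_selection: np.ndarray,
    dr: float = 0.1,
    r_max: float | None = None,
) -> RDFResult:
    """RDF of target atoms around reference atoms, frame- and ref-averaged.

    ``ref_selection`` and ``target_selection`` must be non-empty and
    disjoint.  ``r_max`` defaults to ``min(box)/2 - dr`` and may not exceed
    half the smallest box edge (minimum-image validity).  The bulk density
    is the mean target count divided by the mean box volume.
    """
    ref = np.asarray(ref_selection, dtype=int)
    target = np.asarray(target_selection, dtype=int)
    if ref.size == 0 or target.size == 0:
        raise ValueError("reference and target selections must be non-empty")
    if np.intersect1d(ref, target).size:
        raise ValueError("reference and target selections must be disjoint")
    if dr <= 0:
        raise ValueError("dr must be > 0")
    boxes = np.stack([fr.require_box() for fr in trajectory.frames])
    min_edge = float(boxes.min())
    if r_max is None:
        r_max = min_edge / 2.0 - dr
    if r_max > min_edge / 2.0 + 1e-12:
        raise ValueError(
            f"r_max={r_max:g} exceeds half the smallest box edge ({min_edge / 2:g})"
        )
    n_bins = int(np.floor(r_max / dr + 1e-9))
    if n_bins < 1:
        raise ValueError("r_max too small for the requested dr")
    counts = np.zeros(n_bins, dtype=np.int64)
    for fr in trajectory.frames:
        d = pair_distances(
            fr.coordinates[ref], fr.coordinates[target], fr.box
        ).ravel()
        idx = np.floor(d / dr).astype(int)
        keep = idx < n_bins
        counts += np.bincount(idx[keep], minlength=n_bins)
    volume = float(np.prod(boxes, axis=1).mean())
    rho = target.size / volume
    r_centers = (np.arange(n_bins) + 0.5) * dr
    shell = 4.0 * np.pi * r_centers**2 * dr
    g = counts / (trajectory.n_frames * ref.size * shell * rho)
    return RDFResult(
        r_centers=r_centers,
        g=g,
        raw_counts=counts,
        n_ref=int(ref.size),
        n_frames=trajectory.n_frames,
        bulk_density=rho,
        dr=dr,
    )


def average_rdfs(results) -> RDFResult:
    """Average replicate RDFs on a shared grid (g averaged, counts summed)."""
    results = list(results)
    if not results:
        raise ValueError("no RDFs to average")
    first = results[0]
    for r in results[1:]:
        if r.r_centers.shape != first.r_centers.shape or not np.allclose(
            r.r_centers, first.r_centers
        ):
            raise ValueError("replicate RDFs must share the same radial grid")
    return RDFResult(
        r_centers=first.r_centers.copy(),
        g=np.mean([r.g for r in results], axis=0),
        raw_counts=np.sum([r.raw_counts for r in results], axis=0),
        n_ref=first.n_ref,
        n_frames=sum(r.n_frames for r in results),
        bulk_density=float(np.mean([r.bulk_density for r in results])),
        dr=first.dr,
    )


def _smooth3(g: np.ndarray) -> np.ndarray:
    """3-point moving average; endpoints are kept as-is."""
    out = g.astype(float).copy()
    if len(g) >= 3:
        out[1:-1] = (g[:-2] + g[1:-1] + g[2:]) / 3.0
    return out


def first_peak(
    result: RDFResult,
    r_window: tuple = DEFAULT_PEAK_WINDOW,
    smooth: bool = True,
    min_prominence: float = 0.15,
) -> tuple | None:
    """First local maximum of g(r) inside ``r_window`` -> ``(r_peak, g_peak)``.

    The curve is 3-point smoothed first (disable with ``smooth=False``);
    candidate maxima need a prominence of at least ``min_prominence`` to
    suppress sampling noise.  Ties are broken toward smaller ``r``.  Returns
    ``None`` when no qualifying maximum exists (distinct from an error).
    """
    g = _smooth3(result.g) if smooth else result.g
    lo, hi = r_window
    mask = (result.r_centers >= lo) & (result.r_centers <= hi)
    if not np.any(mask):
        return None
    idx_window = np.flatnonzero(mask)
    segment = g[idx_window]
    # window-edge samples cannot qualify: a maximum at the edge is
    # indistinguishable from a monotone segment, which must report none
    peaks, _ = find_peaks(segment, prominence=min_prominence)
    if peaks.size == 0:
        return None
    best = idx_window[peaks[0]]
    return float(result.r_centers[best]), float(g[best])


def peak_intensity_curve(
    rdfs_by_temperature,
    r_window: tuple = DEFAULT_PEAK_WINDOW,
    smooth: bool = True,
    min_prominence: float = 0.15,
) -> PeakCurve:
    """Track the first-shell peak across temperatures.

    ``rdfs_by_temperature`` maps temperature (K) to :class:`RDFResult` (a
    dict or an iterable of pairs); input order is irrelevant, the curve is
    sorted by temperature.  At temperatures where no local maximum survives
    the prominence filter (e.g. once the shell has melted below bulk
    density), the peak position is recorded as NaN and the intensity is read
    off at the shell radius shared by the temperatures that do show a peak —
    the crossing statistic needs an intensity on both sides of the
    threshold.  If no temperature shows a peak, intensities are NaN.
    """
    if hasattr(rdfs_by_temperature, "items"):
        items = list(rdfs_by_temperature.items())
    else:
        items = list(rdfs_by_temperature)
    items.sort(key=lambda kv: kv[0])
    temperatures = np.array([float(t) for t, _ in items])
    peak_r = np.full(len(items), np.nan)
    intensity = np.full(len(items), np.nan)
    for i, (_, res) in enumerate(items):
        found = first_peak(
            res, r_window=r_window, smooth=smooth, min_prominence=min_prominence
        )
        if found is not None:
            peak_r[i], intensity[i] = found
    if np.any(np.isfinite(peak_r)) and np.any(~np.isfinite(peak_r)):
        shared_r = float(np.nanmean(peak_r))
        for i, (_, res) in enumerate(items):
            if np.isfinite(peak_r[i]):
                continue
            g = _smooth3(res.g) if smooth else res.g
            j = int(np.argmin(np.abs(res.r_centers - shared_r)))
            intensity[i] = float(g[j])
    return PeakCurve(
        temperatures=temperatures, first_peak_r=peak_r, first_peak_intensity=intensity
    )


def crossing_temperature(curve: PeakCurve, threshold: float = 1.0) -> TcrpResult:
    """Temperature at which the first-shell intensity drops below ``threshold``.

    Scans adjacent temperature pairs for ``g(T_i) >= threshold > g(T_{i+1})``
    and linearly interpolates inside the first such bracket.  Returns a
    result with ``temperature=None`` when no pair brackets the threshold
    (including single-temperature curves).  Non-finite intensities raise
    ``ValueError``.
    """
    g = curve.first_peak_intensity
    if not np.all(np.isfinite(g)):
        raise ValueError(
            "curve contains non-finite intensities; cannot locate a crossing"
        )
    t = curve.temperatures
    for i in range(len(t) - 1):
        if g[i] >= threshold > g[i + 1]:
            frac = (g[i] - threshold) / (g[i] - g[i + 1])
            crossing = float(t[i] + frac * (t[i + 1] - t[i]))
            return TcrpResult(
                temperature=crossing, bracket=(float(t[i]), float(t[i + 1]))
            )
    return TcrpResult(temperature=None, bracket=None)


#: Alias matching the crossing-statistic shorthand used in reports.
tcrp = crossing_temperature
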