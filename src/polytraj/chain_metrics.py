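"""Chain-extension observables.

Radius-of-gyration series and distributions, end-to-end length against the
fully-extended main-chain length with the ideal-chain coil/globule criterion,
per-residue side-chain lengths, and the SD/CV fluctuation statistics used in
the tabulated reports.

Statistical conventions (fixed across the package):

* Rg is **unweighted** over the selected atoms:
  ``Rg^2 = (1/N') * sum_n (R_n - R_c)^2`` with ``R_c`` the unweighted
  centroid.  A mass-weighted variant is available but off by default.
* The ideal-chain reference for a chain of ``N`` monomers is ``1/sqrt(N)``.
  (The alternative reading ``1/N`` is inconsistent with every tabulated
  reference value, e.g. ``1/sqrt(28) = 0.19`` vs ``1/28 = 0.04``.)
* SD always uses the sample (``n-1``) denominator; CV = SD / mean.
* Table-style rounding is half-up at the printed precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from ._geometry import backbone_path, make_whole
from .trajectory_io import Frame, Topology, Trajectory, select

__all__ = [
    "RgSeries",
    "RgDistribution",
    "ChainExtensionStats",
    "SideChainStats",
    "TemperatureAverage",
    "ZIGZAG_FACTOR",
    "sample_sd",
    "cv",
    "round_half_up",
    "ideal_chain_reference",
    "radius_of_gyration",
    "rg_series",
    "rg_distribution",
    "end_to_end_length",
    "lmax",
    "chain_extension_stats",
    "temperature_average",
    "side_chain_lengths",
    "side_chain_temperature_stats",
]

#: sin(109.47deg / 2): projection factor for an all-trans tetrahedral backbone.
ZIGZAG_FACTOR = math.sin(math.radians(109.47) / 2.0)


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def sample_sd(values) -> float:
    """Sample standard deviation (``n - 1`` denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("sample_sd needs at least 2 values")
    return float(np.std(arr, ddof=1))


def cv(values) -> float:
    """Coefficient of variation: sample SD divided by the mean (mean != 0)."""
    arr = np.asarray(values, dtype=float)
    mean = float(np.mean(arr))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return sample_sd(arr) / mean


def round_half_up(value: float, ndigits: int) -> float:
    """Round half-up at ``ndigits`` decimals (table-report convention)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def ideal_chain_reference(n_monomers: int) -> float:
    """Ideal-chain (freely jointed) extension ratio ``1/sqrt(N)``."""
    if n_monomers < 1:
        raise ValueError("degree of polymerization must be >= 1")
    return 1.0 / math.sqrt(n_monomers)


# ---------------------------------------------------------------------------
# Rg
# ---------------------------------------------------------------------------

@dataclass
class RgSeries:
    """Radius-of-gyration time series (times in ps, values in Å)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(self.values < 0):
            raise ValueError("Rg values must be >= 0")


@dataclass
class RgDistribution:
    bin_edges: np.ndarray
    density: np.ndarray
    peaks: list  # ordered (rg_at_max, prominence), highest density first
    principal_peak: float
    sd: float
    multimodal: bool


def radius_of_gyration(
    frame: Frame,
    selection: np.ndarray,
    topology: Topology | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Radius of gyration of the selected atoms (Å).

    If ``topology`` is given and the frame has a box, bonded components are
    made whole first, and a warning is emitted when the unwrapped selection
    spans more than half the box in any direction (unwrap ambiguity).
    ``masses`` switches on mass weighting; the default is the unweighted
    definition.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    coords = frame.coordinates
    if topology is not None and frame.box is not None:
        coords = make_whole(coords, frame.box, topology)
        span = coords[selection].max(axis=0) - coords[selection].min(axis=0)
        if np.any(span > frame.box / 2.0):
            warnings.warn(
                "selection spans more than half the box after unwrapping; "
                "Rg may be unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
    pts = coords[selection]
    if masses is None:
        centroid = pts.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    w = np.asarray(masses, dtype=float)
    if w.shape[0] != pts.shape[0]:
        raise ValueError("masses must match selection length")
    centroid = (pts * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((pts - centroid) ** 2, axis=1)).sum() / w.sum()))


def rg_series(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
) -> RgSeries:
    """Per-frame Rg of the polymer selection (defaults to backbone atoms)."""
    topo = trajectory.topology
    if selection is None:
        selection = select(topo, "backbone")
    times = np.array([f.time for f in trajectory.frames])
    values = np.array(
        [radius_of_gyration(f, selection, topology=topo) for f in trajectory.frames]
    )
    return RgSeries(times=times, values=values)


def rg_distribution(
    series: RgSeries,
    bin_width: float = 0.1,
    smoothing_bins: float = 2.0,
    prominence_fraction: float = 0.05,
) -> RgDistribution:
    """Normalized Rg histogram with smoothed-peak detection.

    The histogram (bin width ``bin_width``) is smoothed with a Gaussian
    kernel of ``smoothing_bins`` bins; peaks are local maxima whose
    prominence is at least ``prominence_fraction`` of the maximum smoothed
    density.  ``sd`` is the sample SD of the raw series.  The distribution
    is flagged multimodal when two or more peaks survive the prominence
    threshold.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = series.values
    if values.size < 3:
        raise ValueError("rg_distribution needs at least 3 samples")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi - lo < bin_width:  # constant series
        lo, hi = lo - bin_width / 2.0, lo + bin_width / 2.0
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    smoothed = gaussian_filter1d(density, sigma=smoothing_bins, mode="constant")
    centers = 0.5 * (edges[:-1] + edges[1:])
    if smoothed.max() > 0:
        idx, props = find_peaks(
            np.concatenate(([0.0], smoothed, [0.0])),
            prominence=prominence_fraction * smoothed.max(),
        )
        idx = idx - 1
        peaks = sorted(
            zip(centers[idx], props["prominences"]),
            key=lambda p: -smoothed[np.argmin(np.abs(centers - p[0]))],
        )
    else:
        peaks = []
    if peaks:
        principal = float(peaks[0][0])
    else:
        principal = float(centers[np.argmax(density)])
    sd = sample_sd(values) if values.size >= 2 else 0.0
    return RgDistribution(
        bin_edges=edges,
        density=density,
        peaks=[(float(r), float(p)) for r, p in peaks],
        principal_peak=principal,
        sd=float(sd),
        multimodal=len(peaks) >= 2,
    )


# ---------------------------------------------------------------------------
# End-to-end length and the coil/globule criterion
# ---------------------------------------------------------------------------

def end_to_end_length(frame: Frame, backbone_selection: np.ndarray) -> float:
    """Euclidean distance between the first and last backbone atoms (Å).

    ``backbone_selection`` must already be ordered head-to-tail and the
    coordinates unwrapped.
    """
    sel = np.asarray(backbone_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty backbone selection")
    return float(np.linalg.norm(frame.coordinates[sel[-1]] - frame.coordinates[sel[0]]))


def lmax(
    topology: Topology,
    frame: Frame,
    mode: str = "sum_of_bonds",
    backbone_selection: np.ndarray | None = None,
) -> float:
    """Fully extended main-chain length (Å).

    ``sum_of_bonds`` sums consecutive backbone bond lengths along the bond
    path (exact for freely jointed test chains); ``zigzag`` multiplies that
    sum by ``sin(109.47deg/2)``, the all-trans projection for tetrahedral
    all-atom backbones.  A disconnected or branched backbone raises
    ``ValueError`` naming the gap.
    """
    if mode not in ("sum_of_bonds", "zigzag"):
        raise ValueError(f"unknown lmax mode: {mode!r}")
    if backbone_selection is None:
        backbone_selection = select(topology, "backbone")
    path = backbone_path(topology, backbone_selection)
    coords = make_whole(frame.coordinates, frame.box, topology)
    steps = np.diff(coords[path], axis=0)
    total = float(np.sum(np.linalg.norm(steps, axis=1)))
    if mode == "zigzag":
        total *= ZIGZAG_FACTOR
    return total


@dataclass
class ChainExtensionStats:
    l_bar: float  # time-averaged end-to-end length (Å)
    l_max: float
    ratio: float  # l_bar / l_max
    rms_ratio: float  # sqrt(<L^2>) / l_max
    ideal_ref: float  # 1/sqrt(N)
    state: str  # "coil" | "globule"
    sd: float  # sample SD of per-frame L/Lmax
    cv: float  # sd / ratio
    n_monomers: int
    temperature: float | None = None


def chain_extension_stats(
    trajectory: Trajectory, mode: str = "sum_of_bonds"
) -> ChainExtensionStats:
    """Per-trajectory extension statistics and the coil/globule call.

    The per-frame end-to-end length series L is measured on unwrapped
    backbone coordinates; ``Lmax`` is taken from the first frame.  The chain
    is called ``coil`` iff ``mean(L)/Lmax > 1/sqrt(N)``, ``globule``
    otherwise.
    """
    topo = trajectory.topology
    n = topo.n_residues_polymer
    if n < 1:
        raise ValueError("topology has no polymer residues")
    backbone = select(topo, "backbone")
    path = backbone_path(topo, backbone)
    l_max = lmax(topo, trajectory.frames[0], mode=mode, backbone_selection=backbone)
    if l_max <= 0:
        raise ValueError("Lmax is not positive")
    lengths = np.empty(trajectory.n_frames)
    for k, fr in enumerate(trajectory.frames):
        coords = make_whole(fr.coordinates, fr.box, topo)
        lengths[k] = np.linalg.norm(coords[path[-1]] - coords[path[0]])
    ratios = lengths / l_max
    ratio = float(ratios.mean())
    sd = float(np.std(ratios, ddof=1)) if ratios.size >= 2 else 0.0
    ideal = ideal_chain_reference(n)
    return ChainExtensionStats(
        l_bar=float(lengths.mean()),
        l_max=l_max,
        ratio=ratio,
        rms_ratio=float(np.sqrt(np.mean(lengths**2)) / l_max),
        ideal_ref=ideal,
        state="coil" if ratio > ideal else "globule",
        sd=sd,
        cv=sd / ratio if ratio != 0 else float("nan"),
        n_monomers=n,
        temperature=trajectory.temperature,
    )


@dataclass
class TemperatureAverage:
    mean: float
    sd: float
    cv: float
    n_temperatures: int


def temperature_average(stats_per_temperature) -> TemperatureAverage:
    """Across-temperature mean/SD/CV of extension ratios.

    Accepts a list of :class:`ChainExtensionStats` or raw ratio values.
    """
    ratios = np.array(
        [
            s.ratio if isinstance(s, ChainExtensionStats) else float(s)
            for s in stats_per_temperature
        ]
    )
    if ratios.size < 1:
        raise ValueError("need at least one temperature")
    mean = float(ratios.mean())
    sd = float(np.std(ratios, ddof=1)) if ratios.size >= 2 else 0.0
    return TemperatureAverage(
        mean=mean,
        sd=sd,
        cv=sd / mean if mean != 0 else float("nan"),
        n_temperatures=int(ratios.size),
    )


# ---------------------------------------------------------------------------
# Side-chain lengths
# ---------------------------------------------------------------------------

@dataclass
class SideChainStats:
    per_residue_mean: np.ndarray  # time-averaged length per residue (Å)
    chain_mean: float  # mean over residues (Å)
    temperature: float | None = None


def _anchor_atoms(topology: Topology) -> dict:
    """Per-residue main-chain anchor carbon: the backbone C bonded into the
    residue's side chain (falls back to the residue's only backbone C)."""
    by_residue: dict = {}
    for i, atom in enumerate(topology.atoms):
        if "backbone" in atom.roles and atom.element == "C":
            by_residue.setdefault(atom.residue_index, []).append(i)
    anchors: dict = {}
    for res, candidates in by_residue.items():
        if len(candidates) == 1:
            anchors[res] = candidates[0]
            continue
        linked = [
            i
            for i in candidates
            if any(
                "sidechain" in topology.atoms[j].roles for j in topology.bonded_to(i)
            )
        ]
        if len(linked) != 1:
            raise ValueError(
                f"residue {res}: cannot identify a unique main-chain anchor carbon"
            )
        anchors[res] = linked[0]
    return anchors


def side_chain_lengths(trajectory: Trajectory) -> SideChainStats:
    """Time-averaged anchor-to-terminal side-chain length per residue.

    Each polymer residue must expose one main-chain anchor carbon (backbone,
    element C) and exactly one ``terminal_carbon``.  Distances are measured
    on unwrapped coordinates.
    """
    topo = trajectory.topology
    anchors = _anchor_atoms(topo)
    terminals: dict = {}
    for i, atom in enumerate(topo.atoms):
        if "terminal_carbon" in atom.roles:
            if atom.residue_index in terminals:
                raise ValueError(
                    f"residue {atom.residue_index} has multiple terminal carbons"
                )
            terminals[atom.residue_index] = i
    residues = sorted(terminals)
    if not residues:
        raise ValueError("no terminal carbons tagged")
    missing = [r for r in residues if r not in anchors]
    if missing:
        raise ValueError(f"residues missing a main-chain anchor carbon: {missing}")
    a_idx = np.array([anchors[r] for r in residues])
    t_idx = np.array([terminals[r] for r in residues])
    dists = np.empty((trajectory.n_frames, len(residues)))
    for k, fr in enumerate(trajectory.frames):
        coords = make_whole(fr.coordinates, fr.box, topo)
        dists[k] = np.linalg.norm(coords[t_idx] - coords[a_idx], axis=1)
    per_residue = dists.mean(axis=0)
    return SideChainStats(
        per_residue_mean=per_residue,
        chain_mean=float(per_residue.mean()),
        temperature=trajectory.temperature,
    )


def side_chain_temperature_stats(chain_means_by_temperature) -> TemperatureAverage:
    """Across-temperature mean/SD/CV of per-temperature side-chain lengths."""
    values = np.array(
        [
            s.chain_mean if isinstance(s, SideChainStats) else float(s)
            for s in chain_means_by_temperature
        ]
    )
    if np.any(values <= 0):
        raise ValueError("side-chain lengths must be > 0")
    mean = float(values.mean())
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else 0.0
    return TemperatureAverage(
        mean=mean, sd=sd, cv=sd / mean, n_temperatures=int(values.size)
    )
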