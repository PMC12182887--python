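"""Nearest-neighbor-distance statistics against a complete-spatial-randomness null.

The quantification at the heart of the pipeline: first-NND within a channel
measures receptor self-association (oligomerization); cross-NND from a
ligand channel to a receptor channel measures co-localization. Each observed
distribution is compared with a simulated CSR (homogeneous Poisson) point
pattern at the measured density; the excess of the observed normalized NND
histogram over the CSR histogram at short range, integrated over 0-200 nm,
is the Δ-area statistic. Conditions (e.g. differently labeled ligands) are
compared by one-way ANOVA on per-cell Δ areas.

Histograms use 5 nm bins aligned to zero and are density-normalized so the
integral over the 0-200 nm evaluation window equals one; this makes Δ area
a dimensionless number in [0, 1] comparable across cells and densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .clustering import ProteinPositionSet
from .io import RegionOfInterest

__all__ = [
    "NNDistribution",
    "Histogram",
    "CSREnsemble",
    "DeltaAreaResult",
    "AnovaResult",
    "first_nnd",
    "cross_nnd",
    "estimate_density",
    "simulate_csr",
    "normalized_histogram",
    "delta_area",
    "aggregate_conditions",
    "compare_conditions",
    "significance_stars",
]

DEFAULT_BIN_SIZE = 5.0          # nm, histogram bin width
DEFAULT_RANGE = (0.0, 200.0)    # nm, normalization / Δ-area window
DEFAULT_CSR_N = 5_000_000       # molecules per simulated CSR null


def _coords_of(positions, use_z: bool = False) -> np.ndarray:
    if isinstance(positions, ProteinPositionSet):
        return positions.coords(use_z=use_z)
    arr = np.asarray(positions, dtype=float)
    if arr.ndim != 2:
        raise ValueError("positions must be an (n, d) array or ProteinPositionSet")
    return arr if use_z or arr.shape[1] == 2 else arr[:, :2]


@dataclass
class NNDistribution:
    """First (or cross) nearest-neighbor distances, one per query point."""

    distances: np.ndarray
    n_query: int = 0

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        self.n_query = len(self.distances)


@dataclass
class Histogram:
    """Density-normalized histogram: Σ densities × bin_size = 1 over norm_range."""

    bin_edges: np.ndarray
    densities: np.ndarray
    bin_size: float
    norm_range: tuple[float, float]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def modal_bin_center(self) -> float:
        """Center of the highest bin (first on ties)."""
        return float(self.bin_centers[int(np.argmax(self.densities))])

    def same_binning(self, other: "Histogram") -> bool:
        return (
            self.bin_size == other.bin_size
            and len(self.bin_edges) == len(other.bin_edges)
            and bool(np.allclose(self.bin_edges, other.bin_edges))
        )


@dataclass
class CSREnsemble:
    """Uniform i.i.d. points at a given density in a square region."""

    density_um2: float
    n_simulated: int
    side_nm: float
    positions: np.ndarray
    seed: int


@dataclass
class DeltaAreaResult:
    """Δ area: positive excess of observed over CSR NND density, × bin width."""

    delta_area: float
    per_bin_differences: np.ndarray
    bin_size: float
    condition_label: str = ""


@dataclass
class AnovaResult:
    """One-way ANOVA across condition groups of per-cell Δ areas."""

    f_statistic: float
    p_value: float
    stars: str
    group_means: dict[str, float] = field(default_factory=dict)
    group_stds: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)


def first_nnd(positions, use_z: bool = False) -> NNDistribution:
    """Distance from each position to its nearest *other* position.

    Self-pairs are excluded; at least two positions are required.
    """
    pts = _coords_of(positions, use_z=use_z)
    if len(pts) < 2:
        raise ValueError("first NND undefined for fewer than 2 positions")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return NNDistribution(distances=d[:, 1])


def cross_nnd(query, reference, use_z: bool = False) -> NNDistribution:
    """Distance from each query position to the nearest reference position.

    No self-exclusion (channels are distinct); asymmetric in its arguments.
    """
    q = _coords_of(query, use_z=use_z)
    r = _coords_of(reference, use_z=use_z)
    if len(r) == 0:
        raise ValueError("cross NND undefined for an empty reference set")
    d, _ = cKDTree(r).query(q, k=1)
    return NNDistribution(distances=np.atleast_1d(d))


def estimate_density(positions, roi: RegionOfInterest) -> float:
    """Positions inside the ROI per µm² (count / ROI area)."""
    pts = _coords_of(positions)
    if len(pts) == 0:
        warnings.warn("no positions: density is 0", stacklevel=2)
        return 0.0
    n_in = int(roi.contains(pts).sum())
    if n_in == 0:
        warnings.warn("no positions inside ROI: density is 0", stacklevel=2)
    return n_in / roi.area_um2


def simulate_csr(
    density_um2: float,
    n_molecules: int = DEFAULT_CSR_N,
    seed: int | np.random.Generator = 0,
) -> CSREnsemble:
    """Simulate a CSR point pattern at a measured density.

    ``n_molecules`` points are drawn uniformly i.i.d. in a square whose
    side is chosen so the simulated density equals ``density_um2``; large
    n makes edge effects on the NND negligible without correction.
    """
    if density_um2 <= 0:
        raise ValueError("density must be positive")
    if n_molecules < 2:
        raise ValueError("need at least 2 molecules")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    side_nm = np.sqrt(n_molecules / density_um2) * 1e3  # µm -> nm
    pos = rng.uniform(0.0, side_nm, size=(n_molecules, 2))
    return CSREnsemble(
        density_um2=float(density_um2),
        n_simulated=int(n_molecules),
        side_nm=float(side_nm),
        positions=pos,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )


def normalized_histogram(
    nnd: NNDistribution | np.ndarray,
    bin_size: float = DEFAULT_BIN_SIZE,
    norm_range: tuple[float, float] = DEFAULT_RANGE,
) -> Histogram:
    """Normalized NND histogram with zero-aligned bins.

    Bins cover ``norm_range`` (which must be bin-aligned); heights are
    per-nm densities scaled so the integral over the range is one.
    Distances outside the range are excluded.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    d = nnd.distances if isinstance(nnd, NNDistribution) else np.asarray(nnd, float)
    if len(d) == 0:
        raise ValueError("cannot histogram an empty distance set")
    lo, hi = norm_range
    n_bins = (hi - lo) / bin_size
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("norm_range must span a whole number of bins")
    edges = lo + bin_size * np.arange(round(n_bins) + 1)
    counts, _ = np.histogram(d, bins=edges)
    n_in = counts.sum()
    if n_in == 0:
        raise ValueError("no distances fall inside the normalization range")
    dens = counts / (n_in * bin_size)
    return Histogram(bin_edges=edges, densities=dens, bin_size=float(bin_size),
                     norm_range=(float(lo), float(hi)))


def delta_area(
    experimental: Histogram,
    csr: Histogram,
    condition_label: str = "",
) -> DeltaAreaResult:
    """Σ max(0, h_obs − h_csr) × bin_size over the evaluation window.

    Both histograms must share their binning exactly. Because both are
    unit-integral densities over the window, the result lies in [0, 1]:
    0 for indistinguishable-from-random, approaching 1 when all observed
    mass sits where the CSR null has none.
    """
    if not experimental.same_binning(csr):
        raise ValueError("experimental and CSR histograms must share binning")
    diff = experimental.densities - csr.densities
    value = float(np.sum(np.clip(diff, 0.0, None)) * experimental.bin_size)
    return DeltaAreaResult(delta_area=value, per_bin_differences=diff,
                           bin_size=experimental.bin_size,
                           condition_label=condition_label)


def aggregate_conditions(histograms: list[Histogram]) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and population standard deviation across cells."""
    if not histograms:
        raise ValueError("need at least one histogram")
    first = histograms[0]
    for h in histograms[1:]:
        if not h.same_binning(first):
            raise ValueError("histograms have mixed binning")
    stack = np.stack([h.densities for h in histograms])
    return stack.mean(axis=0), stack.std(axis=0)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_conditions(delta_areas: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA (upper-tail F) across per-cell Δ-area groups.

    Requires >= 2 groups with >= 2 values each. Group summaries use the
    population standard deviation. Identical groups yield F = 0, p = 1.
    """
    if len(delta_areas) < 2:
        raise ValueError("need at least 2 condition groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in delta_areas.items()}
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    f, p = stats.f_oneway(*groups.values())
    if np.isnan(f):  # zero within-group variance and zero between: identical data
        f, p = 0.0, 1.0
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        stars=significance_stars(float(p)),
        group_means={k: float(v.mean()) for k, v in groups.items()},
        group_stds={k: float(v.std()) for k, v in groups.items()},
        group_sizes={k: int(len(v)) for k, v in groups.items()},
    )
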