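"""Model/Results interface over the NND-vs-CSR quantification.

``OligomerizationModel`` wraps one cell's analysis — a set of protein
positions (optionally against a reference channel for cross-NND), an ROI
fixing the density, and the histogram settings — and ``fit`` simulates the
CSR null and produces an ``OligomerizationResults`` carrying the Δ-area
estimate, the observed and null histograms and a ``summary()`` table.
``ConditionComparison`` fits the across-condition one-way ANOVA on per-cell
Δ areas. Both delegate to the functional layer in :mod:`paintnnd.spatial`,
so a result is always reproducible by the direct call chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ProteinPositionSet
from .io import RegionOfInterest
from . import spatial
from .spatial import (DEFAULT_BIN_SIZE, DEFAULT_CSR_N, DEFAULT_RANGE,
                      AnovaResult, CSREnsemble, DeltaAreaResult, Histogram,
                      NNDistribution)

__all__ = ["OligomerizationModel", "OligomerizationResults",
           "ConditionComparison", "ConditionComparisonResults"]


class OligomerizationModel:
    """Single-cell NND analysis against a CSR null.

    Parameters
    ----------
    positions : ProteinPositionSet or (n, 2+) array
        Query protein positions (e.g. the receptor channel).
    roi : RegionOfInterest
        Region fixing the measured density for the CSR null. If omitted, the
        bounding box of the query positions is used (with a small-sample
        bias toward higher density; prefer an explicit ROI).
    reference : ProteinPositionSet, optional
        If given, the statistic is the cross-NND from ``positions`` to
        ``reference`` and the null randomizes the query channel against an
        independent CSR reference at its own measured density.
    bin_size, norm_range : histogram settings (nm); defaults 5 nm, 0-200 nm.
    csr_n : number of simulated CSR molecules (default 5,000,000).
    """

    def __init__(
        self,
        positions,
        roi: RegionOfInterest | None = None,
        reference=None,
        bin_size: float = DEFAULT_BIN_SIZE,
        norm_range: tuple[float, float] = DEFAULT_RANGE,
        csr_n: int = DEFAULT_CSR_N,
        label: str = "",
    ):
        self.positions = (positions if isinstance(positions, ProteinPositionSet)
                          else ProteinPositionSet.from_coords(np.asarray(positions)))
        self.reference = (None if reference is None else
                          reference if isinstance(reference, ProteinPositionSet)
                          else ProteinPositionSet.from_coords(np.asarray(reference)))
        self.roi = roi if roi is not None else self._bounding_roi()
        self.bin_size = float(bin_size)
        self.norm_range = norm_range
        self.csr_n = int(csr_n)
        self.label = label

    def _bounding_roi(self) -> RegionOfInterest:
        xy = self.positions.xy
        (x0, y0), (x1, y1) = xy.min(axis=0), xy.max(axis=0)
        return RegionOfInterest.rectangle(x1 - x0, y1 - y0, x0, y0)

    def fit(self, seed: int = 0) -> "OligomerizationResults":
        """Measure the observed NND, simulate the null, compute Δ area."""
        if self.reference is None:
            nnd = spatial.first_nnd(self.positions)
            density = spatial.estimate_density(self.positions, self.roi)
            csr = spatial.simulate_csr(density, self.csr_n, seed)
            csr_nnd = spatial.first_nnd(csr.positions)
        else:
            nnd = spatial.cross_nnd(self.positions, self.reference)
            density = spatial.estimate_density(self.reference, self.roi)
            # Null: both channels independently random at measured densities.
            q_density = spatial.estimate_density(self.positions, self.roi)
            rng = np.random.default_rng(seed)
            csr = spatial.simulate_csr(density, self.csr_n, rng)
            n_query = max(int(round(q_density * csr.side_nm**2 * 1e-6)), 1)
            q_pos = rng.uniform(0, csr.side_nm, size=(n_query, 2))
            csr_nnd = spatial.cross_nnd(q_pos, csr.positions)
        hist = spatial.normalized_histogram(nnd, self.bin_size, self.norm_range)
        csr_hist = spatial.normalized_histogram(csr_nnd, self.bin_size,
                                                self.norm_range)
        da = spatial.delta_area(hist, csr_hist, condition_label=self.label)
        return OligomerizationResults(
            model=self, nnd=nnd, histogram=hist, csr=csr,
            csr_histogram=csr_hist, density_um2=density,
            delta_area_result=da, seed=int(seed))


@dataclass
class OligomerizationResults:
    """Fitted single-cell NND analysis."""

    model: OligomerizationModel
    nnd: NNDistribution
    histogram: Histogram
    csr: CSREnsemble
    csr_histogram: Histogram
    density_um2: float
    delta_area_result: DeltaAreaResult
    seed: int

    @property
    def delta_area(self) -> float:
        return self.delta_area_result.delta_area

    @property
    def modal_bin_center(self) -> float:
        return self.histogram.modal_bin_center

    def summary(self) -> str:
        kind = "cross-NND" if self.model.reference is not None else "first-NND"
        lines = [
            "NND vs CSR analysis",
            "===================",
            f"statistic:        {kind}",
            f"query positions:  {self.nnd.n_query}",
            f"density:          {self.density_um2:.3f} per um^2",
            f"CSR molecules:    {self.csr.n_simulated}",
            f"bin size:         {self.histogram.bin_size:g} nm",
            f"window:           {self.histogram.norm_range[0]:g}-"
            f"{self.histogram.norm_range[1]:g} nm",
            f"modal bin center: {self.modal_bin_center:g} nm",
            f"median NND:       {float(np.median(self.nnd.distances)):.2f} nm",
            f"delta area:       {self.delta_area:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs CSR normalized NND histograms (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.histogram.bin_centers
        ax.bar(c, self.histogram.densities, width=self.histogram.bin_size,
               alpha=0.6, label="observed")
        ax.plot(c, self.csr_histogram.densities, "k-", label="CSR")
        ax.set_xlabel("NND (nm)")
        ax.set_ylabel("density (1/nm)")
        ax.legend()
        return ax


class ConditionComparison:
    """One-way ANOVA across conditions of per-cell Δ areas."""

    def __init__(self, delta_areas_by_condition: dict[str, np.ndarray]):
        self.groups = {k: np.asarray(v, dtype=float)
                       for k, v in delta_areas_by_condition.items()}

    def fit(self) -> "ConditionComparisonResults":
        return ConditionComparisonResults(anova=spatial.compare_conditions(self.groups),
                                          groups=self.groups)


@dataclass
class ConditionComparisonResults:
    anova: AnovaResult
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> str:
        a = self.anova
        lines = ["Condition comparison (one-way ANOVA on delta areas)",
                 "===================================================="]
        for k in self.groups:
            lines.append(f"{k:<20s} {a.group_means[k]:.3f} +/- "
                         f"{a.group_stds[k]:.3f}  (N = {a.group_sizes[k]})")
        lines.append(f"F = {a.f_statistic:.4g}, p = {a.p_value:.4g}  [{a.stars}]")
        return "\n".join(lines)
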