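"""Localization-cloud clustering: from blinking events to protein positions.

In DNA-PAINT each target protein produces many localizations scattered by
the per-event localization precision. A protein position is recovered by
identifying the circular cluster of localizations around a local density
maximum and taking the precision-weighted mean of its members, with weights
1/lp² per axis. The local-maximum rule is deliberately deterministic:

* each localization gets a neighbor count within ``count_radius``
  (default ``radius / 2``); a localization is a candidate center iff its
  count is >= that of every neighbor within ``radius`` and >= ``min_locs``;
  count ties break toward the lower record index;
* each localization within ``radius`` of at least one center is assigned
  to the nearest center (Euclidean; exact distance ties break toward the
  lower cluster id); others stay unassigned.

The counting kernel is narrower than the grouping radius on purpose:
counting over the full grouping radius low-pass filters the density at
that scale, so two sites separated by roughly the radius (e.g. the two
ligands of a receptor dimer, 11 nm apart, at a 10 nm radius) would always
collapse into one center seeded between them. A half-radius kernel keeps
the density peaks of such sites distinct while the grouping radius still
collects each site's full localization cloud.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import LocalizationTable

__all__ = [
    "ProteinPositionSet",
    "detect_local_maxima",
    "assign_clusters",
    "weighted_center",
    "cluster_channel",
]

UNASSIGNED = -1


@dataclass
class ProteinPositionSet:
    """Clustered protein positions for one channel.

    ``data`` columns: ``cluster_id, x, y[, z], n_locs, mean_precision``.
    ``n_locs`` is the member-localization count, ``mean_precision`` the
    arithmetic mean of the members' lateral precisions (nm).
    """

    channel_id: str
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_z(self) -> bool:
        return "z" in self.data.columns

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    @property
    def xyz(self) -> np.ndarray:
        if not self.has_z:
            raise ValueError(f"channel {self.channel_id!r} positions carry no z")
        return self.data[["x", "y", "z"]].to_numpy(float)

    def coords(self, use_z: bool = False) -> np.ndarray:
        return self.xyz if use_z else self.xy

    @classmethod
    def from_coords(cls, coords: np.ndarray, channel_id: str = "positions"):
        """Build a position set from bare (n, 2) or (n, 3) coordinates.

        Convenience for feeding simulated ground-truth molecules or
        externally clustered centers into the spatial statistics.
        """
        coords = np.asarray(coords, dtype=float)
        cols = {"cluster_id": np.arange(len(coords)),
                "x": coords[:, 0], "y": coords[:, 1]}
        if coords.shape[1] == 3:
            cols["z"] = coords[:, 2]
        cols["n_locs"] = np.ones(len(coords), dtype=int)
        cols["mean_precision"] = np.zeros(len(coords))
        return cls(channel_id=channel_id, data=pd.DataFrame(cols))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".h5", ".hdf5"):
            rec = self.data.to_records(index=False)
            with h5py.File(path, "a" if path.exists() else "w") as f:
                if self.channel_id in f:
                    del f[self.channel_id]
                f.create_dataset(self.channel_id, data=rec)
        else:
            self.data.to_csv(path, index=False)


def detect_local_maxima(
    table: LocalizationTable,
    radius: float,
    min_locs: int,
    use_z: bool = False,
    count_radius: float | None = None,
) -> np.ndarray:
    """Indices of localizations that are local neighbor-count maxima.

    Neighbor counts are taken within ``count_radius`` (default
    ``radius / 2``); candidates are compared against every neighbor within
    ``radius``. Returns record indices sorted ascending; their order
    defines the cluster ids used by :func:`assign_clusters`.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_locs < 1:
        raise ValueError("min_locs must be >= 1")
    if count_radius is None:
        count_radius = radius / 2.0
    if count_radius <= 0:
        raise ValueError("count_radius must be positive")
    pts = table.xyz if use_z else table.xy
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=count_radius, return_length=True)
    # Pairwise "defeat" within the grouping radius: of two neighbors the one
    # with the lower count loses; equal counts lose toward the higher index.
    pairs = tree.query_pairs(radius, output_type="ndarray")  # i < j
    defeated = np.zeros(n, dtype=bool)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        ci, cj = counts[i], counts[j]
        defeated[i[cj > ci]] = True
        defeated[j[ci >= cj]] = True
    return np.flatnonzero(~defeated & (counts >= min_locs))


def assign_clusters(
    table: LocalizationTable,
    maxima: np.ndarray,
    radius: float,
    use_z: bool = False,
) -> np.ndarray:
    """Label each localization with the id of its nearest maximum.

    Labels are indices into ``maxima`` (ascending record order); a
    localization farther than ``radius`` from every maximum gets -1.
    Exact distance ties go to the lower cluster id.
    """
    pts = table.xyz if use_z else table.xy
    labels = np.full(len(pts), UNASSIGNED, dtype=int)
    maxima = np.asarray(maxima, dtype=int)
    if len(maxima) == 0 or len(pts) == 0:
        return labels
    centers = pts[maxima]
    tree = cKDTree(centers)
    k = min(2, len(centers))
    d, idx = tree.query(pts, k=k, distance_upper_bound=radius)
    d, idx = np.atleast_2d(d.T).T, np.atleast_2d(idx.T).T
    hit = np.isfinite(d[:, 0])
    labels[hit] = idx[hit, 0]
    if k == 2:  # exact distance ties resolve toward the lower cluster id
        tied = hit & np.isfinite(d[:, 1]) & (d[:, 0] == d[:, 1])
        for i in np.flatnonzero(tied):
            cand = np.asarray(tree.query_ball_point(pts[i], r=d[i, 0]
                                                    + 1e-12), dtype=int)
            dc = np.linalg.norm(centers[cand] - pts[i], axis=1)
            labels[i] = int(cand[dc == dc.min()].min())
    return labels


def weighted_center(members: pd.DataFrame) -> dict[str, float]:
    """Precision-weighted mean of a cluster's member localizations.

    Per axis a the center is Σ wᵢaᵢ / Σ wᵢ with wᵢ = 1/lpᵢ² using the
    axis-matched precision (lpx for x, lpy for y, lpz for z). Also returns
    ``n_locs`` and ``mean_precision`` (arithmetic mean of the members'
    lateral precisions).
    """
    if len(members) == 0:
        raise ValueError("weighted_center needs at least one member")
    out: dict[str, float] = {}
    axes = [("x", "lpx"), ("y", "lpy")]
    if "z" in members.columns:
        axes.append(("z", "lpz"))
    for coord, prec in axes:
        w = 1.0 / members[prec].to_numpy(float) ** 2
        out[coord] = float(np.sum(w * members[coord].to_numpy(float)) / np.sum(w))
    out["n_locs"] = float(len(members))
    lat = members[["lpx", "lpy"]].to_numpy(float)
    out["mean_precision"] = float(lat.mean())
    return out


def cluster_channel(
    table: LocalizationTable,
    radius: float = 10.0,
    min_locs: int = 10,
    use_z: bool = False,
    count_radius: float | None = None,
) -> ProteinPositionSet:
    """Full clustering of one channel into protein positions.

    Composition of maxima detection, nearest-maximum assignment and
    precision-weighted centering. Clusters whose final membership drops
    below ``min_locs`` (members stolen by a closer maximum) are dropped;
    surviving clusters are renumbered 0..k-1 in detection order. 3D tables
    cluster on lateral (x, y) distance by default — axial precision is
    worse than lateral, so mixing axes degrades separation — with z
    carried through to the weighted center; set ``use_z`` to cluster on
    3D distance.
    """
    maxima = detect_local_maxima(table, radius, min_locs, use_z=use_z,
                                 count_radius=count_radius)
    labels = assign_clusters(table, maxima, radius, use_z=use_z)
    n_clusters = len(maxima)
    assigned = labels >= 0
    lab = labels[assigned]
    sizes = np.bincount(lab, minlength=n_clusters)
    keep = sizes >= min_locs

    def wsum(values, weights):
        return np.bincount(lab, weights=values * weights, minlength=n_clusters)

    df_in = table.data.loc[assigned]
    cols: dict[str, np.ndarray] = {}
    axes = [("x", "lpx"), ("y", "lpy")] + ([("z", "lpz")] if table.has_z else [])
    with np.errstate(invalid="ignore"):
        for coord, prec in axes:
            w = 1.0 / df_in[prec].to_numpy(float) ** 2
            cols[coord] = (wsum(df_in[coord].to_numpy(float), w)
                           / np.bincount(lab, weights=w, minlength=n_clusters))
        lat = 0.5 * (df_in["lpx"].to_numpy(float) + df_in["lpy"].to_numpy(float))
        mean_prec = (np.bincount(lab, weights=lat, minlength=n_clusters)
                     / np.maximum(sizes, 1))
    df = pd.DataFrame({"cluster_id": np.arange(int(keep.sum())),
                       **{c: v[keep] for c, v in cols.items()},
                       "n_locs": sizes[keep].astype(int),
                       "mean_precision": mean_prec[keep]})
    order = ["cluster_id", "x", "y"] + (["z"] if table.has_z else []) + [
        "n_locs", "mean_precision"]
    return ProteinPositionSet(channel_id=table.channel_id, data=df[order])
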