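"""Morphometric quantification of nuclear point patterns (micron units).

Implements the measurement rules used on stained trophoblast preparations:

* internuclear distance — edge-to-edge (not centre-to-centre) distance from
  each nucleus to its nearest neighbour;
* syncytial nuclear clusters (SNCs) — in cultured syncytia, >= 6 nuclei
  linked by edge-to-edge gaps <= 3 um;
* syncytial nuclear aggregates (SNAs) — in tissue sections, clusters of
  >= 10 nuclei; the accompanying histological requirement (the aggregate
  protrudes from the villus edge) needs expert annotation and is only
  flagged, never computed;
* large syncytia — cultured cells with >= 6 nuclei; cytoplasmic area per
  nucleus = boundary-polygon area / nucleus count;
* shed-particle census — particles retained at >= 80 um^2, the estimated
  upper size of red blood cells and single trophoblasts.

Nuclei flagged as excluded (condensed/apoptotic morphology) are dropped by
every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .clustering import ClusterAssignment, find_clusters

__all__ = [
    "PointPattern",
    "NuclearClusters",
    "MorphometryReport",
    "internuclear_distances",
    "detect_snc",
    "detect_sna",
    "sna_density_and_size",
    "large_syncytium_stats",
    "filter_particles",
    "shedding_fraction",
    "SNC_GAP_UM",
    "SNC_MIN_NUCLEI",
    "SNA_MIN_NUCLEI",
    "LARGE_SYNCYTIUM_MIN_NUCLEI",
    "PARTICLE_AREA_THRESHOLD_UM2",
]

SNC_GAP_UM = 3.0
SNC_MIN_NUCLEI = 6
SNA_MIN_NUCLEI = 10
LARGE_SYNCYTIUM_MIN_NUCLEI = 6
PARTICLE_AREA_THRESHOLD_UM2 = 80.0


@dataclass
class PointPattern:
    """Nuclear centroids and radii in microns, with optional cell boundary.

    ``excluded`` marks condensed (apoptotic) nuclei to be ignored by all
    measurements.  ``field_area_mm2`` is the imaged villous area used for
    density reporting.
    """

    centroids: np.ndarray  # (n, 2) um
    radii: np.ndarray  # (n,) um
    boundary_polygon: Optional[Polygon] = None
    field_area_mm2: Optional[float] = None
    excluded: Optional[np.ndarray] = None
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.centroids.size == 0:
            self.centroids = self.centroids.reshape(0, 2)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.radii.size != self.centroids.shape[0]:
            raise ValueError("radii and centroids disagree in length")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")
        if self.boundary_polygon is not None and not self.boundary_polygon.is_simple:
            raise ValueError("boundary polygon must be simple (non-self-intersecting)")
        if self.excluded is None:
            self.excluded = np.zeros(self.radii.size, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool).ravel()

    @property
    def n_nuclei(self) -> int:
        """Count of included (non-apoptotic) nuclei."""
        return int(np.count_nonzero(~self.excluded))

    def included(self) -> "PointPattern":
        """View restricted to non-excluded nuclei."""
        keep = ~self.excluded
        return PointPattern(
            self.centroids[keep], self.radii[keep], self.boundary_polygon,
            self.field_area_mm2, None, self.cell_id,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PointPattern":
        """Build from a table with columns x_um, y_um, radius_um
        (optional: excluded_flag)."""
        excluded = (
            df["excluded_flag"].to_numpy(dtype=bool)
            if "excluded_flag" in df.columns else None
        )
        return cls(
            df[["x_um", "y_um"]].to_numpy(dtype=float),
            df["radius_um"].to_numpy(dtype=float),
            excluded=excluded,
            **kwargs,
        )


@dataclass
class NuclearClusters:
    """Clusters called on a point pattern.

    ``labels`` gives the called cluster index per included nucleus, or -1
    for nuclei "not residing in a cluster"; ``members`` lists the nucleus
    indices of each called cluster.  ``requires_annotation`` flags criteria
    (SNA protrusion from the villus edge) that cannot be evaluated from
    centroids alone.
    """

    members: List[np.ndarray]
    labels: np.ndarray
    min_size: int
    gap_um: float
    requires_annotation: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=int)


def _edge_distance_matrix(pattern: PointPattern) -> np.ndarray:
    c, r = pattern.centroids, pattern.radii
    d = cdist(c, c) - r[:, None] - r[None, :]
    return np.maximum(d, 0.0)


def internuclear_distances(pattern: PointPattern) -> np.ndarray:
    """Edge-to-edge nearest-neighbour distance per included nucleus (um).

    ``min_j (||c_i - c_j|| - r_i - r_j)`` floored at zero for overlapping
    nuclear profiles."""
    pat = pattern.included()
    n = pat.centroids.shape[0]
    if n < 2:
        raise ValueError("internuclear distance needs at least 2 nuclei")
    d = _edge_distance_matrix(pat)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _gap_components(pattern: PointPattern, gap_um: float) -> ClusterAssignment:
    pat = pattern.included()
    n = pat.centroids.shape[0]
    if n == 0:
        return ClusterAssignment(np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp))
    d = _edge_distance_matrix(pat)
    np.fill_diagonal(d, np.inf)
    adjacency = [np.flatnonzero(d[i] <= gap_um) for i in range(n)]
    return find_clusters(adjacency)


def _call_clusters(
    pattern: PointPattern,
    gap_um: float,
    min_size: int,
    strict: bool,
    requires_annotation: bool,
) -> NuclearClusters:
    pat = pattern.included()
    n = pat.centroids.shape[0]
    if strict and n >= 2:
        # post-filter: keep only nuclei whose own nearest neighbour is
        # within the gap, then rebuild components
        nn = internuclear_distances(pat)
        keep = np.flatnonzero(nn <= gap_um)
        sub = PointPattern(pat.centroids[keep], pat.radii[keep])
        comp = _gap_components(sub, gap_um)
        idx_map = keep
    else:
        comp = _gap_components(pat, gap_um)
        idx_map = np.arange(n)
    labels = np.full(n, -1, dtype=int)
    members: List[np.ndarray] = []
    for c in range(comp.n_clusters):
        member_idx = idx_map[np.flatnonzero(comp.labels == c)]
        if member_idx.size >= min_size:
            labels[member_idx] = len(members)
            members.append(member_idx)
    return NuclearClusters(members, labels, min_size, gap_um, requires_annotation)


def detect_snc(
    pattern: PointPattern, gap_um: float = SNC_GAP_UM,
    min_size: int = SNC_MIN_NUCLEI, strict: bool = False,
) -> NuclearClusters:
    """Syncytial nuclear clusters: >= 6 nuclei at edge gaps <= 3 um.

    Formalised as connected components of the <=3 um edge-gap graph (every
    member's nearest neighbour is then necessarily within 3 um); with
    ``strict=True`` nuclei whose own nearest neighbour lies beyond the gap
    are removed before components are formed."""
    return _call_clusters(pattern, gap_um, min_size, strict, requires_annotation=False)


def detect_sna(
    pattern: PointPattern, gap_um: float = SNC_GAP_UM, min_size: int = SNA_MIN_NUCLEI
) -> NuclearClusters:
    """Syncytial nuclear aggregates: clusters of >= 10 nuclei in tissue.

    The histological requirement that an aggregate protrude from the
    villus edge is not computable from centroids; calls are flagged as
    requiring expert annotation."""
    out = _call_clusters(pattern, gap_um, min_size, strict=False, requires_annotation=True)
    return out


def sna_density_and_size(
    clusters: NuclearClusters, pattern: PointPattern, field_area_mm2: Optional[float] = None
) -> dict:
    """SNA density per mm^2 of villous area and per-cluster areas in um^2.

    Cluster area is the convex hull of the member nucleus discs (the
    package's stated convention for the ImageJ-measured aggregate area).
    Returns density, the list of areas and their median."""
    area_mm2 = field_area_mm2 if field_area_mm2 is not None else pattern.field_area_mm2
    if area_mm2 is None or not area_mm2 > 0:
        raise ValueError("a positive field area (mm^2) is required for density")
    pat = pattern.included()
    areas = []
    for member_idx in clusters.members:
        discs = unary_union(
            [Point(*pat.centroids[i]).buffer(pat.radii[i], quad_segs=64) for i in member_idx]
        )
        areas.append(float(discs.convex_hull.area))
    return {
        "density_per_mm2": clusters.n_clusters / area_mm2,
        "areas_um2": areas,
        "median_area_um2": float(np.median(areas)) if areas else float("nan"),
    }


def large_syncytium_stats(patterns: Sequence[PointPattern]) -> dict:
    """Population summary over per-cell patterns with boundary polygons.

    A cell is a "large syncytium" when it holds >= 6 nuclei.  Reports the
    per-cell table (nucleus count, polygon area, cytoplasmic area per
    nucleus, large-syncytium flag, SNC nucleus count) and aggregates: the
    percentage of all nuclei residing in large syncytia and the percentage
    of large-syncytium nuclei residing in SNCs.  Cells without a polygon
    are skipped (counted in ``n_skipped``)."""
    rows = []
    n_skipped = 0
    for k, pat in enumerate(patterns):
        if pat.boundary_polygon is None:
            n_skipped += 1
            continue
        n = pat.n_nuclei
        area = float(pat.boundary_polygon.area)
        large = n >= LARGE_SYNCYTIUM_MIN_NUCLEI
        in_snc = 0
        if large and n >= 2:
            snc = detect_snc(pat)
            in_snc = int(np.count_nonzero(snc.labels >= 0))
        rows.append(
            dict(
                cell_id=pat.cell_id if pat.cell_id is not None else str(k),
                n_nuclei=n,
                polygon_area_um2=area,
                area_per_nucleus_um2=area / n if n else float("nan"),
                is_large_syncytium=large,
                n_nuclei_in_snc=in_snc,
            )
        )
    table = pd.DataFrame(rows)
    total = int(table["n_nuclei"].sum()) if len(table) else 0
    in_large = int(table.loc[table["is_large_syncytium"], "n_nuclei"].sum()) if len(table) else 0
    in_snc = int(table.loc[table["is_large_syncytium"], "n_nuclei_in_snc"].sum()) if len(table) else 0
    return {
        "per_cell": table,
        "n_skipped": n_skipped,
        "percent_nuclei_in_large_syncytia": 100.0 * in_large / total if total else float("nan"),
        "percent_large_syncytium_nuclei_in_snc": 100.0 * in_snc / in_large if in_large else float("nan"),
    }


def filter_particles(
    areas: Sequence[float], threshold_um2: float = PARTICLE_AREA_THRESHOLD_UM2
) -> np.ndarray:
    """Retain shed particles with area >= threshold (inclusive).

    The 80 um^2 default is the estimated upper size of red blood cells and
    single trophoblast cells; retained particles are of SNA-comparable size.
    """
    a = np.asarray(areas, dtype=float).ravel()
    if np.any(a < 0):
        raise ValueError("particle areas must be non-negative")
    return a[a >= threshold_um2]


def shedding_fraction(particles_per_mg_48h: float, snas_per_mg: float) -> float:
    """Shed particles in 48 h as a percentage of tissue SNAs per mg protein."""
    if not snas_per_mg > 0:
        raise ValueError("snas_per_mg must be positive")
    return 100.0 * particles_per_mg_48h / snas_per_mg


@dataclass
class MorphometryReport:
    """Bundle of the standard per-pattern measurements."""

    nn_distances_um: np.ndarray
    snc: NuclearClusters
    sna: NuclearClusters
    summary: dict = field(default_factory=dict)

    @classmethod
    def from_pattern(cls, pattern: PointPattern) -> "MorphometryReport":
        nn = (
            internuclear_distances(pattern)
            if pattern.n_nuclei >= 2 else np.empty(0)
        )
        snc = detect_snc(pattern)
        sna = detect_sna(pattern)
        n = pattern.n_nuclei
        summary = {
            "n_nuclei": n,
            "median_nn_um": float(np.median(nn)) if nn.size else float("nan"),
            "n_snc": snc.n_clusters,
            "n_sna": sna.n_clusters,
            "percent_nuclei_in_snc": (
                100.0 * float(np.count_nonzero(snc.labels >= 0)) / n if n else float("nan")
            ),
        }
        return cls(nn, snc, sna, summary)
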