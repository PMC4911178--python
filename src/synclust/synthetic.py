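"""Ground-truthed synthetic inputs for the morphometry pipeline.

Emulates, with known ground truth, the structures measured in stained
trophoblast preparations: clustered vs dispersed nuclear point patterns
(planted clusters with controlled intra-cluster gaps and inter-cluster
spacing), populations of mononucleate cells and multinucleate syncytia
with boundary polygons, and right-skewed (lognormal) shed-particle area
distributions spanning the 80-900 um^2 range typical of syncytial nuclear
aggregates.

Cluster placement is deterministic-geometric (hexagonal packing around
each cluster seed) so that recovery tests are exact; an optional jitter
adds positional noise for robustness testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon

from .morphometry import SNC_GAP_UM, PointPattern

__all__ = [
    "GeneratorSpec",
    "generate_clustered_pattern",
    "generate_cell_population",
    "generate_particle_areas",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic pattern generators (micron units).

    The particle-area lognormal defaults (log-mean 5.55, log-sd 0.55) put
    ~95% of areas in roughly 85-775 um^2, matching the right-skewed
    80-900 um^2 range reported for SNAs.
    """

    n_clusters: int = 3
    cluster_size: int = 8
    cluster_size_distribution: str = "fixed"  # "fixed" | "poisson"
    cluster_sizes: Optional[Tuple[int, ...]] = None  # explicit override
    intra_cluster_gap: float = 1.0  # um, edge-to-edge within a cluster
    inter_cluster_spacing: float = 60.0  # um between cluster seeds
    background_nuclei: int = 20
    nucleus_radius: float = 4.5  # um (~9 um nuclear diameter)
    field: Tuple[float, float] = (400.0, 400.0)  # um rectangle
    jitter_sd: float = 0.0  # um positional noise on cluster members
    particle_lognormal: Tuple[float, float] = (5.55, 0.55)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.intra_cluster_gap <= 0 or self.inter_cluster_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if self.cluster_size_distribution not in ("fixed", "poisson"):
            raise ValueError("cluster_size_distribution must be 'fixed' or 'poisson'")


def _hex_offsets(n: int, spacing: float) -> np.ndarray:
    """First n sites of a hexagonal packing around the origin."""
    sites = [(0.0, 0.0)]
    k = 1
    while len(sites) < n:
        # ring k: 6k points at radius k*spacing along the hex directions
        corners = [
            (k * spacing * np.cos(a), k * spacing * np.sin(a))
            for a in np.arange(6) * np.pi / 3.0
        ]
        for c in range(6):
            x0, y0 = corners[c]
            x1, y1 = corners[(c + 1) % 6]
            for s in range(k):
                t = s / k
                sites.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
        k += 1
    return np.array(sites[:n])


def _cluster_sizes(spec: GeneratorSpec, rng: np.random.Generator) -> List[int]:
    if spec.cluster_sizes is not None:
        if len(spec.cluster_sizes) != spec.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        return list(spec.cluster_sizes)
    if spec.cluster_size_distribution == "fixed":
        return [spec.cluster_size] * spec.n_clusters
    # shifted Poisson: at least one nucleus per planted cluster
    return [1 + int(rng.poisson(max(spec.cluster_size - 1, 0)))
            for _ in range(spec.n_clusters)]


def generate_clustered_pattern(
    spec: GeneratorSpec, seed=None
) -> Tuple[PointPattern, np.ndarray]:
    """Planted-cluster point pattern with ground-truth labels.

    Cluster seeds sit on a grid at least ``inter_cluster_spacing`` apart;
    members are hex-packed around each seed at centre spacing
    ``2 r + intra_cluster_gap``; background nuclei are uniform in the field
    but kept at least twice the SNC gap away from every cluster nucleus and
    from each other, so they can never join or form a called cluster.

    Returns the pattern and a label array (cluster index per nucleus, -1
    for background).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    W, H = spec.field
    margin = spec.inter_cluster_spacing / 2.0
    sizes = _cluster_sizes(spec, rng)
    member_spacing = 2.0 * spec.nucleus_radius + spec.intra_cluster_gap

    # cluster seeds on a square grid with the required spacing
    if spec.n_clusters > 0:
        per_row = max(1, int((W - 2 * margin) // spec.inter_cluster_spacing) + 1)
        seeds = []
        for c in range(spec.n_clusters):
            gx, gy = c % per_row, c // per_row
            sx = margin + gx * spec.inter_cluster_spacing
            sy = margin + gy * spec.inter_cluster_spacing
            if sx > W - margin / 2 or sy > H - margin / 2:
                raise ValueError(
                    f"field {spec.field} cannot hold {spec.n_clusters} clusters "
                    f"at spacing {spec.inter_cluster_spacing}"
                )
            seeds.append((sx, sy))
    else:
        seeds = []

    centroids, labels = [], []
    for ci, ((sx, sy), size) in enumerate(zip(seeds, sizes)):
        offs = _hex_offsets(size, member_spacing)
        if spec.jitter_sd > 0:
            offs = offs + rng.normal(0.0, spec.jitter_sd, size=offs.shape)
        for ox, oy in offs:
            centroids.append((sx + ox, sy + oy))
            labels.append(ci)

    # background nuclei: far from every cluster nucleus and from each other
    clearance = 2.0 * SNC_GAP_UM + 2.0 * spec.nucleus_radius  # centre distance
    placed = np.array(centroids) if centroids else np.empty((0, 2))
    n_bg = 0
    attempts = 0
    max_attempts = 2000 * max(spec.background_nuclei, 1)
    while n_bg < spec.background_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.background_nuclei} background nuclei "
                f"in field {spec.field}; placed {n_bg}"
            )
        cand = rng.uniform((0, 0), (W, H))
        if placed.shape[0] and np.min(np.sum((placed - cand) ** 2, axis=1)) < clearance**2:
            continue
        placed = np.vstack([placed, cand])
        centroids.append(tuple(cand))
        labels.append(-1)
        n_bg += 1

    centroids_arr = np.array(centroids) if centroids else np.empty((0, 2))
    radii = np.full(centroids_arr.shape[0], spec.nucleus_radius)
    pattern = PointPattern(
        centroids_arr, radii, field_area_mm2=W * H / 1e6
    )
    return pattern, np.array(labels, dtype=int)


def generate_cell_population(
    n_mononucleate: int = 10,
    syncytium_sizes: Sequence[int] = (3, 6, 8, 12),
    nucleus_radius: float = 4.5,
    intra_gap: float = 1.0,
    margin: float = 10.0,
    seed=None,
) -> List[PointPattern]:
    """Mononucleate cells plus syncytia, each with a square boundary polygon.

    Nuclei are hex-packed at the cell centre; the square side is the nuclear
    extent plus ``2 * margin``, so every polygon area is known analytically
    (side^2).  Cells are laid side by side along x.
    """
    rng = np.random.default_rng(seed)
    patterns: List[PointPattern] = []
    x_cursor = 0.0
    spacing = 2.0 * nucleus_radius + intra_gap
    sizes = [1] * n_mononucleate + list(syncytium_sizes)
    for k, size in enumerate(sizes):
        offs = _hex_offsets(size, spacing)
        extent = 2 * (np.max(np.abs(offs)) + nucleus_radius) if size > 1 else 2 * nucleus_radius
        side = extent + 2 * margin
        cx = x_cursor + side / 2.0
        cy = side / 2.0
        poly = Polygon(
            [(x_cursor, 0.0), (x_cursor + side, 0.0),
             (x_cursor + side, side), (x_cursor, side)]
        )
        centroids = offs + np.array([cx, cy])
        patterns.append(
            PointPattern(
                centroids, np.full(size, nucleus_radius),
                boundary_polygon=poly, cell_id=f"cell{k}",
            )
        )
        x_cursor += side + margin
    rng.shuffle(patterns)
    return patterns


def generate_particle_areas(spec: GeneratorSpec, n: int, seed=None) -> np.ndarray:
    """Lognormal shed-particle areas (um^2)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mu, sd = spec.particle_lognormal
    if sd == 0:
        return np.full(n, np.exp(mu))
    return rng.lognormal(mu, sd, size=n)
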