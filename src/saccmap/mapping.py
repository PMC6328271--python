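"""Attention maps: natural-neighbor filling and Lanczos upsampling.

The sensitivity analysis yields values on the 31 tested checkerboard nodes
of the 9x7 lattice.  Full maps are built by Sibson natural-neighbor
interpolation of the untested intersections: the weight of node i for a
query q is the area the Voronoi cell of q (inserted into the diagram)
steals from the cell of i.  Natural-neighbor interpolation is exact for
linear fields inside the convex hull; on the hull boundary it degenerates
to linear interpolation along the hull edge, and outside the hull the
nearest node's value is used (logged).

The coarse 7x9 matrix (rows = y ascending, columns = x ascending) is then
upsampled with a separable Lanczos kernel (mirror-padded, per-sample
normalized) purely for display; statistics always operate on node values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, Voronoi, cKDTree
from shapely.geometry import Polygon

from .geometry import GRID_SPACING

logger = logging.getLogger(__name__)

LATTICE_XS = np.arange(-12.0, 12.1, GRID_SPACING)   # 9 columns
LATTICE_YS = np.arange(-9.0, 9.1, GRID_SPACING)     # 7 rows


@dataclass
class AttentionMap:
    """Coarse full-lattice matrix plus its Lanczos-upsampled field."""

    coarse: np.ndarray                     # (7, 9), rows y ascending
    fine: Optional[np.ndarray] = None
    extent: Tuple[float, float, float, float] = (-12.0, 12.0, -9.0, 9.0)
    factor: int = 1
    provenance: dict = field(default_factory=dict)


def _halfplane(pi: np.ndarray, pj: np.ndarray, radius: float = 1e3) -> Polygon:
    """Big polygon covering {x : |x - pi| <= |x - pj|}."""
    mid = (pi + pj) / 2.0
    d = pj - pi
    d = d / np.hypot(*d)
    perp = np.array([-d[1], d[0]])
    corners = [mid + perp * radius, mid - perp * radius,
               mid - perp * radius - d * radius, mid + perp * radius - d * radius]
    return Polygon(corners)


def sibson_weights(points: np.ndarray, q: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sibson natural-neighbor weights of scattered ``points`` for query ``q``.

    Only valid for queries strictly inside the convex hull (the inserted
    Voronoi cell must be bounded); raises ValueError otherwise.  Returns
    (indices, weights) with weights summing to 1.
    """
    points = np.asarray(points, float)
    n = len(points)
    aug = Voronoi(np.vstack([points, q]))
    region = aug.regions[aug.point_region[n]]
    if len(region) == 0 or -1 in region:
        raise ValueError("query is not strictly inside the convex hull")
    cell = Polygon(aug.vertices[region])
    area = cell.area
    if area <= 0:
        raise ValueError("degenerate inserted Voronoi cell")

    # natural neighbors: points sharing a ridge with the inserted site
    neighbors = set()
    for (a, b) in aug.ridge_points:
        if a == n:
            neighbors.add(int(b))
        elif b == n:
            neighbors.add(int(a))

    idx, wts = [], []
    for i in sorted(neighbors):
        piece = cell
        pi = points[i]
        for j in sorted(neighbors):
            if j == i:
                continue
            piece = piece.intersection(_halfplane(pi, points[j]))
            if piece.is_empty:
                break
        if not piece.is_empty and piece.area > 0:
            idx.append(i)
            wts.append(piece.area)
    w = np.asarray(wts) / area
    return np.asarray(idx, int), w


def natural_neighbor_fill(node_values: Dict[Tuple[float, float], float]) -> np.ndarray:
    """Fill the full 9x7 lattice from values at scattered tested nodes.

    Tested nodes pass through unchanged.  Untested intersections strictly
    inside the convex hull get Sibson weights; boundary intersections get
    the on-hull limit (linear interpolation within the containing Delaunay
    simplex); exterior intersections get the nearest node's value (logged).
    NaN-valued nodes are treated as untested.
    """
    items = [(np.asarray(k, float), float(v)) for k, v in node_values.items()
             if np.isfinite(v)]
    if len(items) < 3:
        raise ValueError("need at least 3 finite-valued nodes")
    pts = np.asarray([p for p, _ in items])
    vals = np.asarray([v for _, v in items])
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("nodes are collinear")

    tri = Delaunay(pts)
    hull = ConvexHull(pts)
    tree = cKDTree(pts)
    # hull edges as (point, unit direction) for boundary detection
    eqs = hull.equations  # a*x + b*y + c = 0, outward normals

    out = np.full((len(LATTICE_YS), len(LATTICE_XS)), np.nan)
    n_exterior = 0
    for iy, yv in enumerate(LATTICE_YS):
        for ix, xv in enumerate(LATTICE_XS):
            q = np.array([xv, yv])
            d, nearest = tree.query(q)
            if d < 1e-9:
                out[iy, ix] = vals[nearest]
                continue
            signed = eqs[:, :2] @ q + eqs[:, 2]
            if (signed > 1e-9).any():           # outside the hull
                out[iy, ix] = vals[nearest]
                n_exterior += 1
                continue
            if (np.abs(signed) <= 1e-9).any():  # on the hull boundary
                out[iy, ix] = _simplex_linear(tri, pts, vals, q)
                continue
            idx, w = sibson_weights(pts, q)
            out[iy, ix] = float(w @ vals[idx])
    if n_exterior:
        logger.info("natural-neighbor fill: %d hull-exterior intersections "
                    "filled by nearest node", n_exterior)
    return out


def _simplex_linear(tri: Delaunay, pts: np.ndarray, vals: np.ndarray,
                    q: np.ndarray) -> float:
    s = tri.find_simplex(q)
    if s < 0:  # numeric edge case: fall back to nearest
        return float(vals[np.argmin(np.hypot(*(pts - q).T))])
    verts = tri.simplices[s]
    T = tri.transform[s]
    bc = T[:2] @ (q - T[2])
    bary = np.append(bc, 1.0 - bc.sum())
    return float(bary @ vals[verts])


def lanczos_kernel(x: np.ndarray, a: int = 3) -> np.ndarray:
    """Lanczos-a window: sinc(x) * sinc(x/a) on |x| < a, else 0."""
    x = np.asarray(x, float)
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def _resample_axis(m: np.ndarray, factor: int, a: int) -> np.ndarray:
    """Upsample along axis 0 with a mirror-padded, normalized Lanczos kernel."""
    n = m.shape[0]
    n_out = n * factor
    # output sample j sits at (j + 0.5)/factor - 0.5 in input coordinates
    coords = (np.arange(n_out) + 0.5) / factor - 0.5
    pad = a + 1
    idx = np.arange(-pad, n + pad)
    # half-sample mirror (x[-1] = x[0]), matching the half-sample output grid
    mirrored = np.where(idx < 0, -idx - 1, idx)
    mirrored = np.where(mirrored >= n, 2 * n - 1 - mirrored, mirrored)
    padded = m[mirrored.clip(0, n - 1)]
    out = np.empty((n_out,) + m.shape[1:])
    for j, c in enumerate(coords):
        base = int(math.floor(c))
        taps = np.arange(base - a + 1, base + a + 1)
        w = lanczos_kernel(c - taps, a)
        w = w / w.sum()
        out[j] = np.tensordot(w, padded[taps + pad], axes=1)
    return out


def lanczos_resample(m: np.ndarray, factor: int = 8, a: int = 3) -> np.ndarray:
    """Separable Lanczos-a upsampling; output dims = input dims x factor."""
    m = np.asarray(m, float)
    if factor < 2:
        raise ValueError("factor must be an integer >= 2")
    if m.ndim != 2 or min(m.shape) < 4:
        raise ValueError("matrix must be 2-D and at least 4x4")
    out = _resample_axis(m, factor, a)
    out = _resample_axis(out.T, factor, a).T
    return out


def build_attention_map(node_values: Dict[Tuple[float, float], float],
                        factor: int = 8, a: int = 3,
                        provenance: Optional[dict] = None) -> AttentionMap:
    coarse = natural_neighbor_fill(node_values)
    fine = lanczos_resample(coarse, factor=factor, a=a)
    return AttentionMap(coarse=coarse, fine=fine, factor=factor,
                        provenance=provenance or {})


def group_average(maps: Sequence[AttentionMap]) -> AttentionMap:
    """Element-wise mean map across participants."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].coarse.shape
    if any(m.coarse.shape != shape for m in maps):
        raise ValueError("maps have mismatched geometry")
    coarse = np.mean([m.coarse for m in maps], axis=0)
    fine = None
    if all(m.fine is not None for m in maps):
        fine = np.mean([m.fine for m in maps], axis=0)
    return AttentionMap(coarse=coarse, fine=fine, factor=maps[0].factor,
                        provenance={"n_participants": len(maps)})


def threshold_map(profile, ft: Tuple[float, float], resolution: float = 0.25,
                  extent: Tuple[float, float, float, float] = (-12, 12, -9, 9),
                  ) -> np.ndarray:
    """Tilt-threshold field: the profile evaluated at each pixel's
    eccentricity from the fixation target (concentric disks)."""
    x0, x1, y0, y1 = extent
    xs = np.arange(x0, x1 + resolution / 2, resolution)
    ys = np.arange(y0, y1 + resolution / 2, resolution)
    gx, gy = np.meshgrid(xs, ys)
    ecc = np.hypot(gx - ft[0], gy - ft[1])
    return np.asarray(profile(ecc), float)


def save_map_tsv(path, amap: AttentionMap, which: str = "coarse") -> None:
    """Serialize a map matrix as TSV with a small header."""
    mat = getattr(amap, which)
    header = (f"# saccmap attention map ({which}); extent "
              f"{amap.extent}; spacing {GRID_SPACING}; factor {amap.factor}")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, mat, delimiter="\t", fmt="%.6f")


def render_map(path, amap: AttentionMap, vmin: float = 0.25, vmax: float = 0.75,
               title: str = "") -> None:
    """Optional PNG render over the standard display range [0.25, 0.75]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = amap.fine if amap.fine is not None else amap.coarse
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(mat, origin="lower", extent=amap.extent, vmin=vmin,
                   vmax=vmax, cmap="viridis", aspect="equal")
    fig.colorbar(im, ax=ax, label="normalized d'")
    ax.set_xlabel("x (dva)")
    ax.set_ylabel("y (dva)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
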