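"""Disk lattice geometry for the corneal basal layer.

The tissue is a round patch of the basal cell layer: a disk of unit-spaced
square-lattice sites of total radius ``R_total``. The outermost annulus of
width ``limbal_width`` is the limbus (the stem-cell niche); everything inside
it is the cornea proper, of radius ``R = R_total - limbal_width``. Sites are
8-connected (Moore neighborhood) so that displacement chains can follow
arbitrary replication-to-removal vectors.

All coordinates are in cell units; angles in radians in [0, 2pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

CORNEA = 0
LIMBUS = 1

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class Site(NamedTuple):
    """A single lattice site."""

    index: int
    x: int
    y: int
    r: float
    theta: float
    region: int  # CORNEA or LIMBUS


@dataclass
class SiteGrid:
    """Static disk lattice: coordinates, regions and adjacency.

    Adjacency is stored in CSR form (``nbr_indptr``/``nbr_indices``) over all
    sites. ``index_map`` maps lattice coordinates (offset by ``R_total``) back
    to site ids, -1 where no site exists.
    """

    R_total: float
    limbal_width: float
    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    region: np.ndarray
    nbr_indptr: np.ndarray
    nbr_indices: np.ndarray
    index_map: np.ndarray
    corneal_sites: np.ndarray = field(repr=False)
    limbal_sites: np.ndarray = field(repr=False)

    @property
    def n_sites(self) -> int:
        return self.x.size

    @property
    def R(self) -> float:
        """Corneal radius (limbus excluded)."""
        return self.R_total - self.limbal_width

    def site(self, i: int) -> Site:
        return Site(i, int(self.x[i]), int(self.y[i]), float(self.r[i]),
                    float(self.theta[i]), int(self.region[i]))

    def neighbors(self, i: int) -> np.ndarray:
        return self.nbr_indices[self.nbr_indptr[i]:self.nbr_indptr[i + 1]]

    def site_at(self, x: int, y: int) -> int:
        """Site id at lattice coordinates, -1 if outside the tissue."""
        off = self.index_map.shape[0] // 2
        if abs(x) > off or abs(y) > off:
            return -1
        return int(self.index_map[x + off, y + off])

    def to_dataframe(self) -> pd.DataFrame:
        """Plain-table export (site id, x, y, r, theta, region)."""
        return pd.DataFrame({
            "site": np.arange(self.n_sites),
            "x": self.x, "y": self.y, "r": self.r, "theta": self.theta,
            "region": np.where(self.region == LIMBUS, "LIMBUS", "CORNEA"),
        })


def build_tissue(R_total: float, limbal_width: float = 1.0) -> SiteGrid:
    """Build the disk lattice of all integer sites with r <= R_total.

    Limbal sites are those with ``r > R_total - limbal_width``; the rest are
    corneal. Raises ``ValueError`` for invalid radius/width combinations.
    """
    if R_total < 1:
        raise ValueError(f"R_total must be >= 1, got {R_total}")
    if not (1 <= limbal_width <= R_total):
        raise ValueError(
            f"limbal_width must satisfy 1 <= width <= R_total, got {limbal_width}")

    n = int(np.floor(R_total))
    ax = np.arange(-n, n + 1)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    mask = X * X + Y * Y <= R_total * R_total
    x = X[mask].astype(np.int32)
    y = Y[mask].astype(np.int32)
    r = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    R = R_total - limbal_width
    if R <= 0:
        region = np.full(r.shape, LIMBUS, dtype=np.uint8)  # all-niche disk
    else:
        region = np.where(r > R, LIMBUS, CORNEA).astype(np.uint8)

    index_map = np.full((2 * n + 1, 2 * n + 1), -1, dtype=np.int32)
    index_map[x + n, y + n] = np.arange(x.size, dtype=np.int32)

    indptr = np.zeros(x.size + 1, dtype=np.int32)
    nbrs = []
    for i in range(x.size):
        for dx, dy in _MOORE:
            xi, yi = x[i] + dx, y[i] + dy
            if abs(xi) <= n and abs(yi) <= n:
                j = index_map[xi + n, yi + n]
                if j >= 0:
                    nbrs.append(j)
        indptr[i + 1] = len(nbrs)
    return SiteGrid(
        R_total=float(R_total), limbal_width=float(limbal_width),
        x=x, y=y, r=r, theta=theta.astype(np.float64), region=region,
        nbr_indptr=indptr, nbr_indices=np.asarray(nbrs, dtype=np.int32),
        index_map=index_map,
        corneal_sites=np.flatnonzero(region == CORNEA).astype(np.int32),
        limbal_sites=np.flatnonzero(region == LIMBUS).astype(np.int32),
    )


def _sector_mask(grid: SiteGrid, center: int, m: float, alpha: float) -> np.ndarray:
    """Boolean mask over all sites for the inward-facing removal sector."""
    dx = grid.x.astype(np.float64) - grid.x[center]
    dy = grid.y.astype(np.float64) - grid.y[center]
    d2 = dx * dx + dy * dy
    mask = (d2 > 0) & (d2 <= m * m) & (grid.region == CORNEA)
    rc = grid.r[center]
    if rc >= 0.5 and alpha < 2 * np.pi:
        # inward radial unit vector at the center site
        ux, uy = -grid.x[center] / rc, -grid.y[center] / rc
        cosang = (dx * ux + dy * uy) / np.sqrt(np.where(d2 > 0, d2, 1.0))
        mask &= cosang >= np.cos(alpha / 2) - 1e-12
    return mask


def local_sector(grid: SiteGrid, center: int, m: float, alpha: float) -> np.ndarray:
    """Corneal sites within distance m of ``center`` inside the inward sector.

    The sector of angular width ``alpha`` is bisected by the inward radial
    direction (toward the tissue center). ``alpha = 2*pi`` disables the bias
    and returns the full m-disk intersected with the cornea. For a center at
    the exact tissue middle (r < 0.5) the inward direction is undefined and
    the full disk is returned. The center site itself is excluded. May be
    empty near the tissue boundary; callers must handle that.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0 < alpha <= 2 * np.pi + 1e-12):
        raise ValueError(f"alpha must be in (0, 2*pi], got {alpha}")
    return np.flatnonzero(_sector_mask(grid, center, m, alpha)).astype(np.int32)


def central_disk(grid: SiteGrid, rho: float) -> np.ndarray:
    """All corneal sites with r <= rho (uncoupled-model removal region)."""
    if not (1 <= rho <= grid.R):
        raise ValueError(f"rho must satisfy 1 <= rho <= R={grid.R}, got {rho}")
    return np.flatnonzero((grid.region == CORNEA) & (grid.r <= rho)).astype(np.int32)


def distance_to_segment(px: float, py: float, ax: float, ay: float,
                        bx: float, by: float) -> float:
    """Euclidean distance from point p to the closed segment ab.

    Degenerate segments (a == b) fall back to the point distance.
    """
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    if L2 == 0.0:
        return float(np.hypot(px - ax, py - ay))
    t = ((px - ax) * vx + (py - ay) * vy) / L2
    t = min(1.0, max(0.0, t))
    return float(np.hypot(px - (ax + t * vx), py - (ay + t * vy)))


def sector_table(grid: SiteGrid, m: float, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Precompute per-site removal-sector candidates in CSR form.

    Used by the event kernel so a removal draw is a single uniform index.
    Rows may be empty (boundary-clipped sectors); the engine falls back to
    the full m-disk there.
    """
    # Candidate offsets within the m-disk, precomputed once; per-site work is
    # then O(m^2) rather than O(n_sites).
    mi = int(np.floor(m))
    ox, oy = np.meshgrid(np.arange(-mi, mi + 1), np.arange(-mi, mi + 1),
                         indexing="ij")
    keep = (ox * ox + oy * oy > 0) & (ox * ox + oy * oy <= m * m)
    ox, oy = ox[keep].astype(np.int64), oy[keep].astype(np.int64)
    od = np.sqrt((ox * ox + oy * oy).astype(np.float64))
    cos_half = np.cos(alpha / 2) - 1e-12
    off = grid.index_map.shape[0] // 2

    indptr = np.zeros(grid.n_sites + 1, dtype=np.int64)
    chunks = []
    total = 0
    for i in range(grid.n_sites):
        xi, yi = int(grid.x[i]), int(grid.y[i])
        xs, ys = xi + ox, yi + oy
        inb = (np.abs(xs) <= off) & (np.abs(ys) <= off)
        ids = np.full(ox.size, -1, dtype=np.int32)
        ids[inb] = grid.index_map[xs[inb] + off, ys[inb] + off]
        ok = (ids >= 0)
        ok[ok] = grid.region[ids[ok]] == CORNEA
        rc = grid.r[i]
        if rc >= 0.5 and alpha < 2 * np.pi:
            cosang = (ox * (-xi) + oy * (-yi)) / (od * rc)
            ok &= cosang >= cos_half
        sel = ids[ok]
        chunks.append(sel)
        total += sel.size
        indptr[i + 1] = total
    return indptr, (np.concatenate(chunks).astype(np.int32) if total
                    else np.empty(0, np.int32))
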