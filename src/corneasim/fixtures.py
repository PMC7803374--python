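"""Deterministic synthetic clone patterns and tiny grids for testing.

These generators make every statistic checkable against hand-countable
values without running long simulations: perfect angular stripes, contiguous
patches, salt-and-pepper noise, and a labeled annulus front of known depth.
Fixtures are byte-identical given the same (spec, seed).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .engine import P_CORNEAL, S_CELL, TissueState
from .geometry import CORNEA, LIMBUS, SiteGrid, build_tissue

STRIPES = "stripes"
PATCHES = "patches"
SALT_PEPPER = "salt_pepper"
ANNULUS_FRONT = "annulus_front"


@dataclass
class PatternSpec:
    kind: str
    n_clones: int = 8
    depth: float = 5.0  # labeled depth for ANNULUS_FRONT, cells from limbus
    seed: int = 0

    def __post_init__(self):
        if self.kind not in (STRIPES, PATCHES, SALT_PEPPER, ANNULUS_FRONT):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


def tiny_grid(R_total: float = 4, limbal_width: float = 1.0) -> SiteGrid:
    """Small disk grid for exhaustive-enumeration oracles (R_total <= 8)."""
    if R_total > 8:
        raise ValueError("tiny_grid is for R_total <= 8")
    return build_tissue(R_total, limbal_width)


def _base_state(grid: SiteGrid) -> TissueState:
    n = grid.n_sites
    cell_type = np.full(n, P_CORNEAL, dtype=np.uint8)
    cell_type[grid.limbal_sites] = S_CELL
    return TissueState(grid, cell_type, np.full(n, -1, dtype=np.int32),
                       np.zeros(n, dtype=np.int32), np.zeros(n))


def make_pattern(grid: SiteGrid, spec: PatternSpec) -> TissueState:
    """Build a labeled TissueState realizing the requested pattern.

    STRIPES: each clone occupies one contiguous angular wedge over all
    radii (a perfect centripetal stripe pattern; unmixing = 1 everywhere).
    PATCHES: contiguous connected blobs grown breadth-first from random
    seed sites. SALT_PEPPER: labels assigned independently per site.
    ANNULUS_FRONT: stripes labeled only within ``depth`` of the limbus.
    """
    state = _base_state(grid)
    cs = grid.corneal_sites
    if spec.n_clones > cs.size:
        raise ValueError(f"n_clones={spec.n_clones} exceeds corneal "
                         f"site count {cs.size}")
    rng = np.random.default_rng(spec.seed)
    wedge = np.floor(grid.theta / (2 * np.pi) * spec.n_clones).astype(np.int32)
    wedge = np.minimum(wedge, spec.n_clones - 1)

    if spec.kind == STRIPES:
        state.clone[:] = wedge
    elif spec.kind == ANNULUS_FRONT:
        depth = grid.R - grid.r
        sel = (grid.region == CORNEA) & (depth < spec.depth)
        state.clone[sel] = wedge[sel]
        state.clone[grid.limbal_sites] = wedge[grid.limbal_sites]
    elif spec.kind == SALT_PEPPER:
        state.clone[cs] = rng.integers(0, spec.n_clones, size=cs.size)
        state.clone[grid.limbal_sites] = wedge[grid.limbal_sites]
    elif spec.kind == PATCHES:
        seeds = rng.choice(cs, size=spec.n_clones, replace=False)
        labels = np.full(grid.n_sites, -1, dtype=np.int32)
        q = deque()
        for c, s in enumerate(seeds):
            labels[s] = c
            q.append(s)
        while q:  # breadth-first growth guarantees contiguity per clone
            i = q.popleft()
            nbrs = grid.neighbors(i)
            nbrs = nbrs[rng.permutation(nbrs.size)]
            for j in nbrs:
                if labels[j] < 0 and grid.region[j] == CORNEA:
                    labels[j] = labels[i]
                    q.append(j)
        state.clone[cs] = labels[cs]
        state.clone[grid.limbal_sites] = wedge[grid.limbal_sites]
    return state


def line_grid(n: int) -> SiteGrid:
    """A 1 x n strip of corneal sites (displacement-chain oracle geometry).

    Sites sit at (0,0)..(n-1,0) with nearest-neighbor adjacency; distances
    to the tissue 'center' are measured from site 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    x = np.arange(n, dtype=np.int32)
    y = np.zeros(n, dtype=np.int32)
    r = x.astype(float)
    theta = np.zeros(n)
    region = np.zeros(n, dtype=np.uint8)
    indptr = np.zeros(n + 1, dtype=np.int32)
    idx = []
    for i in range(n):
        if i > 0:
            idx.append(i - 1)
        if i < n - 1:
            idx.append(i + 1)
        indptr[i + 1] = len(idx)
    index_map = np.full((2 * n + 1, 2 * n + 1), -1, dtype=np.int32)
    index_map[x + n, y + n] = np.arange(n, dtype=np.int32)
    return SiteGrid(R_total=float(n), limbal_width=0.0, x=x, y=y, r=r,
                    theta=theta, region=region, nbr_indptr=indptr,
                    nbr_indices=np.asarray(idx, dtype=np.int32),
                    index_map=index_map,
                    corneal_sites=np.arange(n, dtype=np.int32),
                    limbal_sites=np.empty(0, dtype=np.int32))
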