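"""Observables of simulated clone patterns.

Everything here consumes a :class:`~corneasim.engine.TissueState` or
:class:`~corneasim.engine.Trajectory` and produces the quantities used to
characterize corneal renewal: renewed fraction, renewal time, front depth,
the clonal unmixing order parameter (1 for perfect centripetal stripes,
decaying toward 0 for angularly mixed labels), the post-mitotic radial
profile, clone counts/sizes, time-averaged occupancy, and the minimal
replicative lifespan that still permits full renewal.

Radial coordinates are expressed as *depth from the limbus* in cell units
(depth = R - r), matching how the profiles are usually plotted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import (EQUIPOTENT, LIMBUS, CORNEA, ModelConfig, S_CELL,
                     TissueState, Trajectory, run)


@dataclass
class RadialProfile:
    """Per-bin value along depth-from-limbus. Bins partition [0, R]."""

    edges: np.ndarray   # length n_bins + 1, in cells from the limbus inward
    values: np.ndarray  # per-bin value (NaN where undefined)
    counts: np.ndarray  # per-bin sample count

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_lo": self.edges[:-1],
                             "depth_hi": self.edges[1:],
                             "value": self.values, "count": self.counts})


def _depth(state: TissueState) -> np.ndarray:
    return state.grid.R - state.grid.r


def renewed_fraction(state: TissueState) -> float:
    """Fraction of corneal sites holding a labeled (limbus-derived) cell."""
    cs = state.grid.corneal_sites
    return float(np.mean(state.clone[cs] >= 0))


def front_depth(state: TissueState, n_sectors: int = 64) -> float:
    """Mean over angular sectors of the contiguous labeled depth.

    Within each sector, depth rings (1-cell annuli) are walked inward from
    the limbus; the front is the number of consecutive occupied rings that
    contain at least one labeled site. 0 for an unlabeled cornea, R when
    fully renewed.
    """
    g = state.grid
    cs = g.corneal_sites
    ring = np.floor(_depth(state)[cs]).astype(int)
    sector = np.floor(g.theta[cs] / (2 * np.pi) * n_sectors).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)
    labeled = state.clone[cs] >= 0
    n_rings = int(np.floor(g.R)) + 1
    has_site = np.zeros((n_sectors, n_rings), dtype=bool)
    has_label = np.zeros((n_sectors, n_rings), dtype=bool)
    np.logical_or.at(has_site, (sector, ring), True)
    np.logical_or.at(has_label, (sector, ring), labeled)
    depths = np.empty(n_sectors)
    for s in range(n_sectors):
        d = 0
        for k in range(n_rings):
            if not has_site[s, k]:
                continue  # no lattice site of this sector on this ring
            if has_label[s, k]:
                d = k + 1
            else:
                break
        else:
            d = n_rings  # labeled all the way in (narrow sectors lack
            #              central sites; a clear run counts as full depth)
        depths[s] = min(d, g.R)
    return float(depths.mean())


def renewal_time(trajectory: Trajectory) -> float:
    """Normalized time of first full renewal; NaN for a stalled run."""
    if not math.isnan(trajectory.renewal_tau):
        return trajectory.renewal_tau
    full = np.flatnonzero(trajectory.renewed_frac >= 1.0)
    if full.size:
        return float(trajectory.taus[full[0]])
    return math.nan


def _annulus_unmixing(clones: np.ndarray, thetas: np.ndarray) -> float:
    """Unmixing of one annulus: (#distinct clones) / (#circular runs)."""
    order = np.argsort(thetas, kind="stable")
    lab = clones[order]
    n = lab.size
    runs = int(np.sum(lab != np.roll(lab, 1)))
    if runs == 0:
        runs = 1  # a single clone all around: one run
    return len(np.unique(lab)) / runs


def unmixing(state: TissueState, band: tuple[float, float],
             min_labeled: int = 8) -> float:
    """Clonal unmixing order parameter within a depth band.

    For each 1-cell annulus in ``band`` (depths from the limbus), labeled
    sites are ordered by angle and the statistic
    (#distinct clones) / (#circular runs of equal labels) is computed; the
    result is the average over annuli. 1 means perfect contiguous angular
    stripes; values decay toward 0 as labels mix. Annuli with fewer than
    ``min_labeled`` labeled sites are skipped; NaN if none qualify.
    """
    d0, d1 = band
    g = state.grid
    cs = g.corneal_sites
    depth = _depth(state)[cs]
    labeled = state.clone[cs] >= 0
    vals = []
    for k in range(int(np.floor(d0)), int(np.ceil(d1))):
        sel = (depth >= k) & (depth < k + 1) & labeled
        if np.sum(sel) < min_labeled:
            continue
        vals.append(_annulus_unmixing(state.clone[cs][sel],
                                      g.theta[cs][sel]))
    return float(np.mean(vals)) if vals else math.nan


def unmixing_profile(state: TissueState, bin_width: float = 5.0,
                     min_labeled: int = 8) -> RadialProfile:
    """Unmixing per radial bin of width ``bin_width`` cells from the limbus."""
    R = state.grid.R
    edges = np.arange(0, R + bin_width, bin_width)
    edges[-1] = max(edges[-1], R)
    vals, cnts = [], []
    depth = _depth(state)[state.grid.corneal_sites]
    labeled = state.clone[state.grid.corneal_sites] >= 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        vals.append(unmixing(state, (lo, hi), min_labeled=min_labeled))
        cnts.append(int(np.sum((depth >= lo) & (depth < hi) & labeled)))
    return RadialProfile(edges, np.asarray(vals), np.asarray(cnts))


def post_mitotic_profile(state: TissueState, config: ModelConfig,
                         bin_width: float = 5.0) -> RadialProfile:
    """Fraction of corneal cells that exhausted their lifespan, per bin."""
    rls = config.rls_effective
    g = state.grid
    cs = g.corneal_sites
    depth = _depth(state)[cs]
    post = state.divisions[cs] >= rls
    edges = np.arange(0, g.R + bin_width, bin_width)
    edges[-1] = max(edges[-1], g.R)
    vals = np.full(edges.size - 1, np.nan)
    cnts = np.zeros(edges.size - 1, dtype=int)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (depth >= lo) & (depth < hi)
        cnts[i] = int(sel.sum())
        if cnts[i]:
            vals[i] = float(np.mean(post[sel]))
    return RadialProfile(edges, vals, cnts)


def clone_table(state: TissueState) -> pd.DataFrame:
    """Per-clone sizes split by region (labeled cells only)."""
    g = state.grid
    rows = []
    for region, name in ((LIMBUS, "LIMBUS"), (CORNEA, "CORNEA")):
        sites = np.flatnonzero(g.region == region)
        lab = state.clone[sites]
        ids, sizes = np.unique(lab[lab >= 0], return_counts=True)
        rows.append(pd.DataFrame({"clone": ids, "region": name,
                                  "size": sizes}))
    return pd.concat(rows, ignore_index=True)


def _snapshot_states(trajectory: Trajectory) -> list[tuple[float, np.ndarray]]:
    if trajectory.snapshots is None:
        raise ValueError("trajectory was run without record_snapshots=True")
    return [(tau, clone) for tau, clone, _div, _ct in trajectory.snapshots]


def clone_counts(trajectory: Trajectory, region: str = "CORNEA") -> pd.DataFrame:
    """Number of distinct clone labels in the region at each checkpoint."""
    g = trajectory.final_state.grid
    code = LIMBUS if region.upper() == "LIMBUS" else CORNEA
    sites = np.flatnonzero(g.region == code)
    rows = []
    for tau, clone in _snapshot_states(trajectory):
        lab = clone[sites]
        rows.append((tau, int(np.unique(lab[lab >= 0]).size)))
    return pd.DataFrame(rows, columns=["tau", "n_clones"])


@dataclass
class CloneSizeStats:
    """Clone-size histograms and the late-time scale-invariance check."""

    taus: np.ndarray
    mean_sizes: np.ndarray
    scaled_sizes: list[np.ndarray]  # per-checkpoint n / <n>
    ks_statistic: float             # two-sample KS between last two checkpoints
    ks_pvalue: float


def clone_size_stats(trajectory: Trajectory,
                     region: str = "LIMBUS") -> CloneSizeStats:
    """Per-checkpoint clone sizes rescaled by their mean (n / <n>).

    Neutral-drift clone dynamics predict that the rescaled size
    distribution is time-invariant; the two-sample Kolmogorov-Smirnov
    distance between the last two checkpoints quantifies that.
    """
    g = trajectory.final_state.grid
    code = LIMBUS if region.upper() == "LIMBUS" else CORNEA
    sites = np.flatnonzero(g.region == code)
    taus, means, scaled = [], [], []
    for tau, clone in _snapshot_states(trajectory):
        lab = clone[sites]
        _, sizes = np.unique(lab[lab >= 0], return_counts=True)
        if sizes.size == 0:
            continue
        taus.append(tau)
        means.append(sizes.mean())
        scaled.append(sizes / sizes.mean())
    if len(scaled) < 2:
        raise ValueError("need at least two checkpoints with clones")
    ks = sps.ks_2samp(scaled[-1], scaled[-2])
    return CloneSizeStats(np.asarray(taus), np.asarray(means), scaled,
                          float(ks.statistic), float(ks.pvalue))


def time_average_map(trajectory: Trajectory,
                     window: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Modal clone label per site over the trailing time window.

    Returns (modal_label, modal_frequency, n_snapshots_used). Raises if the
    window is longer than the recorded trajectory.
    """
    snaps = _snapshot_states(trajectory)
    if not snaps:
        raise ValueError("no snapshots recorded")
    tau_end = snaps[-1][0]
    span = tau_end - snaps[0][0]
    if window > span and len(snaps) > 1:
        raise ValueError(f"window {window} exceeds trajectory span {span}")
    sel = [c for tau, c in snaps if tau >= tau_end - window - 1e-9]
    stack = np.stack(sel)
    mode = sps.mode(stack, axis=0, keepdims=False)
    freq = mode.count / stack.shape[0]
    return mode.mode.astype(np.int32), freq, stack.shape[0]


def find_min_rls(config: ModelConfig, rls_range: tuple[int, int],
                 seeds: Sequence[int] = (1, 2, 3),
                 tau_max: Optional[float] = None, tables=None,
                 require: int = 2) -> int:
    """Smallest RLS in range for which >= ``require`` of the seeded runs
    achieve full renewal (no stall), found by bisection.

    Raises ``ValueError`` with diagnostics if the range does not bracket
    the renewal transition.
    """
    from .engine import build_tables

    tb = tables if tables is not None else build_tables(config)

    def renews(rls: int) -> bool:
        ok = 0
        for s in seeds:
            cfg = _dc_replace(config, rls=rls, seed=s)
            tr = run(cfg, stop="renewal", tau_max=tau_max, tables=tb)
            ok += tr.stop_reason == "full_renewal"
            if ok >= require:
                return True
            if ok + (len(seeds) - list(seeds).index(s) - 1) < require:
                return False
        return ok >= require

    lo, hi = int(rls_range[0]), int(rls_range[1])
    if renews(lo):
        raise ValueError(f"range does not bracket: RLS={lo} already renews")
    if not renews(hi):
        raise ValueError(f"range does not bracket: RLS={hi} fails to renew")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if renews(mid):
            hi = mid
        else:
            lo = mid
    return hi
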