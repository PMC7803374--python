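"""Stochastic event loop for corneal homeostasis.

The model: a fixed disk lattice (see :mod:`corneasim.geometry`) is always
fully occupied. In each Monte-Carlo event a dividing cell is drawn with
probability proportional to its division rate (lambda_s for stem cells,
lambda_p for progenitors that have not exhausted their replicative lifespan),
a removed cell is drawn according to the model class (coupled: uniform over
an inward-facing sector of radius m around the divider; uncoupled: uniform
over a central disk of radius rho, independent of the divider), the tissue
relaxes along the division->removal vector by a hole-pulling chain, and the
clock advances by the mean-field Gillespie increment 1/(total rate).

Lineage labels: at t=0 only limbal stem cells carry (distinct) clone labels;
corneal tissue starts unlabeled. A corneal site is "renewed" once it holds a
labeled (limbus-derived) cell; full renewal is 100% of corneal sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as K
from .geometry import (CORNEA, LIMBUS, SiteGrid, build_tissue, central_disk,
                       sector_table)

RLS_INF = 2**31 - 1  # sentinel for unlimited replicative lifespan

COUPLED = "coupled"
UNCOUPLED = "uncoupled"
EQUIPOTENT = "equipotent"
HIERARCHICAL = "hierarchical"

S_CELL = K.S_CELL
P_LIMBAL = K.P_LIMBAL
P_CORNEAL = K.P_CORNEAL


@dataclass
class ModelConfig:
    """All model parameters, with validation.

    Parameters
    ----------
    model_class : "coupled" or "uncoupled" replication-removal.
    alpha : sector angle in radians (coupled bias; bias = 1 - alpha/2pi).
    rho : central-disk radius in cells (uncoupled bias; None or R = no bias).
    m : local interaction radius in cells (coupled model).
    rls : replicative lifespan — max divisions along a progenitor lineage;
        None means unlimited.
    lambda_s, lambda_p : stem / progenitor division rates (per day).
    a : fraction of stem divisions that are asymmetric (equipotent model).
    stem_model : "equipotent" (every limbal cell is a stem cell) or
        "hierarchical" (a stem_fraction subset, never displaced).
    stem_fraction : fraction of limbal sites that are stem cells
        (forced to 1 for the equipotent model).
    R_total, limbal_width : tissue radius and limbal annulus width (cells).
    seed : RNG seed for the run.
    sigma : width (cells) of the displacement-chain Gaussian kernel.
    checkpoint_interval : trajectory checkpoint spacing, in normalized
        replication times (t * lambda_p).
    stall_window : normalized-time window with no renewed-fraction
        improvement after which the front is declared stalled.
    """

    model_class: str = COUPLED
    alpha: float = math.pi / 6  # headline model: strong centripetal bias
    rho: Optional[float] = None
    m: float = 5.0
    rls: Optional[int] = 60
    lambda_s: float = 1.0 / 7.0
    lambda_p: float = 1.0 / 3.0
    a: float = 0.2
    stem_model: str = EQUIPOTENT
    stem_fraction: float = 1.0
    R_total: float = 101.0
    limbal_width: float = 1.0
    seed: int = 1
    sigma: float = 1.0
    checkpoint_interval: float = 1.0
    stall_window: float = 20.0

    def __post_init__(self):
        if self.model_class not in (COUPLED, UNCOUPLED):
            raise ValueError(f"unknown model_class {self.model_class!r}")
        if self.stem_model not in (EQUIPOTENT, HIERARCHICAL):
            raise ValueError(f"unknown stem_model {self.stem_model!r}")
        if self.R_total < 2:
            raise ValueError(f"R_total must be >= 2, got {self.R_total}")
        if not (1 <= self.limbal_width < self.R_total):
            raise ValueError("limbal_width must be in [1, R_total)")
        if not (0 < self.alpha <= 2 * math.pi + 1e-12):
            raise ValueError(f"alpha must be in (0, 2*pi], got {self.alpha}")
        R = self.R_total - self.limbal_width
        if self.rho is not None and not (1 <= self.rho <= R):
            raise ValueError(f"rho must be in [1, R={R}], got {self.rho}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.rls is not None and self.rls < 0:
            raise ValueError(f"rls must be >= 0, got {self.rls}")
        if self.lambda_s <= 0 or self.lambda_p <= 0:
            raise ValueError("division rates must be positive")
        if not (0 <= self.a <= 1):
            raise ValueError(f"a must be in [0, 1], got {self.a}")
        if not (0 < self.stem_fraction <= 1):
            raise ValueError("stem_fraction must be in (0, 1]")
        if self.stem_model == EQUIPOTENT:
            self.stem_fraction = 1.0
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def R(self) -> float:
        """Corneal radius in cells."""
        return self.R_total - self.limbal_width

    @property
    def bias(self) -> float:
        """Centripetal bias of the coupled model, 1 - alpha/2pi."""
        return 1.0 - self.alpha / (2 * math.pi)

    @property
    def rls_effective(self) -> int:
        return RLS_INF if self.rls is None else int(self.rls)

    @property
    def rho_effective(self) -> float:
        return self.R if self.rho is None else float(self.rho)


@dataclass
class TissueState:
    """Mutable simulation state: the lattice plus one cell record per site."""

    grid: SiteGrid
    cell_type: np.ndarray   # uint8, codes S_CELL / P_LIMBAL / P_CORNEAL
    clone: np.ndarray       # int32, -1 = unlabeled
    divisions: np.ndarray   # int32 lineage depth
    birth_time: np.ndarray  # float64
    t: float = 0.0
    event_count: int = 0

    def copy(self) -> "TissueState":
        return TissueState(self.grid, self.cell_type.copy(), self.clone.copy(),
                           self.divisions.copy(), self.birth_time.copy(),
                           self.t, self.event_count)

    def n_competent(self, rls: int) -> int:
        """Number of progenitors that can still divide."""
        return int(np.sum((self.cell_type != S_CELL) & (self.divisions < rls)))

    def renewed_count(self) -> int:
        return int(np.sum(self.clone[self.grid.corneal_sites] >= 0))


@dataclass
class Trajectory:
    """Checkpointed observables of a single run plus its final state."""

    config: ModelConfig
    seed: int
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    taus: np.ndarray = field(default_factory=lambda: np.empty(0))
    renewed_frac: np.ndarray = field(default_factory=lambda: np.empty(0))
    stop_reason: str = ""
    stalled: bool = False
    renewal_tau: float = math.nan  # normalized time of first full renewal
    events: Optional[dict] = None
    snapshots: Optional[list] = None  # list of (tau, clone, divisions, type)
    final_state: Optional[TissueState] = None


@dataclass
class RunTables:
    """Precomputed per-config lookup tables for the event kernel."""

    grid: SiteGrid
    sec_indptr: np.ndarray
    sec_indices: np.ndarray
    dsk_indptr: np.ndarray
    dsk_indices: np.ndarray
    cdisk: np.ndarray
    limb_nbr_indptr: np.ndarray
    limb_nbr_indices: np.ndarray


def build_tables(config: ModelConfig, grid: Optional[SiteGrid] = None) -> RunTables:
    grid = grid if grid is not None else build_tissue(config.R_total,
                                                      config.limbal_width)
    dsk_indptr, dsk_indices = sector_table(grid, config.m, 2 * math.pi)
    if config.model_class == COUPLED and config.alpha < 2 * math.pi:
        sec_indptr, sec_indices = sector_table(grid, config.m, config.alpha)
    else:
        sec_indptr, sec_indices = dsk_indptr, dsk_indices
    cdisk = central_disk(grid, config.rho_effective)
    # per-site limbal-neighbor CSR (rows non-empty only for limbal sites)
    indptr = np.zeros(grid.n_sites + 1, dtype=np.int64)
    idx = []
    for i in range(grid.n_sites):
        if grid.region[i] == LIMBUS:
            for j in grid.neighbors(i):
                if grid.region[j] == LIMBUS:
                    idx.append(j)
        indptr[i + 1] = len(idx)
    return RunTables(grid, sec_indptr, sec_indices, dsk_indptr, dsk_indices,
                     cdisk, indptr, np.asarray(idx, dtype=np.int32))


def init_state(config: ModelConfig, grid: Optional[SiteGrid] = None) -> TissueState:
    """Initial tissue: labeled stem cells in the limbus, unlabeled cornea.

    Equipotent: every limbal site holds an S cell with a distinct clone
    label. Hierarchical: a stem_fraction subset of limbal sites (chosen by
    the config seed) holds S cells; the rest hold unlabeled limbal
    progenitors. Corneal sites hold unlabeled progenitors with zero
    lineage depth.
    """
    grid = grid if grid is not None else build_tissue(config.R_total,
                                                      config.limbal_width)
    n = grid.n_sites
    cell_type = np.full(n, P_CORNEAL, dtype=np.uint8)
    clone = np.full(n, -1, dtype=np.int32)
    divisions = np.zeros(n, dtype=np.int32)
    birth_time = np.zeros(n, dtype=np.float64)

    limbal = grid.limbal_sites
    if config.stem_model == EQUIPOTENT:
        s_sites = limbal
    else:
        rng = np.random.default_rng(config.seed)
        n_s = max(1, int(round(config.stem_fraction * limbal.size)))
        s_sites = rng.choice(limbal, size=n_s, replace=False)
        cell_type[limbal] = P_LIMBAL
    cell_type[s_sites] = S_CELL
    clone[np.sort(s_sites)] = np.arange(len(s_sites), dtype=np.int32)
    return TissueState(grid, cell_type, clone, divisions, birth_time)


def _stem_sites(state: TissueState) -> np.ndarray:
    return np.flatnonzero(state.cell_type == S_CELL).astype(np.int32)


def _p_candidates(state: TissueState) -> np.ndarray:
    """Sites that can hold progenitors (everything except stem sites)."""
    return np.flatnonzero(state.cell_type != S_CELL).astype(np.int32)


def normalized_time(t_or_obj, lambda_p: Optional[float] = None) -> float:
    """Time in units of corneal progenitor doubling times, t * lambda_p."""
    if isinstance(t_or_obj, TissueState):
        if lambda_p is None:
            raise ValueError("lambda_p required with a TissueState")
        return t_or_obj.t * lambda_p
    return float(t_or_obj) * float(lambda_p)


def _seed_from(rng) -> int:
    if rng is None:
        return 0
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31 - 1)
    return int(rng.integers(0, 2**31 - 1))


def select_division(state: TissueState, config: ModelConfig, rng=None) -> int:
    """Single division draw (testing surface over the kernel)."""
    if rng is not None:
        K.seed_rng(_seed_from(rng))
    rls = config.rls_effective
    site = K.select_division(state.cell_type, state.divisions, rls,
                             _stem_sites(state), _p_candidates(state),
                             state.n_competent(rls),
                             config.lambda_s, config.lambda_p)
    if site < 0:
        raise RuntimeError("no mitotically competent cell (renewal failure)")
    return int(site)


def select_removal(state: TissueState, div_site: int, config: ModelConfig,
                   rng=None, tables: Optional[RunTables] = None) -> int:
    """Single removal draw per model class (testing surface)."""
    if rng is not None:
        K.seed_rng(_seed_from(rng))
    tb = tables if tables is not None else build_tables(config, state.grid)
    site, _ = K.select_removal(div_site, config.model_class == COUPLED,
                               tb.sec_indptr, tb.sec_indices, tb.dsk_indptr,
                               tb.dsk_indices, tb.cdisk,
                               state.grid.corneal_sites)
    if site < 0:
        raise RuntimeError("empty removal candidate set")
    return int(site)


def apply_division(state: TissueState, div_site: int, rem_site: int,
                   config: ModelConfig, rng=None) -> TissueState:
    """Apply one replication-removal event in place and return the state.

    The case is inferred from the cells involved: limbal-to-limbal events
    are stem-ring replacements; otherwise the removed corneal cell is
    deleted, the tissue relaxes along the division->removal segment, and the
    daughter is placed next to the divider.
    """
    if div_site == rem_site:
        raise ValueError("division and removal sites must differ")
    g = state.grid
    rls = config.rls_effective
    ct = state.cell_type
    if ct[div_site] != S_CELL and state.divisions[div_site] >= rls:
        raise ValueError("post-mitotic cell selected for division")
    if rng is not None:
        K.seed_rng(_seed_from(rng))
    t = state.t
    if g.region[rem_site] == LIMBUS:
        if ct[div_site] != S_CELL:
            raise ValueError("only stem divisions may replace limbal cells")
        if ct[rem_site] == S_CELL and config.stem_model == HIERARCHICAL:
            raise ValueError("hierarchical stem cells are never removable")
        new_type = S_CELL if config.stem_model == EQUIPOTENT else P_LIMBAL
        ct[rem_site] = new_type
        state.clone[rem_site] = state.clone[div_site]
        state.divisions[rem_site] = 0
        state.birth_time[rem_site] = t
    else:
        hole = K.relax_chain(g.x, g.y, g.region, g.nbr_indptr, g.nbr_indices,
                             ct, state.clone, state.divisions,
                             state.birth_time, div_site, rem_site,
                             config.sigma)
        if ct[div_site] == S_CELL:
            d = 0
        else:
            d = int(state.divisions[div_site]) + 1
            state.divisions[div_site] = d
        ct[hole] = P_CORNEAL
        state.clone[hole] = state.clone[div_site]
        state.divisions[hole] = d
        state.birth_time[hole] = t
    n_s = int(np.sum(ct == S_CELL))
    total = n_s * config.lambda_s + state.n_competent(rls) * config.lambda_p
    state.t += 1.0 / total if total > 0 else 0.0
    state.event_count += 1
    return state


def run(config: ModelConfig, stop: str = "renewal",
        tau_max: Optional[float] = None, record_events: bool = False,
        record_snapshots: bool = False, snapshot_interval: Optional[float] = None,
        tables: Optional[RunTables] = None) -> Trajectory:
    """Run a full simulation; reproducible given ``config.seed``.

    ``stop``: "renewal" (stop at 100% labeled cornea, or on front stall),
    "stall" (run to the stalled steady state, or renewal), or "time" (run to
    ``tau_max`` normalized replication times). ``tau_max`` always acts as a
    safety cap (default 20000). A trajectory that stops because the renewed
    fraction made no progress for ``config.stall_window`` normalized times
    is flagged ``stalled`` rather than raising.
    """
    if stop not in ("renewal", "stall", "time"):
        raise ValueError(f"unknown stop condition {stop!r}")
    if stop == "time" and tau_max is None:
        raise ValueError("stop='time' requires tau_max")
    cap = 20000.0 if tau_max is None else float(tau_max)

    tb = tables if tables is not None else build_tables(config)
    state = init_state(config, tb.grid)
    g = tb.grid
    rls = config.rls_effective
    lam_s, lam_p = config.lambda_s, config.lambda_p
    coupled = config.model_class == COUPLED
    equip = config.stem_model == EQUIPOTENT
    s_sites = _stem_sites(state)
    p_cands = _p_candidates(state)
    n_cornea = g.corneal_sites.size
    n_comp = state.n_competent(rls)
    renewed = 0

    K.seed_rng(int(config.seed) % (2**31 - 1))

    taus = [0.0]
    times = [0.0]
    renew = [0.0]
    ev_div, ev_rem, ev_t = [], [], []
    snaps = None
    if record_snapshots:
        snaps = [(0.0, state.clone.copy(), state.divisions.copy(),
                  state.cell_type.copy())]
    snap_dt = (snapshot_interval if snapshot_interval is not None
               else config.checkpoint_interval)
    next_snap = snap_dt

    t = 0.0
    event_count = 0
    best = 0
    last_improve = 0.0
    next_tau = config.checkpoint_interval
    # fixed-time runs continue past full renewal (late-time clone drift)
    renewal_target = n_cornea if stop != "time" else n_cornea + 1
    stop_reason = ""
    stalled = False
    renewal_tau = math.nan

    # recording buffers sized to the expected events per chunk
    empty = np.empty(0, dtype=np.int32)
    empty_t = np.empty(0, dtype=np.float64)

    while True:
        tau_target = min(next_tau, cap)
        t_end = tau_target / lam_p
        if record_events:
            n_s = s_sites.size
            est = int(1.5 * (n_s * lam_s + n_comp * lam_p) * max(t_end - t, 0)
                      ) + 1024
            rdiv = np.empty(est, dtype=np.int32)
            rrem = np.empty(est, dtype=np.int32)
            rt = np.empty(est, dtype=np.float64)
            max_events = est
        else:
            rdiv, rrem, rt = empty, empty, empty_t
            max_events = 2**62
        t, event_count, n_comp, renewed, nrec, reason = K.run_chunk(
            g.x, g.y, g.region, g.nbr_indptr, g.nbr_indices,
            tb.limb_nbr_indptr, tb.limb_nbr_indices,
            tb.sec_indptr, tb.sec_indices, tb.dsk_indptr, tb.dsk_indices,
            tb.cdisk, g.corneal_sites, s_sites, p_cands,
            state.cell_type, state.clone, state.divisions, state.birth_time,
            coupled, equip, rls, lam_s, lam_p, config.a, config.sigma,
            t, event_count, n_comp, renewed,
            t_end, renewal_target, max_events,
            rdiv, rrem, rt)
        if record_events and nrec:
            ev_div.append(rdiv[:nrec].copy())
            ev_rem.append(rrem[:nrec].copy())
            ev_t.append(rt[:nrec].copy())
        tau_now = t * lam_p

        if reason == K.FULL_RENEWAL:
            renewal_tau = tau_now
            stop_reason = "full_renewal"
        elif reason == K.NO_COMPETENT:
            stop_reason = "no_competent_cells"
            stalled = True
        elif reason == K.INTERNAL_ERROR:
            raise RuntimeError("event kernel failed to draw a removal site")
        elif reason == K.MAX_EVENTS:
            continue  # recording buffer filled mid-chunk; keep going

        if reason == K.REACHED_T_END:
            times.append(t)
            taus.append(tau_now)
            renew.append(renewed / n_cornea)
            if record_snapshots and tau_now >= next_snap - 1e-9:
                snaps.append((tau_now, state.clone.copy(),
                              state.divisions.copy(), state.cell_type.copy()))
                next_snap += snap_dt
            if renewed > best:
                best = renewed
                last_improve = tau_now
            elif stop != "time" and tau_now - last_improve >= config.stall_window:
                stop_reason = "stall"
                stalled = True
            if tau_now >= cap and not stop_reason:
                stop_reason = "tau_max" if stop != "time" else "time"
        else:
            if tau_now > taus[-1]:
                times.append(t)
                taus.append(tau_now)
                renew.append(renewed / n_cornea)
            if record_snapshots:
                snaps.append((tau_now, state.clone.copy(),
                              state.divisions.copy(), state.cell_type.copy()))

        if stop_reason:
            break
        next_tau += config.checkpoint_interval

    state.t = t
    state.event_count = event_count
    events = None
    if record_events:
        events = {
            "div_site": (np.concatenate(ev_div) if ev_div else
                         np.empty(0, np.int32)),
            "rem_site": (np.concatenate(ev_rem) if ev_rem else
                         np.empty(0, np.int32)),
            "t": np.concatenate(ev_t) if ev_t else np.empty(0, np.float64),
        }
    return Trajectory(config=config, seed=config.seed,
                      times=np.asarray(times), taus=np.asarray(taus),
                      renewed_frac=np.asarray(renew), stop_reason=stop_reason,
                      stalled=stalled, renewal_tau=renewal_tau, events=events,
                      snapshots=snaps, final_state=state)
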