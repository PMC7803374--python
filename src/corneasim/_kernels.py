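"""Numba event-loop kernels.

All mutable simulation state lives in flat numpy arrays; these kernels are the
single implementation of the event dynamics (division selection, removal
selection, displacement chain, bookkeeping). The Python wrappers in
``engine`` expose the same operations one event at a time for testing.

Cell type codes: 0 = S (stem), 1 = P_L (limbal progenitor),
2 = P_C (corneal progenitor). Region codes: 0 = cornea, 1 = limbus.
Clone label -1 means unlabeled (pre-existing corneal tissue).
"""

import math

import numpy as np
from numba import njit

S_CELL = 0
P_LIMBAL = 1
P_CORNEAL = 2

# chunk-return reason codes
REACHED_T_END = 0
FULL_RENEWAL = 1
NO_COMPETENT = 2
MAX_EVENTS = 3
INTERNAL_ERROR = 4


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def dist_to_segment(px, py, ax, ay, bx, by):
    vx = bx - ax
    vy = by - ay
    L2 = vx * vx + vy * vy
    if L2 == 0.0:
        return math.hypot(px - ax, py - ay)
    t = ((px - ax) * vx + (py - ay) * vy) / L2
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


@njit(cache=True)
def select_division(cell_type, divisions, rls, s_sites, p_cands, n_comp,
                    lam_s, lam_p):
    """Draw a mitotically competent cell, probability proportional to rate.

    Stem cells carry rate lam_s, competent progenitors (divisions < RLS)
    lam_p; post-mitotic cells are never returned. Returns -1 if no competent
    cell exists.
    """
    n_s = s_sites.size
    total = n_s * lam_s + n_comp * lam_p
    if total <= 0.0:
        return -1
    u = np.random.random() * total
    if u < n_s * lam_s or n_comp == 0:
        if n_s == 0:
            return -1
        return s_sites[np.random.randint(n_s)]
    # rejection-sample a competent progenitor
    for _ in range(2_000_000):
        j = p_cands[np.random.randint(p_cands.size)]
        if cell_type[j] != S_CELL and divisions[j] < rls:
            return j
    # competence is astronomically sparse: exact linear draw
    k = np.random.randint(n_comp)
    cnt = 0
    for idx in range(p_cands.size):
        j = p_cands[idx]
        if cell_type[j] != S_CELL and divisions[j] < rls:
            if cnt == k:
                return j
            cnt += 1
    return -1


@njit(cache=True)
def select_removal(div, coupled, sec_indptr, sec_indices, dsk_indptr,
                   dsk_indices, cdisk, corneal_sites):
    """Draw the removed site for a division at ``div``.

    Coupled: uniform over the precomputed inward sector of ``div``; if the
    sector is empty (clipped by the boundary) fall back to the full m-disk.
    Uncoupled: uniform over the central disk, independent of ``div``.
    Returns (site, fallback_used); site -1 on failure.
    """
    if coupled:
        a = sec_indptr[div]
        b = sec_indptr[div + 1]
        if b > a:
            return sec_indices[a + np.random.randint(b - a)], False
        a = dsk_indptr[div]
        b = dsk_indptr[div + 1]
        if b > a:
            return dsk_indices[a + np.random.randint(b - a)], True
        # degenerate tiny grid: any corneal site other than div
        for _ in range(1000):
            s = corneal_sites[np.random.randint(corneal_sites.size)]
            if s != div:
                return s, True
        return -1, True
    else:
        for _ in range(200):
            s = cdisk[np.random.randint(cdisk.size)]
            if s != div:
                return s, False
        for _ in range(1000):
            s = corneal_sites[np.random.randint(corneal_sites.size)]
            if s != div:
                return s, True
        return -1, True


@njit(cache=True)
def relax_chain(xs, ys, region, nbr_indptr, nbr_indices,
                cell_type, clone, divisions, birth_time,
                div, rem, sigma):
    """Hole-pulling relaxation along the division->removal segment.

    Starting from the vacancy at ``rem``, repeatedly pull in a corneal
    neighbor of the hole that is strictly closer to ``div``, weighted by
    exp(-d^2 / (2 sigma^2)) where d is the neighbor's distance to the
    div->rem segment, until the hole is adjacent to ``div``. Returns the
    final hole site (where the daughter is placed).
    """
    hole = rem
    ax = float(xs[div])
    ay = float(ys[div])
    bx = float(xs[rem])
    by = float(ys[rem])
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    ws = np.empty(8, dtype=np.float64)
    cs = np.empty(8, dtype=np.int64)
    guard = 0
    while max(abs(xs[hole] - xs[div]), abs(ys[hole] - ys[div])) > 1:
        guard += 1
        if guard > 100000:
            break
        dh = math.hypot(float(xs[hole] - xs[div]), float(ys[hole] - ys[div]))
        nc = 0
        wsum = 0.0
        for k in range(nbr_indptr[hole], nbr_indptr[hole + 1]):
            j = nbr_indices[k]
            if j == div or region[j] != 0:
                continue
            dj = math.hypot(float(xs[j] - xs[div]), float(ys[j] - ys[div]))
            if dj >= dh - 1e-12:
                continue
            d = dist_to_segment(float(xs[j]), float(ys[j]), ax, ay, bx, by)
            w = math.exp(-d * d * inv2s2)
            ws[nc] = w
            cs[nc] = j
            wsum += w
            nc += 1
        if nc == 0:
            break  # boundary-pinned hole on a degenerate grid
        u = np.random.random() * wsum
        acc = 0.0
        pick = cs[nc - 1]
        for q in range(nc):
            acc += ws[q]
            if u < acc:
                pick = cs[q]
                break
        # pull the picked cell into the hole
        cell_type[hole] = cell_type[pick]
        clone[hole] = clone[pick]
        divisions[hole] = divisions[pick]
        birth_time[hole] = birth_time[pick]
        hole = pick
    return hole


@njit(cache=True)
def run_chunk(xs, ys, region, nbr_indptr, nbr_indices,
              limb_nbr_indptr, limb_nbr_indices,
              sec_indptr, sec_indices, dsk_indptr, dsk_indices,
              cdisk, corneal_sites, s_sites, p_cands,
              cell_type, clone, divisions, birth_time,
              coupled, equipotent, rls, lam_s, lam_p, a_frac, sigma,
              t, event_count, n_comp, renewed,
              t_end, n_cornea, max_events,
              rec_div, rec_rem, rec_t):
    """Advance the event loop until t_end / full renewal / event cap.

    Returns (t, event_count, n_comp, renewed, n_recorded, reason).
    Event recording is enabled when rec_div.size > 0 (caller must then set
    max_events <= rec_div.size).
    """
    nrec = 0
    n_s = s_sites.size
    events_done = 0
    while True:
        if renewed >= n_cornea:
            return t, event_count, n_comp, renewed, nrec, FULL_RENEWAL
        if t >= t_end:
            return t, event_count, n_comp, renewed, nrec, REACHED_T_END
        if events_done >= max_events:
            return t, event_count, n_comp, renewed, nrec, MAX_EVENTS
        total = n_s * lam_s + n_comp * lam_p
        if total <= 0.0:
            return t, event_count, n_comp, renewed, nrec, NO_COMPETENT

        div = select_division(cell_type, divisions, rls, s_sites, p_cands,
                              n_comp, lam_s, lam_p)
        if div < 0:
            return t, event_count, n_comp, renewed, nrec, NO_COMPETENT

        rem = -1
        ct = cell_type[div]
        if ct == S_CELL:
            if equipotent and np.random.random() >= a_frac:
                # symmetric stem division: neutral drift along the limbal ring
                a0 = limb_nbr_indptr[div]
                b0 = limb_nbr_indptr[div + 1]
                if b0 > a0:
                    tgt = limb_nbr_indices[a0 + np.random.randint(b0 - a0)]
                    cell_type[tgt] = S_CELL
                    clone[tgt] = clone[div]
                    divisions[tgt] = 0
                    birth_time[tgt] = t
                    rem = tgt
            else:
                handled = False
                if not equipotent:
                    # hierarchical asymmetric S: new P_L replaces a non-stem
                    # limbal neighbor (stem cells are never displaced)
                    a0 = limb_nbr_indptr[div]
                    b0 = limb_nbr_indptr[div + 1]
                    ncand = 0
                    for k in range(a0, b0):
                        if cell_type[limb_nbr_indices[k]] != S_CELL:
                            ncand += 1
                    if ncand > 0:
                        pick = np.random.randint(ncand)
                        tgt = -1
                        cnt = 0
                        for k in range(a0, b0):
                            j = limb_nbr_indices[k]
                            if cell_type[j] != S_CELL:
                                if cnt == pick:
                                    tgt = j
                                    break
                                cnt += 1
                        if divisions[tgt] < rls:
                            n_comp -= 1  # replaced competent P_L destroyed
                        cell_type[tgt] = P_LIMBAL
                        clone[tgt] = clone[div]
                        divisions[tgt] = 0
                        birth_time[tgt] = t
                        if rls > 0:
                            n_comp += 1
                        rem = tgt
                        handled = True
                if not handled:
                    # asymmetric S pushing a fresh progenitor into the cornea
                    rem, _ = select_removal(div, coupled, sec_indptr,
                                            sec_indices, dsk_indptr,
                                            dsk_indices, cdisk, corneal_sites)
                    if rem < 0:
                        return t, event_count, n_comp, renewed, nrec, INTERNAL_ERROR
                    removed_labeled = clone[rem] >= 0
                    removed_comp = divisions[rem] < rls
                    hole = relax_chain(xs, ys, region, nbr_indptr, nbr_indices,
                                       cell_type, clone, divisions, birth_time,
                                       div, rem, sigma)
                    cell_type[hole] = P_CORNEAL
                    clone[hole] = clone[div]
                    divisions[hole] = 0
                    birth_time[hole] = t
                    if clone[div] >= 0:
                        renewed += 1
                    if removed_labeled:
                        renewed -= 1
                    if rls > 0:
                        n_comp += 1
                    if removed_comp:
                        n_comp -= 1
        else:
            # progenitor division (P_L toward the cornea, or P_C anywhere)
            rem, _ = select_removal(div, coupled, sec_indptr, sec_indices,
                                    dsk_indptr, dsk_indices, cdisk,
                                    corneal_sites)
            if rem < 0:
                return t, event_count, n_comp, renewed, nrec, INTERNAL_ERROR
            removed_labeled = clone[rem] >= 0
            removed_comp = divisions[rem] < rls
            hole = relax_chain(xs, ys, region, nbr_indptr, nbr_indices,
                               cell_type, clone, divisions, birth_time,
                               div, rem, sigma)
            d = divisions[div] + 1
            divisions[div] = d
            if d >= rls:
                n_comp -= 1  # parent exhausted its lifespan
            cell_type[hole] = P_CORNEAL
            clone[hole] = clone[div]
            divisions[hole] = d
            birth_time[hole] = t
            if clone[div] >= 0:
                renewed += 1
            if removed_labeled:
                renewed -= 1
            if d < rls:
                n_comp += 1
            if removed_comp:
                n_comp -= 1

        t += 1.0 / total
        event_count += 1
        events_done += 1
        if rec_div.size > 0 and nrec < rec_div.size:
            rec_div[nrec] = div
            rec_rem[nrec] = rem
            rec_t[nrec] = t
            nrec += 1
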