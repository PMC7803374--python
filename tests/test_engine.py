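"""Event-loop dynamics: selection distributions, relaxation, invariants."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from corneasim import _kernels as K
from corneasim import engine as E
from corneasim.fixtures import line_grid
from corneasim.geometry import CORNEA, LIMBUS


def recount(state, rls):
    """Independent recount of the kernel's incremental counters."""
    return (state.n_competent(rls), state.renewed_count())


# ---------------------------------------------------------------- config


def test_config_validation():
    with pytest.raises(ValueError):
        E.ModelConfig(alpha=0)
    with pytest.raises(ValueError):
        E.ModelConfig(model_class="uncoupled", rho=200.0)
    with pytest.raises(ValueError):
        E.ModelConfig(a=1.5)
    with pytest.raises(ValueError):
        E.ModelConfig(lambda_p=0)
    with pytest.raises(ValueError):
        E.ModelConfig(stem_model="hierarchical", stem_fraction=0)
    cfg = E.ModelConfig(stem_model="equipotent", stem_fraction=0.3)
    assert cfg.stem_fraction == 1.0  # equipotent forces a full stem limbus
    assert E.ModelConfig(alpha=math.pi).bias == pytest.approx(0.5)


# ------------------------------------------------------------ init_state


def test_init_equipotent_all_limbal_stem(grid31):
    cfg = E.ModelConfig(R_total=31)
    st = E.init_state(cfg, grid31)
    limbal = grid31.limbal_sites
    assert np.all(st.cell_type[limbal] == E.S_CELL)
    labels = st.clone[limbal]
    assert np.unique(labels).size == limbal.size  # distinct clone per stem
    assert np.all(st.clone[grid31.corneal_sites] == -1)
    assert st.renewed_count() == 0


def test_init_hierarchical_stem_fraction(grid31):
    cfg = E.ModelConfig(R_total=31, stem_model="hierarchical",
                        stem_fraction=0.1, seed=5)
    st = E.init_state(cfg, grid31)
    limbal = grid31.limbal_sites
    n_s = int(np.sum(st.cell_type[limbal] == E.S_CELL))
    assert n_s == pytest.approx(0.1 * limbal.size, abs=1)
    assert np.all(st.cell_type[grid31.corneal_sites] == E.P_CORNEAL)
    # only stem cells carry labels at t=0
    assert np.sum(st.clone >= 0) == n_s


# ------------------------------------------------- division selection


def test_select_division_uniform_when_rates_equal(tiny_tables):
    cfg, tb = tiny_tables
    cfg = dataclasses.replace(cfg, lambda_s=cfg.lambda_p, rls=None)
    st = E.init_state(cfg, tb.grid)
    rls = cfg.rls_effective
    s_sites = np.flatnonzero(st.cell_type == E.S_CELL).astype(np.int32)
    p_cands = np.flatnonzero(st.cell_type != E.S_CELL).astype(np.int32)
    n_comp = st.n_competent(rls)
    K.seed_rng(7)
    n_draws = 100_000
    counts = np.zeros(st.grid.n_sites, dtype=int)
    for _ in range(n_draws):
        site = K.select_division(st.cell_type, st.divisions, rls, s_sites,
                                 p_cands, n_comp, cfg.lambda_s, cfg.lambda_p)
        counts[site] += 1
    # chi-square against the exact uniform distribution over all cells
    chi = sps.chisquare(counts)
    assert chi.pvalue > 1e-3


def test_select_division_rate_ratio(tiny_tables):
    cfg, tb = tiny_tables
    # stem cells divide at twice the progenitor rate: odds n_S*2 : n_P
    cfg = dataclasses.replace(cfg, lambda_s=2.0, lambda_p=1.0, rls=None)
    st = E.init_state(cfg, tb.grid)
    rls = cfg.rls_effective
    s_sites = np.flatnonzero(st.cell_type == E.S_CELL).astype(np.int32)
    p_cands = np.flatnonzero(st.cell_type != E.S_CELL).astype(np.int32)
    n_comp = st.n_competent(rls)
    K.seed_rng(11)
    n_draws = 100_000
    s_hits = 0
    for _ in range(n_draws):
        site = K.select_division(st.cell_type, st.divisions, rls, s_sites,
                                 p_cands, n_comp, 2.0, 1.0)
        s_hits += st.cell_type[site] == E.S_CELL
    expect = 2 * s_sites.size / (2 * s_sites.size + n_comp)
    se = math.sqrt(expect * (1 - expect) / n_draws)
    assert abs(s_hits / n_draws - expect) < 5 * se


def test_select_division_skips_post_mitotic(tiny_tables):
    cfg, tb = tiny_tables
    cfg = dataclasses.replace(cfg, rls=1)
    st = E.init_state(cfg, tb.grid)
    st.divisions[st.grid.corneal_sites] = 1  # exhaust every corneal cell
    for seed in range(50):
        site = E.select_division(st, cfg, rng=seed)
        assert st.grid.region[site] == LIMBUS


def test_select_division_no_competent_raises():
    cfg = E.ModelConfig(R_total=4, rls=0, stem_model="hierarchical",
                        stem_fraction=0.5)
    st = E.init_state(cfg)
    st.cell_type[st.cell_type == E.S_CELL] = E.P_LIMBAL  # no stems left
    with pytest.raises(RuntimeError):
        E.select_division(st, cfg, rng=1)


# -------------------------------------------------- removal selection


def test_removal_uniform_over_disk_chi_square(tiny_tables):
    cfg, tb = tiny_tables
    st = E.init_state(cfg, tb.grid)
    g = tb.grid
    div = g.site_at(0, 0)
    expected = set(tb.dsk_indices[tb.dsk_indptr[div]:tb.dsk_indptr[div + 1]])
    K.seed_rng(3)
    counts = {}
    n_draws = 100_000
    for _ in range(n_draws):
        s, fb = K.select_removal(div, True, tb.sec_indptr, tb.sec_indices,
                                 tb.dsk_indptr, tb.dsk_indices, tb.cdisk,
                                 g.corneal_sites)
        assert not fb
        counts[s] = counts.get(s, 0) + 1
    assert set(counts) == expected
    chi = sps.chisquare(list(counts.values()))
    assert chi.pvalue > 1e-3


def test_removal_uncoupled_independent_of_divider(grid8):
    cfg = E.ModelConfig(R_total=8, model_class="uncoupled", rho=None)
    tb = E.build_tables(cfg, grid8)
    g = grid8
    div_a, div_b = g.site_at(0, 5), g.site_at(-4, 0)
    K.seed_rng(9)
    n_draws = 60_000
    hist = {div_a: {}, div_b: {}}
    for div in (div_a, div_b):
        for _ in range(n_draws):
            s, _ = K.select_removal(div, False, tb.sec_indptr, tb.sec_indices,
                                    tb.dsk_indptr, tb.dsk_indices, tb.cdisk,
                                    g.corneal_sites)
            hist[div][s] = hist[div].get(s, 0) + 1
    keys = sorted((set(hist[div_a]) | set(hist[div_b])) - {div_a, div_b})
    a = np.array([hist[div_a].get(k, 0) for k in keys])
    b = np.array([hist[div_b].get(k, 0) for k in keys])
    # same removal distribution regardless of the divider
    chi = sps.chi2_contingency(np.stack([a, b]))
    assert chi.pvalue > 1e-3


def test_removal_uncoupled_rho1_central_site(grid31):
    cfg = E.ModelConfig(R_total=31, model_class="uncoupled", rho=1.0)
    tb = E.build_tables(cfg, grid31)
    st = E.init_state(cfg, grid31)
    div = grid31.site_at(10, 3)
    central = set(tb.cdisk.tolist())
    for seed in range(30):
        s = E.select_removal(st, div, cfg, rng=seed, tables=tb)
        assert s in central
        assert grid31.r[s] <= 1


# ---------------------------------------------------- apply_division


def test_apply_adjacent_no_chain(grid31):
    cfg = E.ModelConfig(R_total=31, rls=None)
    st = E.init_state(cfg, grid31)
    div = grid31.site_at(10, 0)
    st.clone[div] = 77
    rem = grid31.site_at(9, 0)
    E.apply_division(st, div, rem, cfg, rng=1)
    assert st.clone[rem] == 77  # daughter dropped straight into the vacancy
    assert st.divisions[rem] == 1
    assert st.divisions[div] == 1  # lineage depth advances for both cells


def test_apply_rejects_bad_preconditions(grid31):
    cfg = E.ModelConfig(R_total=31, rls=2)
    st = E.init_state(cfg, grid31)
    div = grid31.site_at(10, 0)
    with pytest.raises(ValueError):
        E.apply_division(st, div, div, cfg)
    st.divisions[div] = 2  # post-mitotic
    with pytest.raises(ValueError):
        E.apply_division(st, div, grid31.site_at(9, 0), cfg)


def test_chain_on_strip_is_interval_shift():
    g = line_grid(8)
    cfg = E.ModelConfig(R_total=31, rls=None, sigma=1.0)
    n = g.n_sites
    st = E.TissueState(g, np.full(n, E.P_CORNEAL, np.uint8),
                       np.arange(n, dtype=np.int32),
                       np.zeros(n, np.int32), np.zeros(n))
    E.apply_division(st, 1, 5, cfg, rng=4)
    # cells 2..4 shift one step toward the vacancy; daughter fills site 2
    assert st.clone.tolist() == [0, 1, 1, 2, 3, 4, 6, 7]


def test_conservation_and_counter_bookkeeping():
    """Occupancy, renewed count and competent count survive 10^4 events."""
    for model, stem in (("coupled", "equipotent"),
                        ("uncoupled", "equipotent"),
                        ("coupled", "hierarchical")):
        cfg = E.ModelConfig(R_total=13, m=3, alpha=math.pi, rls=8,
                            model_class=model, stem_model=stem,
                            stem_fraction=0.2, seed=42,
                            checkpoint_interval=2.0)
        tr = E.run(cfg, stop="time", tau_max=30)
        st = tr.final_state
        # every site still occupied by a valid cell
        assert np.all(np.isin(st.cell_type, [0, 1, 2]))
        assert st.cell_type.size == st.grid.n_sites
        # S only limbal, P_C only corneal
        assert np.all(st.grid.region[st.cell_type == E.S_CELL] == LIMBUS)
        assert np.all(st.grid.region[st.cell_type == E.P_CORNEAL] == CORNEA)


def test_run_determinism_identical_event_logs():
    cfg = E.ModelConfig(R_total=13, m=3, alpha=math.pi / 2, rls=10, seed=99)
    a = E.run(cfg, stop="time", tau_max=15, record_events=True)
    b = E.run(cfg, stop="time", tau_max=15, record_events=True)
    assert np.array_equal(a.events["div_site"], b.events["div_site"])
    assert np.array_equal(a.events["rem_site"], b.events["rem_site"])
    assert np.allclose(a.events["t"], b.events["t"])
    assert np.array_equal(a.final_state.clone, b.final_state.clone)


def test_rls0_hierarchical_only_limbal_divisions():
    cfg = E.ModelConfig(R_total=9, m=2, rls=0, stem_model="hierarchical",
                        stem_fraction=0.3, seed=3)
    tr = E.run(cfg, stop="time", tau_max=10, record_events=True)
    g = tr.final_state.grid
    assert tr.events["div_site"].size > 0
    assert np.all(g.region[tr.events["div_site"]] == LIMBUS)


def test_rls_safety_and_lineage_soundness():
    cfg = E.ModelConfig(R_total=13, m=3, alpha=math.pi / 3, rls=5, seed=8)
    st0 = E.init_state(cfg)
    initial_labels = set(st0.clone[st0.clone >= 0].tolist())
    tr = E.run(cfg, stop="stall", tau_max=300)
    st = tr.final_state
    assert np.max(st.divisions) <= 5
    labels = set(st.clone[st.clone >= 0].tolist())
    assert labels <= initial_labels  # every clone traces to an initial stem


def test_equipotent_limbus_always_stem():
    cfg = E.ModelConfig(R_total=13, m=3, rls=10, a=0.3, seed=21)
    tr = E.run(cfg, stop="time", tau_max=25)
    st = tr.final_state
    assert np.all(st.cell_type[st.grid.limbal_sites] == E.S_CELL)


def test_hierarchical_stem_set_constant():
    cfg = E.ModelConfig(R_total=13, m=3, rls=10, seed=5,
                        stem_model="hierarchical", stem_fraction=0.15)
    st0 = E.init_state(cfg)
    before = np.flatnonzero(st0.cell_type == E.S_CELL)
    tr = E.run(cfg, stop="time", tau_max=25)
    after = np.flatnonzero(tr.final_state.cell_type == E.S_CELL)
    assert np.array_equal(before, after)


def test_renewed_fraction_statistically_monotone():
    for seed in (1, 2, 3):
        cfg = E.ModelConfig(R_total=16, m=3, alpha=math.pi / 2, rls=30,
                            seed=seed, lambda_s=1 / 3, a=1.0)
        tr = E.run(cfg, stop="renewal", tau_max=300)
        diffs = np.diff(tr.renewed_frac)
        assert np.min(diffs) > -0.05  # only small stochastic dips
        assert tr.renewed_frac[-1] == max(tr.renewed_frac)


def test_normalized_time():
    assert E.normalized_time(0.0, 1 / 3) == 0
    assert E.normalized_time(3.0, 1 / 3) == pytest.approx(1.0)
    cfg = E.ModelConfig(R_total=9, m=2, rls=None, seed=2)
    tr = E.run(cfg, stop="time", tau_max=2.0)
    st = tr.final_state
    assert E.normalized_time(st, cfg.lambda_p) == pytest.approx(
        tr.taus[-1], rel=1e-6)
    # after ~n_cells uniform-rate divisions the normalized clock is ~1
    n_events_per_tau = st.event_count / tr.taus[-1]
    total_cells = st.grid.n_sites
    assert n_events_per_tau == pytest.approx(total_cells, rel=0.15)


def test_coupled_rls1_front_confined_to_neighborhood():
    cfg = E.ModelConfig(R_total=21, m=3, rls=1, seed=6, alpha=2 * math.pi)
    tr = E.run(cfg, stop="stall", tau_max=2000)
    assert tr.stalled
    from corneasim.stats import front_depth
    # steady-state renewed band fills roughly the interaction neighborhood
    assert front_depth(tr.final_state) == pytest.approx(cfg.m, abs=2.0)
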