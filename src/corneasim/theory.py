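"""Closed-form and one-step benchmark models.

These are the analytic limits the lattice simulation is checked against:

* coupled model, ideal centripetal bias: minimal replicative lifespan
  ``ceil(R/m)`` and renewal-time limit ``2R/(m+1)`` replication times;
* uncoupled model at RLS=0 (only stem cells divide): first-passage renewal
  times with perfect bias, ``(lambda_p / (2 lambda_s a)) (R+1)``, and with
  no bias, ``(lambda_p / (lambda_s a)) H_R R`` with the harmonic number H_R;
* uncoupled model, ideal bias and high RLS: stripes double per replication,
  so the minimal renewal time is ``log2(R)``;
* a one-step binomial reduction of the no-bias coupled front, where each
  added unit of lifespan advances the steady-state front by one cell with
  probability ``p_advance`` (about 3/8 for the radial front geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps


@dataclass
class TheoryParams:
    """Symbols of the closed-form benchmarks."""

    R: float = 100.0
    m: float = 5.0
    lambda_s: float = 1.0 / 7.0
    lambda_p: float = 1.0 / 3.0
    a: float = 0.2
    p_advance: float = 3.0 / 8.0

    def __post_init__(self):
        if not (self.R > self.m >= 1):
            raise ValueError("need R > m >= 1")
        if self.lambda_s <= 0 or self.lambda_p <= 0:
            raise ValueError("rates must be positive")
        if not (0 < self.p_advance <= 1):
            raise ValueError("p_advance must be in (0, 1]")


def harmonic_number(n: int) -> float:
    """H_n = sum_{k=1..n} 1/k."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def min_rls_ideal_bias(R: float, m: float) -> int:
    """Minimal replicative lifespan for full renewal with ideal bias: R/m.

    Each lifespan advances the renewed front by at most the interaction
    radius m, so reaching the center needs ceil(R/m) lifespans.
    """
    if not (R >= m >= 1):
        raise ValueError("need R >= m >= 1")
    return math.ceil(R / m)


def renewal_time_limit_coupled(R: float, m: float) -> float:
    """Lower limit on coupled-model renewal time with ideal bias: 2R/(m+1).

    With removal distances uniform on 1..m the front advances (m+1)/2 cells
    per corneal replication time.
    """
    if not (R >= m >= 1):
        raise ValueError("need R >= m >= 1")
    return 2.0 * R / (m + 1.0)


def renewal_time_uncoupled_rls0(R: float, lambda_s: float, lambda_p: float,
                                a: float, bias: str = "ideal") -> float:
    """Zero-RLS renewal time of the uncoupled model, replication times.

    Only stem cells divide; each asymmetric stem division (rate
    lambda_s * a per limbal cell) pushes a column inward. With perfect bias
    t = (lambda_p / (2 lambda_s a)) (R+1); with no bias the front position
    performs a biased walk and t = (lambda_p / (lambda_s a)) H_R R.
    """
    if a <= 0:
        raise ValueError("a must be positive (no renewal otherwise)")
    pref = lambda_p / (lambda_s * a)
    if bias == "ideal":
        return pref / 2.0 * (R + 1.0)
    if bias == "none":
        return pref * harmonic_number(int(round(R))) * R
    raise ValueError(f"bias must be 'ideal' or 'none', got {bias!r}")


def uncoupled_bias_ratio(R: int) -> float:
    """Parameter-free ratio t_nobias / t_withbias = 2 H_R R / (R+1)."""
    return 2.0 * harmonic_number(R) * R / (R + 1.0)


def min_renewal_time_uncoupled(R: float, integer: bool = False) -> float:
    """Minimal uncoupled renewal time with ideal bias and high RLS: log2(R).

    Each corneal replication time every labeled stripe doubles its length,
    so reaching the center takes log2(R) doublings (ceil for whole
    replications when ``integer``).
    """
    if R < 2:
        raise ValueError(f"R must be >= 2, got {R}")
    v = math.log2(R)
    return float(math.ceil(v)) if integer else v


@dataclass
class OneStepFrontResult:
    """Steady-state front distribution of the one-step binomial process."""

    depths: np.ndarray          # possible front depths (cells from limbus)
    pmf: np.ndarray             # probability of each depth
    mean_depth: float
    renewed_fraction: float     # implied renewed area fraction of the disk


def one_step_front_model(R: float, m: float, rls: int,
                         p_advance: float = 3.0 / 8.0,
                         n_samples: int = 0,
                         rng: Optional[np.random.Generator] = None
                         ) -> OneStepFrontResult:
    """One-step reduction of the no-bias coupled front.

    The front starts at depth m (the RLS=1 steady state fills the local
    interaction neighborhood) and each additional unit of lifespan advances
    it by one cell with probability ``p_advance``: depth = m +
    Binomial(RLS-1, p). With ``n_samples`` > 0 the distribution is estimated
    by Monte-Carlo instead of evaluated exactly (cross-check).
    """
    if rls < 1:
        raise ValueError("rls must be >= 1")
    n = rls - 1
    if n_samples > 0:
        rng = rng if rng is not None else np.random.default_rng()
        draws = m + rng.binomial(n, p_advance, size=n_samples)
        depths, cnt = np.unique(draws, return_counts=True)
        pmf = cnt / n_samples
    else:
        depths = m + np.arange(n + 1)
        pmf = sps.binom.pmf(np.arange(n + 1), n, p_advance)
    depths = np.minimum(depths.astype(float), R)
    mean_depth = float(np.sum(depths * pmf))
    # renewed area fraction of a disk of radius R labeled to depth d
    frac = float(np.sum((1.0 - ((R - depths) / R) ** 2) * pmf))
    return OneStepFrontResult(depths, pmf, mean_depth, frac)


def front_advance_probability(R: float, m: float, n_samples: int = 200_000,
                              rng: Optional[np.random.Generator] = None,
                              ideal_bias: bool = False,
                              front_radius: Optional[float] = None) -> float:
    """Monte-Carlo front-advance probability of the no-bias coupled model.

    A cell on the circular renewal front (radius ``front_radius`` from the
    tissue center, default R - m) divides; the removed cell is drawn
    uniformly from the disk of radius m around it (points closer than half
    a cell map to the divider itself and are rejected). The front advances
    when the removal lies at least one full cell deeper (closer to the
    center) than the divider. For m=5, R=100 this is about 3/8. With
    ``ideal_bias`` the removal is drawn on the inward ray at a distance
    uniform on [1, m] and the probability is 1 by construction.
    """
    if not (R > m >= 1):
        raise ValueError("need R > m >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    c = R - m if front_radius is None else float(front_radius)
    if ideal_bias:
        return 1.0  # removal always >= 1 cell inward
    # divider at (c, 0); removal uniform in the m-disk around it
    n = 0
    adv = 0
    while n < n_samples:
        k = min(n_samples - n, 100_000)
        u = rng.random(k)
        r = m * np.sqrt(rng.random(k))
        phi = 2 * np.pi * u
        ok = r >= 0.5
        px = c + r[ok] * np.cos(phi[ok])
        py = r[ok] * np.sin(phi[ok])
        adv += int(np.sum(np.hypot(px, py) <= c - 1.0))
        n += int(np.sum(ok))
    return adv / n


def flat_front_advance_probability(m: float, drop: float = 1.0,
                                   r_min: float = 0.5) -> float:
    """Closed-form flat-front limit of :func:`front_advance_probability`.

    Fraction of the m-disk (excluding the central r < r_min core) lying
    more than ``drop`` below the divider: the circular-segment area
    m^2 acos(drop/m) - drop sqrt(m^2 - drop^2) over pi (m^2 - r_min^2).
    """
    if drop >= m:
        return 0.0
    seg = m * m * math.acos(drop / m) - drop * math.sqrt(m * m - drop * drop)
    return seg / (math.pi * (m * m - r_min * r_min))


def theory_table(params: TheoryParams) -> "pd.DataFrame":
    """Labeled table of all closed forms for the given parameters."""
    import pandas as pd

    R, m = params.R, params.m
    Ri = int(round(R))
    rows = [
        ("min_rls_ideal_bias", "replications", min_rls_ideal_bias(R, m)),
        ("renewal_time_limit_coupled", "replication times",
         renewal_time_limit_coupled(R, m)),
        ("renewal_time_uncoupled_rls0_ideal", "replication times",
         renewal_time_uncoupled_rls0(R, params.lambda_s, params.lambda_p,
                                     params.a, "ideal")),
        ("renewal_time_uncoupled_rls0_none", "replication times",
         renewal_time_uncoupled_rls0(R, params.lambda_s, params.lambda_p,
                                     params.a, "none")),
        ("uncoupled_bias_ratio", "fold", uncoupled_bias_ratio(Ri)),
        ("min_renewal_time_uncoupled", "replication times",
         min_renewal_time_uncoupled(R)),
        ("harmonic_number_R", "-", harmonic_number(Ri)),
        ("p_advance_default", "-", params.p_advance),
    ]
    return pd.DataFrame(rows, columns=["quantity", "units", "value"])
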