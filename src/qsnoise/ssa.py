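"""Exact Gillespie simulation of the multicellular autoinducer network.

Reaction channels, for each cell i of N sharing one extracellular pool:

    off_i  → on_i        rate β          (transcription of the single mRNA)
    on_i   → off_i       rate α          (mRNA degradation)
    on_i   → on_i + A_i  rate k₊         (autoinducer synthesis)
    A_i    → ∅           rate k₋·A_i     (intracellular degradation/dilution)
    A_i    → A_ext       rate D·A_i      (efflux)
    A_ext  → A_i         rate r·D·A_ext  (influx, per destination cell)
    A_ext  → ∅           rate k₋·A_ext   (extracellular degradation/dilution)

The influx channels are lumped into one channel of propensity N·r·D·A_ext
with a uniform destination draw — the master equation is identical and the
channel count stays O(1) in N.  The count-level influx propensity follows
from flux matching: D·c_ext·V = D·(A_ext/V_ext)·V = r·D·A_ext.

Stationary statistics are exact time integrals of the piecewise-constant
trajectory (holding-time weighting between events), so the estimators carry
no discretization bias.  The dual-reporter variant duplicates the synthesis/
degradation/transport channels for two distinguishable products A1, A2 of the
same mRNA, each with its own external pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from numba import njit

from .params import (
    PhysicalParams,
    concentration_from_molecules,
    molecules_from_concentration,
    to_dimensionless,
)
from . import analytics

__all__ = [
    "SSAState",
    "RunResult",
    "Channel",
    "build_channels",
    "initial_state",
    "default_burn_in",
    "ssa_run",
    "ssa_run_dual",
    "ssa_replicates",
]


@dataclass
class SSAState:
    """Integer molecule counts plus the clock.

    ``M`` holds the per-cell mRNA indicator (0 or 1).  For single-reporter
    runs ``A`` is the per-cell autoinducer count and ``A_ext`` the shared
    pool; dual-reporter runs carry (A, A2) and (A_ext, A_ext2).
    """

    t: float
    M: np.ndarray
    A: np.ndarray
    A_ext: int
    A2: np.ndarray | None = None
    A_ext2: int | None = None

    def validate(self) -> None:
        if not np.all((self.M == 0) | (self.M == 1)):
            raise ValueError("M entries must be 0 or 1")
        if np.any(self.A < 0) or self.A_ext < 0:
            raise ValueError("counts must be non-negative")
        if self.A2 is not None and (np.any(self.A2 < 0) or (self.A_ext2 or 0) < 0):
            raise ValueError("counts must be non-negative")


class Channel(NamedTuple):
    """One reaction channel: a name, its propensity as a function of an
    :class:`SSAState`, and a human-readable effect."""

    name: str
    propensity: Callable[[SSAState], float]
    effect: str


def build_channels(p: PhysicalParams, dual: bool = False) -> list[Channel]:
    """Symbolic channel set (used for introspection and cross-checks; the
    compiled kernel implements the same propensities)."""
    chans = [
        Channel("switch_on", lambda s: p.beta * (p.N - int(s.M.sum())), "M_i: 0→1"),
        Channel("switch_off", lambda s: p.alpha * int(s.M.sum()), "M_i: 1→0"),
        Channel("synthesis", lambda s: p.k_plus * int(s.M.sum()), "A_i += 1"),
        Channel("degradation", lambda s: p.k_minus * int(s.A.sum()), "A_i -= 1"),
        Channel("efflux", lambda s: p.D * int(s.A.sum()), "A_i -= 1, A_ext += 1"),
        Channel(
            "influx",
            lambda s: p.N * p.r * p.D * s.A_ext,
            "A_ext -= 1, A_i += 1 (uniform cell)",
        ),
        Channel("ext_degradation", lambda s: p.k_minus * s.A_ext, "A_ext -= 1"),
    ]
    if dual:
        chans += [
            Channel("synthesis_2", lambda s: p.k_plus * int(s.M.sum()), "A2_i += 1"),
            Channel("degradation_2", lambda s: p.k_minus * int(s.A2.sum()), "A2_i -= 1"),
            Channel("efflux_2", lambda s: p.D * int(s.A2.sum()), "A2_i -= 1, A_ext2 += 1"),
            Channel(
                "influx_2",
                lambda s: p.N * p.r * p.D * (s.A_ext2 or 0),
                "A_ext2 -= 1, A2_i += 1 (uniform cell)",
            ),
            Channel("ext_degradation_2", lambda s: p.k_minus * (s.A_ext2 or 0), "A_ext2 -= 1"),
        ]
    return chans


def stationary_count_mean(p: PhysicalParams) -> float:
    """Predicted stationary per-cell count (k₊/k₋)·⟨c̃_A⟩ (real, not rounded)."""
    d = to_dimensionless(p)
    return p.k_plus / p.k_minus * analytics.mean_dimensionless(
        d.alpha_t, d.beta_t, d.D_t, d.Nr
    )


def initial_state(
    p: PhysicalParams, mode: str = "stationary_guess", seed: int = 0, dual: bool = False
) -> SSAState:
    """Draw an initial state.

    ``stationary_guess`` samples M ~ Bernoulli(β/(α+β)), per-cell counts from
    Poisson at the predicted stationary mean, and the pool from Poisson at
    its quasi-steady level; it cuts the burn-in needed relative to ``zeros``.
    """
    if mode == "zeros":
        return SSAState(
            t=0.0,
            M=np.zeros(p.N, dtype=np.int64),
            A=np.zeros(p.N, dtype=np.int64),
            A_ext=0,
            A2=np.zeros(p.N, dtype=np.int64) if dual else None,
            A_ext2=0 if dual else None,
        )
    if mode != "stationary_guess":
        raise ValueError("mode must be 'stationary_guess' or 'zeros'")
    rng = np.random.default_rng(seed)
    occ = p.beta / (p.alpha + p.beta) if (p.alpha + p.beta) > 0 else 0.0
    n_bar = stationary_count_mean(p)
    d = to_dimensionless(p)
    # pool mean: QSS external concentration times V_ext, in counts
    if p.D > 0:
        c_ext_counts = (
            analytics.external_qss_concentration(n_bar / p.V, d.D_t, p.N, p.r)
            * p.V_ext
        )
    else:
        c_ext_counts = 0.0
    M = (rng.random(p.N) < occ).astype(np.int64)
    A = rng.poisson(n_bar, size=p.N).astype(np.int64)
    A_ext = int(rng.poisson(c_ext_counts))
    if dual:
        A2 = rng.poisson(n_bar, size=p.N).astype(np.int64)
        A_ext2 = int(rng.poisson(c_ext_counts))
        return SSAState(0.0, M, A, A_ext, A2, A_ext2)
    return SSAState(0.0, M, A, A_ext)


def default_burn_in(p: PhysicalParams) -> float:
    """20 × the slowest relaxation scale, max(1/k₋, τ_c, 1/(k₋+D)) (min)."""
    return 20.0 * max(1.0 / p.k_minus, p.tau_c, 1.0 / (p.k_minus + p.D))


@njit(cache=True)
def _pick_weighted(A, total, u):
    """Index i with probability A[i]/total, via linear cumulative scan."""
    target = u * total
    cum = 0.0
    for i in range(A.shape[0]):
        cum += A[i]
        if cum > target:
            return i
    return A.shape[0] - 1


@njit(cache=True)
def _pick_state(M, want, N):
    """Uniform index among cells with M[i] == want (rejection sampling;
    callers guarantee at least one such cell)."""
    while True:
        i = int(np.random.random() * N)
        if i >= N:
            continue
        if M[i] == want:
            return i


@njit(cache=True)
def _ssa_core(
    alpha, beta, k_plus, k_minus, D, N, r, t_burn, t_end, seed,
    M, A, A_ext_arr, thin_dt, thin_M, thin_A, thin_E,
):
    """Direct-method SSA with exact holding-time moment accumulation.

    Returns (T, iS, iS2, iSS, iM, iE, t, n_events, absorbing, n_thin) where
    iS = ∫ΣA dt, iS2 = ∫ΣA² dt, iSS = ∫(ΣA)² dt, iM = ∫Σ M dt, iE = ∫A_ext dt
    over the stationary window [t_burn, t_end).  State arrays are mutated in
    place; A_ext is carried in a length-1 array.
    """
    np.random.seed(seed)
    n_on = 0
    S = 0
    S2 = 0
    for i in range(N):
        n_on += M[i]
        S += A[i]
        S2 += A[i] * A[i]
    A_ext = A_ext_arr[0]

    T = 0.0
    iS = 0.0
    iS2 = 0.0
    iSS = 0.0
    iM = 0.0
    iE = 0.0
    t = 0.0
    n_events = 0
    absorbing = 0
    n_thin = 0
    next_thin = t_burn if thin_dt > 0.0 else 1e300

    while t < t_end:
        a_on = beta * (N - n_on)
        a_off = alpha * n_on
        a_syn = k_plus * n_on
        a_deg = k_minus * S
        a_eff = D * S
        a_in = N * r * D * A_ext
        a_ext = k_minus * A_ext
        a_tot = a_on + a_off + a_syn + a_deg + a_eff + a_in + a_ext

        if a_tot <= 0.0:
            t_new = t_end
        else:
            t_new = t + (-math.log(np.random.random()) / a_tot)

        # exact time-weighted accumulation over the pre-event interval
        lo = t if t > t_burn else t_burn
        hi = t_new if t_new < t_end else t_end
        if hi > lo:
            w = hi - lo
            T += w
            iS += w * S
            iS2 += w * S2
            iSS += w * S * S
            iM += w * n_on
            iE += w * A_ext
        while next_thin < t_new and next_thin < t_end and n_thin < thin_M.shape[0]:
            thin_M[n_thin] = M[0]
            thin_A[n_thin] = A[0]
            thin_E[n_thin] = A_ext
            n_thin += 1
            next_thin += thin_dt

        if a_tot <= 0.0:
            absorbing = 1
            t = t_end
            break
        t = t_new
        if t >= t_end:
            break

        u = np.random.random() * a_tot
        n_events += 1
        if u < a_on:
            i = _pick_state(M, 0, N)
            M[i] = 1
            n_on += 1
        elif u < a_on + a_off:
            i = _pick_state(M, 1, N)
            M[i] = 0
            n_on -= 1
        elif u < a_on + a_off + a_syn:
            i = _pick_state(M, 1, N)
            S2 += 2 * A[i] + 1
            A[i] += 1
            S += 1
        elif u < a_on + a_off + a_syn + a_deg:
            i = _pick_weighted(A, float(S), np.random.random())
            S2 -= 2 * A[i] - 1
            A[i] -= 1
            S -= 1
        elif u < a_on + a_off + a_syn + a_deg + a_eff:
            i = _pick_weighted(A, float(S), np.random.random())
            S2 -= 2 * A[i] - 1
            A[i] -= 1
            S -= 1
            A_ext += 1
        elif u < a_on + a_off + a_syn + a_deg + a_eff + a_in:
            i = int(np.random.random() * N)
            if i >= N:
                i = N - 1
            S2 += 2 * A[i] + 1
            A[i] += 1
            S += 1
            A_ext -= 1
        else:
            A_ext -= 1

    A_ext_arr[0] = A_ext
    return T, iS, iS2, iSS, iM, iE, t, n_events, absorbing, n_thin


@njit(cache=True)
def _ssa_core_dual(
    alpha, beta, k_plus, k_minus, D, N, r, t_burn, t_end, seed,
    M, A1, A2, E_arr,
):
    """Dual-reporter SSA: two distinguishable products of the same mRNA,
    with duplicated synthesis/degradation/transport channels and separate
    external pools.

    Returns (T, i1, i2, i11, i22, i12, iM, n_events) with i1 = ∫ΣA1 dt,
    i11 = ∫ΣA1² dt, i12 = ∫Σ_i A1_i·A2_i dt over the stationary window.
    """
    np.random.seed(seed)
    n_on = 0
    S1 = 0
    S2_ = 0
    Q1 = 0
    Q2 = 0
    C = 0
    for i in range(N):
        n_on += M[i]
        S1 += A1[i]
        S2_ += A2[i]
        Q1 += A1[i] * A1[i]
        Q2 += A2[i] * A2[i]
        C += A1[i] * A2[i]
    E1 = E_arr[0]
    E2 = E_arr[1]

    T = 0.0
    i1 = 0.0
    i2 = 0.0
    i11 = 0.0
    i22 = 0.0
    i12 = 0.0
    iM = 0.0
    t = 0.0
    n_events = 0

    while t < t_end:
        a_on = beta * (N - n_on)
        a_off = alpha * n_on
        a_syn = k_plus * n_on
        a_deg1 = k_minus * S1
        a_eff1 = D * S1
        a_in1 = N * r * D * E1
        a_ext1 = k_minus * E1
        a_deg2 = k_minus * S2_
        a_eff2 = D * S2_
        a_in2 = N * r * D * E2
        a_ext2 = k_minus * E2
        a_tot = (
            a_on + a_off + 2.0 * a_syn
            + a_deg1 + a_eff1 + a_in1 + a_ext1
            + a_deg2 + a_eff2 + a_in2 + a_ext2
        )
        if a_tot <= 0.0:
            t_new = t_end
        else:
            t_new = t + (-math.log(np.random.random()) / a_tot)

        lo = t if t > t_burn else t_burn
        hi = t_new if t_new < t_end else t_end
        if hi > lo:
            w = hi - lo
            T += w
            i1 += w * S1
            i2 += w * S2_
            i11 += w * Q1
            i22 += w * Q2
            i12 += w * C
            iM += w * n_on

        if a_tot <= 0.0:
            t = t_end
            break
        t = t_new
        if t >= t_end:
            break

        u = np.random.random() * a_tot
        n_events += 1
        edge = a_on
        if u < edge:
            i = _pick_state(M, 0, N)
            M[i] = 1
            n_on += 1
            continue
        edge += a_off
        if u < edge:
            i = _pick_state(M, 1, N)
            M[i] = 0
            n_on -= 1
            continue
        edge += a_syn
        if u < edge:
            i = _pick_state(M, 1, N)
            Q1 += 2 * A1[i] + 1
            C += A2[i]
            A1[i] += 1
            S1 += 1
            continue
        edge += a_syn
        if u < edge:
            i = _pick_state(M, 1, N)
            Q2 += 2 * A2[i] + 1
            C += A1[i]
            A2[i] += 1
            S2_ += 1
            continue
        edge += a_deg1
        if u < edge:
            i = _pick_weighted(A1, float(S1), np.random.random())
            Q1 -= 2 * A1[i] - 1
            C -= A2[i]
            A1[i] -= 1
            S1 -= 1
            continue
        edge += a_eff1
        if u < edge:
            i = _pick_weighted(A1, float(S1), np.random.random())
            Q1 -= 2 * A1[i] - 1
            C -= A2[i]
            A1[i] -= 1
            S1 -= 1
            E1 += 1
            continue
        edge += a_in1
        if u < edge:
            i = int(np.random.random() * N)
            if i >= N:
                i = N - 1
            Q1 += 2 * A1[i] + 1
            C += A2[i]
            A1[i] += 1
            S1 += 1
            E1 -= 1
            continue
        edge += a_ext1
        if u < edge:
            E1 -= 1
            continue
        edge += a_deg2
        if u < edge:
            i = _pick_weighted(A2, float(S2_), np.random.random())
            Q2 -= 2 * A2[i] - 1
            C -= A1[i]
            A2[i] -= 1
            S2_ -= 1
            continue
        edge += a_eff2
        if u < edge:
            i = _pick_weighted(A2, float(S2_), np.random.random())
            Q2 -= 2 * A2[i] - 1
            C -= A1[i]
            A2[i] -= 1
            S2_ -= 1
            E2 += 1
            continue
        edge += a_in2
        if u < edge:
            i = int(np.random.random() * N)
            if i >= N:
                i = N - 1
            Q2 += 2 * A2[i] + 1
            C += A1[i]
            A2[i] += 1
            S2_ += 1
            E2 -= 1
            continue
        E2 -= 1

    E_arr[0] = E1
    E_arr[1] = E2
    return T, i1, i2, i11, i22, i12, iM, n_events


@dataclass
class RunResult:
    """Stationary statistics of one SSA run (pooled over cells and time)."""

    params: PhysicalParams
    seed: int
    t_burn: float
    t_end: float
    window: float
    n_events: int
    absorbing: bool
    mean_count: float           # E[A_i], pooled
    second_moment_count: float  # E[A_i²], pooled
    m_occupancy: float          # E[M_i]
    ext_mean_count: float       # E[A_ext]
    pair_moment_count: float | None = None  # E[A_i A_j], i≠j
    dual: bool = False
    mean2_count: float | None = None
    second_moment2_count: float | None = None
    cross_moment_count: float | None = None  # E[A1_i A2_i], same cell
    final_state: SSAState | None = None
    thin_t: np.ndarray | None = None
    thin_M: np.ndarray | None = None
    thin_A: np.ndarray | None = None
    thin_E: np.ndarray | None = None

    @property
    def var_count(self) -> float:
        return self.second_moment_count - self.mean_count**2

    @property
    def eta2_total(self) -> float:
        """Squared CV of pooled per-cell concentration (scale-free: counts
        and nM give the same value)."""
        if self.mean_count <= 0:
            raise ValueError("noise undefined for zero mean")
        return self.var_count / self.mean_count**2

    @property
    def mean_nM(self) -> float:
        return concentration_from_molecules(self.mean_count, self.params.V)

    @property
    def cross_cell_cov(self) -> float:
        """Cov(A_i, A_j) for i ≠ j (counts); ≈ 0 when cells only couple
        weakly through the pool, exactly 0 in distribution at D = 0."""
        if self.pair_moment_count is None:
            raise ValueError("pair moment not recorded for this run")
        return self.pair_moment_count - self.mean_count**2

    @property
    def diff_second_moment(self) -> float:
        """E[(A1_i − A2_i)²] for dual runs."""
        if not self.dual:
            raise ValueError("dual statistics not present")
        return (
            self.second_moment_count
            + self.second_moment2_count
            - 2.0 * self.cross_moment_count
        )


def ssa_run(
    p: PhysicalParams,
    t_end: float,
    *,
    t_burn: float | None = None,
    seed: int = 0,
    init: str = "stationary_guess",
    thin_dt: float = 0.0,
    keep_final_state: bool = True,
) -> RunResult:
    """Run the direct-method SSA and return exact stationary statistics.

    Statistics are accumulated only for t > t_burn.  ``thin_dt`` > 0 records
    a thinned trajectory of cell 0 and the pool (output convenience only;
    estimators never touch it).
    """
    if t_burn is None:
        t_burn = default_burn_in(p)
    if not (t_end > t_burn >= 0):
        raise ValueError("need t_end > t_burn >= 0")
    state = initial_state(p, init, seed=seed)
    ext = np.array([state.A_ext], dtype=np.int64)
    if thin_dt > 0:
        n_slots = int((t_end - t_burn) / thin_dt) + 1
    else:
        n_slots = 0
    thin_M = np.zeros(n_slots, dtype=np.int64)
    thin_A = np.zeros(n_slots, dtype=np.int64)
    thin_E = np.zeros(n_slots, dtype=np.int64)

    T, iS, iS2, iSS, iM, iE, t, n_events, absorbing, n_thin = _ssa_core(
        p.alpha, p.beta, p.k_plus, p.k_minus, p.D, p.N, p.r,
        float(t_burn), float(t_end), int(seed) % 2**31,
        state.M, state.A, ext, float(thin_dt), thin_M, thin_A, thin_E,
    )
    state.A_ext = int(ext[0])
    state.t = t
    N = p.N
    mean = iS / (T * N)
    second = iS2 / (T * N)
    pair = (iSS - iS2) / (T * N * (N - 1)) if N > 1 else None
    res = RunResult(
        params=p,
        seed=seed,
        t_burn=t_burn,
        t_end=t_end,
        window=T,
        n_events=int(n_events),
        absorbing=bool(absorbing),
        mean_count=mean,
        second_moment_count=second,
        m_occupancy=iM / (T * N),
        ext_mean_count=iE / T,
        pair_moment_count=pair,
        final_state=state if keep_final_state else None,
    )
    if thin_dt > 0:
        res.thin_t = t_burn + thin_dt * np.arange(n_thin)
        res.thin_M = thin_M[:n_thin]
        res.thin_A = thin_A[:n_thin]
        res.thin_E = thin_E[:n_thin]
    return res


def ssa_run_dual(
    p: PhysicalParams,
    t_end: float,
    *,
    t_burn: float | None = None,
    seed: int = 0,
    init: str = "stationary_guess",
    keep_final_state: bool = True,
) -> RunResult:
    """Dual-reporter SSA run; returns paired (A1, A2) pooled statistics."""
    if t_burn is None:
        t_burn = default_burn_in(p)
    if not (t_end > t_burn >= 0):
        raise ValueError("need t_end > t_burn >= 0")
    state = initial_state(p, init, seed=seed, dual=True)
    E = np.array([state.A_ext, state.A_ext2], dtype=np.int64)
    T, i1, i2, i11, i22, i12, iM, n_events = _ssa_core_dual(
        p.alpha, p.beta, p.k_plus, p.k_minus, p.D, p.N, p.r,
        float(t_burn), float(t_end), int(seed) % 2**31,
        state.M, state.A, state.A2, E,
    )
    state.A_ext, state.A_ext2 = int(E[0]), int(E[1])
    state.t = t_end
    N = p.N
    return RunResult(
        params=p,
        seed=seed,
        t_burn=t_burn,
        t_end=t_end,
        window=T,
        n_events=int(n_events),
        absorbing=False,
        mean_count=i1 / (T * N),
        second_moment_count=i11 / (T * N),
        m_occupancy=iM / (T * N),
        ext_mean_count=float("nan"),
        dual=True,
        mean2_count=i2 / (T * N),
        second_moment2_count=i22 / (T * N),
        cross_moment_count=i12 / (T * N),
        final_state=state if keep_final_state else None,
    )


def ssa_replicates(
    p: PhysicalParams,
    t_end: float,
    *,
    n_replicates: int = 8,
    base_seed: int = 0,
    t_burn: float | None = None,
    init: str = "stationary_guess",
    dual: bool = False,
) -> list[RunResult]:
    """Independent replicate runs seeded base_seed + index."""
    runner = ssa_run_dual if dual else ssa_run
    return [
        runner(
            p,
            t_end,
            t_burn=t_burn,
            seed=(base_seed + k) % 2**31,
            init=init,
            keep_final_state=False,
        )
        for k in range(n_replicates)
    ]
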