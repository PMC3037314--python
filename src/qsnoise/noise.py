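"""Noise estimation and decomposition for simulation outputs.

The total squared CV of the intracellular autoinducer concentration splits as

    η²_total = η²_int + η²_tran,

where η²_tran is the closed-form transcriptional (mRNA-switching) component
and η²_int the molecular-discreteness remainder.  Two independent estimators
of η²_int are provided: subtracting the analytic η²_tran from the simulated
total, and the dual-reporter perpendicular-spread estimator
⟨(c₁−c₂)²⟩ / (2⟨c₁⟩⟨c₂⟩).  The diffusion-scan experiment recalibrates k₊ at
every D̃ so the mean concentration stays pinned (at 25 nM by default) while
the noise components trade places.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import analytics
from .params import PhysicalParams, calibrated, to_dimensionless
from .pdmp import pdmp_run
from .ssa import RunResult, ssa_replicates

__all__ = [
    "NoiseEstimate",
    "ScanResult",
    "total_noise",
    "intrinsic_by_decomposition",
    "intrinsic_dual_reporter",
    "diffusion_scan",
    "ols_slope",
]


@dataclass(frozen=True)
class NoiseEstimate:
    """A squared CV with its replicate standard error and provenance."""

    eta2: float
    se: float
    source: str  # ssa_total | analytic_tran | decomposition_intrinsic | dual_reporter_intrinsic
    params: dict = field(default_factory=dict)
    flagged: bool = False  # negative beyond sampling error (decomposition only)


def _eta2_stats(values: Sequence[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")
    return mean, se


def total_noise(runs: RunResult | Sequence) -> NoiseEstimate:
    """Total η² from one or more replicate runs (SSA or PDMP results).

    Accepts anything exposing ``eta2_total`` (SSA) or ``eta2`` (PDMP); with
    several replicates the SE is the spread across them.
    """
    seq = [runs] if not isinstance(runs, (list, tuple)) else list(runs)
    vals = []
    for rn in seq:
        vals.append(rn.eta2_total if hasattr(rn, "eta2_total") else rn.eta2)
    eta2, se = _eta2_stats(vals)
    params: dict = {}
    first = seq[0]
    if isinstance(first, RunResult):
        d = to_dimensionless(first.params)
        params = {
            "alpha_t": d.alpha_t,
            "beta_t": d.beta_t,
            "D_t": d.D_t,
            "N": first.params.N,
            "r": first.params.r,
            "seeds": [rn.seed for rn in seq if isinstance(rn, RunResult)],
        }
    return NoiseEstimate(eta2=eta2, se=se, source="ssa_total", params=params)


def analytic_transcriptional(p: PhysicalParams) -> NoiseEstimate:
    """Closed-form η²_tran for a physical parameter set."""
    d = to_dimensionless(p)
    return NoiseEstimate(
        eta2=analytics.transcriptional_noise(d.alpha_t, d.beta_t, d.D_t, p.N, p.r),
        se=0.0,
        source="analytic_tran",
        params={"alpha_t": d.alpha_t, "beta_t": d.beta_t, "D_t": d.D_t},
    )


def intrinsic_by_decomposition(
    total: NoiseEstimate, p: PhysicalParams
) -> NoiseEstimate:
    """η²_int = η²_total − η²_tran(closed form), SE inherited from the total.

    A negative value larger in magnitude than twice the SE is flagged: it
    signals an estimator/parameter mismatch rather than sampling noise.
    """
    d = to_dimensionless(p)
    for key, val in (("alpha_t", d.alpha_t), ("beta_t", d.beta_t), ("D_t", d.D_t)):
        got = total.params.get(key)
        if got is not None and not math.isclose(got, val, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"parameter mismatch for {key}: total has {got}, p has {val}")
    tran = analytics.transcriptional_noise(d.alpha_t, d.beta_t, d.D_t, p.N, p.r)
    eta2 = total.eta2 - tran
    se = total.se
    flagged = eta2 < 0 and not (math.isnan(se) or abs(eta2) <= 2.0 * se)
    return NoiseEstimate(
        eta2=eta2,
        se=se,
        source="decomposition_intrinsic",
        params=dict(total.params),
        flagged=flagged,
    )


def intrinsic_dual_reporter(runs: RunResult | Sequence[RunResult]) -> NoiseEstimate:
    """Dual-reporter intrinsic noise ⟨(c₁−c₂)²⟩ / (2⟨c₁⟩⟨c₂⟩).

    The shared mRNA drive is common mode; only uncorrelated molecular events
    push the two reporters off the diagonal, so the perpendicular spread
    isolates η²_int.  (Counts and concentrations give the same ratio.)
    """
    seq = [runs] if isinstance(runs, RunResult) else list(runs)
    vals = []
    for rn in seq:
        if not rn.dual:
            raise ValueError("dual-reporter statistics required")
        if rn.mean_count <= 0 or rn.mean2_count <= 0:
            raise ValueError("noise undefined for zero mean")
        vals.append(rn.diff_second_moment / (2.0 * rn.mean_count * rn.mean2_count))
    eta2, se = _eta2_stats(vals)
    d = to_dimensionless(seq[0].params)
    return NoiseEstimate(
        eta2=eta2,
        se=se,
        source="dual_reporter_intrinsic",
        params={
            "alpha_t": d.alpha_t,
            "beta_t": d.beta_t,
            "D_t": d.D_t,
            "seeds": [rn.seed for rn in seq],
        },
    )


def ols_slope(
    x: Sequence[float],
    y: Sequence[float],
    y_se: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Ordinary least-squares slope and its standard error.

    With ``y_se`` given, the SE is propagated from the per-point measurement
    errors through the OLS weights — far better conditioned than the
    residual-based estimate when the fit has only a few degrees of freedom
    (each replicate-derived se carries many more).  Without it, the classic
    residual-variance SE is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a slope with an SE")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / sxx
    if y_se is not None:
        var = float((xc**2) @ (np.asarray(y_se, dtype=float) ** 2)) / sxx**2
        return slope, math.sqrt(var)
    resid = y - y.mean() - slope * xc
    sigma2 = float(resid @ resid) / (n - 2)
    return slope, math.sqrt(sigma2 / sxx)


@dataclass
class ScanResult:
    """Diffusion-scan table with the intrinsic-noise regression."""

    table: pd.DataFrame  # columns: D_t, eta2_total, eta2_total_se, eta2_tran,
    #                      eta2_int, eta2_int_se, n_reps, seed0
    slope: float         # OLS slope of eta2_int vs D_t
    slope_se: float      # propagated from the replicate SEs via OLS weights
    argmax_D_t: float    # grid argmax of eta2_total

    @property
    def intrinsic_grid_average(self) -> float:
        return float(self.table["eta2_int"].mean())

    @property
    def intrinsic_grid_average_se(self) -> float:
        se = self.table["eta2_int_se"].to_numpy(dtype=float)
        return float(np.sqrt(np.nansum(se**2)) / len(se))


def diffusion_scan(
    base: PhysicalParams,
    D_t_grid: Sequence[float],
    *,
    target_mean_nM: float = 25.0,
    n_replicates: int = 8,
    base_seed: int = 0,
    t_window: float = 2000.0,
    t_burn: float = 300.0,
    engine: str = "ssa",
) -> ScanResult:
    """Scan η² over diffusion with k₊ recalibrated at every grid point.

    ``base`` supplies (α, β, k₋, N, r, V); its D and k₊ are overridden per
    point.  Engine "ssa" gives the full (intrinsic + transcriptional) noise;
    "pdmp" simulates the reduced process, whose intrinsic column should
    vanish.  Replicate seeds at grid point i are base_seed + 7919·i + j.
    """
    if len(D_t_grid) == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    for i, D_t in enumerate(sorted(D_t_grid)):
        p = calibrated(
            PhysicalParams(
                alpha=base.alpha,
                beta=base.beta,
                k_plus=1.0,
                k_minus=base.k_minus,
                D=D_t * base.k_minus,
                N=base.N,
                r=base.r,
                V=base.V,
            ),
            target_mean_nM,
        )
        seed0 = (base_seed + 7919 * i) % 2**31
        if engine == "ssa":
            runs = ssa_replicates(
                p,
                t_burn + t_window,
                n_replicates=n_replicates,
                base_seed=seed0,
                t_burn=t_burn,
            )
            tot = total_noise(runs)
        elif engine == "pdmp":
            d = to_dimensionless(p)
            # same physical duration, expressed in units of 1/k₋
            results = [
                pdmp_run(
                    d,
                    (t_burn + t_window) * base.k_minus,
                    t_burn=t_burn * base.k_minus,
                    seed=(seed0 + j) % 2**31,
                )
                for j in range(n_replicates)
            ]
            eta2, se = _eta2_stats([rn.eta2 for rn in results])
            dd = to_dimensionless(p)
            tot = NoiseEstimate(
                eta2=eta2,
                se=se,
                source="ssa_total",
                params={"alpha_t": dd.alpha_t, "beta_t": dd.beta_t, "D_t": dd.D_t},
            )
        else:
            raise ValueError("engine must be 'ssa' or 'pdmp'")
        intr = intrinsic_by_decomposition(tot, p)
        tran = analytic_transcriptional(p)
        rows.append(
            {
                "D_t": float(D_t),
                "eta2_total": tot.eta2,
                "eta2_total_se": tot.se,
                "eta2_tran": tran.eta2,
                "eta2_int": intr.eta2,
                "eta2_int_se": intr.se,
                "n_reps": n_replicates,
                "seed0": seed0,
            }
        )
    table = pd.DataFrame(rows).sort_values("D_t", ignore_index=True)
    if len(table) >= 3:
        slope, slope_se = ols_slope(
            table["D_t"], table["eta2_int"], y_se=table["eta2_int_se"]
        )
    else:
        slope, slope_se = float("nan"), float("nan")
    argmax = float(table.loc[table["eta2_total"].idxmax(), "D_t"])
    return ScanResult(table=table, slope=slope, slope_se=slope_se, argmax_D_t=argmax)
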