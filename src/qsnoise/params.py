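"""Model parameter sets for the quorum-sensing signaling model.

The model describes a population of ``N`` well-stirred cells, each carrying a
two-state (telegraph) mRNA switch that drives synthesis of a diffusible
autoinducer.  Molecules are exchanged with a single shared extracellular pool
whose volume exceeds the cell volume by a factor ``1/r``.  All rates are in
1/min; concentrations are handled externally in nM and internally as molecule
counts per compartment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "AVOGADRO",
    "PhysicalParams",
    "DimensionlessParams",
    "PRESETS",
    "preset",
    "to_dimensionless",
    "from_dimensionless",
    "molecules_from_concentration",
    "concentration_from_molecules",
    "calibrate_k_plus",
    "calibrated",
    "effective_diffusion_from_active_transport",
]

AVOGADRO = 6.02214076e23

#: molecules per (nM × μm³): 1e-9 mol/L × 1e-15 L/μm³ × N_A
_COUNT_PER_NM_UM3 = 1e-9 * 1e-15 * AVOGADRO


class LowExpressionWarning(UserWarning):
    """Emitted when the single-transcript regime (α > 2β) is violated."""


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional rates, geometry, and population size of one model instance.

    Parameters
    ----------
    alpha : float
        mRNA degradation rate (1/min); rate of the on → off switch.
    beta : float
        Transcription frequency (1/min); rate of the off → on switch.
    k_plus : float
        Autoinducer synthesis rate per mRNA molecule (molecules/min).
    k_minus : float
        Effective degradation/dilution rate (1/min), identical inside and
        outside the cell (dilution dominates chemical decay).
    D : float
        Membrane exchange (diffusion) rate (1/min).
    N : int
        Number of cells (≥ 1).
    r : float
        Cell-to-external volume ratio V/V_ext (> 0).
    V : float
        Cell volume (μm³, > 0).
    """

    alpha: float
    beta: float
    k_plus: float
    k_minus: float
    D: float
    N: int
    r: float
    V: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "k_plus", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_minus <= 0:
            raise ValueError("degradation rate must be positive")
        if self.N < 1 or int(self.N) != self.N:
            raise ValueError("N must be an integer >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.V <= 0:
            raise ValueError("V must be positive")
        if not self.low_expression:
            warnings.warn(
                "alpha <= 2*beta: outside the low-constitutive-expression "
                "regime; the single-transcript telegraph picture is strained "
                "but the analytics remain mathematically valid",
                LowExpressionWarning,
                stacklevel=2,
            )

    @property
    def nu(self) -> float:
        """Sensing potential ν = 1/(rN): dilution of signal into the medium."""
        return 1.0 / (self.r * self.N)

    @property
    def tau_c(self) -> float:
        """mRNA autocorrelation time τ_c = 1/(α+β) (min)."""
        s = self.alpha + self.beta
        if s <= 0:
            raise ValueError("tau_c undefined for alpha + beta = 0")
        return 1.0 / s

    @property
    def low_expression(self) -> bool:
        """True iff α > 2β, the single-transcript-at-a-time regime."""
        return self.alpha > 2.0 * self.beta

    @property
    def V_ext(self) -> float:
        """External volume (μm³)."""
        return self.V / self.r


@dataclass(frozen=True)
class DimensionlessParams:
    """Reduced parameter set driving the stationary analytics.

    Time is measured in units of the signal lifetime 1/k₋ and concentration in
    units of the maximal level c_A⁺ = k₊/(k₋V); the model then depends only on
    (α̃, β̃, D̃, Nr).
    """

    alpha_t: float   # α/k₋
    beta_t: float    # β/k₋
    D_t: float       # D/k₋
    Nr: float        # N·r
    c_scale: float   # c_A⁺ = k₊/(k₋·V), in nM-equivalent molecule density

    def __post_init__(self) -> None:
        for name in ("alpha_t", "beta_t", "D_t", "Nr", "c_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def k_eff(self) -> float:
        """Effective dimensionless relaxation rate, 1 + D̃ (exact)."""
        return 1.0 + self.D_t

    @property
    def k_plus_eff(self) -> float:
        """Effective dimensionless influx from the pool, at the
        self-consistent mean: ⟨c̃_A⟩·D̃ / (1 + 1/(ND̃r))."""
        from . import analytics  # local import; analytics depends on params

        return analytics.k_plus_eff_from_mean(
            analytics.mean_dimensionless(self.alpha_t, self.beta_t, self.D_t, self.Nr),
            self.D_t,
            self.Nr,
        )


def to_dimensionless(p: PhysicalParams) -> DimensionlessParams:
    """Non-dimensionalize a physical parameter set (rates over k₋)."""
    k = p.k_minus
    return DimensionlessParams(
        alpha_t=p.alpha / k,
        beta_t=p.beta / k,
        D_t=p.D / k,
        Nr=p.N * p.r,
        c_scale=p.k_plus / (k * p.V),
    )


def from_dimensionless(
    d: DimensionlessParams, k_minus: float, V: float, N: int
) -> PhysicalParams:
    """Invert :func:`to_dimensionless` given the stripped scales (k₋, V, N)."""
    if k_minus <= 0:
        raise ValueError("degradation rate must be positive")
    return PhysicalParams(
        alpha=d.alpha_t * k_minus,
        beta=d.beta_t * k_minus,
        k_plus=d.c_scale * k_minus * V,
        k_minus=k_minus,
        D=d.D_t * k_minus,
        N=N,
        r=d.Nr / N,
        V=V,
    )


def molecules_from_concentration(conc_nM: float, V_um3: float) -> float:
    """Expected molecule count for a concentration (nM) in a volume (μm³).

    25 nM in an E. coli-sized 1.5 μm³ cell is ≈ 22.58 molecules — the low
    copy numbers that make intrinsic noise non-negligible here.
    """
    if conc_nM < 0:
        raise ValueError("concentration must be non-negative")
    if V_um3 <= 0:
        raise ValueError("volume must be positive")
    return conc_nM * V_um3 * _COUNT_PER_NM_UM3


def concentration_from_molecules(count: float, V_um3: float) -> float:
    """Inverse of :func:`molecules_from_concentration` (count → nM)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if V_um3 <= 0:
        raise ValueError("volume must be positive")
    return count / (V_um3 * _COUNT_PER_NM_UM3)


def calibrate_k_plus(target_mean_nM: float, p: PhysicalParams) -> float:
    """Synthesis rate k₊ that pins the stationary mean at ``target_mean_nM``.

    The stationary mean count is (k₊/k₋)·⟨c̃_A⟩ with ⟨c̃_A⟩ the closed-form
    dimensionless mean, so k₊ = n̄·k₋/⟨c̃_A⟩ with n̄ the target count.  The
    ``k_plus`` field of ``p`` is ignored.
    """
    from . import analytics

    if target_mean_nM <= 0:
        raise ValueError("target mean must be positive")
    if p.beta <= 0:
        raise ValueError("mean autoinducer level is zero; cannot calibrate")
    d = to_dimensionless(p)
    m = analytics.mean_dimensionless(d.alpha_t, d.beta_t, d.D_t, d.Nr)
    n_bar = molecules_from_concentration(target_mean_nM, p.V)
    return n_bar * p.k_minus / m


def calibrated(p: PhysicalParams, target_mean_nM: float = 25.0) -> PhysicalParams:
    """Copy of ``p`` with k₊ recalibrated to the target mean concentration."""
    return replace(p, k_plus=calibrate_k_plus(target_mean_nM, p))


def effective_diffusion_from_active_transport(
    D_in: float, D_out: float, r: float, rel_tolerance: float = 10.0
) -> tuple[float, bool]:
    """Map active influx/efflux rates onto the passive-diffusion model.

    The passive model with D = D_out reproduces active transport when the
    rate asymmetry matches the volume asymmetry, r ≈ D_in/D_out.  Returns
    (D_out, flag); the flag is True when D_in/D_out is within a factor
    ``rel_tolerance`` of r.
    """
    if D_in < 0 or D_out < 0:
        raise ValueError("transport rates must be non-negative")
    if D_out == 0:
        raise ValueError("D_out must be positive")
    if r <= 0:
        raise ValueError("r must be positive")
    ratio = D_in / D_out
    valid = ratio > 0 and (1.0 / rel_tolerance) <= (ratio / r) <= rel_tolerance
    return D_out, bool(valid)


# Toy dimensionless (α̃, β̃) pairs spanning the qualitative regimes of the
# stationary density, shipped with the reference geometry: N=100 cells,
# r=1e-5 (so ν = 10³), k₋ = 0.02/min, V = 1.5 μm³, mean pinned at 25 nM.
_PRESET_GAMMAS = {
    "gamma1": (8.0, 2.0),
    "gamma2": (15.0, 5.0),
    "gamma3": (8.0, 0.5),
    "gamma4": (15.0, 0.5),
}

PRESETS = dict(_PRESET_GAMMAS)

DEFAULT_K_MINUS = 2e-2
DEFAULT_N = 100
DEFAULT_R = 1e-5
DEFAULT_V = 1.5
DEFAULT_TARGET_NM = 25.0


def preset(
    name: str,
    D_t: float = 0.0,
    *,
    target_mean_nM: float = DEFAULT_TARGET_NM,
    N: int = DEFAULT_N,
    r: float = DEFAULT_R,
    k_minus: float = DEFAULT_K_MINUS,
    V: float = DEFAULT_V,
) -> PhysicalParams:
    """Build a named preset as a calibrated :class:`PhysicalParams`."""
    try:
        alpha_t, beta_t = _PRESET_GAMMAS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid: {sorted(_PRESET_GAMMAS)}"
        ) from None
    p = PhysicalParams(
        alpha=alpha_t * k_minus,
        beta=beta_t * k_minus,
        k_plus=1.0,  # placeholder, recalibrated below
        k_minus=k_minus,
        D=D_t * k_minus,
        N=N,
        r=r,
        V=V,
    )
    return calibrated(p, target_mean_nM)
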