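"""Two-compartment Frank-Starling circulation model and its stroke-volume map.

The model splits the circulating blood into an arterial and a venous
compartment of compliances ``C_A`` and ``C_V`` (μl/mmHg), with pressures
``P_x = V_x / C_x``.  Each cardiac cycle the heart ejects a stroke volume that
depends linearly on venous (filling) pressure — the linearised Frank-Starling
law ``SV = β P_V`` — moving blood from the venous to the arterial side; blood
then returns passively through the peripheral resistance ``R`` at
``V_R = (P_A - P_V)/R`` per cycle (the cycle interval is absorbed into the
units of ``R``).  Total volume ``V_T = V_V + V_A`` is conserved exactly.

Eliminating the volumes shows that successive stroke volumes obey the affine
recursion

    SV_{i+1} = A SV_i + B,
    A = (1 - β/C_V) [1 - (1/R)(1/C_A + 1/C_V)],
    B = V_T β / (R C_A C_V),

which converges to the fixed point ``SV̄ = B/(1-A)`` whenever ``|A| < 1``.
With per-cycle Gaussian innovations the recursion becomes a stationary AR(1)
process, so stroke-volume variability has closed-form variance
``σ_eff²/(1-A²)`` and Poincaré indices ``SD1 = σ_eff/sqrt(1+A)``,
``SD2 = σ_eff/sqrt(1-A)``.  Noise may enter the recursion directly in μl
(``recursion_additive``, σ_eff = σ) or as a venous-pressure (preload)
fluctuation in mmHg scaled by the Frank-Starling gain (``preload``,
σ_eff = β σ).  Under preload noise the stationary SV variance is proportional
to β², which is how a loss of contractility (smaller β) lowers stroke-volume
variability even though it raises A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal

from .errors import NonPhysicalParametersError, UnstableMapError

__all__ = [
    "CompartmentParams",
    "CompartmentState",
    "MapCoefficients",
    "NoiseSpec",
    "StepResult",
    "FixedPoint",
    "StationaryMoments",
    "SimulationResult",
    "MechanisticTrajectory",
    "pressures",
    "coefficients",
    "fixed_point",
    "step",
    "simulate",
    "simulate_mechanistic",
    "stationary_moments",
    "beta_sweep",
    "params_for_a",
    "DEFAULT_PARAMS",
]

BURN_IN = 100  # cycles flagged as transient in simulation output


@dataclass(frozen=True)
class CompartmentParams:
    """Parameters of the two-compartment circulation.

    c_a, c_v : arterial / venous compliance (μl/mmHg)
    r        : peripheral resistance (mmHg·cycle/μl; per-cycle interval absorbed)
    beta     : Frank-Starling gain (μl/mmHg), 0 < beta <= c_v
    v_t      : total blood volume (μl), conserved
    """

    c_a: float
    c_v: float
    r: float
    beta: float
    v_t: float

    def __post_init__(self) -> None:
        for name in ("c_a", "c_v", "r", "beta", "v_t"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.beta > self.c_v:
            raise ValueError("beta must not exceed c_v (post-stroke venous factor < 0)")

    def replace(self, **kwargs) -> "CompartmentParams":
        from dataclasses import replace

        return replace(self, **kwargs)


# Control-like murine operating point: SV̄ ≈ 24 μl at P_V ≈ 4 mmHg, P_A ≈ 60 mmHg.
DEFAULT_PARAMS = CompartmentParams(c_a=2.0, c_v=50.0, r=2.853, beta=6.0, v_t=320.0)


@dataclass(frozen=True)
class CompartmentState:
    """Venous and arterial volumes (μl); their sum is the total blood volume."""

    v_v: float
    v_a: float

    def __post_init__(self) -> None:
        if self.v_v < 0 or self.v_a < 0:
            raise ValueError("compartment volumes must be non-negative")

    @property
    def v_t(self) -> float:
        return self.v_v + self.v_a


@dataclass(frozen=True)
class MapCoefficients:
    """Coefficients of the affine stroke-volume map SV_{i+1} = A SV_i + B."""

    a: float
    b: float
    stable: bool


@dataclass(frozen=True)
class NoiseSpec:
    """How per-cycle Gaussian noise enters the stroke-volume recursion.

    entry : 'recursion_additive' (innovation in μl added to the recursion) or
            'preload' (venous-pressure fluctuation in mmHg, scaled by beta).
    sigma : innovation SD (μl or mmHg according to entry).
    seed  : RNG seed.
    """

    entry: Literal["recursion_additive", "preload"] = "preload"
    sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.entry not in ("recursion_additive", "preload"):
            raise ValueError(f"unknown noise entry {self.entry!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def effective_sigma(self, params: CompartmentParams) -> float:
        """Innovation SD expressed in μl on the stroke-volume recursion."""
        return self.sigma * (params.beta if self.entry == "preload" else 1.0)


@dataclass(frozen=True)
class StepResult:
    state: CompartmentState
    sv: float
    clipped: bool


@dataclass(frozen=True)
class FixedPoint:
    sv: float
    v_v: float


@dataclass(frozen=True)
class StationaryMoments:
    mean: float
    variance: float
    sd1: float
    sd2: float
    sigma_eff: float


@dataclass
class SimulationResult:
    """Stroke-volume trajectory of the stochastic recursion."""

    sv: np.ndarray
    burn_in: int
    n_clipped: int
    params: CompartmentParams
    noise: NoiseSpec

    def stationary(self) -> np.ndarray:
        """The trajectory with the burn-in cycles removed."""
        return self.sv[self.burn_in:]


@dataclass
class MechanisticTrajectory:
    """Stroke volumes and compartment volumes from repeated mechanistic steps."""

    sv: np.ndarray
    v_v: np.ndarray
    v_a: np.ndarray
    n_clipped: int


def pressures(state: CompartmentState, params: CompartmentParams) -> tuple[float, float]:
    """Arterial and venous pressures (mmHg), ``P_x = V_x / C_x``."""
    return state.v_a / params.c_a, state.v_v / params.c_v


def coefficients(params: CompartmentParams) -> MapCoefficients:
    """Closed-form map coefficients A and B of the stroke-volume recursion."""
    bracket = 1.0 - (1.0 / params.r) * (1.0 / params.c_a + 1.0 / params.c_v)
    a = (1.0 - params.beta / params.c_v) * bracket
    b = params.v_t * params.beta / (params.r * params.c_a * params.c_v)
    return MapCoefficients(a=a, b=b, stable=abs(a) < 1.0)


def fixed_point(params: CompartmentParams) -> FixedPoint:
    """Stationary stroke volume ``SV̄ = B/(1-A)`` and implied venous volume.

    Raises :class:`UnstableMapError` when ``|A| >= 1``.
    """
    coef = coefficients(params)
    if not coef.stable:
        raise UnstableMapError(f"|A| = {abs(coef.a):.4g} >= 1: no stable fixed point")
    sv = coef.b / (1.0 - coef.a)
    return FixedPoint(sv=sv, v_v=sv * params.c_v / params.beta)


def step(
    state: CompartmentState,
    params: CompartmentParams,
    preload_noise: float = 0.0,
) -> StepResult:
    """Advance the mechanistic model by one cardiac cycle.

    The heart ejects ``SV = β (P_V + preload_noise)`` (clipped below at 0) from
    the venous to the arterial compartment; blood then returns passively,
    ``V_R = (P_A - P_V)/R`` evaluated at the post-stroke volumes.  Total volume
    is conserved exactly by construction.

    Returns the next state, the emitted stroke volume, and whether the
    non-negativity clip fired.  Raises :class:`NonPhysicalParametersError` if a
    compartment volume would become negative.
    """
    _, p_v = pressures(state, params)
    sv_raw = params.beta * (p_v + preload_noise)
    clipped = sv_raw < 0.0
    sv = 0.0 if clipped else sv_raw

    v_v_mid = state.v_v - sv
    v_a_mid = state.v_a + sv
    if v_v_mid < 0.0:
        raise NonPhysicalParametersError(
            f"stroke volume {sv:.4g} μl exceeds venous volume {state.v_v:.4g} μl"
        )
    v_r = (v_a_mid / params.c_a - v_v_mid / params.c_v) / params.r
    v_v_next = v_v_mid + v_r
    v_a_next = v_a_mid - v_r
    if v_v_next < 0.0 or v_a_next < 0.0:
        raise NonPhysicalParametersError(
            "passive return drove a compartment volume negative "
            f"(V_V={v_v_next:.4g}, V_A={v_a_next:.4g})"
        )
    return StepResult(state=CompartmentState(v_v=v_v_next, v_a=v_a_next), sv=sv, clipped=clipped)


def simulate(
    params: CompartmentParams,
    n_cycles: int,
    noise: NoiseSpec | None = None,
    initial_v_v: float | None = None,
    burn_in: int = BURN_IN,
) -> SimulationResult:
    """Simulate the stochastic stroke-volume recursion for ``n_cycles`` cycles.

    The trajectory follows ``SV_{i+1} = A SV_i + B + η_i`` with i.i.d. Gaussian
    innovations ``η_i`` of SD ``σ_eff`` set by the noise entry (``σ`` for
    ``recursion_additive``, ``β σ`` for ``preload``).  The first ``burn_in``
    cycles are flagged as transient; :meth:`SimulationResult.stationary` drops
    them.  Stroke volumes are clipped below at zero (events counted) — in the
    physiological regimes studied here the clip never fires.

    Raises :class:`UnstableMapError` for ``|A| >= 1``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    noise = noise or NoiseSpec(sigma=0.0)
    coef = coefficients(params)
    if not coef.stable:
        raise UnstableMapError(f"|A| = {abs(coef.a):.4g} >= 1: refusing divergent simulation")

    v_v0 = params.v_t / 2.0 if initial_v_v is None else float(initial_v_v)
    sv0 = params.beta * v_v0 / params.c_v
    sigma_eff = noise.effective_sigma(params)

    rng = np.random.default_rng(noise.seed)
    eta = rng.normal(0.0, sigma_eff, size=n_cycles - 1) if sigma_eff > 0 else np.zeros(n_cycles - 1)
    # SV_i = A SV_{i-1} + B + η: an IIR filter with a one-pole denominator.
    drive = coef.b + eta
    zi = signal.lfiltic([1.0], [1.0, -coef.a], [sv0])
    rest, _ = signal.lfilter([1.0], [1.0, -coef.a], drive, zi=zi)
    sv = np.concatenate([[sv0], rest])

    n_clipped = int(np.sum(sv < 0.0))
    if n_clipped:
        sv = np.clip(sv, 0.0, None)
    return SimulationResult(
        sv=sv, burn_in=min(burn_in, n_cycles), n_clipped=n_clipped, params=params, noise=noise
    )


def simulate_mechanistic(
    params: CompartmentParams,
    n_cycles: int,
    noise: NoiseSpec | None = None,
    initial_state: CompartmentState | None = None,
) -> MechanisticTrajectory:
    """Iterate the mechanistic :func:`step` with per-cycle preload noise.

    This keeps the full compartment-state bookkeeping (volume conservation,
    clipping) rather than the reduced recursion.  Note that preload noise fed
    through the state propagates with a one-cycle moving-average correction,
    so long-run moments differ slightly from the reduced AR(1) closed forms;
    see the methods note.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    noise = noise or NoiseSpec(sigma=0.0)
    if noise.entry != "preload":
        raise ValueError("mechanistic simulation supports only preload noise")
    coef = coefficients(params)
    if not coef.stable and noise.sigma > 0:
        raise UnstableMapError("refusing noisy simulation of an unstable map")

    state = initial_state or CompartmentState(v_v=params.v_t / 2.0, v_a=params.v_t / 2.0)
    rng = np.random.default_rng(noise.seed)
    xi = rng.normal(0.0, noise.sigma, size=n_cycles) if noise.sigma > 0 else np.zeros(n_cycles)

    sv = np.empty(n_cycles)
    v_v = np.empty(n_cycles)
    v_a = np.empty(n_cycles)
    n_clipped = 0
    for i in range(n_cycles):
        out = step(state, params, preload_noise=xi[i])
        state = out.state
        sv[i] = out.sv
        v_v[i] = state.v_v
        v_a[i] = state.v_a
        n_clipped += out.clipped
    return MechanisticTrajectory(sv=sv, v_v=v_v, v_a=v_a, n_clipped=n_clipped)


def stationary_moments(params: CompartmentParams, noise: NoiseSpec) -> StationaryMoments:
    """Closed-form stationary mean, variance and Poincaré indices of SV.

    mean = B/(1-A); variance = σ_eff²/(1-A²);
    SD1 = σ_eff/sqrt(1+A); SD2 = σ_eff/sqrt(1-A).
    """
    coef = coefficients(params)
    if not coef.stable:
        raise UnstableMapError(f"|A| = {abs(coef.a):.4g} >= 1: no stationary moments")
    s = noise.effective_sigma(params)
    a = coef.a
    return StationaryMoments(
        mean=coef.b / (1.0 - a),
        variance=s * s / (1.0 - a * a),
        sd1=s / math.sqrt(1.0 + a),
        sd2=s / math.sqrt(1.0 - a),
        sigma_eff=s,
    )


def beta_sweep(params: CompartmentParams, beta_grid, noise: NoiseSpec) -> pd.DataFrame:
    """Evaluate the map and its stationary variability along a grid of β values.

    Returns one row per β with columns ``beta, A, B, SV_bar, sd, SD1, SD2,
    stable``; rows with ``|A| >= 1`` are flagged unstable and their moments
    left as NaN.
    """
    grid = np.asarray(beta_grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("beta grid is empty")
    if np.any(grid <= 0) or np.any(grid > params.c_v):
        raise ValueError("every beta must lie in (0, c_v]")
    rows = []
    for beta in grid:
        p = params.replace(beta=float(beta))
        coef = coefficients(p)
        row = {"beta": float(beta), "A": coef.a, "B": coef.b, "stable": coef.stable,
               "SV_bar": np.nan, "sd": np.nan, "SD1": np.nan, "SD2": np.nan}
        if coef.stable:
            mom = stationary_moments(p, noise)
            row.update(SV_bar=mom.mean, sd=math.sqrt(mom.variance), SD1=mom.sd1, SD2=mom.sd2)
        rows.append(row)
    return pd.DataFrame(rows, columns=["beta", "A", "B", "SV_bar", "sd", "SD1", "SD2", "stable"])


def params_for_a(a_target: float, base: CompartmentParams = DEFAULT_PARAMS) -> CompartmentParams:
    """Parameter set sharing ``base``'s vascular properties with a chosen A.

    Solves ``A = (1 - β/C_V)·bracket`` for β; requires the implied β to lie in
    (0, C_V], i.e. ``a_target`` between 0 and the bracket term.
    """
    bracket = 1.0 - (1.0 / base.r) * (1.0 / base.c_a + 1.0 / base.c_v)
    if bracket == 0:
        raise ValueError("bracket term is zero; A does not depend on beta")
    beta = base.c_v * (1.0 - a_target / bracket)
    return base.replace(beta=beta)
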