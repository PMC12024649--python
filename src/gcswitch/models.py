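"""Growth-rate-aware dynamical models of bistable regulatory switches.

Four switch architectures are modelled as deterministic ODE systems in which
protein production is a Hill function of a regulator and every intracellular
species is lost to dilution at the specific growth rate ``lam`` (plus an
optional first-order molecular decay ``delta``).  Each model reduces, with
fast variables (phosphorylation, dimerization, intracellular inducer) at
quasi-steady state, to a single scalar balance ``dx/dt = production(x, s) -
decay_rate * x`` whose fixed points define the off/on/bistable behaviour.

Units: time in hours, concentrations in µM, growth rate ``lam`` in 1/h
(doublings per hour = lam / ln 2).  Signals are in arbitrary signal units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Literal, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

LN2 = math.log(2.0)

#: Avogadro-derived conversion: molecules = conc_uM * volume_fL * UM_FL_TO_MOLECULES
UM_FL_TO_MOLECULES = 602.214076


# ---------------------------------------------------------------------------
# growth context
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthContext:
    """Specific growth rate and molecular decay defining the dilution balance.

    Parameters
    ----------
    lam:
        Specific (exponential) growth rate in 1/h.  Doubling time is
        ``ln 2 / lam``.
    delta:
        First-order molecular decay rate in 1/h, applied on top of dilution.
    """

    lam: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"growth rate must be >= 0, got {self.lam}")
        if self.delta < 0:
            raise ValueError(f"decay rate must be >= 0, got {self.delta}")

    @classmethod
    def from_doubling_time(cls, doubling_time_h: float, delta: float = 0.0) -> "GrowthContext":
        if doubling_time_h <= 0:
            raise ValueError("doubling time must be > 0")
        return cls(lam=LN2 / doubling_time_h, delta=delta)

    @property
    def doubling_time(self) -> float:
        """Doubling time in hours (inf at growth arrest)."""
        return math.inf if self.lam == 0 else LN2 / self.lam

    @property
    def doublings_per_hour(self) -> float:
        return self.lam / LN2

    @property
    def g(self) -> float:
        """Total first-order concentration loss rate, dilution + decay (1/h)."""
        return self.lam + self.delta


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AutoactivatorParams:
    """Transcription factor positively regulating its own operon.

    ``dx/dt = b + beta * x^n / (K^n + x^n) - (lam + delta) * x``
    """

    b: float      # basal production, µM/h
    beta: float   # maximal regulated production, µM/h
    K: float      # activation half-max concentration, µM
    n: float = 2  # Hill coefficient

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("basal production b must be >= 0")
        if self.beta <= 0 or self.K <= 0:
            raise ValueError("beta and K must be > 0")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")


@dataclass(frozen=True)
class ProteaseSwitchParams:
    """Autoactivator whose decay is set by a signal-repressed protease.

    The external signal s represses protease activity, so the total decay
    rate is ``lam + delta + delta_p / (1 + (s/s0)^h_p)``.
    """

    auto: AutoactivatorParams
    delta_p: float    # maximal protease-mediated decay, 1/h
    s0: float         # signal at half-maximal protease activity
    h_p: float = 2.0  # protease-repression Hill coefficient

    def __post_init__(self) -> None:
        if self.delta_p <= 0 or self.s0 <= 0:
            raise ValueError("delta_p and s0 must be > 0")
        if self.h_p < 1:
            raise ValueError("h_p must be >= 1")


@dataclass(frozen=True)
class TwoComponentParams:
    """Two-component switch: operon expresses TF X and membrane kinase K.

    Signal activates the kinase (activity fraction a(s) = s/(s+k_act)); the
    phosphorylated TF dimerizes, and the active dimer drives the operon's
    promoter.  At quasi-steady state the phosphorylated fraction is
    ``p = a*kin*k_phos / (a*kin*k_phos + k_deph)`` with kinase concentration
    ``kin = rho * X`` (same operon), and the active dimer is
    ``D = (p X)^2 / K_D``.
    """

    auto: AutoactivatorParams  # promoter parameters; Hill input is the dimer D
    rho: float = 1.0           # kinase : TF expression ratio
    k_act: float = 1.0         # signal-activation half-max, signal units
    k_phos: float = 1.0        # phosphorylation rate constant, 1/(µM h)
    k_deph: float = 1.0        # dephosphorylation rate, 1/h
    K_D: float = 1.0           # dimerization dissociation constant, µM

    def __post_init__(self) -> None:
        for name in ("rho", "k_act", "k_phos", "k_deph", "K_D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# --- lac full-induction regulation modes -----------------------------------

@dataclass(frozen=True)
class ConstantProduction:
    """Full-induction production rate independent of growth rate (µM/h)."""

    y0: float

    def __post_init__(self) -> None:
        if self.y0 <= 0:
            raise ValueError("y0 must be > 0")

    def production(self, ctx: GrowthContext) -> float:
        return self.y0


@dataclass(frozen=True)
class CLine:
    """Catabolic growth law: full-induction *concentration* decreases
    linearly with growth rate, y_h(lam) = y0 * (1 - lam/lam_star) (µM).

    The corresponding production rate is ``(lam + delta) * y_h(lam)`` since
    a stable protein's steady-state concentration is production / dilution.
    """

    y0: float        # zero-growth full-induction concentration, µM
    lam_star: float  # growth rate at which full-induction expression hits 0, 1/h

    def __post_init__(self) -> None:
        if self.y0 <= 0 or self.lam_star <= 0:
            raise ValueError("y0 and lam_star must be > 0")

    def concentration(self, lam: float) -> float:
        if lam >= self.lam_star:
            raise ValueError(
                f"c-line expression is non-positive at lam={lam:g} >= lam_star={self.lam_star:g}"
            )
        return self.y0 * (1.0 - lam / self.lam_star)

    def production(self, ctx: GrowthContext) -> float:
        return ctx.g * self.concentration(ctx.lam)


@dataclass(frozen=True)
class RLine:
    """Translation-inhibition growth law: full-induction concentration
    increases proportionally to growth rate, y_h(lam) = kappa * lam (µM),
    so the production rate is ``(lam + delta) * kappa * lam``."""

    kappa: float  # µM h (concentration per unit growth rate)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    def production(self, ctx: GrowthContext) -> float:
        return ctx.g * self.kappa * ctx.lam


Regulation = Union[ConstantProduction, CLine, RLine]


@dataclass(frozen=True)
class LacParams:
    """lac-operon positive feedback through inducer import.

    The scalar state is the transporter (LacY) concentration Y.  The
    intracellular inducer is at quasi-steady state,
    ``tau = alpha_imp * Y * c_ext / (lam + delta + k_hyd * Y)``, and
    production is ``y_prod(lam) * (leak + (1-leak) * tau^n / (tau^n + K_tau^n))``.
    """

    regulation: Regulation
    leak: float = 0.01          # basal expression fraction
    alpha_imp: float = 0.1      # import rate per transporter per external inducer, 1/(µM h) per µM LacY
    k_tau0: float = 10.0        # half-induction intracellular inducer conc at lam_ref, µM
    n_tau: float = 2.0          # induction Hill coefficient
    k_hyd: float = 0.0          # inducer removal rate per enzyme, 1/(µM h); 0 for gratuitous inducers
    ktau_exponent: float = 0.0  # theta in K_tau ∝ lam^theta
    lam_ref: float = LN2        # reference growth rate for K_tau scaling, 1/h
    volume_fl: float = 2.5      # cell volume for molecule <-> µM conversion, fL

    def __post_init__(self) -> None:
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must be in [0, 1]")
        for name in ("alpha_imp", "k_tau0", "n_tau", "lam_ref", "volume_fl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_hyd < 0:
            raise ValueError("k_hyd must be >= 0")

    def k_tau(self, lam: float) -> float:
        if self.ktau_exponent == 0.0:
            return self.k_tau0
        if lam <= 0:
            raise ValueError("K_tau scaling with theta != 0 requires lam > 0")
        return self.k_tau0 * (lam / self.lam_ref) ** self.ktau_exponent


ModelKind = Literal["autoactivator", "protease", "two_component", "lac"]


@dataclass(frozen=True)
class ModelSpec:
    """Dispatch wrapper pairing a model kind with its parameter set."""

    kind: ModelKind
    params: Union[AutoactivatorParams, ProteaseSwitchParams, TwoComponentParams, LacParams]
    modulation: Literal["nutrient", "translation"] = "nutrient"

    _EXPECTED = {
        "autoactivator": AutoactivatorParams,
        "protease": ProteaseSwitchParams,
        "two_component": TwoComponentParams,
        "lac": LacParams,
    }

    def __post_init__(self) -> None:
        expected = self._EXPECTED.get(self.kind)
        if expected is None:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not isinstance(self.params, expected):
            raise TypeError(f"params for kind {self.kind!r} must be {expected.__name__}")


# ---------------------------------------------------------------------------
# reduced scalar dynamics
# ---------------------------------------------------------------------------

def _hill(x, K: float, n: float):
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        xn = np.where(x > 0, (x / K) ** n, 0.0)
        out = np.where(np.isfinite(xn), xn / (1.0 + xn), 1.0)
    return out


def _two_component_dimer(p: TwoComponentParams, x, kin, signal: float):
    """Active dimer concentration given total TF x and kinase concentration."""
    a = signal / (signal + p.k_act)
    drive = a * p.k_phos * np.asarray(kin, dtype=float)
    frac = np.where(drive + p.k_deph > 0, drive / (drive + p.k_deph), 0.0)
    xp = frac * np.asarray(x, dtype=float)
    return xp * xp / p.K_D


def _lac_inducer(p: LacParams, y, c_ext: float, ctx: GrowthContext):
    """Quasi-steady intracellular inducer concentration."""
    y = np.asarray(y, dtype=float)
    sink = ctx.g + p.k_hyd * y
    return p.alpha_imp * y * c_ext / sink


def reduced_rhs(spec: ModelSpec, x, signal: float, ctx: GrowthContext):
    """dx/dt of the reduced scalar system at concentration ``x`` (µM/h).

    ``x`` may be a scalar or array (vectorized over x).  ``signal`` is the
    external signal: protease/two-component signal units, or the external
    inducer concentration (µM) for the lac model; it is ignored by the plain
    autoactivator.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("concentration x must be >= 0")
    if signal < 0:
        raise ValueError("signal must be >= 0")
    p = spec.params
    if spec.kind == "autoactivator":
        rhs = p.b + p.beta * _hill(x_arr, p.K, p.n) - ctx.g * x_arr
    elif spec.kind == "protease":
        a = p.auto
        decay = ctx.g + p.delta_p / (1.0 + (signal / p.s0) ** p.h_p)
        rhs = a.b + a.beta * _hill(x_arr, a.K, a.n) - decay * x_arr
    elif spec.kind == "two_component":
        a = p.auto
        dimer = _two_component_dimer(p, x_arr, p.rho * x_arr, signal)
        rhs = a.b + a.beta * _hill(dimer, a.K, a.n) - ctx.g * x_arr
    elif spec.kind == "lac":
        y_prod = p.regulation.production(ctx)
        tau = _lac_inducer(p, x_arr, signal, ctx)
        frac = p.leak + (1.0 - p.leak) * _hill(tau, p.k_tau(ctx.lam), p.n_tau)
        rhs = y_prod * frac - ctx.g * x_arr
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(spec.kind)
    return rhs if isinstance(x, np.ndarray) else float(rhs)


def _production_bounds(spec: ModelSpec, signal: float, ctx: GrowthContext) -> tuple[float, float, float]:
    """(min production, max production, effective linear decay rate)."""
    p = spec.params
    if spec.kind == "autoactivator":
        return p.b, p.b + p.beta, ctx.g
    if spec.kind == "protease":
        a = p.auto
        decay = ctx.g + p.delta_p / (1.0 + (signal / p.s0) ** p.h_p)
        return a.b, a.b + a.beta, decay
    if spec.kind == "two_component":
        a = p.auto
        return a.b, a.b + a.beta, ctx.g
    y_prod = p.regulation.production(ctx)
    return p.leak * y_prod, y_prod, ctx.g


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPoint:
    x: float
    stability: int  # +1 stable, -1 unstable, 0 marginal (saddle-node)

    @property
    def stable(self) -> bool:
        return self.stability > 0


def find_fixed_points(
    spec: ModelSpec,
    signal: float,
    ctx: GrowthContext,
    *,
    n_grid: int = 2000,
    merge_rtol: float = 1e-6,
) -> list[FixedPoint]:
    """All fixed points of the reduced system, sorted ascending in x.

    Roots are located by a sign-change scan over a log-spaced grid spanning
    the invariant interval [p_min/decay, p_max/decay] (which contains every
    fixed point, since production is bounded by the basal and maximal rates),
    refined by Brent's method.  Stability is read off the direction of the
    sign change; roots closer than ``merge_rtol`` times the concentration
    scale are merged into a single marginal (saddle-node) point.
    """
    if ctx.g <= 0:
        raise ValueError("find_fixed_points requires lam + delta > 0")
    pmin, pmax, decay = _production_bounds(spec, signal, ctx)
    x_hi = 1.001 * pmax / decay
    x_lo = 0.999 * pmin / decay

    def f(x):
        return reduced_rhs(spec, x, signal, ctx)

    roots: list[tuple[float, int]] = []
    if pmin == 0.0:
        # x = 0 may itself be a fixed point (no basal production)
        if abs(f(0.0)) == 0.0:
            eps = 1e-12 * x_hi
            roots.append((0.0, +1 if f(eps) < 0 else -1))
        x_lo = 1e-9 * x_hi
    grid = np.geomspace(max(x_lo, 1e-300), x_hi, n_grid)
    vals = np.asarray(reduced_rhs(spec, grid, signal, ctx))
    sign = np.sign(vals)
    # exact zeros on the grid count as roots
    for i in np.flatnonzero(sign == 0):
        roots.append((float(grid[i]), 0))
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if len(idx) == 0 and not roots:
        raise RuntimeError(
            f"no fixed point found on scan range [{grid[0]:.3g}, {grid[-1]:.3g}] "
            f"for kind={spec.kind!r} at signal={signal:g}"
        )
    for i in idx:
        r = brentq(f, grid[i], grid[i + 1], xtol=1e-14 * x_hi, rtol=8.9e-16)
        stab = +1 if vals[i] > 0 else -1
        roots.append((float(r), stab))
    roots.sort(key=lambda t: t[0])
    # merge near-coincident roots (saddle-node tangency)
    merged: list[tuple[float, int]] = []
    tol = merge_rtol * x_hi
    for r, s in roots:
        if merged and r - merged[-1][0] < tol:
            prev_r, prev_s = merged[-1]
            merged[-1] = ((prev_r + r) / 2.0, 0 if prev_s != s else prev_s)
        else:
            merged.append((r, s))
    return [FixedPoint(x=r, stability=s) for r, s in merged]


def stable_points(spec: ModelSpec, signal: float, ctx: GrowthContext, **kw) -> list[float]:
    return [fp.x for fp in find_fixed_points(spec, signal, ctx, **kw) if fp.stable]


# ---------------------------------------------------------------------------
# ODE integration oracle (un-reduced systems)
# ---------------------------------------------------------------------------

def _full_rhs(spec: ModelSpec, signal: float, ctx: GrowthContext) -> tuple[Callable, int]:
    """Vector field of the un-reduced system and its dimension.

    The autoactivator and protease switch are genuinely one-dimensional.
    The two-component model un-reduces the kinase-TF stoichiometry (kinase
    gets its own ODE, with phospho-transfer and dimerization at quasi-steady
    state); the lac model un-reduces the intracellular inducer.  Both share
    their steady states exactly with the reduced scalar system.
    """
    p = spec.params
    if spec.kind in ("autoactivator", "protease"):
        def f(t, x):
            return [reduced_rhs(spec, max(x[0], 0.0), signal, ctx)]
        return f, 1
    if spec.kind == "two_component":
        a = p.auto

        def f(t, state):
            x, kin = max(state[0], 0.0), max(state[1], 0.0)
            dimer = float(_two_component_dimer(p, x, kin, signal))
            prod = a.b + a.beta * float(_hill(dimer, a.K, a.n))
            return [prod - ctx.g * x, p.rho * prod - ctx.g * kin]
        return f, 2
    if spec.kind == "lac":
        def f(t, state):
            y, tau = max(state[0], 0.0), max(state[1], 0.0)
            y_prod = p.regulation.production(ctx)
            frac = p.leak + (1.0 - p.leak) * float(_hill(tau, p.k_tau(ctx.lam), p.n_tau))
            dy = y_prod * frac - ctx.g * y
            dtau = p.alpha_imp * y * signal - (ctx.g + p.k_hyd * y) * tau
            return [dy, dtau]
        return f, 2
    raise ValueError(spec.kind)  # pragma: no cover


def full_state(spec: ModelSpec, x: float, signal: float, ctx: GrowthContext) -> np.ndarray:
    """Full initial state with fast companions at their quasi-steady values."""
    if x < 0:
        raise ValueError("x must be >= 0")
    if spec.kind in ("autoactivator", "protease"):
        return np.array([x])
    if spec.kind == "two_component":
        return np.array([x, spec.params.rho * x])
    tau = float(_lac_inducer(spec.params, x, signal, ctx))
    return np.array([x, tau])


def integrate(
    spec: ModelSpec,
    x0: Sequence[float],
    t_grid: Sequence[float],
    signal: float,
    ctx: GrowthContext,
    *,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Integrate the un-reduced ODEs over ``t_grid`` (strictly increasing).

    Returns the trajectory with shape (len(t_grid), dim); the reduced
    coordinate (TF or LacY concentration) is column 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    f, dim = _full_rhs(spec, signal, ctx)
    if x0.shape != (dim,):
        raise ValueError(f"x0 must have shape ({dim},) for kind {spec.kind!r}")
    scale = max(_production_bounds(spec, signal, ctx)[1] / ctx.g, 1e-6)
    sol = solve_ivp(
        f, (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
        method="LSODA", rtol=rtol, atol=1e-10 * scale,
    )
    if not sol.success:  # pragma: no cover - solver failure is diagnostic
        raise RuntimeError(f"ODE integration failed: {sol.message} (nfev={sol.nfev})")
    return sol.y.T


def settle(
    spec: ModelSpec,
    x0: float,
    signal: float,
    ctx: GrowthContext,
    *,
    rhs_tol: float = 1e-9,
    max_chunks: int = 12,
) -> float:
    """Integrate from scalar initial concentration ``x0`` until the reduced
    derivative is below ``rhs_tol`` (relative to the production scale);
    returns the attractor's reduced coordinate."""
    state = full_state(spec, x0, signal, ctx)
    horizon = 30.0 / ctx.g
    scale = _production_bounds(spec, signal, ctx)[1]
    for _ in range(max_chunks):
        traj = integrate(spec, state, np.linspace(0.0, horizon, 8), signal, ctx)
        state = np.maximum(traj[-1], 0.0)
        if abs(reduced_rhs(spec, float(state[0]), signal, ctx)) < rhs_tol * scale:
            return float(state[0])
    raise RuntimeError(
        f"trajectory did not settle within {max_chunks} x {horizon:.3g} h "
        f"(|rhs| still {abs(reduced_rhs(spec, float(state[0]), signal, ctx)):.3g})"
    )


# ---------------------------------------------------------------------------
# closed-form lac threshold scaling (cross-check oracle)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _lac_dimensionless_boundaries(leak: float, n_tau: float) -> tuple[float, float]:
    """Saddle-node boundaries of u = leak + (1-leak) * (g u)^n / (1 + (g u)^n).

    ``u`` is LacY in units of its full-induction level and ``g`` the single
    dimensionless group alpha * y_prod * c / ((lam+delta)^2 * K_tau) that the
    gratuitous-inducer (k_hyd = 0) lac balance collapses onto.  Returns
    (g_low, g_high): the window of g values with three fixed points.
    """
    if not 0 < leak < 0.5:
        raise ValueError("closed-form boundaries require 0 < leak < 0.5")

    u = np.geomspace(leak * 0.999, 1.001, 4000)

    def n_roots(gamma: float) -> int:
        v = gamma * u
        f = leak + (1.0 - leak) * v ** n_tau / (1.0 + v ** n_tau) - u
        s = np.sign(f)
        return int(np.count_nonzero(s[:-1] * s[1:] < 0))

    gammas = np.geomspace(1e-3, 1e4, 600)
    counts = np.array([n_roots(g) for g in gammas])
    tri = np.flatnonzero(counts >= 3)
    if len(tri) == 0:
        raise ValueError(f"no bistable window for leak={leak}, n_tau={n_tau}")

    def bisect(lo: float, hi: float, want_three_at_hi: bool) -> float:
        for _ in range(80):
            mid = math.sqrt(lo * hi)
            if (n_roots(mid) >= 3) == want_three_at_hi:
                hi = mid
            else:
                lo = mid
        return math.sqrt(lo * hi)

    g_low = bisect(gammas[tri[0] - 1], gammas[tri[0]], True)
    g_high = bisect(gammas[tri[-1]], gammas[tri[-1] + 1], False)
    return g_low, g_high


def lac_threshold_relation(
    params: LacParams,
    ctx: GrowthContext,
    which: Literal["low", "high", "center"] = "center",
) -> float:
    """Closed-form critical external inducer concentration (µM).

    For a gratuitous inducer (``k_hyd = 0``) the reduced lac balance depends
    on the external concentration only through the dimensionless group
    ``alpha_imp * y_prod * c / ((lam+delta)^2 * K_tau)``, so the saddle-node
    boundaries obey exactly ``c = gamma * K_tau(lam) * (lam+delta)^2 /
    (alpha_imp * y_prod(lam))`` with gamma an O(1)-O(10) constant depending
    only on (leak, n_tau).  Used as a cross-check oracle for the numerical
    phase-boundary scan.
    """
    if params.k_hyd != 0:
        raise ValueError("closed-form threshold requires a gratuitous inducer (k_hyd = 0)")
    g_low, g_high = _lac_dimensionless_boundaries(params.leak, params.n_tau)
    gamma = {"low": g_low, "high": g_high, "center": math.sqrt(g_low * g_high)}[which]
    y_prod = params.regulation.production(ctx)
    return gamma * params.k_tau(ctx.lam) * ctx.g ** 2 / (params.alpha_imp * y_prod)
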