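"""Shared test utilities: random model draws and brute-force oracles."""

import math

import numpy as np

from gcswitch.models import (
    AutoactivatorParams,
    ConstantProduction,
    GrowthContext,
    LacParams,
    ModelSpec,
    ProteaseSwitchParams,
    TwoComponentParams,
    find_fixed_points,
    settle,
)

LN2 = math.log(2.0)


def random_switch_draw(kind: str, rng) -> tuple[ModelSpec, float]:
    """A random parameterization of one preset family plus a signal level."""
    if kind == "autoactivator":
        spec = ModelSpec(kind=kind, params=AutoactivatorParams(
            b=rng.uniform(0, 0.05), beta=10 ** rng.uniform(-1, 1),
            K=10 ** rng.uniform(-0.5, 0.5), n=float(rng.choice([1, 2, 3, 4]))))
        return spec, 0.0
    if kind == "protease":
        spec = ModelSpec(kind=kind, params=ProteaseSwitchParams(
            auto=AutoactivatorParams(b=rng.uniform(0, 0.05),
                                     beta=10 ** rng.uniform(-1, 1), K=1.0, n=2),
            delta_p=10 ** rng.uniform(-1, 0.5), s0=10 ** rng.uniform(-1, 1),
            h_p=float(rng.choice([1, 2, 4]))))
        return spec, 10 ** rng.uniform(-2, 2)
    if kind == "two_component":
        spec = ModelSpec(kind=kind, params=TwoComponentParams(
            auto=AutoactivatorParams(b=rng.uniform(0.01, 0.1), beta=1.0,
                                     K=10 ** rng.uniform(-2, 0), n=2),
            rho=10 ** rng.uniform(-0.5, 0.5), k_act=10 ** rng.uniform(0, 2),
            k_phos=10 ** rng.uniform(0, 2), k_deph=10 ** rng.uniform(-0.5, 1),
            K_D=10 ** rng.uniform(-1, 1)))
        return spec, 10 ** rng.uniform(-2, 2)
    spec = ModelSpec(kind="lac", params=LacParams(
        regulation=ConstantProduction(10 ** rng.uniform(-0.5, 0.5)),
        leak=10 ** rng.uniform(-3, -1.3), alpha_imp=10 ** rng.uniform(-1.5, 0),
        k_tau0=10 ** rng.uniform(0.5, 1.5), n_tau=float(rng.choice([2, 3]))))
    return spec, 10 ** rng.uniform(0, 3)


def stable_points_equal_attractors(spec: ModelSpec, signal: float,
                                   ctx: GrowthContext) -> bool:
    """Do the reduced system's stable fixed points coincide with the
    un-reduced ODE's attractors (basin-bracketing initial conditions)?"""
    fps = find_fixed_points(spec, signal, ctx)
    stable = sorted(fp.x for fp in fps if fp.stable)
    xs = [fp.x for fp in fps]
    ics = [0.5 * min(xs) if min(xs) > 0 else 1e-6, 2 * max(xs) + 1e-6]
    for a, b in zip(fps[:-1], fps[1:]):
        mid = math.sqrt(max(a.x, 1e-12) * b.x)
        ics += [mid * 1.01, mid * 0.99]
    attractors = {round(settle(spec, x0, signal, ctx), 8) for x0 in ics}
    scale = max(xs) + 1e-12
    tol = 1e-3 * scale + 1e-9
    return (all(any(abs(a - s) < tol for s in stable) for a in attractors)
            and all(any(abs(a - s) < tol for a in attractors) for s in stable))


def slope_posterior_by_grid(x, y, sigma_i, sigma, a_center, a_sd, b_center):
    """Brute-force posterior mean/SD of the slope by 2-D integration over
    (slope, intercept) at fixed total variance."""
    v = sigma ** 2 + np.asarray(sigma_i) ** 2
    a_g = np.linspace(a_center - 8 * a_sd, a_center + 8 * a_sd, 801)
    b_g = np.linspace(b_center - 5, b_center + 5, 801)
    A, B = np.meshgrid(a_g, b_g, indexing="ij")
    ll = -((np.asarray(y)[None, None, :] - A[..., None] * np.asarray(x)[None, None, :]
            - B[..., None]) ** 2 / (2 * v[None, None, :])).sum(-1)
    w = np.exp(ll - ll.max())
    pa = w.sum(axis=1)
    pa /= pa.sum()
    mean = float((a_g * pa).sum())
    sd = float(np.sqrt(((a_g - mean) ** 2 * pa).sum()))
    return mean, sd
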