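"""Versioned default parameter sets for the four switch presets.

The presets place each architecture in the physiological regime its
phenomenology calls for; they are calibrated constants, not fits to data:

* ``autoactivator`` — basal/maximal production ratio set so the feedback
  loop is bistable for doubling times between roughly 5 and 50 hours and
  stably on/off outside that window.
* ``protease_switch`` — the same operon with a signal-repressed protease;
  at intermediate signal the switch stays bistable out to growth arrest.
* ``two_component`` — calibrated so the bistability-onset signal scales as
  the inverse square of doubling time (100-fold drop per decade of doubling
  time) in the 1-10 h range, with mild phospho-transfer saturation at fast
  growth; below ~0.5 h doubling time the system is bistable for arbitrarily
  strong signal.
* ``lac`` — gratuitous-inducer (TMG-like) configuration: the unstable
  threshold separating induced from uninduced sits at ~0.2 µM LacY (a few
  hundred molecules at 2.5 fL) for 1-2 h doubling times, and the critical
  external inducer concentration is O(100 µM) at fast growth.

``DELTA_48H`` is the default molecular decay used with the lac and
two-component presets: a 48-hour protein/inducer half-life.
"""

from __future__ import annotations

import math

from .models import (
    AutoactivatorParams,
    CLine,
    ConstantProduction,
    LacParams,
    ModelSpec,
    ProteaseSwitchParams,
    RLine,
    TwoComponentParams,
)

PRESETS_VERSION = "1.0"

#: decay rate for a 48-hour molecular half-life (1/h)
DELTA_48H = math.log(2.0) / 48.0


def autoactivator() -> ModelSpec:
    return ModelSpec(
        kind="autoactivator",
        params=AutoactivatorParams(b=1.75e-4, beta=0.28, K=1.0, n=2),
    )


def protease_switch() -> ModelSpec:
    return ModelSpec(
        kind="protease",
        params=ProteaseSwitchParams(
            auto=AutoactivatorParams(b=1.75e-4, beta=0.28, K=1.0, n=2),
            delta_p=0.5,
            s0=1.0,
            h_p=2.0,
        ),
    )


def two_component() -> ModelSpec:
    return ModelSpec(
        kind="two_component",
        params=TwoComponentParams(
            auto=AutoactivatorParams(b=0.05, beta=1.0, K=0.07, n=2),
            rho=1.0,
            k_act=100.0,
            k_phos=50.0,
            k_deph=1.0,
            K_D=1.0,
        ),
    )


def lac(regulation=None, *, modulation: str = "nutrient", **overrides) -> ModelSpec:
    """lac preset; pass a regulation object or field overrides to vary it.

    Default regulation is a growth-rate-independent full-induction
    production rate of 1 µM/h (the simplest scenario, giving the quadratic
    critical-inducer scaling).
    """
    if regulation is None:
        regulation = ConstantProduction(y0=1.0)
    params = LacParams(regulation=regulation, **overrides)
    return ModelSpec(kind="lac", params=params, modulation=modulation)


#: lactose-operon import efficiency (1/(µM h) per µM LacY) used in the
#: C-line / sugar-preference context; calibrated so that the C-line fitted
#: against the inverse lactose Monod curve lands at the physiological scale
#: (full-induction concentration y0 ~ 70 µM at growth arrest)
ALPHA_LACTOSE = 0.00373


def lac_cline(y0: float = 62.3, lam_star: float = 0.7344) -> ModelSpec:
    """lac preset under catabolic (C-line) regulation; defaults near the
    values that make the bistable center track the inverse lactose Monod
    curve (see sugar.calibrate_cline)."""
    return lac(
        CLine(y0=y0, lam_star=lam_star),
        modulation="nutrient",
        alpha_imp=ALPHA_LACTOSE,
    )


def lac_rline(kappa: float = 10.0) -> ModelSpec:
    """lac preset under translation-inhibition (R-line) regulation."""
    return lac(RLine(kappa=kappa), modulation="translation")
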