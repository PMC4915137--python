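"""The canonical synthetic study session used by the analysis drivers.

Bundles the generator defaults into one reproducible "recording session":
the default checking agent, plus MCC and LPFC populations whose tuning
mixes emulate the reported area asymmetries — feedback and Check/Work
coding more prevalent and earlier in MCC, cued-side coding more prevalent
and earlier in LPFC, with a small MCC contingent carrying gauge and
distance-to-check signals between trials.  All spike counts are
overdispersed (NB dispersion 2) so the family-selection and OLRE machinery
is exercised under realistic conditions.
"""

from __future__ import annotations

import numpy as np

from .synth import (
    AREA_LATENCY_OFFSET,
    AgentPolicy,
    EffectSpec,
    SimulatedSession,
    TaskConfig,
    TuningSpec,
    simulate_session,
)

#: Fraction of units per area assigned to each factor (rest untuned).
#: MCC is feedback/check biased; LPFC is cued-side biased.
AREA_TUNING_MIX = {
    "MCC": (
        ("FEEDBACK", 0.35),
        ("CHECKWORK", 0.20),
        ("CUED_SIDE", 0.10),
        ("GAUGE", 0.05),
        ("DISTANCE_TO_CHECK", 0.05),
    ),
    "LPFC": (
        ("FEEDBACK", 0.15),
        ("CHECKWORK", 0.10),
        ("CUED_SIDE", 0.35),
        ("GAUGE", 0.03),
        ("DISTANCE_TO_CHECK", 0.02),
    ),
}

DEFAULT_AMPLITUDE_HZ = 9.0
DEFAULT_DURATION_S = 0.6
DEFAULT_DISPERSION = 2.0


def study_population(
    n_per_area: int = 40, seed: int | np.random.Generator = 0
) -> list[TuningSpec]:
    """Area-biased tuned populations with area-specific latencies."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    specs: list[TuningSpec] = []
    for area in ("MCC", "LPFC"):
        assignment: list[str | None] = []
        for factor, frac in AREA_TUNING_MIX[area]:
            assignment += [factor] * int(round(frac * n_per_area))
        assignment += [None] * (n_per_area - len(assignment))
        for i, factor in enumerate(assignment):
            effects: tuple[EffectSpec, ...] = ()
            if factor is not None:
                sign = 1.0 if rng.random() < (0.7 if factor == "CHECKWORK" else 0.5) else -1.0
                latency = AREA_LATENCY_OFFSET[(area, factor)]
                if factor == "CHECKWORK":
                    # anticipatory build-up toward the decision to check
                    latency, duration = -0.6 + latency, 1.0
                elif factor in ("GAUGE", "DISTANCE_TO_CHECK"):
                    duration = 1.6
                else:
                    duration = DEFAULT_DURATION_S
                effects = (
                    EffectSpec(
                        factor=factor,
                        amplitude_hz=sign * DEFAULT_AMPLITUDE_HZ,
                        latency_s=latency,
                        duration_s=duration,
                    ),
                )
            specs.append(
                TuningSpec(
                    unit_id=f"{area}_{i:03d}",
                    area=area,
                    baseline_rate_hz=float(rng.uniform(2.0, 12.0)),
                    dispersion=DEFAULT_DISPERSION,
                    effects=effects,
                )
            )
    return specs


def build_study_session(
    seed: int = 0,
    n_blocks: int = 30,
    n_per_area: int = 40,
    with_gaze: bool = True,
) -> SimulatedSession:
    """Simulate the full canonical session from one seed."""
    rng = np.random.default_rng(seed)
    tuning = study_population(n_per_area, rng)
    return simulate_session(
        config=TaskConfig(n_blocks=n_blocks),
        policy=AgentPolicy(),
        tuning=tuning,
        seed=seed,
        with_gaze=with_gaze,
    )
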