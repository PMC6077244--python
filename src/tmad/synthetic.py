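"""Seeded synthetic expirograms emulating real-time sensor recordings.

The generator simulates a clean expirogram with the transport model, then
resamples it at the sensor acquisition interval (default 0.14 s) and adds
independent Gaussian measurement noise at the sensor precision (default
2 ppb).  Optionally the recorded flow channel is perturbed with jitter and
half-cosine start/end ramps to mimic the transients of subject-controlled
exhalation.  Everything is deterministic for a given seed.

These traces emulate the *statistical* character of measured expirograms
(sampling, precision, flow transients); they inherit the model's geometry
and physics, so recovery tests on them probe estimator behaviour, not
model adequacy against real lungs.
"""

from __future__ import annotations

import numpy as np

from .maneuver import BreathManeuver, Expirogram, run_maneuver
from .morphometry import TrumpetGrid
from .physiology import ExchangeParams
from .io import SensorModel
from .solver import NumericsConfig

__all__ = ["generate_synthetic_expirogram"]


def generate_synthetic_expirogram(
    grid: TrumpetGrid,
    params: ExchangeParams,
    maneuver: BreathManeuver,
    sensor: SensorModel | None = None,
    seed: int | None = None,
    numerics: NumericsConfig | None = None,
) -> Expirogram:
    """Simulate one maneuver and degrade it to sensor-like data.

    Returns an :class:`Expirogram` sampled at the sensor interval with
    additive Gaussian noise; the clean resampled concentrations are kept in
    ``metadata["clean_co_ppb"]`` for recovery studies.
    """
    sensor = sensor or SensorModel()
    numerics = numerics or NumericsConfig()
    rng = np.random.default_rng(seed)
    clean, _ = run_maneuver(grid, params, maneuver, numerics)

    t = np.arange(0.0, clean.time_s[-1] + 1e-12, sensor.sampling_interval_s)
    co_clean = np.interp(t, clean.time_s, clean.co_ppb)
    co = co_clean + rng.normal(0.0, sensor.noise_sd_ppb, size=t.size) \
        if sensor.noise_sd_ppb > 0 else co_clean.copy()

    flow = np.full(t.size, maneuver.EFR)
    if sensor.flow_ramp_s > 0:
        ramp = sensor.flow_ramp_s
        rise = t < ramp
        flow[rise] *= 0.5 * (1 - np.cos(np.pi * t[rise] / ramp))
        fall = t > t[-1] - ramp
        flow[fall] *= 0.5 * (1 - np.cos(np.pi * (t[-1] - t[fall]) / ramp))
    if sensor.flow_jitter_sd_ml_s > 0:
        flow = np.clip(
            flow + rng.normal(0.0, sensor.flow_jitter_sd_ml_s, size=t.size),
            0.0, None,
        )

    return Expirogram(
        time_s=t,
        volume_ml=np.interp(t, clean.time_s, clean.volume_ml),
        co_ppb=co,
        flow_ml_s=flow,
        maneuver=maneuver,
        params=params,
        metadata={
            "synthetic": True,
            "seed": seed,
            "sensor": sensor,
            "clean_co_ppb": co_clean,
        },
    )
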