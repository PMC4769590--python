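"""Bundled case fixtures and synthetic noisy observation series.

The fixture library ships the published parameter sets for the five
rat-rhabdomyosarcoma dose levels and the five radiosurgery cases as
versioned JSON (``data/``).  `synthesize_observations` turns any config
into a noisy volume series for fitting and recovery tests; the raw animal
measurements exist only as a figure, so synthetic series stand in for
them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .fitting import VolumeSeries
from .simulator import CaseConfig, simulate

__all__ = [
    "NoiseSpec",
    "rat_case_configs",
    "clinical_case_configs",
    "all_case_configs",
    "synthesize_observations",
]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model for synthetic volume series.

    mode "multiplicative_lognormal": each volume is multiplied by a
    lognormal factor with unit mean and coefficient of variation ``cv``
    (volume errors scale with size for both caliper and MRI readings).

    mode "sphere_radius": the radius of the equivalent sphere is
    perturbed uniformly within +/- ``dr_mm`` millimetres and the volume
    recomputed — the MRI-style uncertainty of a +/-1 mm contour error.
    """

    mode: str = "multiplicative_lognormal"
    cv: float = 0.0
    dr_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("multiplicative_lognormal", "sphere_radius"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.dr_mm < 0:
            raise ValueError("dr_mm must be >= 0")


def _load_fixture(name: str) -> list[CaseConfig]:
    text = resources.files("radkin.data").joinpath(name).read_text()
    payload = json.loads(text)
    return [CaseConfig.from_dict(d) for d in payload["cases"]]


def rat_case_configs() -> list[CaseConfig]:
    """The five rat-rhabdomyosarcoma configs (control, 10/20/30/40 Gy)."""
    return _load_fixture("rat_cases.json")


def clinical_case_configs() -> list[CaseConfig]:
    """The five radiosurgery case configs, with local-control metadata."""
    return _load_fixture("clinical_cases.json")


def all_case_configs() -> list[CaseConfig]:
    return rat_case_configs() + clinical_case_configs()


def equivalent_sphere_radius_cm(volume_cm3) -> np.ndarray | float:
    """Radius, cm, of the sphere with the given volume."""
    v = np.asarray(volume_cm3, dtype=float)
    r = (v / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    return r.item() if r.ndim == 0 else r


def synthesize_observations(
    config: CaseConfig, times, noise: NoiseSpec
) -> VolumeSeries:
    """Simulate ``config`` on ``times`` and perturb per the noise spec.

    Deterministic given ``noise.seed``; zero cv / dr_mm reproduces the
    exact model values.  In sphere mode the per-point ``sigma`` column is
    filled with the half-width of the +/- dr_mm volume band.
    """
    times = np.asarray(times, dtype=float)
    traj = simulate(config, times)
    true_v = traj.v_total
    rng = np.random.default_rng(noise.seed)

    if noise.mode == "multiplicative_lognormal":
        if noise.cv == 0.0:
            return VolumeSeries(times=times, volumes=true_v.copy())
        # lognormal factor with unit mean and CV = cv
        s2 = math.log1p(noise.cv**2)
        factors = rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=times.size)
        return VolumeSeries(times=times, volumes=true_v * factors)

    # sphere_radius mode
    dr_cm = noise.dr_mm / 10.0
    r = equivalent_sphere_radius_cm(true_v)
    if dr_cm == 0.0:
        return VolumeSeries(times=times, volumes=true_v.copy())
    perturbed_r = np.maximum(r + rng.uniform(-dr_cm, dr_cm, size=times.size), 1e-6)
    volumes = _FOUR_THIRDS_PI * perturbed_r**3
    hi = _FOUR_THIRDS_PI * (r + dr_cm) ** 3
    lo = _FOUR_THIRDS_PI * np.maximum(r - dr_cm, 0.0) ** 3
    sigma = 0.5 * (hi - lo)
    return VolumeSeries(times=times, volumes=volumes, sigma=sigma)
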