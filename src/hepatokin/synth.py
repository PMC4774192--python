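"""Synthetic surrogates for the external inputs of the analysis.

The measured diurnal plasma-glucose profiles, the pooled glucose-hormone
scatter used to fit the GHT curves, and the random enzyme-abundance
samples are all generated here as pure functions of (spec, seed), so
every downstream stage (diurnal ensembles, regulation-mode dissection,
control analysis) runs without external data.  The diurnal profiles are
synthetic stand-ins that reproduce the qualitative features of measured
rat profiles (fed: meal excursions spanning the fed set point; fasted:
flat low-normal glucose; diabetic: persistent hyperglycemia above
14 mM), not the measured traces themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import DEFAULT_ABUNDANCE, AbundanceTable
from .hormones import GHTParams

__all__ = ["ProfileSpec", "ScatterSpec", "gen_diurnal_glucose",
           "sample_abundance_ratios", "gen_ght_scatter", "PROFILE_DEFAULTS"]


@dataclass(frozen=True)
class ProfileSpec:
    """Shape of a synthetic 24-h plasma glucose profile.

    Meal pulses are smooth Gaussian excursions (times in h, widths in h,
    heights in mM) on top of a baseline with a slow sinusoidal
    modulation of the given amplitude.  Noise is a smooth random
    modulation with the given standard deviation.
    """

    condition: str  # fed | fasted | diabetic
    baseline: float  # mM
    amplitude: float = 0.0  # mM, slow sinusoidal modulation
    meal_times: tuple = ()
    meal_widths: tuple = ()
    meal_heights: tuple = ()
    noise_sd: float = 0.0  # mM
    n_points: int = 97

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline glucose must be > 0")
        if not (len(self.meal_times) == len(self.meal_widths)
                == len(self.meal_heights)):
            raise ValueError("meal pulse fields must have equal length")


# Default study conditions.  Fed rats (nocturnal feeders) show meal
# excursions from ~5.8 up to ~8.5 mM crossing the fed set point; fasted
# rats sit in a narrow low-normal band around 4.2 mM; untreated diabetic
# rats remain persistently above 14 mM with blunted excursions.
PROFILE_DEFAULTS: dict[str, ProfileSpec] = {
    "fed": ProfileSpec("fed", baseline=5.8, amplitude=0.3,
                       meal_times=(2.0, 10.0, 20.0),
                       meal_widths=(1.5, 1.5, 1.2),
                       meal_heights=(2.6, 2.2, 1.6)),
    "fasted": ProfileSpec("fasted", baseline=4.2, amplitude=0.4),
    "diabetic": ProfileSpec("diabetic", baseline=16.5, amplitude=0.8,
                            meal_times=(2.0, 10.0),
                            meal_widths=(1.8, 1.8),
                            meal_heights=(2.0, 1.6)),
}


def gen_diurnal_glucose(spec: ProfileSpec | str, seed: int | None = None,
                        noise_sd: float | None = None):
    """Generate a smooth positive 24-h plasma glucose profile.

    Returns (time_h, glucose_mM) arrays; the profile is periodic
    (endpoints match).  A string spec selects the defaults for that
    condition.  Same (spec, seed) -> identical profile.
    """
    if isinstance(spec, str):
        spec = PROFILE_DEFAULTS[spec]
    sd = spec.noise_sd if noise_sd is None else noise_sd
    t = np.linspace(0.0, 24.0, spec.n_points)
    g = spec.baseline + spec.amplitude * np.sin(2 * np.pi * (t - 6.0) / 24.0)
    for tm, w, h in zip(spec.meal_times, spec.meal_widths, spec.meal_heights):
        # periodic distance so pulses near midnight wrap smoothly
        dt = np.minimum(np.abs(t - tm), 24.0 - np.abs(t - tm))
        g = g + h * np.exp(-0.5 * (dt / w) ** 2)
    if sd > 0:
        rng = np.random.default_rng(seed)
        # smooth periodic noise from a few random Fourier modes
        phase = rng.uniform(0, 2 * np.pi, size=3)
        coef = rng.normal(size=3)
        coef *= sd / max(np.sqrt(np.sum(coef ** 2) / 2), 1e-12)
        for k, (c, ph) in enumerate(zip(coef, phase), start=1):
            g = g + c * np.sin(2 * np.pi * k * t / 24.0 + ph)
    g[-1] = g[0]
    if np.any(g <= 0):
        raise ValueError("profile spec produced nonpositive glucose")
    if spec.condition == "diabetic" and g.min() <= 14.0:
        raise ValueError("diabetic profile must stay above 14 mM")
    return t, g


def sample_abundance_ratios(table: AbundanceTable = DEFAULT_ABUNDANCE,
                            state: str = "fasted",
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            reaction_ids=None) -> dict[str, float]:
    """Draw one abundance-ratio vector for a physiological state.

    Independent uniform draws within each enzyme's reported [min, max]
    range; enzymes without a range keep the fixed mean.  Pass ``rng`` to
    draw several samples from one seeded generator.
    """
    if state == "fed":
        raise ValueError("the fed state is the reference; nothing to sample")
    if state not in ("normal", "fasted", "diabetic"):
        raise ValueError(f"unknown physiological state {state!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if reaction_ids is None:
        reaction_ids = sorted(table.entries)
    out = {}
    for rid in reaction_ids:
        rng_range = table.range(rid, state) if table.has_entry(rid) else None
        if rng_range is None:
            out[rid] = table.alpha(rid, state) if table.has_entry(rid) else 1.0
        else:
            lo, hi = rng_range
            out[rid] = float(rng.uniform(lo, hi))
    return out


@dataclass(frozen=True)
class ScatterSpec:
    """Synthetic glucose-hormone scatter around a known transfer curve."""

    true_params: GHTParams
    n: int = 50
    glucose_range: tuple[float, float] = (2.0, 20.0)
    relative_noise: float = 0.1

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("need at least 8 scatter points")
        if self.relative_noise < 0:
            raise ValueError("noise must be >= 0")


def gen_ght_scatter(spec: ScatterSpec, seed: int | None = None) -> pd.DataFrame:
    """Points on the true GHT curve with multiplicative noise.

    Returns a DataFrame with columns glucose_mM, hormone_pM, hormone.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.glucose_range
    g = np.linspace(lo, hi, spec.n)
    y = spec.true_params(g)
    if spec.relative_noise > 0:
        y = y * (1.0 + spec.relative_noise * rng.standard_normal(spec.n))
        y = np.maximum(y, 0.0)
    return pd.DataFrame({"glucose_mM": g, "hormone_pM": y,
                         "hormone": spec.true_params.hormone})
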