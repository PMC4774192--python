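"""Glucose-hormone transfer (GHT) functions and the phosphorylation signal.

Plasma insulin and glucagon are driven by plasma glucose through
empirical Hill-type transfer curves (the GHT functions): insulin rises
with glucose, glucagon falls.  The diabetic variant scales insulin to
10 % and glucagon to 200 % of the normal curves, the experimentally
reported impairment of the portal hormone levels in type-2 diabetic
rats.

The hormone pair is mapped onto the phosphorylated fraction
gamma in [0, 1] of the interconvertible enzymes by a single empirical
signal function: glucagon drives gamma toward 1, insulin toward 0, with
saturation at hormone levels of 1e5 pM.  One gamma function is shared by
all phospho-regulated enzymes.  All hormone levels are in pM, glucose in
mM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GHTParams", "GammaParams", "HormonePair", "ght", "gamma",
    "gamma_at_glucose", "GHTModel", "GHTFitResult", "fit_ght",
    "NORMAL_GHT", "DIABETIC_GHT", "DEFAULT_GAMMA",
]

SATURATING_HORMONE = 1e5  # pM


@dataclass(frozen=True)
class HormonePair:
    """Plasma insulin and glucagon levels, pM."""

    insulin: float
    glucagon: float

    def __post_init__(self):
        if self.insulin < 0 or self.glucagon < 0:
            raise ValueError("hormone levels must be >= 0")


@dataclass(frozen=True)
class GHTParams:
    """Hill-type glucose->hormone transfer curve for one hormone.

    rising  (insulin):  y(g) = basal + amplitude * g^h / (K^h + g^h)
    falling (glucagon): y(g) = basal + amplitude * K^h / (K^h + g^h)
    """

    hormone: str
    basal: float  # pM
    amplitude: float  # pM
    half_saturation: float  # mM glucose
    hill: float
    direction: str  # "rising" | "falling"
    variant: str = "normal"

    def __post_init__(self):
        if self.basal < 0 or self.amplitude < 0:
            raise ValueError("hormone levels must be >= 0")
        if self.half_saturation <= 0 or self.hill <= 0:
            raise ValueError("half-saturation and Hill exponent must be > 0")
        if self.direction not in ("rising", "falling"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __call__(self, glucose_mM):
        g = np.asarray(glucose_mM, dtype=float)
        if np.any(g <= 0):
            raise ValueError("plasma glucose must be > 0")
        x = g ** self.hill
        k = self.half_saturation ** self.hill
        frac = x / (k + x) if self.direction == "rising" else k / (k + x)
        return self.basal + self.amplitude * frac


# Normal-state transfer curves (pM, mM); calibrated so that the fitted
# curves run through the physiological portal levels of the rat:
# insulin low (~40 pM) in hypoglycemia and near 800 pM in hyperglycemia,
# glucagon ~190 pM in hypoglycemia falling to ~30 pM basal.
NORMAL_GHT: dict[str, GHTParams] = {
    "insulin": GHTParams("insulin", basal=20.0, amplitude=800.0,
                         half_saturation=8.0, hill=3.0, direction="rising"),
    "glucagon": GHTParams("glucagon", basal=30.0, amplitude=160.0,
                          half_saturation=7.46, hill=4.0, direction="falling"),
}

# Diabetic impairment: portal insulin reduced to about 10 %, portal
# glucagon increased to almost 200 % of the normal levels.
DIABETIC_GHT: dict[str, GHTParams] = {
    "insulin": replace(NORMAL_GHT["insulin"], basal=2.0, amplitude=80.0,
                       variant="diabetic"),
    "glucagon": replace(NORMAL_GHT["glucagon"], basal=60.0, amplitude=320.0,
                        variant="diabetic"),
}

_VARIANTS = {"normal": NORMAL_GHT, "diabetic": DIABETIC_GHT}


def ght(glucose_mM: float, variant: str = "normal") -> HormonePair:
    """Plasma hormone levels on the fitted transfer curves.

    The fed/fasted/normal physiological states share the normal curves;
    the diabetic state uses the impaired variant.
    """
    if glucose_mM <= 0:
        raise ValueError(f"plasma glucose must be > 0, got {glucose_mM}")
    if variant in ("fed", "fasted"):  # abundance states share normal GHT
        variant = "normal"
    try:
        curves = _VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown GHT variant {variant!r}") from None
    return HormonePair(insulin=float(curves["insulin"](glucose_mM)),
                       glucagon=float(curves["glucagon"](glucose_mM)))


@dataclass(frozen=True)
class GammaParams:
    """Signal function mapping (insulin, glucagon) -> phosphorylated share.

    gamma(I, G) = [g0 + (1 - g0) * G^hg / (KG^hg + G^hg)]
                  / (1 + (I / KI)^hi)

    monotone increasing in glucagon G, decreasing in insulin I, bounded
    by [0, 1]; g0 is the hormone-free basal phosphorylation.
    """

    basal: float = 0.3757  # g0
    k_glucagon: float = 130.0  # KG, pM
    hill_glucagon: float = 2.0  # hg
    k_insulin: float = 355.0  # KI, pM
    hill_insulin: float = 2.0  # hi

    def __call__(self, insulin: float, glucagon: float) -> float:
        if insulin < 0 or glucagon < 0:
            raise ValueError("hormone levels must be >= 0")
        xg = (glucagon / self.k_glucagon) ** self.hill_glucagon
        act = self.basal + (1.0 - self.basal) * xg / (1.0 + xg)
        sup = 1.0 + (insulin / self.k_insulin) ** self.hill_insulin
        return act / sup


DEFAULT_GAMMA = GammaParams()


def gamma(hormones: HormonePair, params: GammaParams = DEFAULT_GAMMA) -> float:
    """Phosphorylated enzyme fraction for a hormone pair."""
    return params(hormones.insulin, hormones.glucagon)


def gamma_at_glucose(glucose_mM: float, variant: str = "normal",
                     params: GammaParams = DEFAULT_GAMMA) -> float:
    """gamma at the hormone levels the GHT curves assign to a glucose level."""
    return gamma(ght(glucose_mM, variant), params)


# -- least-squares fitting of GHT curves --------------------------------


class GHTFitResult:
    """Least-squares fit of one GHT branch.

    Carries the fitted :class:`GHTParams`, the residual sum of squares,
    asymptotic standard errors from the Jacobian at the optimum, and a
    plain-text ``summary()``.
    """

    PARAM_NAMES = ("basal", "amplitude", "half_saturation", "hill")

    def __init__(self, model: "GHTModel", params: GHTParams, rss: float,
                 jac: np.ndarray):
        self.model = model
        self.params = params
        self.rss = float(rss)
        self.nobs = len(model.glucose)
        dof = max(self.nobs - len(self.PARAM_NAMES), 1)
        self.scale = self.rss / dof
        jtj = jac.T @ jac
        try:
            cov = self.scale * np.linalg.inv(jtj)
            self.bse = dict(zip(self.PARAM_NAMES, np.sqrt(np.diag(cov))))
        except np.linalg.LinAlgError:
            self.bse = dict.fromkeys(self.PARAM_NAMES, np.nan)

    def predict(self, glucose_mM):
        return self.params(glucose_mM)

    def summary(self) -> str:
        lines = [
            f"GHT fit: {self.params.hormone} ({self.params.direction}), "
            f"n = {self.nobs}",
            f"residual sum of squares = {self.rss:.6g}",
            f"{'parameter':<16}{'estimate':>12}{'std err':>12}",
        ]
        for name in self.PARAM_NAMES:
            lines.append(f"{name:<16}{getattr(self.params, name):>12.5g}"
                         f"{self.bse[name]:>12.3g}")
        return "\n".join(lines)


class GHTModel:
    """Hill-curve model for one hormone branch of the GHT function.

    Parameters
    ----------
    glucose, hormone : arrays of observed (glucose mM, hormone pM) pairs
    hormone_name : "insulin" or "glucagon" (fixes the direction unless
        ``direction`` is given explicitly)
    """

    def __init__(self, glucose, hormone, hormone_name: str = "insulin",
                 direction: str | None = None):
        self.glucose = np.asarray(glucose, dtype=float)
        self.hormone = np.asarray(hormone, dtype=float)
        if self.glucose.shape != self.hormone.shape or self.glucose.ndim != 1:
            raise ValueError("glucose and hormone must be 1-D and equal length")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose values must be > 0")
        if len(self.glucose) < 4:
            raise ValueError("need at least 4 points to fit 4 parameters")
        if np.ptp(self.glucose) == 0:
            raise ValueError("degenerate data: all glucose values identical")
        self.hormone_name = hormone_name
        if direction is None:
            direction = "rising" if hormone_name == "insulin" else "falling"
        self.direction = direction

    def _predict(self, theta, g):
        b, a, k, h = theta
        x = g ** h
        kh = k ** h
        frac = x / (kh + x) if self.direction == "rising" else kh / (kh + x)
        return b + a * frac

    def fit(self) -> GHTFitResult:
        """Nonlinear least squares with five deterministic multi-starts.

        Ties are broken by lowest residual, then lowest Hill exponent.
        """
        g, y = self.glucose, self.hormone
        span = max(np.ptp(y), 1e-9)
        base = float(y.min())
        gmid = float(np.median(g))
        starts = [
            (base, span, gmid, 1.0),
            (base, span, gmid, 2.0),
            (base, span, gmid, 4.0),
            (base, 2 * span, 0.5 * gmid, 2.0),
            (0.5 * base + 1e-9, span, 1.5 * gmid, 3.0),
        ]
        lower = [0.0, 0.0, 1e-3, 0.2]
        upper = [np.inf, np.inf, 1e3, 12.0]
        best = None
        for theta0 in starts:
            theta0 = np.clip(theta0, lower, upper)
            sol = least_squares(lambda th: self._predict(th, g) - y, theta0,
                                bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
            rss = float(2 * sol.cost)
            key = (round(rss, 10), sol.x[3])
            if best is None or key < best[0]:
                best = (key, sol)
        sol = best[1]
        params = GHTParams(self.hormone_name, *map(float, sol.x),
                           direction=self.direction, variant="fitted")
        return GHTFitResult(self, params, 2 * sol.cost, sol.jac)


def fit_ght(glucose, hormone, hormone_name: str = "insulin",
            direction: str | None = None) -> GHTFitResult:
    """Fit one GHT branch to scatter data (thin wrapper over GHTModel)."""
    return GHTModel(glucose, hormone, hormone_name, direction).fit()
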