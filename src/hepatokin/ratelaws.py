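"""Modular enzyme-kinetic rate laws.

Every reaction rate is composed multiplicatively from

* a saturable core (reversible Michaelis-Menten form or a carrier /
  antiporter form for membrane transport),
* optional allosteric saturation factors, one per effector, each a
  function of X = E/p only (E effector concentration, p its binding
  constant),
* for interconvertible enzymes a phospho-pair: the overall rate is the
  weighted linear combination gamma * v_phospho + (1-gamma) * v_dephospho
  of the rates of the phosphorylated and dephosphorylated enzyme forms,
* an optional glycogen-store structural factor that makes glycogen
  synthesis stall at a full store.

Rates are in umol/g/h once multiplied by Vmax; concentrations in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AllostericTerm", "PhosphoForm", "RateLaw"]


@dataclass(frozen=True)
class AllostericTerm:
    """Multiplicative effector saturation factor.

    The factor depends on the effector concentration E only through
    X = E/p with binding constant p (mM) and Hill exponent h:

    * activator:  f(X) = (a0 + X^h) / (1 + X^h)   rising from a0 to 1
    * inhibitor:  f(X) = (1 + a0*X^h) / (1 + X^h) falling from 1 to a0

    with basal level 0 <= a0 < 1.  Both forms are positive, bounded by 1
    and monotone in the effector concentration.
    """

    effector: str
    binding_constant: float  # p, mM
    hill: float = 1.0
    mode: str = "activator"
    basal: float = 0.0  # a0

    def __post_init__(self):
        if self.binding_constant <= 0:
            raise ValueError(
                f"allosteric binding constant for {self.effector} must be > 0"
            )
        if self.mode not in ("activator", "inhibitor"):
            raise ValueError(f"unknown allosteric mode {self.mode!r}")
        if not 0 <= self.basal < 1:
            raise ValueError("basal activity must lie in [0, 1)")

    def factor(self, effector_conc: float,
               binding_constant: float | None = None) -> float:
        """Evaluate the saturation factor at one effector concentration."""
        if effector_conc < 0:
            raise ValueError(f"negative effector concentration for "
                             f"{self.effector}")
        p = self.binding_constant if binding_constant is None else binding_constant
        if p <= 0:
            raise ValueError("binding constant must be > 0")
        x = (effector_conc / p) ** self.hill
        if self.mode == "activator":
            return (self.basal + x) / (1.0 + x)
        return (1.0 + self.basal * x) / (1.0 + x)


@dataclass(frozen=True)
class PhosphoForm:
    """Kinetics of one form (phosphorylated or not) of an enzyme.

    ``vmax_scale`` multiplies the reference Vmax; ``km_scale`` multiplies
    every substrate binding constant of the core.
    """

    vmax_scale: float = 1.0
    km_scale: float = 1.0


@dataclass
class RateLaw:
    """Fully parameterized kinetic law of one reaction.

    Parameters
    ----------
    form : {"saturable", "carrier"}
        "saturable" is a generalized reversible Michaelis-Menten law;
        "carrier" a (possibly antiport) facilitated-diffusion law in
        which substrates[i] and products[i] are the two faces of the
        membrane for the i-th transported couple.
    substrates, products : dict
        species id -> (Km in mM, Hill exponent).  A bare float is read
        as Km with exponent 1.
    keq : float or None
        Apparent equilibrium constant on the Km-scaled concentrations;
        None marks the reaction irreversible (no reverse numerator term,
        listed products still bind competitively).
    vmax_fed : float
        Reference maximal rate, umol/g/h, fed state.
    """

    form: str
    substrates: dict
    products: dict
    vmax_fed: float
    keq: float | None = None
    allosteric: list[AllostericTerm] = field(default_factory=list)
    phospho: dict[str, PhosphoForm] | None = None
    store_capacity: float | None = None  # mM glucosyl units; GS only
    store_species: str = "Glyc"
    store_exponent: float = 4.0

    def __post_init__(self):
        if self.form not in ("saturable", "carrier"):
            raise ValueError(f"unknown rate-law form {self.form!r}")
        self.substrates = {k: self._norm(v) for k, v in self.substrates.items()}
        self.products = {k: self._norm(v) for k, v in self.products.items()}
        if self.form == "carrier" and len(self.substrates) != len(self.products):
            raise ValueError("carrier form needs equally many substrates "
                             "and products (transported couples)")
        if self.phospho is not None:
            missing = {"phospho", "dephospho"} - set(self.phospho)
            if missing:
                raise ValueError(f"phospho pair incomplete: missing {missing}")

    @staticmethod
    def _norm(v):
        if isinstance(v, (tuple, list)):
            km, h = float(v[0]), float(v[1])
        else:
            km, h = float(v), 1.0
        if km <= 0:
            raise ValueError("binding constant must be > 0")
        return km, h

    @property
    def is_phospho_pair(self) -> bool:
        return self.phospho is not None

    # -- core kinetics -------------------------------------------------

    def _core(self, conc: dict, km_scale: float = 1.0) -> float:
        """Saturable/carrier core, dimensionless, in (-1, 1)."""
        if self.form == "carrier":
            drive_f = drive_r = 1.0
            den = 1.0
            for (s, (km, _)), (p, _kmp) in zip(self.substrates.items(),
                                               self.products.items()):
                km = km * km_scale
                xs, xp = conc[s] / km, conc[p] / km
                drive_f *= xs
                drive_r *= xp
                den *= 1.0 + xs + xp
            return (drive_f - drive_r) / den

        num_f, den_s = 1.0, 1.0
        for s, (km, h) in self.substrates.items():
            x = (conc[s] / (km * km_scale)) ** h
            num_f *= x
            den_s *= 1.0 + x
        num_r, den_p = 1.0, 1.0
        for p, (km, h) in self.products.items():
            x = (conc[p] / km) ** h
            num_r *= x
            den_p *= 1.0 + x
        num = num_f if self.keq is None else num_f - num_r / self.keq
        return num / (den_s + den_p - 1.0)

    def allosteric_product(self, conc: dict,
                           frozen: dict | None = None) -> float:
        """Product of all effector saturation factors.

        ``frozen`` maps effector id -> fixed numeric factor, replacing
        the live term (used for regulation-depleted model variants).
        """
        f = 1.0
        for term in self.allosteric:
            if frozen is not None and term.effector in frozen:
                f *= frozen[term.effector]
            else:
                f *= term.factor(conc[term.effector])
        return f

    def _store_factor(self, conc: dict) -> float:
        if self.store_capacity is None:
            return 1.0
        fill = conc[self.store_species] / self.store_capacity
        return max(0.0, 1.0 - fill ** self.store_exponent)

    def rate(self, conc: dict, gamma: float = 0.0, alpha: float = 1.0,
             frozen_allosteric: dict | None = None) -> float:
        """Reaction rate in umol/g/h.

        gamma is the phosphorylated fraction; it is ignored for enzymes
        without a phospho pair.  alpha scales Vmax (abundance ratio).
        """
        if not 0.0 <= gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
        shared = (alpha * self.vmax_fed
                  * self.allosteric_product(conc, frozen_allosteric)
                  * self._store_factor(conc))
        if self.phospho is None:
            return shared * self._core(conc)
        fp, fd = self.phospho["phospho"], self.phospho["dephospho"]
        v_p = fp.vmax_scale * self._core(conc, fp.km_scale)
        v_d = fd.vmax_scale * self._core(conc, fd.km_scale)
        return shared * (gamma * v_p + (1.0 - gamma) * v_d)

    def parameter_names(self) -> list[str]:
        """Names of the perturbable kinetic parameters of this law."""
        names = ["vmax"]
        names += [f"km:{s}" for s in self.substrates]
        names += [f"km:{p}" for p in self.products]
        names += [f"ka:{t.effector}" for t in self.allosteric]
        if self.phospho is not None:
            names.append("gamma")
        return names
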