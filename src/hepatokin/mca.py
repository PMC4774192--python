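"""Metabolic control analysis of the glucose exchange flux.

Flux control coefficients C_i quantify the relative change of the
stationary glucose exchange flux v_ex per relative change of the amount
of the enzyme catalyzing reaction i; by the summation theorem they add
up to one.  pi-elasticities quantify the relative sensitivity of an
isolated enzyme's rate to one of its kinetic parameters (exactly 1 for
the enzyme's own abundance); epsilon-elasticities refer to effector
concentrations, and for a parameter entering the rate law only through
the ratio E_k/p_k the two coincide up to sign.  Response coefficients
factorize as R_ik = C_i * pi_ik.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hormones import DEFAULT_GAMMA, GammaParams
from .network import MetabolicNetwork
from .ratelaws import RateLaw
from .simulate import (ClampSet, ConvergenceError, SteadyStateResult,
                       state_alphas, steady_state)

__all__ = [
    "ControlTable", "ElasticityTable", "ResponseTable",
    "control_coefficients", "pi_elasticity", "epsilon_elasticity",
    "elasticity_table", "response_coefficients", "relative_elasticities",
    "diurnal_control", "KEY_CONTROL_THRESHOLD",
]

#: |C_i| above this in at least one canonical state marks a key enzyme
KEY_CONTROL_THRESHOLD = 0.1

#: |v_ex| below this floor (umol/g/h) makes control coefficients
#: non-reportable (they diverge at the glucose set point)
VEX_FLOOR = 1.0


@dataclass
class ControlTable:
    """Flux control coefficients of v_ex at one reference state."""

    table: pd.DataFrame  # index reaction id, column "C"
    v_ex: float
    perturbation: float
    state: str
    clamps: ClampSet

    @property
    def summation(self) -> float:
        return float(self.table["C"].sum())

    def key_enzymes(self, threshold: float = KEY_CONTROL_THRESHOLD):
        c = self.table["C"].abs()
        return list(self.table.index[c > threshold])


@dataclass
class ElasticityTable:
    """pi- and epsilon-elasticities of the isolated rate laws."""

    table: pd.DataFrame  # columns: reaction, parameter, category, pi
    state_descriptor: tuple


@dataclass
class ResponseTable:
    table: pd.DataFrame  # columns: reaction, parameter, C, pi, R
    state_descriptor: tuple


def control_coefficients(network: MetabolicNetwork, state: str,
                         clamps: ClampSet, perturbation: float = 0.05,
                         gamma_params: GammaParams = DEFAULT_GAMMA,
                         reference: SteadyStateResult | None = None
                         ) -> ControlTable:
    """Finite-difference flux control coefficients of v_ex.

    Each enzyme amount is varied by ``perturbation`` (default 5 %,
    symmetric) and the system re-solved to a full steady state from the
    reference; C_i = (dv_ex / v_ex) / (dE_i / E_i) by central
    difference.  Fails when the reference exchange flux lies below the
    divergence floor; a perturbed solve that does not converge yields a
    missing coefficient (NaN).
    """
    if reference is None:
        reference = steady_state(network, clamps, state,
                                 gamma_params=gamma_params)
    v0 = reference.v_ex
    if abs(v0) < VEX_FLOOR:
        raise ValueError(
            f"reference |v_ex| = {abs(v0):.3g} umol/g/h is below the "
            f"divergence floor ({VEX_FLOOR}); control coefficients are "
            "undefined near the glucose set point")
    alpha0 = dict(reference.alpha)
    rows = {}
    warm = reference.concentrations
    for rid in network.reaction_ids:
        try:
            vex = []
            for sign in (+1.0, -1.0):
                alpha = dict(alpha0)
                alpha[rid] = alpha.get(rid, 1.0) * (1.0 + sign * perturbation)
                pert = steady_state(network, clamps, state, alpha=alpha,
                                    gamma_params=gamma_params, x0=warm)
                vex.append(pert.v_ex)
            rows[rid] = (vex[0] - vex[1]) / v0 / (2.0 * perturbation)
        except ConvergenceError:
            rows[rid] = np.nan
    table = pd.DataFrame({"C": pd.Series(rows)})
    table.index.name = "reaction"
    return ControlTable(table=table, v_ex=v0, perturbation=perturbation,
                        state=state, clamps=clamps)


# -- elasticities -------------------------------------------------------


def _perturbed_law(law: RateLaw, parameter: str, factor: float) -> RateLaw:
    """Copy of a rate law with one named parameter scaled by ``factor``."""
    kind, _, target = parameter.partition(":")
    if kind == "vmax":
        return dataclasses.replace(law, vmax_fed=law.vmax_fed * factor)
    if kind == "km":
        subs = dict(law.substrates)
        prods = dict(law.products)
        if target in subs:
            km, h = subs[target]
            subs[target] = (km * factor, h)
        elif target in prods:
            km, h = prods[target]
            prods[target] = (km * factor, h)
        else:
            raise KeyError(f"no reactant {target!r} in rate law")
        return dataclasses.replace(law, substrates=subs, products=prods)
    if kind == "ka":
        terms = []
        found = False
        for t in law.allosteric:
            if t.effector == target:
                terms.append(dataclasses.replace(
                    t, binding_constant=t.binding_constant * factor))
                found = True
            else:
                terms.append(t)
        if not found:
            raise KeyError(f"no allosteric effector {target!r} in rate law")
        return dataclasses.replace(law, allosteric=terms)
    raise KeyError(f"unknown parameter {parameter!r}")


PARAM_CATEGORY = {"vmax": "abundance", "km": "reactant binding constant",
                  "ka": "allosteric binding constant", "gamma": "gamma"}


def pi_elasticity(network: MetabolicNetwork, reaction_id: str,
                  parameter: str, conc: dict[str, float],
                  gamma: float = 0.0, alpha: float = 1.0,
                  rel_step: float = 1e-4) -> float:
    """pi_ik = (p_k / v_i) dv_i/dp_k on the isolated rate law.

    Central differences with relative step; the local state supplies
    all concentrations and gamma.  Fails when v_i = 0 (the
    normalization is undefined).
    """
    law = network.reactions[reaction_id].rate_law
    if parameter == "gamma":
        if law.phospho is None:
            raise KeyError(f"{reaction_id} has no phospho pair")
        v0 = law.rate(conc, gamma=gamma, alpha=alpha)
        if v0 == 0:
            raise ZeroDivisionError(f"v_{reaction_id} = 0 at local state")
        h = max(rel_step * gamma, 1e-8)
        lo, hi = max(gamma - h, 0.0), min(gamma + h, 1.0)
        v_hi = law.rate(conc, gamma=hi, alpha=alpha)
        v_lo = law.rate(conc, gamma=lo, alpha=alpha)
        return (v_hi - v_lo) / (hi - lo) * gamma / v0
    v0 = law.rate(conc, gamma=gamma, alpha=alpha)
    if v0 == 0:
        raise ZeroDivisionError(f"v_{reaction_id} = 0 at local state")
    v_hi = _perturbed_law(law, parameter, 1.0 + rel_step).rate(
        conc, gamma=gamma, alpha=alpha)
    v_lo = _perturbed_law(law, parameter, 1.0 - rel_step).rate(
        conc, gamma=gamma, alpha=alpha)
    return (v_hi - v_lo) / (2.0 * rel_step * v0)


def epsilon_elasticity(network: MetabolicNetwork, reaction_id: str,
                       species_id: str, conc: dict[str, float],
                       gamma: float = 0.0, alpha: float = 1.0,
                       rel_step: float = 1e-4) -> float:
    """epsilon_ik = (E_k / v_i) dv_i/dE_k for an effector concentration."""
    law = network.reactions[reaction_id].rate_law
    v0 = law.rate(conc, gamma=gamma, alpha=alpha)
    if v0 == 0:
        raise ZeroDivisionError(f"v_{reaction_id} = 0 at local state")
    e0 = conc[species_id]
    h = max(rel_step * e0, 1e-10)
    up, dn = dict(conc), dict(conc)
    up[species_id] = e0 + h
    dn[species_id] = max(e0 - h, 0.0)
    v_hi = law.rate(up, gamma=gamma, alpha=alpha)
    v_lo = law.rate(dn, gamma=gamma, alpha=alpha)
    return (v_hi - v_lo) / (up[species_id] - dn[species_id]) * e0 / v0


def elasticity_table(network: MetabolicNetwork,
                     reference: SteadyStateResult,
                     reactions=None) -> ElasticityTable:
    """pi-elasticities of every perturbable parameter of each enzyme."""
    rows = []
    for rid in (reactions or network.reaction_ids):
        law = network.reactions[rid].rate_law
        a = reference.alpha.get(rid, 1.0)
        if abs(reference.fluxes[rid]) < 1e-9:
            continue
        for pname in law.parameter_names():
            kind = pname.split(":", 1)[0] if ":" in pname else pname
            pi = pi_elasticity(network, rid, pname, reference.concentrations,
                               gamma=reference.gamma, alpha=a)
            rows.append({"reaction": rid, "parameter": pname,
                         "category": PARAM_CATEGORY[kind], "pi": pi})
    df = pd.DataFrame(rows)
    return ElasticityTable(
        table=df, state_descriptor=(reference.state, reference.clamps))


def response_coefficients(control: ControlTable,
                          elasticities: ElasticityTable) -> ResponseTable:
    """R_ik = C_i * pi_ik; both tables must share the reference state."""
    if (control.state, control.clamps) != elasticities.state_descriptor:
        raise ValueError(
            "control and elasticity tables were computed at different "
            f"states: {(control.state, control.clamps)} vs "
            f"{elasticities.state_descriptor}")
    df = elasticities.table.copy()
    df["C"] = df["reaction"].map(control.table["C"])
    df["R"] = df["C"] * df["pi"]
    return ResponseTable(table=df,
                         state_descriptor=elasticities.state_descriptor)


def relative_elasticities(elasticities: ElasticityTable,
                          reaction_id: str) -> pd.Series:
    """|pi_ik| shares of one enzyme, normalized to sum to one."""
    sub = elasticities.table[elasticities.table["reaction"] == reaction_id]
    if sub.empty:
        raise KeyError(f"no elasticities for {reaction_id}")
    total = sub["pi"].abs().sum()
    if total == 0:
        raise ZeroDivisionError(f"all elasticities of {reaction_id} vanish")
    out = sub.set_index("parameter")["pi"].abs() / total
    out.name = reaction_id
    return out


def diurnal_control(network: MetabolicNetwork, state: str, profile,
                    reactions=None, sample_hours=None,
                    gamma_params: GammaParams = DEFAULT_GAMMA,
                    perturbation: float = 0.05) -> pd.DataFrame:
    """Flux control coefficients along a diurnal glucose profile.

    At each sampled hour the system is brought to the quasi-stationary
    state implied by the instantaneous plasma glucose and the simulated
    glycogen filling, and the control coefficients of the requested
    reactions are recomputed.  Points where |v_ex| falls below the
    divergence floor are flagged (``divergent`` = True, C = NaN).
    """
    from .simulate import run_diurnal

    if sample_hours is None:
        sample_hours = np.arange(0.0, 24.1, 2.0)
    diurnal = run_diurnal(network, profile, state,
                          gamma_params=gamma_params,
                          t_eval=np.asarray(sample_hours, dtype=float))
    if reactions is None:
        reactions = network.reaction_ids
    rows = []
    for i, t in enumerate(diurnal.time_h):
        clamps = ClampSet(glucose=float(diurnal.glucose[i]),
                          glycogen_fill=float(
                              np.clip(diurnal.glycogen_fill[0, i], 0.0, 1.0)))
        row = {"time_h": t, "glucose_mM": clamps.glucose,
               "divergent": False}
        try:
            ct = control_coefficients(network, state, clamps,
                                      perturbation=perturbation,
                                      gamma_params=gamma_params)
            for rid in reactions:
                row[rid] = float(ct.table["C"].get(rid, np.nan))
            row["sum_C"] = ct.summation
        except ValueError:
            row["divergent"] = True
            for rid in reactions:
                row[rid] = np.nan
            row["sum_C"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
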