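"""SBML import and export of the kinetic model.

The network is exported as SBML Level 3 Version 2 with one reaction per
kinetic step, clamped species marked as boundary species, and the full
rate law emitted as the reaction's kinetic law with all numeric
parameters inlined as local parameters.  The modular composition of the
law (core form, phospho pair, allosteric terms, glycogen-store factor)
is encoded through a local-parameter naming convention, so that a model
written by :func:`export_sbml` reimports bit-exactly through
:func:`import_sbml`.  Foreign SBML files (Level 2 or 3) are imported on
a best-effort basis: species, compartments, and stoichiometry are
always mapped; kinetic laws that do not follow the naming convention
are reported as unsupported rather than silently dropped.
"""

from __future__ import annotations

import re

import libsbml

from .network import MetabolicNetwork, Reaction, Species, build_network
from .ratelaws import AllostericTerm, PhosphoForm, RateLaw

__all__ = ["export_sbml", "import_sbml", "validate_sbml"]

_COMPARTMENTS = {"cytosol": "cytosol", "mitochondrion": "mitochondrion",
                 "ER": "ER", "external": "external"}


def _sid(species_id: str) -> str:
    """SBML-legal identifier for a species id (may start with a digit)."""
    s = re.sub(r"[^A-Za-z0-9_]", "_", species_id)
    if not re.match(r"[A-Za-z_]", s):
        s = "x" + s
    return s


def _check(status, what):
    if status is None or (isinstance(status, int)
                          and status != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise RuntimeError(f"libsbml error while {what}: status {status}")


def _add_param(kl, pid, value, units="dimensionless"):
    p = kl.createLocalParameter()
    _check(p.setId(pid), f"parameter {pid}")
    _check(p.setValue(float(value)), f"parameter {pid}")


def _law_formula(rxn_id: str, law: RateLaw, sid: dict[str, str]) -> str:
    """Explicit infix formula of the composed rate law."""

    def core(kms_prefix: str, km_scale_name: str | None) -> str:
        scale = f" * {km_scale_name}" if km_scale_name else ""
        if law.form == "carrier":
            fwd, rev, den = [], [], []
            for (s, (km, _)), (p, _) in zip(law.substrates.items(),
                                            law.products.items()):
                kmn = f"{kms_prefix}km_s_{_sid(s)}"
                fwd.append(f"({sid[s]} / ({kmn}{scale}))")
                rev.append(f"({sid[p]} / ({kmn}{scale}))")
                den.append(f"(1 + {sid[s]} / ({kmn}{scale}) "
                           f"+ {sid[p]} / ({kmn}{scale}))")
            return (f"(({' * '.join(fwd)}) - ({' * '.join(rev)})) "
                    f"/ ({' * '.join(den)})")
        num_f, den_s = [], []
        for s, (km, h) in law.substrates.items():
            t = (f"({sid[s]} / ({kms_prefix}km_s_{_sid(s)}{scale}))"
                 f"^{kms_prefix}h_s_{_sid(s)}")
            num_f.append(t)
            den_s.append(f"(1 + {t})")
        num_r, den_p = [], []
        for p, (km, h) in law.products.items():
            t = (f"({sid[p]} / {kms_prefix}km_p_{_sid(p)})"
                 f"^{kms_prefix}h_p_{_sid(p)}")
            num_r.append(t)
            den_p.append(f"(1 + {t})")
        fwd = " * ".join(num_f) if num_f else "1"
        den = " * ".join(den_s) if den_s else "1"
        denp = " * ".join(den_p) if den_p else "1"
        if law.keq is not None and num_r:
            num = f"({fwd} - ({' * '.join(num_r)}) / keq)"
        else:
            num = f"({fwd})"
        return f"{num} / ({den} + {denp} - 1)"

    factors = []
    for i, t in enumerate(law.allosteric):
        x = f"({sid[t.effector]} / allo{i}_k)^allo{i}_h"
        if t.mode == "activator":
            factors.append(f"((allo{i}_a0 + {x}) / (1 + {x}))")
        else:
            factors.append(f"((1 + allo{i}_a0 * {x}) / (1 + {x}))")
    if law.store_capacity is not None:
        factors.append(f"max(0, 1 - ({sid[law.store_species]} / store_cap)"
                       f"^store_exp)")
    allo = " * ".join(factors)
    if law.phospho is not None:
        core_expr = (f"(gamma_phospho * pp_vmax * {core('', 'pp_kms')} + "
                     f"(1 - gamma_phospho) * pd_vmax * {core('', 'pd_kms')})")
    else:
        core_expr = core("", None)
    expr = f"vmax * {core_expr}"
    if allo:
        expr += f" * {allo}"
    return expr


def export_sbml(network: MetabolicNetwork, path) -> None:
    """Write the network as SBML L3V2 with inlined kinetic laws."""
    ns = libsbml.SBMLNamespaces(3, 2)
    doc = libsbml.SBMLDocument(ns)
    model = doc.createModel()
    _check(model.setId(re.sub(r"[^A-Za-z0-9_]", "_", network.name)),
           "model id")
    model.setName(network.name)

    for cid in _COMPARTMENTS.values():
        c = model.createCompartment()
        _check(c.setId(cid), f"compartment {cid}")
        c.setConstant(True)
        c.setSize(1.0)
        c.setSpatialDimensions(3)

    sid = {s: _sid(s) for s in network.species_ids}
    for spid, sp in network.species.items():
        s = model.createSpecies()
        _check(s.setId(sid[spid]), f"species {spid}")
        s.setName(spid)
        s.setCompartment(_COMPARTMENTS[sp.compartment])
        s.setInitialConcentration(sp.concentration)
        s.setBoundaryCondition(bool(sp.clamped))
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)

    gp = model.createParameter()
    _check(gp.setId("gamma_phospho"), "gamma parameter")
    gp.setValue(0.0)
    gp.setConstant(False)

    for rid, rxn in network.reactions.items():
        law = rxn.rate_law
        if law.vmax_fed is None:
            raise ValueError(f"reaction {rid}: incomplete rate law")
        r = model.createReaction()
        _check(r.setId(_sid(rid)), f"reaction {rid}")
        r.setName(rid)
        r.setReversible(rxn.reversible)
        for spid, coef in rxn.stoichiometry.items():
            ref = (r.createReactant() if coef < 0 else r.createProduct())
            _check(ref.setSpecies(sid[spid]), f"stoich {rid}/{spid}")
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        # species appearing in the rate law but not in the stoichiometry
        # (allosteric effectors, store species) are declared as modifiers
        law_species = set(law.substrates) | set(law.products)
        law_species |= {t.effector for t in law.allosteric}
        if law.store_capacity is not None:
            law_species.add(law.store_species)
        for spid in sorted(law_species - set(rxn.stoichiometry)):
            mod = r.createModifier()
            _check(mod.setSpecies(sid[spid]), f"modifier {rid}/{spid}")
        kl = r.createKineticLaw()
        _add_param(kl, "vmax", law.vmax_fed)
        if law.keq is not None:
            _add_param(kl, "keq", law.keq)
        if law.form == "carrier":
            _add_param(kl, "form_carrier", 1.0)
        for s, (km, h) in law.substrates.items():
            _add_param(kl, f"km_s_{_sid(s)}", km)
            _add_param(kl, f"h_s_{_sid(s)}", h)
        for p, (km, h) in law.products.items():
            _add_param(kl, f"km_p_{_sid(p)}", km)
            _add_param(kl, f"h_p_{_sid(p)}", h)
        for i, t in enumerate(law.allosteric):
            _add_param(kl, f"allo{i}_k", t.binding_constant)
            _add_param(kl, f"allo{i}_h", t.hill)
            _add_param(kl, f"allo{i}_a0", t.basal)
            _add_param(kl, f"allo{i}_mode",
                       1.0 if t.mode == "activator" else 0.0)
            _add_param(kl, f"allo{i}_eff_{_sid(t.effector)}", 1.0)
        if law.phospho is not None:
            _add_param(kl, "pp_vmax", law.phospho["phospho"].vmax_scale)
            _add_param(kl, "pp_kms", law.phospho["phospho"].km_scale)
            _add_param(kl, "pd_vmax", law.phospho["dephospho"].vmax_scale)
            _add_param(kl, "pd_kms", law.phospho["dephospho"].km_scale)
        if law.store_capacity is not None:
            _add_param(kl, "store_cap", law.store_capacity)
            _add_param(kl, "store_exp", law.store_exponent)
        math = libsbml.parseL3Formula(_law_formula(rid, law, sid))
        if math is None:
            raise ValueError(f"reaction {rid}: could not build kinetic law "
                             f"math ({libsbml.getLastParseL3Error()})")
        _check(kl.setMath(math), f"kinetic law of {rid}")
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def validate_sbml(path) -> list[str]:
    """Validator error messages (severity >= error) for an SBML file."""
    doc = libsbml.readSBMLFromFile(str(path))
    doc.checkConsistency()
    errors = []
    for i in range(doc.getNumErrors()):
        e = doc.getError(i)
        if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(e.getMessage().strip())
    return errors


def import_sbml(path) -> MetabolicNetwork:
    """Read an SBML file written by :func:`export_sbml`.

    Species/compartments/stoichiometry are mapped directly; rate laws
    are reconstructed from the local-parameter naming convention.
    Unsupported constructs raise with a description instead of being
    dropped.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage().strip()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise ValueError("invalid SBML: " + "; ".join(msgs[:5]))
    model = doc.getModel()
    if model is None:
        raise ValueError("SBML file contains no model")

    comp_rev = {v: k for k, v in _COMPARTMENTS.items()}
    species, names = [], {}
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        orig = s.getName() or s.getId()
        names[s.getId()] = orig
        comp = comp_rev.get(s.getCompartment(), "cytosol")
        conc = s.getInitialConcentration()
        if conc != conc:  # NaN: fall back to initial amount
            conc = s.getInitialAmount()
        species.append(Species(id=orig, compartment=comp,
                               concentration=float(conc),
                               clamped=bool(s.getBoundaryCondition())))

    capacity = 500.0
    reactions = []
    unsupported = []
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        rid = r.getName() or r.getId()
        stoich: dict[str, int] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[names[ref.getSpecies()]] = stoich.get(
                names[ref.getSpecies()], 0) - int(round(ref.getStoichiometry()))
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[names[ref.getSpecies()]] = stoich.get(
                names[ref.getSpecies()], 0) + int(round(ref.getStoichiometry()))
        kl = r.getKineticLaw()
        if kl is None:
            unsupported.append(f"{rid}: no kinetic law")
            continue
        pars = {kl.getLocalParameter(j).getId(): kl.getLocalParameter(j).getValue()
                for j in range(kl.getNumLocalParameters())}
        if "vmax" not in pars:
            unsupported.append(f"{rid}: kinetic law lacks the vmax "
                               "local-parameter convention")
            continue
        subs, prods = {}, {}
        allo_eff = {}
        for pid in pars:
            if pid.startswith("km_s_"):
                key = pid[5:]
                subs[key] = (pars[pid], pars.get(f"h_s_{key}", 1.0))
            elif pid.startswith("km_p_"):
                key = pid[5:]
                prods[key] = (pars[pid], pars.get(f"h_p_{key}", 1.0))
            m = re.match(r"allo(\d+)_eff_(.+)", pid)
            if m:
                allo_eff[int(m.group(1))] = m.group(2)
        sid_rev = {_sid(orig): orig for orig in names.values()}
        subs = {sid_rev[k]: v for k, v in subs.items()}
        prods = {sid_rev[k]: v for k, v in prods.items()}
        allosteric = []
        for idx in sorted(allo_eff):
            allosteric.append(AllostericTerm(
                effector=sid_rev[allo_eff[idx]],
                binding_constant=pars[f"allo{idx}_k"],
                hill=pars[f"allo{idx}_h"],
                mode=("activator" if pars[f"allo{idx}_mode"] > 0.5
                      else "inhibitor"),
                basal=pars[f"allo{idx}_a0"]))
        phospho = None
        if "pp_vmax" in pars:
            phospho = {
                "phospho": PhosphoForm(pars["pp_vmax"], pars["pp_kms"]),
                "dephospho": PhosphoForm(pars["pd_vmax"], pars["pd_kms"]),
            }
        store = pars.get("store_cap")
        if store is not None:
            capacity = store
        law = RateLaw(
            form="carrier" if pars.get("form_carrier") else "saturable",
            substrates=subs, products=prods, vmax_fed=pars["vmax"],
            keq=pars.get("keq"), allosteric=allosteric, phospho=phospho,
            store_capacity=store,
            store_exponent=pars.get("store_exp", 4.0))
        reactions.append(Reaction(id=rid, stoichiometry=stoich, rate_law=law))
    if unsupported:
        raise ValueError("unsupported SBML constructs: "
                         + "; ".join(unsupported))
    return MetabolicNetwork(species, reactions, glycogen_capacity=capacity,
                            name=model.getName() or model.getId())
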