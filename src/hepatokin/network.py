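"""Reaction network of hepatocyte glucose metabolism.

The network covers glycolysis, gluconeogenesis, and glycogen turnover in
a rat hepatocyte with four compartments (cytosol, mitochondrion, ER,
external space), 32 reactions and transporters, and a species roster in
which the cofactor pools (ATP/ADP, NAD/NADH, GTP/GDP, UTP/UDP,
phosphate) are clamped constants rather than dynamic variables.

The default parameterization is bundled with the package
(``data/liver_model.yaml``) and is calibrated against published
steady-state glucose exchange fluxes, set-point ranges, and maximal
gluconeogenesis rates of perfused rat liver.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ratelaws import AllostericTerm, PhosphoForm, RateLaw

COMPARTMENTS = ("cytosol", "mitochondrion", "ER", "external")

DEFAULT_PARAMS = "liver_model.yaml"


@dataclass
class Species:
    """One metabolite of the network."""

    id: str
    compartment: str
    concentration: float  # initial / clamped value, mM
    clamped: bool = False

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"species {self.id}: unknown compartment {self.compartment!r}")
        if self.concentration < 0:
            raise ValueError(f"species {self.id}: concentration must be >= 0")


@dataclass
class Reaction:
    """One enzymatic reaction or membrane transport step."""

    id: str
    stoichiometry: dict[str, int]
    rate_law: RateLaw

    @property
    def reversible(self) -> bool:
        return self.rate_law.form == "carrier" or self.rate_law.keq is not None


class MetabolicNetwork:
    """Species, reactions, stoichiometry and rate evaluation."""

    def __init__(self, species: list[Species], reactions: list[Reaction],
                 glycogen_capacity: float, name: str = "hepatocyte-glucose"):
        self.name = name
        self.glycogen_capacity = float(glycogen_capacity)
        self.species = {s.id: s for s in species}
        if len(self.species) != len(species):
            raise ValueError("duplicate species ids")
        self.reactions = {r.id: r for r in reactions}
        if len(self.reactions) != len(reactions):
            raise ValueError("duplicate reaction ids")
        for r in reactions:
            for sid in r.stoichiometry:
                if sid not in self.species:
                    raise ValueError(
                        f"reaction {r.id}: unknown species {sid!r}")
            for sid in list(r.rate_law.substrates) + list(r.rate_law.products):
                if sid not in self.species:
                    raise ValueError(
                        f"reaction {r.id}: rate law references unknown "
                        f"species {sid!r}")
            for term in r.rate_law.allosteric:
                if term.effector not in self.species:
                    raise ValueError(
                        f"reaction {r.id}: unknown allosteric effector "
                        f"{term.effector!r}")
        self.species_ids = list(self.species)
        self.reaction_ids = list(self.reactions)
        self.dynamic_ids = [s.id for s in species if not s.clamped]
        self.clamped_ids = [s.id for s in species if s.clamped]
        self._S_dyn = self._build_stoich(self.dynamic_ids)

    # -- construction helpers -------------------------------------------

    def _build_stoich(self, row_ids: list[str]) -> np.ndarray:
        S = np.zeros((len(row_ids), len(self.reactions)))
        row = {sid: i for i, sid in enumerate(row_ids)}
        for j, rxn in enumerate(self.reactions.values()):
            for sid, coef in rxn.stoichiometry.items():
                if sid in row:
                    S[row[sid], j] = coef
        return S

    def stoichiometric_matrix(self, dynamic_only: bool = True) -> np.ndarray:
        if dynamic_only:
            return self._S_dyn.copy()
        return self._build_stoich(self.species_ids)

    # -- state handling --------------------------------------------------

    def initial_concentrations(self) -> dict[str, float]:
        return {sid: sp.concentration for sid, sp in self.species.items()}

    def conc_dict(self, dynamic: np.ndarray,
                  overrides: dict[str, float] | None = None) -> dict[str, float]:
        """Full concentration mapping from a dynamic-state vector.

        Clamped species take their parameter-file values unless
        ``overrides`` replaces them (e.g. external glucose or lactate).
        """
        conc = {sid: self.species[sid].concentration for sid in self.clamped_ids}
        conc.update(zip(self.dynamic_ids, dynamic))
        if overrides:
            conc.update(overrides)
        return conc

    # -- rate evaluation --------------------------------------------------

    def rates(self, conc: dict[str, float], gamma: float = 0.0,
              alpha: dict[str, float] | None = None,
              frozen_allosteric: dict[str, dict[str, float]] | None = None,
              frozen_gamma: float | None = None) -> np.ndarray:
        """All 32 reaction rates (umol/g/h) at one metabolic state.

        ``alpha`` maps reaction id -> abundance scaling (default 1);
        ``frozen_allosteric`` maps reaction id -> {effector: factor} for
        regulation-depleted variants; ``frozen_gamma`` pins the
        phosphorylated fraction of every interconvertible enzyme.
        """
        g = gamma if frozen_gamma is None else frozen_gamma
        out = np.empty(len(self.reactions))
        for j, (rid, rxn) in enumerate(self.reactions.items()):
            a = 1.0 if alpha is None else alpha.get(rid, 1.0)
            fz = None if frozen_allosteric is None else frozen_allosteric.get(rid)
            out[j] = rxn.rate_law.rate(conc, gamma=g, alpha=a,
                                       frozen_allosteric=fz)
        return out

    def reaction_rate(self, reaction_id: str, conc: dict[str, float],
                      gamma: float = 0.0, alpha: float = 1.0) -> float:
        """Rate of a single reaction with input validation."""
        rxn = self.reactions[reaction_id]
        for sid in set(rxn.rate_law.substrates) | set(rxn.rate_law.products):
            if conc[sid] < 0:
                raise ValueError(
                    f"negative concentration for {sid} in {reaction_id}")
        return rxn.rate_law.rate(conc, gamma=gamma, alpha=alpha)

    def __repr__(self):
        return (f"<MetabolicNetwork {self.name}: {len(self.species)} species "
                f"({len(self.dynamic_ids)} dynamic), "
                f"{len(self.reactions)} reactions>")


# -- parameter-file loading ---------------------------------------------


def _load_source(parameter_source) -> dict:
    if parameter_source is None:
        ref = importlib.resources.files("hepatokin.data") / DEFAULT_PARAMS
        return yaml.safe_load(ref.read_text())
    if isinstance(parameter_source, dict):
        return parameter_source
    return yaml.safe_load(Path(parameter_source).read_text())


def build_network(parameter_source=None) -> MetabolicNetwork:
    """Build the fully parameterized network.

    ``parameter_source`` may be None (bundled default parameterization),
    a path to a YAML/JSON parameter file, or an already-loaded dict.
    Raises with the offending reaction id when a rate-law parameter is
    missing and on references to unknown species.
    """
    doc = _load_source(parameter_source)
    model = doc.get("model", {})
    capacity = float(model.get("glycogen_capacity", 500.0))

    species = []
    for sid, sdoc in doc["species"].items():
        species.append(Species(
            id=str(sid),
            compartment=sdoc.get("compartment", "cytosol"),
            concentration=float(sdoc["init"]),
            clamped=bool(sdoc.get("clamped", False)),
        ))

    reactions = []
    for rid, rdoc in doc["reactions"].items():
        rid = str(rid)
        try:
            allosteric = [
                AllostericTerm(
                    effector=str(t["effector"]),
                    binding_constant=float(t["k"]),
                    hill=float(t.get("hill", 1.0)),
                    mode=t.get("mode", "activator"),
                    basal=float(t.get("basal", 0.0)),
                ) for t in rdoc.get("allosteric", [])
            ]
            phospho = None
            if "phospho" in rdoc:
                phospho = {
                    form: PhosphoForm(
                        vmax_scale=float(fd.get("vmax_scale", 1.0)),
                        km_scale=float(fd.get("km_scale", 1.0)),
                    ) for form, fd in rdoc["phospho"].items()
                }
            law = RateLaw(
                form=rdoc.get("form", "saturable"),
                substrates=rdoc["substrates"],
                products=rdoc.get("products", {}),
                vmax_fed=float(rdoc["vmax_fed"]),
                keq=(float(rdoc["keq"]) if rdoc.get("keq") is not None
                     else None),
                allosteric=allosteric,
                phospho=phospho,
                store_capacity=(capacity if rdoc.get("store_capacity_factor")
                                else None),
            )
        except KeyError as exc:
            raise KeyError(
                f"reaction {rid}: missing rate-law parameter {exc}") from exc
        reactions.append(Reaction(
            id=rid,
            stoichiometry={str(k): int(v)
                           for k, v in rdoc["stoichiometry"].items()},
            rate_law=law,
        ))

    return MetabolicNetwork(species, reactions, glycogen_capacity=capacity,
                            name=model.get("name", "hepatocyte-glucose"))
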