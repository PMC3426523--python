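"""One-way SBML Level 3 export of the chemical reaction network.

Writes species, parameters and mass-action kinetic laws so the chemical
subsystem can be inspected or re-simulated in any SBML-aware tool.  Only the
chemical network is exported: the clamped odor input, channel fluxes and
membrane potential are outside SBML's plain reaction formalism and are
omitted (documented in the model notes element).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.dom import minidom

from .network import SPECIES, ReactionNetwork

__all__ = ["export_sbml"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(name: str) -> str:
    return "s_" + name.replace("::", "_")


def _math_times(parent: ET.Element, factors: list[str]) -> None:
    if len(factors) == 1:
        ET.SubElement(parent, "ci").text = f" {factors[0]} "
        return
    apply_el = ET.SubElement(parent, "apply")
    ET.SubElement(apply_el, "times")
    for f in factors:
        ET.SubElement(apply_el, "ci").text = f" {f} "


def export_sbml(network: ReactionNetwork, path) -> None:
    """Write the chemical network as an SBML L3V1 document."""
    ET.register_namespace("", _SBML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(sbml, "model", {
        "id": "awc_odor_transduction",
        "substanceUnits": "substance", "timeUnits": "time",
        "extentUnits": "substance",
    })
    comps = ET.SubElement(model, "listOfCompartments")
    ET.SubElement(comps, "compartment", {
        "id": "cell", "size": "1", "constant": "true", "spatialDimensions": "3"})

    species_el = ET.SubElement(model, "listOfSpecies")
    y0 = network.initial_state()
    for i, name in enumerate(SPECIES):
        ET.SubElement(species_el, "species", {
            "id": _sid(name), "compartment": "cell",
            "initialConcentration": f"{y0[i]:.10g}",
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if name == "Odor" else "false",
            "constant": "false",
        })

    params_el = ET.SubElement(model, "listOfParameters")
    seen: set[str] = set()
    for rxn in network.reactions:
        for pname, value in ((rxn.kf_name, rxn.kf), (rxn.kr_name, rxn.kr)):
            if pname and pname not in seen:
                seen.add(pname)
                ET.SubElement(params_el, "parameter", {
                    "id": pname, "value": f"{value:.10g}", "constant": "true"})

    rxns_el = ET.SubElement(model, "listOfReactions")
    for rxn in network.reactions:
        r_el = ET.SubElement(rxns_el, "reaction", {
            "id": "r_" + rxn.label, "reversible": str(rxn.reversible).lower()})
        if rxn.reactants:
            lor = ET.SubElement(r_el, "listOfReactants")
            for sp, st in rxn.reactants:
                ET.SubElement(lor, "speciesReference", {
                    "species": _sid(sp), "stoichiometry": str(st), "constant": "true"})
        if rxn.products:
            lop = ET.SubElement(r_el, "listOfProducts")
            for sp, st in rxn.products:
                ET.SubElement(lop, "speciesReference", {
                    "species": _sid(sp), "stoichiometry": str(st), "constant": "true"})
        kl = ET.SubElement(r_el, "kineticLaw")
        math = ET.SubElement(kl, f"{{{_MATHML_NS}}}math")
        fwd = [rxn.kf_name or f"{rxn.kf:.10g}"]
        for sp, st in rxn.reactants:
            fwd.extend([_sid(sp)] * st)
        if rxn.reversible:
            apply_el = ET.SubElement(math, "apply")
            ET.SubElement(apply_el, "minus")
            _math_times(apply_el, fwd)
            rev = [rxn.kr_name]
            for sp, st in rxn.products:
                rev.extend([_sid(sp)] * st)
            _math_times(apply_el, rev)
        else:
            _math_times(math, fwd)

    pretty = minidom.parseString(ET.tostring(sbml)).toprettyxml(indent="  ")
    with open(path, "w") as fh:
        fh.write(pretty)
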