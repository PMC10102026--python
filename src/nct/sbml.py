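"""Minimal SBML Level 3 export of a compiled reaction network.

Writes mass-action kinetic laws so the model can be cross-validated in an
external simulator.  Species identifiers are ``<species>__<compartment>``
with the complex-forming colon mapped to a double underscore-safe token.
"""

from __future__ import annotations

from lxml import etree

from .network import ReactionNetwork

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(species: str, compartment: str) -> str:
    return f"{species.replace(':', '_')}__{compartment}"


def network_to_sbml(network: ReactionNetwork, model_id: str = "nct_transport") -> bytes:
    """Serialize the network as an SBML L3V2 document (bytes, UTF-8)."""
    network.compile()
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS},
                         level="3", version="2")
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model", id=model_id)

    loc = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for comp in network.compartments.values():
        etree.SubElement(
            loc, f"{{{SBML_NS}}}compartment", id=comp.name,
            size=repr(comp.volume), constant="true", spatialDimensions="3")

    los = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    x0 = network.x0
    for (sp, comp), c0 in zip(network.states, x0):
        etree.SubElement(
            los, f"{{{SBML_NS}}}species", id=_sid(sp, comp), name=sp,
            compartment=comp, initialConcentration=repr(float(c0)),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false")

    lor = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for i, rxn in enumerate(network.reactions):
        r = etree.SubElement(
            lor, f"{{{SBML_NS}}}reaction",
            id=f"r{i:03d}", name=rxn.name, reversible="false")
        lref = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
        for sp, comp in rxn.reactants:
            etree.SubElement(lref, f"{{{SBML_NS}}}speciesReference",
                             species=_sid(sp, comp), stoichiometry="1",
                             constant="true")
        lpro = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
        for sp, comp in rxn.products:
            etree.SubElement(lpro, f"{{{SBML_NS}}}speciesReference",
                             species=_sid(sp, comp), stoichiometry="1",
                             constant="true")
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
        cn = etree.SubElement(apply_, f"{{{MATHML_NS}}}cn")
        cn.text = repr(float(rxn.k))
        vref = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
        vref.text = f" {rxn.rate_compartment} "
        for sp, comp in rxn.reactants:
            ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
            ci.text = f" {_sid(sp, comp)} "
    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_sbml(network: ReactionNetwork, path, model_id: str = "nct_transport") -> None:
    with open(path, "wb") as fh:
        fh.write(network_to_sbml(network, model_id))
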