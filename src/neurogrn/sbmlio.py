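"""SBML Level 3 export/import of fitted models.

Models are exported as ODE-level SBML: one species per network node, one
constant parameter per rate/interaction coefficient (ids follow the
``alpha_X`` / ``delta_X`` / ``beta_X`` / ``k_SRC_TGT`` / ``h_SRC_TGT`` /
``beta_RESTi`` / ``beta_vAscl1`` convention), and one rate rule per species
carrying the full Shea–Ackers MathML expression in its conversion-stage
form (both external-input parameters appear symbolically; set them to zero
to recover the earlier stages).  The signed topology is additionally stored
in a model annotation so that import is exact.

The importer handles exactly this dialect.  Foreign SBML without the
topology annotation or the id convention raises
:class:`UnsupportedSBMLError` naming what is missing — reaction-network
SBML is out of scope here.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .network import (
    ACTIVATION,
    INHIBITION,
    NetworkTopology,
    ParameterSet,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:neurogrn:topology"


class UnsupportedSBMLError(ValueError):
    def __init__(self, missing: list[str]):
        super().__init__(
            "unsupported SBML document; missing/unsupported features: "
            + "; ".join(missing)
        )
        self.missing = missing


def _m(tag: str, *children: ET.Element, text: str | None = None, **attrib) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}{tag}", attrib)
    if text is not None:
        el.text = text
    el.extend(children)
    return el


def _ci(name: str) -> ET.Element:
    return _m("ci", text=f" {name} ")


def _cn(value: float) -> ET.Element:
    return _m("cn", text=f" {value:g} ")


def _apply(op: str, *args: ET.Element) -> ET.Element:
    return _m("apply", _m(op), *args)


def _hill_term(src: str, tgt: str) -> ET.Element:
    # ((S / k_S_T)^h_S_T)
    return _apply(
        "power",
        _apply("divide", _ci(src), _ci(f"k_{src}_{tgt}")),
        _ci(f"h_{src}_{tgt}"),
    )


def _sum(terms: list[ET.Element]) -> ET.Element:
    if not terms:
        return _cn(0.0)
    if len(terms) == 1:
        return terms[0]
    return _apply("plus", *terms)


def _rate_rule_math(node: str, topology: NetworkTopology) -> ET.Element:
    act_terms = [_hill_term(s, node) for s in topology.activators_of(node)]
    if topology.has_beta(node):
        act_terms.insert(0, _ci(f"beta_{node}"))
    if topology.external_activator_of(node) is not None:
        act_terms.append(_ci("beta_vAscl1"))
    inh_terms = [_hill_term(s, node) for s in topology.inhibitors_of(node)]
    if topology.external_inhibitor_of(node) is not None:
        inh_terms.append(_ci("beta_RESTi"))

    if act_terms:
        num = _sum(act_terms)
        den = _sum([_cn(1.0), _sum(act_terms), *inh_terms])
    else:
        num = _cn(1.0)
        den = _sum([_cn(1.0), *inh_terms])
    sa = _apply("divide", num, den)
    rate = _apply(
        "minus",
        _apply("times", _ci(f"alpha_{node}"), sa),
        _apply("times", _ci(f"delta_{node}"), _ci(node)),
    )
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(rate)
    return math


def write_sbml(
    topology: NetworkTopology,
    params: ParameterSet,
    path: str | Path,
    initial_state: dict[str, float] | None = None,
    model_id: str = "neurogrn_model",
) -> None:
    params.validate(topology)
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    annot = ET.SubElement(model, f"{{{SBML_NS}}}annotation")
    topo_el = ET.SubElement(annot, f"{{{ANNOT_NS}}}network")
    for src, tgt, sign in topology.regulatory_edges():
        ET.SubElement(
            topo_el,
            f"{{{ANNOT_NS}}}edge",
            {"source": src, "target": tgt, "sign": sign},
        )
    for name, tgt, sign in sorted(topology.external_inputs):
        ET.SubElement(
            topo_el,
            f"{{{ANNOT_NS}}}externalInput",
            {"name": name, "target": tgt, "sign": sign},
        )

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "constant": "true", "size": "1"},
    )

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    init = initial_state or {}
    for node in topology.nodes:
        ET.SubElement(
            species_el,
            f"{{{SBML_NS}}}species",
            {
                "id": node,
                "compartment": "cell",
                "initialConcentration": f"{init.get(node, 0.0):.17g}",
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )

    params_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name, value in params.as_flat().items():
        ET.SubElement(
            params_el,
            f"{{{SBML_NS}}}parameter",
            {"id": name, "value": f"{value:.17g}", "constant": "true"},
        )

    rules_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfRules")
    for node in topology.nodes:
        rule = ET.SubElement(
            rules_el, f"{{{SBML_NS}}}rateRule", {"variable": node}
        )
        rule.append(_rate_rule_math(node, topology))

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="UTF-8")


def read_sbml(path: str | Path) -> tuple[NetworkTopology, ParameterSet, dict[str, float]]:
    """Import a model written by :func:`write_sbml` (or hand-edited copies)."""
    tree = ET.parse(path)
    root = tree.getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    missing = []
    if model is None:
        raise UnsupportedSBMLError(["no <model> element in the SBML namespace"])

    topo_el = model.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}network")
    if topo_el is None:
        missing.append("topology annotation (urn:neurogrn:topology)")

    species = model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    if not species:
        missing.append("listOfSpecies")
    param_els = model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")
    if not param_els:
        missing.append("listOfParameters")
    if missing:
        raise UnsupportedSBMLError(missing)

    nodes = tuple(s.get("id") for s in species)
    initial = {
        s.get("id"): float(s.get("initialConcentration", "0")) for s in species
    }
    edges = frozenset(
        (e.get("source"), e.get("target"), e.get("sign"))
        for e in topo_el.findall(f"{{{ANNOT_NS}}}edge")
    )
    externals = frozenset(
        (e.get("name"), e.get("target"), e.get("sign"))
        for e in topo_el.findall(f"{{{ANNOT_NS}}}externalInput")
    )
    self_pairs = frozenset((s, t) for s, t, _ in edges if s == t)
    topology = NetworkTopology(nodes, edges, externals, permitted_self=self_pairs)

    flat = {p.get("id"): float(p.get("value")) for p in param_els}
    try:
        alpha = {n: flat[f"alpha_{n}"] for n in nodes}
        delta = {n: flat[f"delta_{n}"] for n in nodes}
        beta = {n: flat[f"beta_{n}"] for n in topology.beta_nodes}
        k = {(s, t): flat[f"k_{s}_{t}"] for s, t, _ in edges}
        h = {(s, t): flat[f"h_{s}_{t}"] for s, t, _ in edges}
        params = ParameterSet(
            alpha, delta, beta, k, h, flat["beta_RESTi"], flat["beta_vAscl1"]
        )
    except KeyError as err:
        raise UnsupportedSBMLError(
            [f"parameter id convention: missing {err.args[0]!r}"]
        ) from err
    params.validate(topology)
    return topology, params, initial
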