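"""Minimal SBML Level 3 export/import of the Lsr reaction system.

Writes the built-in Lsr network as an SBML L3V2 document (species,
global parameters, reactions with content-MathML kinetic laws) and
reads such documents back, reconstructing parameter values and a
symbolic rate expression per reaction via sympy. The bridge is
deliberately small: it covers the MathML subset the Lsr rate laws use
(arithmetic, powers, symbols, numbers), not the full SBML standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp
from lxml import etree

from .lsr_model import LsrCellState, LsrParams, lsr_rhs

__all__ = ["save_sbml", "load_sbml", "SbmlModel"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_SPECIES = ("Ae", "Ai", "Ap", "M", "T")

_PARAMETER_NAMES = (
    "K_synth", "V_ydgG", "basal", "K_b", "k_phos", "d_Ap", "alpha0",
    "alpha1", "k2", "hill", "d_M", "k_T", "d_T", "V_ind", "K_ind",
    "activation_fold", "volume_ratio",
)

# reaction id -> (reactants, products, sympy rate in species/parameter symbols)
# transport reactions move AI-2 across the membrane; volume_ratio scales
# the extracellular side exactly as in the built-in right-hand side.
def _reactions():
    Ae, Ai, Ap, M, T = sp.symbols("Ae Ai Ap M T")
    (K_synth, V_ydgG, basal, K_b, k_phos, d_Ap, alpha0, alpha1, k2, hill,
     d_M, k_T, d_T, V_ind, K_ind) = sp.symbols(
        "K_synth V_ydgG basal K_b k_phos d_Ap alpha0 alpha1 k2 hill "
        "d_M k_T d_T V_ind K_ind"
    )
    return {
        "synthesis": ((), ("Ai",), K_synth),
        "basal_import": (("Ae",), ("Ai",), basal * Ae / (K_b + Ae)),
        "induced_import": (("Ae",), ("Ai",), V_ind * T * Ae / (K_ind + Ae)),
        "export": (("Ai",), ("Ae",), V_ydgG * Ai),
        "phosphorylation": (("Ai",), ("Ap",), k_phos * Ai),
        "ap_degradation": (("Ap",), (), d_Ap * Ap),
        "transcription": ((), ("M",), alpha0 + alpha1 * Ap**hill / (k2**hill + Ap**hill)),
        "mrna_decay": (("M",), (), d_M * M),
        "translation": ((), ("T",), k_T * M),
        "transporter_decay": (("T",), (), d_T * T),
    }


def _expr_to_mathml(expr: sp.Expr) -> etree._Element:
    M = lambda tag: etree.SubElement  # noqa: E731 - brevity below

    def build(e, parent):
        if isinstance(e, sp.Symbol):
            ci = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
            ci.text = f" {e.name} "
        elif isinstance(e, (sp.Integer, sp.Float, sp.Rational)) or e.is_Number:
            cn = etree.SubElement(parent, f"{{{MATHML_NS}}}cn")
            cn.text = f" {float(e)} "
        elif isinstance(e, sp.Add):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}plus")
            for a in e.args:
                build(a, ap)
        elif isinstance(e, sp.Mul):
            num, den = sp.fraction(sp.together(e))
            if den != 1:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}divide")
                build(num, ap)
                build(den, ap)
            else:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}times")
                for a in e.args:
                    build(a, ap)
        elif isinstance(e, sp.Pow):
            if e.exp.is_Number and e.exp < 0:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}divide")
                cn = etree.SubElement(ap, f"{{{MATHML_NS}}}cn")
                cn.text = " 1.0 "
                build(sp.Pow(e.base, -e.exp), ap)
            else:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}power")
                build(e.base, ap)
                build(e.exp, ap)
        else:
            raise ValueError(f"unsupported expression node: {e!r}")

    math = etree.Element(f"{{{MATHML_NS}}}math")
    build(sp.expand(expr) if expr.is_Add else expr, math)
    return math


def _mathml_to_expr(node: etree._Element) -> sp.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ValueError("math element must have exactly one child")
        return _mathml_to_expr(children[0])
    if tag == "ci":
        return sp.Symbol(node.text.strip())
    if tag == "cn":
        return sp.Float(node.text.strip())
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_expr(c) for c in children[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "times":
            return sp.Mul(*args)
        if op == "minus":
            return args[0] - args[1] if len(args) == 2 else -args[0]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        raise ValueError(f"unsupported MathML operator: {op}")
    raise ValueError(f"unsupported MathML element: {tag}")


@dataclass
class SbmlModel:
    """Result of an SBML import: parameters plus symbolic reactions."""

    params: LsrParams
    volume_ratio: float
    reactions: dict  # id -> (reactants, products, sympy expression)

    def rhs(self, state: LsrCellState) -> LsrCellState:
        """Evaluate the imported right-hand side at ``state``."""
        subs = {sp.Symbol(n): getattr(state, n) for n in _SPECIES}
        for n in _PARAMETER_NAMES:
            if n == "volume_ratio":
                subs[sp.Symbol(n)] = self.volume_ratio
            else:
                subs[sp.Symbol(n)] = getattr(self.params, n)
        deriv = dict.fromkeys(_SPECIES, 0.0)
        vr = self.volume_ratio
        for _rid, (reac, prod, expr) in self.reactions.items():
            rate = float(expr.evalf(subs=subs))
            for s in reac:
                deriv[s] -= rate * (vr if s == "Ae" else 1.0)
            for s in prod:
                deriv[s] += rate * (vr if s == "Ae" else 1.0)
        return LsrCellState(**deriv)


def save_sbml(params: LsrParams, path, volume_ratio: float = 1.0 / 24.0) -> None:
    """Write the Lsr system as an SBML Level 3 document."""
    nsmap = {None: SBML_NS}
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model", id="lsr_ai2")
    comps = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cid, size in (("cytosol", 1.0), ("medium", 24.0)):
        etree.SubElement(
            comps, f"{{{SBML_NS}}}compartment",
            id=cid, size=str(size), constant="true",
        )
    species = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sid in _SPECIES:
        etree.SubElement(
            species, f"{{{SBML_NS}}}species",
            id=sid,
            compartment="medium" if sid == "Ae" else "cytosol",
            initialConcentration="0",
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )
    plist = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in _PARAMETER_NAMES:
        value = volume_ratio if name == "volume_ratio" else getattr(params, name)
        etree.SubElement(
            plist, f"{{{SBML_NS}}}parameter",
            id=name, value=repr(float(value)), constant="true",
        )
    rxns = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rid, (reac, prod, expr) in _reactions().items():
        r = etree.SubElement(
            rxns, f"{{{SBML_NS}}}reaction", id=rid, reversible="false"
        )
        if reac:
            lor = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for s in reac:
                etree.SubElement(
                    lor, f"{{{SBML_NS}}}speciesReference",
                    species=s, stoichiometry="1", constant="true",
                )
        if prod:
            lop = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for s in prod:
                etree.SubElement(
                    lop, f"{{{SBML_NS}}}speciesReference",
                    species=s, stoichiometry="1", constant="true",
                )
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_expr_to_mathml(expr))
    etree.ElementTree(sbml).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def load_sbml(path) -> SbmlModel:
    """Read an SBML document written by :func:`save_sbml` (or compatible).

    Raises a descriptive error listing identifiers that do not match the
    Lsr system's species/parameters.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError(f"{path}: no <model> element (not SBML level 3?)")

    values: dict[str, float] = {}
    for p in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        values[p.get("id")] = float(p.get("value"))
    unknown = sorted(set(values) - set(_PARAMETER_NAMES))
    missing = sorted(set(_PARAMETER_NAMES) - set(values))
    if missing:
        raise ValueError(f"{path}: unmatched parameter identifiers; missing {missing}"
                         + (f", unknown {unknown}" if unknown else ""))

    found_species = [
        s.get("id")
        for s in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
    ]
    missing_sp = sorted(set(_SPECIES) - set(found_species))
    if missing_sp:
        raise ValueError(f"{path}: missing species {missing_sp}")

    vr = values.pop("volume_ratio")
    values.pop("activation_fold_extras", None)
    params = LsrParams(**{k: v for k, v in values.items()})

    reactions = {}
    for r in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = r.get("id")
        reac = tuple(
            sr.get("species")
            for sr in r.findall(
                f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
            )
        )
        prod = tuple(
            sr.get("species")
            for sr in r.findall(
                f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
            )
        )
        math = r.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        if math is None:
            raise ValueError(f"{path}: reaction {rid} has no kinetic law")
        reactions[rid] = (reac, prod, _mathml_to_expr(math))
    return SbmlModel(params=params, volume_ratio=vr, reactions=reactions)
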