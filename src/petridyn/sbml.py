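"""SBML (Level 2/3) subset importer.

Maps the mass-action fragment of SBML onto Pathway Petri Nets: species
become places, reactions become transitions (reversible reactions are
split into a forward transition and an ``_Reverse`` one), reactant and
product references become weighted arcs, and modifiers become promoter
arcs — or inhibitor arcs when an SBO term or an explicit per-model
override says so.  Models that use constructs outside the subset (rules,
events, non-mass-action rate laws) are *rejected*, never silently
mangled: screening a model collection requires knowing which models were
dropped and why.

Only a deliberately narrow slice of SBML is understood; see
:data:`INHIBITOR_SBO_TERMS` and :func:`import_sbml` for the contract.
"""

from __future__ import annotations

import re
from pathlib import Path

from lxml import etree

from .core import PPN, Arc, KineticLaw, ValidationError, validate

__all__ = ["UnsupportedSBMLError", "import_sbml", "INHIBITOR_SBO_TERMS"]

#: SBO terms classifying a modifier as an inhibitor.  Everything else
#: (catalyst, stimulator, unspecified) defaults to promoter: SBML does not
#: distinguish promotion from inhibition structurally, and SBO coverage in
#: public repositories is patchy, hence the ``modifier_roles`` override.
INHIBITOR_SBO_TERMS = frozenset(
    {"SBO:0000020", "SBO:0000206", "SBO:0000207", "SBO:0000536", "SBO:0000537", "SBO:0000597"}
)

_PROMOTER = "promoter"
_INHIBITOR = "inhibitor"


class UnsupportedSBMLError(ValueError):
    """The model uses a construct outside the supported subset."""

    def __init__(self, feature: str, detail: str = ""):
        self.feature = feature
        msg = f"unsupported: {feature}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _findall(elem, name: str):
    return [c for c in elem.iter() if isinstance(c.tag, str) and _local(c.tag) == name]


def _children(elem, name: str):
    return [c for c in elem if isinstance(c.tag, str) and _local(c.tag) == name]


def _child(elem, name: str):
    found = _children(elem, name)
    return found[0] if found else None


def _stoich(ref) -> int:
    raw = ref.get("stoichiometry", "1")
    val = float(raw)
    n = int(round(val))
    if abs(val - n) > 1e-9 or n < 1:
        raise UnsupportedSBMLError("non-integer stoichiometry", raw)
    return n


# ---------------------------------------------------------------------------
# MathML mass-action recognition


class _NotMassAction(Exception):
    pass


def _flatten_product(node, symbols: dict[str, float], species: set[str]):
    """Reduce a MathML product to (numeric factor, {species: power}).

    ``symbols`` maps parameter/compartment identifiers to values; any
    other ``ci`` must be a species.  Raises :class:`_NotMassAction` for
    anything that is not a plain product of symbols and integer powers.
    """
    name = _local(node.tag)
    if name == "ci":
        ident = node.text.strip()
        if ident in species:
            return 1.0, {ident: 1}
        if ident in symbols:
            return symbols[ident], {}
        raise _NotMassAction(f"unknown symbol {ident!r}")
    if name == "cn":
        return float(node.text.strip()), {}
    if name == "apply":
        kids = [c for c in node if isinstance(c.tag, str)]
        op = _local(kids[0].tag)
        if op == "times":
            k, pows = 1.0, {}
            for child in kids[1:]:
                ck, cp = _flatten_product(child, symbols, species)
                k *= ck
                for s, e in cp.items():
                    pows[s] = pows.get(s, 0) + e
            return k, pows
        if op == "power" and len(kids) == 3:
            base_k, base_p = _flatten_product(kids[1], symbols, species)
            if _local(kids[2].tag) != "cn":
                raise _NotMassAction("non-constant exponent")
            exp = float(kids[2].text.strip())
            n = int(round(exp))
            if abs(exp - n) > 1e-9 or n < 0:
                raise _NotMassAction(f"non-integer exponent {exp}")
            return base_k**n, {s: e * n for s, e in base_p.items()}
        raise _NotMassAction(f"operator {op!r}")
    raise _NotMassAction(f"element {name!r}")


def _match_term(node, symbols, species, expected: dict[str, int]) -> float:
    """Recognize ``k * prod(species^stoich)`` and return k."""
    k, pows = _flatten_product(node, symbols, species)
    if pows != {s: w for s, w in expected.items() if w > 0}:
        raise _NotMassAction(f"species powers {pows} do not match stoichiometry {expected}")
    if not k > 0:
        raise _NotMassAction(f"non-positive rate constant {k}")
    return k


def _rate_constants(kinetic_law, symbols, species, fwd: dict[str, int], rev: dict[str, int], reversible: bool):
    """Extract (k_forward, k_reverse|None) from a kineticLaw element."""
    math = _child(kinetic_law, "math")
    if math is None:
        raise _NotMassAction("missing math")
    body = [c for c in math if isinstance(c.tag, str)]
    if len(body) != 1:
        raise _NotMassAction("math with multiple roots")
    node = body[0]
    if reversible:
        if _local(node.tag) == "apply":
            kids = [c for c in node if isinstance(c.tag, str)]
            if _local(kids[0].tag) == "minus" and len(kids) == 3:
                return (
                    _match_term(kids[1], symbols, species, fwd),
                    _match_term(kids[2], symbols, species, rev),
                )
        raise _NotMassAction("reversible rate law is not a difference of mass-action terms")
    return _match_term(node, symbols, species, fwd), None


# ---------------------------------------------------------------------------


def import_sbml(
    path: str | Path,
    modifier_roles: dict[str, str] | None = None,
    on_unrecognized_rate: str = "reject",
) -> PPN:
    """Import an SBML Level 2/3 model as a PPN.

    Parameters
    ----------
    path:
        SBML file.
    modifier_roles:
        Per-model override table mapping a species id (or a
        ``"reaction:species"`` pair) to ``"promoter"`` or ``"inhibitor"``;
        consulted before SBO terms.
    on_unrecognized_rate:
        ``"reject"`` (default) raises :class:`UnsupportedSBMLError` when a
        kinetic law is not recognizably mass action; ``"fit"`` assigns the
        first locally declared parameter value (else 1.0) as the
        mass-action constant instead.

    Raises
    ------
    UnsupportedSBMLError
        If the model contains rules, events, or (under the default
        policy) an unrecognized rate law.
    """
    if on_unrecognized_rate not in ("reject", "fit"):
        raise ValueError(f"bad policy {on_unrecognized_rate!r}")
    modifier_roles = modifier_roles or {}
    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise UnsupportedSBMLError("not an SBML document", _local(root.tag))
    model = _child(root, "model")
    if model is None:
        raise UnsupportedSBMLError("missing model element")

    for feature, tags in (
        ("rules", ("assignmentRule", "rateRule", "algebraicRule")),
        ("events", ("event",)),
    ):
        for tag in tags:
            if _findall(model, tag):
                raise UnsupportedSBMLError(feature)

    symbols: dict[str, float] = {}
    for comp in _findall(model, "compartment"):
        symbols[comp.get("id", "")] = float(comp.get("size", comp.get("volume", "1") or "1"))
    lop = _child(model, "listOfParameters")
    if lop is not None:
        for par in _children(lop, "parameter"):
            symbols[par.get("id", "")] = float(par.get("value", "0") or "0")

    ppn = PPN()
    species_ids: set[str] = set()
    for sp in _findall(model, "species"):
        sid = sp.get("id")
        if not sid:
            raise UnsupportedSBMLError("species without id")
        species_ids.add(sid)
        ppn.places.add(sid)
        conc = sp.get("initialConcentration", sp.get("initialAmount", "0"))
        ppn.initial_marking[sid] = float(conc or "0")
        name = sp.get("name")
        if name:
            ppn.display_names[sid] = name

    def modifier_role(rid: str, sid: str, sbo: str | None) -> str:
        for key in (f"{rid}:{sid}", sid):
            if key in modifier_roles:
                return modifier_roles[key]
        if sbo and sbo in INHIBITOR_SBO_TERMS:
            return _INHIBITOR
        return _PROMOTER

    for rx in _findall(model, "reaction"):
        rid = rx.get("id")
        if not rid:
            raise UnsupportedSBMLError("reaction without id")
        if rid in species_ids:  # prevent namespace collision after import
            rid = f"t_{rid}"
        reversible = rx.get("reversible", "true").lower() == "true"

        fwd: dict[str, int] = {}
        rev: dict[str, int] = {}
        lor = _child(rx, "listOfReactants")
        if lor is not None:
            for ref in _children(lor, "speciesReference"):
                fwd[ref.get("species")] = fwd.get(ref.get("species"), 0) + _stoich(ref)
        lopr = _child(rx, "listOfProducts")
        if lopr is not None:
            for ref in _children(lopr, "speciesReference"):
                rev[ref.get("species")] = rev.get(ref.get("species"), 0) + _stoich(ref)
        mods: list[tuple[str, str]] = []
        lom = _child(rx, "listOfModifiers")
        if lom is not None:
            for ref in _children(lom, "modifierSpeciesReference"):
                mods.append((ref.get("species"), modifier_role(rid, ref.get("species"), ref.get("sboTerm"))))

        local_symbols = dict(symbols)
        kl = _child(rx, "kineticLaw")
        first_local: float | None = None
        if kl is not None:
            for plist in ("listOfParameters", "listOfLocalParameters"):
                pl = _child(kl, plist)
                if pl is not None:
                    for par in list(_children(pl, "parameter")) + list(_children(pl, "localParameter")):
                        val = float(par.get("value", "0") or "0")
                        local_symbols[par.get("id", "")] = val
                        if first_local is None:
                            first_local = val

        k_fwd: float
        k_rev: float | None
        try:
            if kl is None:
                raise _NotMassAction("no kineticLaw")
            k_fwd, k_rev = _rate_constants(kl, local_symbols, species_ids, fwd, rev, reversible)
        except _NotMassAction as exc:
            if on_unrecognized_rate == "reject":
                raise UnsupportedSBMLError("rate law", f"reaction {rid}: {exc}") from exc
            k_fwd = first_local if first_local and first_local > 0 else 1.0
            k_rev = k_fwd if reversible else None

        def add_transition(tid: str, reactants: dict[str, int], products: dict[str, int], k: float) -> None:
            ppn.transitions.add(tid)
            ppn.kinetics[tid] = KineticLaw(rate_constant=k)
            for s, w in reactants.items():
                ppn.arcs.add(Arc(s, tid, "reactant", w))
            for s, w in products.items():
                ppn.arcs.add(Arc(tid, s, "product", w))
            for s, role in mods:
                ppn.arcs.add(Arc(s, tid, role, 1))

        add_transition(rid, fwd, rev, k_fwd)
        if reversible:
            add_transition(f"{rid}_Reverse", rev, fwd, k_rev if k_rev is not None else k_fwd)

    violations = validate(ppn)
    if violations:
        raise ValidationError(violations)
    return ppn


def strip_sbml_ws(text: str) -> str:
    """Collapse whitespace in inline SBML fixtures (testing helper)."""
    return re.sub(r">\s+<", "><", text.strip())
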