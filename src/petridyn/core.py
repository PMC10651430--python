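"""Pathway Petri Net (PPN) data model and structural validation.

A PPN is a bipartite directed graph over *places* (molecular species) and
*transitions* (reactions).  Arcs are typed by the role the species plays in
the reaction — ``reactant``, ``product``, ``promoter`` or ``inhibitor`` —
and weighted by an integer stoichiometric coefficient.  Each transition
carries a mass-action kinetic law and each place an initial concentration
(the *initial marking*), so the net is both a graph and a complete
specification of an ODE system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ROLES",
    "MODIFIER_ROLES",
    "Arc",
    "KineticLaw",
    "PPN",
    "ValidationError",
    "validate",
]

#: Arc roles.  Reactant/promoter/inhibitor arcs run place -> transition,
#: product arcs run transition -> place.
ROLES = ("reactant", "product", "promoter", "inhibitor")
MODIFIER_ROLES = ("promoter", "inhibitor")


class ValidationError(ValueError):
    """Raised when a PPN violates its structural invariants.

    Carries the full list of violations in ``violations``.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid PPN:\n  " + "\n  ".join(self.violations))


@dataclass(frozen=True, order=True)
class Arc:
    """A typed, weighted arc of a PPN."""

    source: str
    target: str
    role: str
    weight: int = 1


@dataclass(frozen=True)
class KineticLaw:
    """Mass-action kinetics for one transition.

    ``rate_constant`` is the mass-action constant k.  Modifier algebra:
    promoters multiply the rate by their concentration
    (``multiplicative``), inhibitors multiply it by 1/(1+[i])
    (``saturating``).  Both reduce to plain mass action when the
    transition has no modifiers.
    """

    kind: str = "mass_action"
    rate_constant: float = 1.0
    promoter_mode: str = "multiplicative"
    inhibitor_mode: str = "saturating"


@dataclass
class PPN:
    """A Pathway Petri Net.

    Invariants (checked by :func:`validate`): places and transitions are
    disjoint and nonempty; every arc endpoint exists; every transition has
    a kinetic law; arc weights are positive integers; modifier arcs have
    weight 1; reactant/modifier arcs run place->transition and product
    arcs transition->place; no duplicate (source, target, role) triples.
    """

    places: set[str] = field(default_factory=set)
    transitions: set[str] = field(default_factory=set)
    arcs: set[Arc] = field(default_factory=set)
    kinetics: dict[str, KineticLaw] = field(default_factory=dict)
    initial_marking: dict[str, float] = field(default_factory=dict)
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # every place has a marking entry (default 0.0)
        for p in self.places:
            self.initial_marking.setdefault(p, 0.0)

    # -- convenience accessors -------------------------------------------

    def marking(self, place: str) -> float:
        return self.initial_marking.get(place, 0.0)

    def arcs_of(self, transition: str, role: str) -> list[Arc]:
        """Arcs of the given role attached to ``transition``, sorted."""
        if role == "product":
            sel = [a for a in self.arcs if a.role == role and a.source == transition]
        else:
            sel = [a for a in self.arcs if a.role == role and a.target == transition]
        return sorted(sel)

    def reactants(self, t: str) -> list[tuple[str, int]]:
        return [(a.source, a.weight) for a in self.arcs_of(t, "reactant")]

    def products(self, t: str) -> list[tuple[str, int]]:
        return [(a.target, a.weight) for a in self.arcs_of(t, "product")]

    def promoters(self, t: str) -> list[str]:
        return [a.source for a in self.arcs_of(t, "promoter")]

    def inhibitors(self, t: str) -> list[str]:
        return [a.source for a in self.arcs_of(t, "inhibitor")]

    def without_arc(self, arc: Arc, prune_empty: bool = True) -> "PPN":
        """A copy of the net with ``arc`` deleted.

        A transition left with no arcs at all is pruned (it could never
        influence any species).  Used by the arc knock-out analysis.
        """
        if arc not in self.arcs:
            raise KeyError(f"arc {arc} not in PPN")
        arcs = {a for a in self.arcs if a != arc}
        transitions = set(self.transitions)
        kinetics = dict(self.kinetics)
        if prune_empty:
            touched = {a.source for a in arcs} | {a.target for a in arcs}
            for t in sorted(self.transitions):
                if t not in touched:
                    transitions.discard(t)
                    kinetics.pop(t, None)
        return PPN(
            places=set(self.places),
            transitions=transitions,
            arcs=arcs,
            kinetics=kinetics,
            initial_marking=dict(self.initial_marking),
            display_names=dict(self.display_names),
        )

    def copy(self) -> "PPN":
        return PPN(
            places=set(self.places),
            transitions=set(self.transitions),
            arcs=set(self.arcs),
            kinetics=dict(self.kinetics),
            initial_marking=dict(self.initial_marking),
            display_names=dict(self.display_names),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPN):
            return NotImplemented
        return (
            self.places == other.places
            and self.transitions == other.transitions
            and self.arcs == other.arcs
            and self.kinetics == other.kinetics
            and self.initial_marking == other.initial_marking
            and self.display_names == other.display_names
        )


def validate(ppn: PPN) -> list[str]:
    """Check all PPN structural invariants; return violation descriptions.

    Violations are data, not exceptions: an empty list means the net is
    valid.  The input is never mutated.
    """
    v: list[str] = []
    if not ppn.places:
        v.append("no places")
    if not ppn.transitions:
        v.append("no transitions")
    overlap = ppn.places & ppn.transitions
    if overlap:
        v.append(f"identifiers used as both place and transition: {sorted(overlap)}")
    nodes = ppn.places | ppn.transitions
    seen: set[tuple[str, str, str]] = set()
    for a in sorted(ppn.arcs):
        if a.source not in nodes:
            v.append(f"arc {a.source}->{a.target}: unknown source {a.source!r}")
        if a.target not in nodes:
            v.append(f"arc {a.source}->{a.target}: unknown target {a.target!r}")
        if a.role not in ROLES:
            v.append(f"arc {a.source}->{a.target}: unknown role {a.role!r}")
            continue
        if not isinstance(a.weight, int) or a.weight < 1:
            v.append(f"arc {a.source}->{a.target}: weight must be a positive integer, got {a.weight!r}")
        if a.role in MODIFIER_ROLES and a.weight != 1:
            v.append(f"{a.role} arc {a.source}->{a.target} must have weight 1, got {a.weight}")
        if a.role == "product":
            if a.source not in ppn.transitions or a.target not in ppn.places:
                v.append(f"product arc {a.source}->{a.target} must run transition->place")
        else:
            if a.source not in ppn.places or a.target not in ppn.transitions:
                v.append(f"{a.role} arc {a.source}->{a.target} must run place->transition")
        key = (a.source, a.target, a.role)
        if key in seen:
            v.append(f"duplicate arc {key}")
        seen.add(key)
    for t in sorted(ppn.transitions):
        law = ppn.kinetics.get(t)
        if law is None:
            v.append(f"transition {t}: no kinetic law")
        else:
            if law.kind != "mass_action":
                v.append(f"transition {t}: unsupported kinetic kind {law.kind!r}")
            if not law.rate_constant > 0:
                v.append(f"transition {t}: rate constant must be > 0, got {law.rate_constant}")
    for p in sorted(ppn.places):
        m = ppn.initial_marking.get(p)
        if m is None:
            v.append(f"place {p}: missing initial-marking entry")
        elif m < 0:
            v.append(f"place {p}: negative initial concentration {m}")
    for ident in sorted(nodes):
        if not ident or any(c.isspace() for c in ident):
            v.append(f"identifier {ident!r} is empty or contains whitespace")
    return v


def checked(ppn: PPN) -> PPN:
    """Return ``ppn`` unchanged, raising :class:`ValidationError` if invalid."""
    violations = validate(ppn)
    if violations:
        raise ValidationError(violations)
    return ppn
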