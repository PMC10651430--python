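"""SBML subset import: mapping, modifier classification, rejection."""

import pytest

from petridyn import UnsupportedSBMLError, import_sbml

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML = "http://www.w3.org/1998/Math/MathML"


def sbml_doc(species, reactions, extra_model=""):
    """Assemble a minimal SBML L2 document from fragments."""
    sp = "".join(
        f'<species id="{sid}" compartment="c" initialConcentration="{conc}"/>' for sid, conc in species
    )
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{SBML_NS}" level="2" version="4">
  <model id="m">
    <listOfCompartments><compartment id="c" size="1"/></listOfCompartments>
    <listOfSpecies>{sp}</listOfSpecies>
    {extra_model}
    <listOfReactions>{reactions}</listOfReactions>
  </model>
</sbml>"""


def mass_action_reaction(rid, reactants, products, k, modifiers="", reversible="false", k_rev=None):
    """Reaction with rate k * prod(reactants) (minus k_rev * prod(products) if reversible)."""
    refs = lambda pairs: "".join(
        f'<speciesReference species="{s}" stoichiometry="{w}"/>' for s, w in pairs
    )

    def term(const, pairs):
        factors = f"<ci>{const}</ci>" + "".join(
            f"<ci>{s}</ci>" if w == 1 else f"<apply><power/><ci>{s}</ci><cn>{w}</cn></apply>"
            for s, w in pairs
        )
        return f"<apply><times/>{factors}</apply>"

    if reversible == "true":
        math = f"<apply><minus/>{term('kf', reactants)}{term('kr', products)}</apply>"
        params = f'<parameter id="kf" value="{k}"/><parameter id="kr" value="{k_rev}"/>'
    else:
        math = term("k1", reactants)
        params = f'<parameter id="k1" value="{k}"/>'
    return f"""
    <reaction id="{rid}" reversible="{reversible}">
      <listOfReactants>{refs(reactants)}</listOfReactants>
      <listOfProducts>{refs(products)}</listOfProducts>
      {modifiers}
      <kineticLaw>
        <math xmlns="{MATHML}">{math}</math>
        <listOfParameters>{params}</listOfParameters>
      </kineticLaw>
    </reaction>"""


@pytest.fixture
def write(tmp_path):
    def _write(doc: str):
        path = tmp_path / "model.xml"
        path.write_text(doc)
        return path

    return _write


class TestMapping:
    def test_two_reactants_one_product_mass_action(self, write):
        doc = sbml_doc(
            [("A", 1.0), ("B", 2.0), ("C", 0.0)],
            mass_action_reaction("r1", [("A", 1), ("B", 1)], [("C", 1)], k=0.5),
        )
        ppn = import_sbml(write(doc))
        assert ppn.places == {"A", "B", "C"}
        assert ppn.transitions == {"r1"}
        assert sorted(ppn.reactants("r1")) == [("A", 1), ("B", 1)]
        assert ppn.products("r1") == [("C", 1)]
        assert ppn.kinetics["r1"].rate_constant == 0.5
        assert ppn.initial_marking == {"A": 1.0, "B": 2.0, "C": 0.0}

    def test_stoichiometric_exponents_recognized(self, write):
        doc = sbml_doc(
            [("A", 1.0), ("B", 0.0)],
            mass_action_reaction("r1", [("A", 2)], [("B", 1)], k=3.0),
        )
        ppn = import_sbml(write(doc))
        assert ppn.reactants("r1") == [("A", 2)]
        assert ppn.kinetics["r1"].rate_constant == 3.0

    def test_reversible_reaction_splits_into_forward_and_reverse(self, write):
        doc = sbml_doc(
            [("A", 1.0), ("B", 0.0)],
            mass_action_reaction("r1", [("A", 1)], [("B", 1)], k=2.0, reversible="true", k_rev=0.25),
        )
        ppn = import_sbml(write(doc))
        assert ppn.transitions == {"r1", "r1_Reverse"}
        assert ppn.kinetics["r1"].rate_constant == 2.0
        assert ppn.kinetics["r1_Reverse"].rate_constant == 0.25
        assert ppn.reactants("r1_Reverse") == [("B", 1)]
        assert ppn.products("r1_Reverse") == [("A", 1)]


class TestModifiers:
    def mods(self, sbo=None):
        attr = f' sboTerm="{sbo}"' if sbo else ""
        return f'<listOfModifiers><modifierSpeciesReference species="M"{attr}/></listOfModifiers>'

    def doc(self, modifiers):
        return sbml_doc(
            [("A", 1.0), ("B", 0.0), ("M", 1.0)],
            mass_action_reaction("r1", [("A", 1)], [("B", 1)], k=1.0, modifiers=modifiers),
        )

    def test_modifier_defaults_to_promoter(self, write):
        ppn = import_sbml(write(self.doc(self.mods())))
        assert ppn.promoters("r1") == ["M"]
        assert ppn.inhibitors("r1") == []

    def test_inhibitor_sbo_term_classifies_inhibitor(self, write):
        ppn = import_sbml(write(self.doc(self.mods(sbo="SBO:0000020"))))
        assert ppn.inhibitors("r1") == ["M"]

    def test_override_table_beats_default(self, write):
        ppn = import_sbml(write(self.doc(self.mods())), modifier_roles={"M": "inhibitor"})
        assert ppn.inhibitors("r1") == ["M"]


class TestRejection:
    def test_assignment_rule_rejected(self, write):
        rules = '<listOfRules><assignmentRule variable="A"><math/></assignmentRule></listOfRules>'
        doc = sbml_doc(
            [("A", 1.0), ("B", 0.0)],
            mass_action_reaction("r1", [("A", 1)], [("B", 1)], k=1.0),
            extra_model=rules,
        )
        with pytest.raises(UnsupportedSBMLError, match="unsupported: rules"):
            import_sbml(write(doc))

    def test_event_rejected(self, write):
        events = '<listOfEvents><event id="e"/></listOfEvents>'
        doc = sbml_doc(
            [("A", 1.0), ("B", 0.0)],
            mass_action_reaction("r1", [("A", 1)], [("B", 1)], k=1.0),
            extra_model=events,
        )
        with pytest.raises(UnsupportedSBMLError, match="unsupported: events"):
            import_sbml(write(doc))

    def non_mass_action(self):
        # Michaelis-Menten-style law: not a plain product of symbols
        math = (
            f'<math xmlns="{MATHML}"><apply><divide/>'
            "<apply><times/><ci>V</ci><ci>A</ci></apply>"
            "<apply><plus/><ci>Km</ci><ci>A</ci></apply></apply></math>"
        )
        return sbml_doc(
            [("A", 1.0), ("B", 0.0)],
            f"""<reaction id="r1" reversible="false">
              <listOfReactants><speciesReference species="A"/></listOfReactants>
              <listOfProducts><speciesReference species="B"/></listOfProducts>
              <kineticLaw>{math}
                <listOfParameters><parameter id="V" value="2.0"/><parameter id="Km" value="0.5"/></listOfParameters>
              </kineticLaw>
            </reaction>""",
        )

    def test_unrecognized_rate_law_rejected_by_default(self, write):
        with pytest.raises(UnsupportedSBMLError, match="rate law"):
            import_sbml(write(self.non_mass_action()))

    def test_fit_policy_falls_back_to_first_parameter(self, write):
        ppn = import_sbml(write(self.non_mass_action()), on_unrecognized_rate="fit")
        assert ppn.kinetics["r1"].rate_constant == 2.0  # first local parameter V

    def test_reaction_id_colliding_with_species_gets_prefixed(self, write):
        doc = sbml_doc(
            [("A", 1.0), ("B", 0.0)],
            mass_action_reaction("A", [("A", 1)], [("B", 1)], k=1.0),
        )
        ppn = import_sbml(write(doc))
        assert "t_A" in ppn.transitions
        assert ppn.places & ppn.transitions == set()
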