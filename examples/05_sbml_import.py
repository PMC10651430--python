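"""Import an SBML mass-action model as a Pathway Petri Net.

A reversible binding reaction is split into forward and _Reverse
transitions; the modifier with an inhibition SBO term becomes an
inhibitor arc.  Models using rules, events, or rate laws that are not
recognizably mass action are rejected with an explicit reason.
"""

from pathlib import Path

from petridyn import UnsupportedSBMLError, import_sbml
from petridyn.io import dumps_ppn

SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="binding">
    <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
    <listOfSpecies>
      <species id="L" compartment="cell" initialConcentration="1.0" name="ligand"/>
      <species id="R" compartment="cell" initialConcentration="0.5" name="receptor"/>
      <species id="LR" compartment="cell" initialConcentration="0.0" name="complex"/>
      <species id="X" compartment="cell" initialConcentration="0.2" name="blocker"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="bind" reversible="true">
        <listOfReactants>
          <speciesReference species="L"/><speciesReference species="R"/>
        </listOfReactants>
        <listOfProducts><speciesReference species="LR"/></listOfProducts>
        <listOfModifiers>
          <modifierSpeciesReference species="X" sboTerm="SBO:0000020"/>
        </listOfModifiers>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><minus/>
              <apply><times/><ci>kon</ci><ci>L</ci><ci>R</ci></apply>
              <apply><times/><ci>koff</ci><ci>LR</ci></apply>
            </apply>
          </math>
          <listOfParameters>
            <parameter id="kon" value="2.0"/><parameter id="koff" value="0.1"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>"""

path = Path("binding.xml")
path.write_text(SBML)
try:
    ppn = import_sbml(path)
finally:
    path.unlink()

print(dumps_ppn(ppn))
# Note the split transitions bind / bind_Reverse with constants 2.0 and
# 0.1, and the inhibitor arc X -> bind from the SBO term.
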