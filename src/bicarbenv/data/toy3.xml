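<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="toy3" name="three-reaction toy" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" name="metabolite A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"
               fbc:chemicalFormula="CH2O" fbc:charge="0"/>
      <species id="B" name="metabolite B" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"
               fbc:chemicalFormula="CH2O" fbc:charge="0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_uptake" value="-1" constant="true"/>
      <parameter id="lb_zero" value="0" constant="true"/>
      <parameter id="ub_big" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="EX_A" name="A exchange" reversible="true" fast="false"
                fbc:lowerFluxBound="lb_uptake" fbc:upperFluxBound="ub_big">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="R_AB" name="A to B" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_big">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="EX_B" name="B exchange" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_zero" fbc:upperFluxBound="ub_big">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
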