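# Domain-knowledge library for Predator-Prey population dynamics.
template entity Population {
  vars: d {aggregation: sum, unit: "kg/m3", range: <0, 500>};  # density
}
template process Growth(pop: Population) {
  consts: gR {range: <0, 5>};
}
template process ExponentialGrowth : Growth {
  equations: td(pop.d) = gR * pop.d;
}
template process LogisticGrowth : Growth {
  equations: td(pop.d) = gR * pop.d / (1 - pop.d / gR);
}
template process Decay(pop: Population) {
  consts: dR {range: <0, 2>};
  equations: td(pop.d) = -dR * pop.d;
}
template process Interaction(pop1: Population, pop2: Population) {
  consts: iR {range: <0, 2>}, eF {range: <0, 1>};
}
template process UnsaturatedPP : Interaction {
  equations: td(pop.d) = iR * eF * pop1.d * pop2.d,
             td(pop.d) = -iR * pop1.d * pop2.d;
}
template process SaturatedPP : Interaction {
  consts: sR {range: <0, 10>};
  equations: td(pop.d) = iR * eF * pop1.d * pop2.d / (pop2.d + sR),
             td(pop.d) = -iR * pop1.d * pop2.d / (pop2.d + sR);
}
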