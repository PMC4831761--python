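# Modeling assumptions: predator growth and the interaction are left at
# their general templates (2 x 2 alternatives -> 4 candidate structures);
# decay is pinned to its (leaf) template.
incomplete model PredatorPrey {
  entity prey : Population;
  entity predator : Population;
  process growth : Growth(pop = prey);
  process predator_prey : Interaction(pop1 = predator, pop2 = prey);
  process decay : Decay(pop = predator);
}
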