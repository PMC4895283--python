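# Intramolecular per-pair energies [kcal/mol], on top of helix initiation
# (+4.0 once per helix, on its innermost pair) and the stacking terms in
# stack_energies.tsv.  Weak pair types carry a small extra cost.
# pair	energy
CG	0.0
GC	0.0
AU	0.3
UA	0.3
GU	0.6
UG	0.6
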