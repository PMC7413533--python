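# Example RegionConfig for a ZitR homodimer (chains A and B).
#
# Secondary-structure residue ranges are NOT built into the package: they
# come from the structure annotation of the entry you analyse (the ranges
# below are placeholders in plausible positions — replace them with the
# annotated ranges of your structure).  The probe residue defaults to 71
# (A71/A71'), whose two C-alpha atoms define the recognition-helix
# separation; the DNA-binding domain spans the start of alpha2 through
# the end of beta2.
protein_chains: [A, B]
dna_binding_domain: [39, 100]
elements:
  alpha1: [5, 25]
  loop1: [26, 38]
  alpha2: [39, 50]
  alpha3: [53, 60]
  alpha4: [63, 76]
  beta1: [80, 86]
  beta2: [93, 100]
  alpha5: [103, 118]
  alpha6: [122, 140]
probe_residue: 71
temperature: 300.0
dna_chains: []
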