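# Default cofactor identifiers removed during reaction simplification.
# The list is editable; every run logs the list actually used.
# Acyl donors such as acetyl-CoA are deliberately NOT listed (they carry the
# transferred group).
cofactors:
  - H2O
  - H(+)
  - H+
  - O2
  - CO2
  - NH3
  - Phosphate
  - Pi
  - Diphosphate
  - PPi
  - ATP
  - ADP
  - AMP
  - NAD(+)
  - NAD+
  - NADH
  - NADP(+)
  - NADP+
  - NADPH
  - FAD
  - FADH2
  - CoA
  - SAM
  - S-Adenosyl-L-methionine
  - SAH
  - S-Adenosyl-L-homocysteine
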