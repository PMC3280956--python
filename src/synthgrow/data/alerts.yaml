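# Unwanted-substructure alerts for building-block curation: reactive or
# promiscuous groups excluded from the purchasable catalog. The list is
# configurable per run (pass your own file to `synthgrow prep --alerts`).
# Deliberate scope choices: azide is absent (the click cycloaddition
# templates require azide blocks) and the alkyl-halide alert exempts
# benzylic/allylic/alpha-carbonyl-activated halides, which serve as coupling
# handles. FGA/FGI-derived blocks are not re-screened against this list,
# so handles introduced on purpose (e.g. isocyanates) survive.
version: 1
alerts:
  - id: acyl_halide
    smarts: "[#6][CX3](=[OX1])[Cl,Br,I]"
  - id: isocyanate
    smarts: "[NX2]=[CX2]=[OX1]"
  - id: epoxide_aziridine
    smarts: "[O,N;r3]1[#6r3][#6r3]1"
  - id: peroxide
    smarts: "[OX2][OX2]"
  - id: michael_acceptor_aldehyde
    smarts: "[CX3H1](=[OX1])[CX3]=[CX3]"
  - id: unactivated_alkyl_halide
    smarts: "[Cl,Br,I][CX4;!$([CX4]a);!$([CX4][CX3]=[C,O,N,S]);!$([CX4]C#C)]"
  - id: anhydride
    smarts: "[CX3](=[OX1])[OX2][CX3](=[OX1])"
  - id: diazonium
    smarts: "[N+]#N"
  - id: thiol
    smarts: "[SX2H1]"
  - id: nitroso
    smarts: "[NX2]=[OX1;!$([OX1][O,N])]"
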