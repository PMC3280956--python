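# Functional group addition / interconversion (FGA/FGI) preprocessing
# reactions: one-component transforms that create reactive handles on
# building blocks before coupling. Same schema as coupling.yaml.
# The boronation leaving-group formula is mass bookkeeping only, not a
# mechanistic statement.
version: 1
templates:
  - id: fgi_nitro_reduction
    name: Nitro to primary amine reduction
    smarts: "[#6:1][NX3+:2](=[OX1])[OX1-]>>[#6:1][NH2+0:2]"
    dummy_fragments: ["C[N+](=O)[O-]"]
    reagent_gain: H6
    leaving_group: H4O2
    reference: "catalytic hydrogenation of nitro group"
  - id: fgi_nitrile_reduction
    name: Nitrile to primary amine reduction
    smarts: "[#6:1][CX2:2]#[NX1:3]>>[#6:1][CH2:2][NH2:3]"
    dummy_fragments: ["CC#N"]
    reagent_gain: H4
    reference: "LiAlH4 reduction of nitrile"
  - id: fgi_ester_hydrolysis
    name: Methyl ester hydrolysis to acid
    smarts: "[#6:4][CX3:1](=[OX1:2])[OX2][CH3]>>[#6:4][C:1](=[O:2])[OX2H1]"
    dummy_fragments: ["COC(C)=O"]
    reagent_gain: H2O
    leaving_group: CH4O
    reference: "saponification of methyl ester"
  - id: fga_amine_to_isocyanate
    name: Primary amine to isocyanate
    smarts: "[#6:1][NX3H2;+0;!$(N[C,S,P]=[O,S,N]);!$(NN):2]>>[#6:1][NX2:2]=C=O"
    dummy_fragments: ["CN"]
    reagent_gain: CCl2O
    leaving_group: HCl.HCl
    reference: "phosgenation of primary amine"
  - id: fgi_halide_to_azide
    name: Alkyl bromide to azide
    smarts: "[CX4;!$(C=O):1][Br]>>[C:1][NX2+0]=[N+]=[N-]"
    dummy_fragments: ["CBr"]
    reagent_gain: HN3
    leaving_group: HBr
    reference: "nucleophilic substitution with sodium azide"
  - id: fgi_bromide_to_boronic_acid
    name: Aryl bromide to boronic acid
    smarts: "[c:1][Br]>>[c:1][B]([OX2H1])[OX2H1]"
    dummy_fragments: ["Brc1ccccc1"]
    reagent_gain: BH3O3
    leaving_group: HBrO
    reference: "Miyaura borylation"
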