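# Coupling reaction library: one- and two-component reactions encoded as
# reaction SMARTS over neutral-form molecules. Reactant patterns describe
# only the reaction center; R-groups stay variable. Each record declares the
# minimal dummy fragment per component, a leaving-group formula and (where a
# non-denominated reagent contributes atoms) a reagent-gain formula, so that
# product mass = sum(reactant masses) + reagent_gain - leaving_group.
# Regioisomer-producing reactions are split into variants sharing a
# regioisomer_group. Extend by appending records with the same schema.
version: 1
templates:
  - id: amide_coupling
    name: Amide coupling
    smarts: "[CX3:1](=[OX1:2])[OX2H1].[NX3;H2,H1;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):3]>>[C:1](=[O:2])[N:3]"
    dummy_fragments: ["OC=O", "CN"]
    leaving_group: H2O
    reference: "carbodiimide-mediated acid/amine condensation"
  - id: ester_formation
    name: Ester formation
    smarts: "[CX3:1](=[OX1:2])[OX2H1].[OX2H1;$([OX2H1][CX4]):3]>>[C:1](=[O:2])[O:3]"
    dummy_fragments: ["OC=O", "CO"]
    leaving_group: H2O
    reference: "Fischer/Steglich esterification"
  - id: sulfonamide_formation
    name: Sulfonamide formation
    smarts: "[#6:1][SX4:2](=[OX1:3])(=[OX1:4])[Cl].[NX3;H2,H1;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):5]>>[#6:1][S:2](=[O:3])(=[O:4])[N:5]"
    dummy_fragments: ["CS(=O)(=O)Cl", "CN"]
    leaving_group: HCl
    reference: "sulfonyl chloride + amine"
  - id: sulfonate_ester_formation
    name: Sulfonate ester formation
    smarts: "[#6:1][SX4:2](=[OX1:3])(=[OX1:4])[Cl].[OX2H1;$([OX2H1][CX4]):5]>>[#6:1][S:2](=[O:3])(=[O:4])[O:5]"
    dummy_fragments: ["CS(=O)(=O)Cl", "CO"]
    leaving_group: HCl
    reference: "sulfonyl chloride + alcohol"
  - id: suzuki_coupling
    name: Suzuki-Miyaura biaryl coupling
    smarts: "[c:1][Br].[c:2][BX3]([OX2H1])[OX2H1]>>[c:1][c:2]"
    dummy_fragments: ["Brc1ccccc1", "OB(O)c1ccccc1"]
    leaving_group: H2BBrO2
    reference: "Pd-catalyzed aryl halide + arylboronic acid"
  - id: buchwald_amination
    name: Buchwald-Hartwig amination
    smarts: "[c:1][Br].[NX3;H2,H1;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):2]>>[c:1][N:2]"
    dummy_fragments: ["Brc1ccccc1", "CN"]
    leaving_group: HBr
    reference: "Pd-catalyzed aryl halide amination"
  - id: williamson_ether
    name: Williamson ether synthesis
    smarts: "[CX4;!$(C=O):1][Br].[OX2H1;$([OX2H1][CX4]):2]>>[C:1][O:2]"
    dummy_fragments: ["CBr", "CO"]
    leaving_group: HBr
    reference: "alkyl halide + alkoxide"
  - id: n_alkylation
    name: Amine N-alkylation
    smarts: "[CX4;!$(C=O):1][Br].[NX3;H2,H1;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):2]>>[C:1][N:2]"
    dummy_fragments: ["CBr", "CN"]
    leaving_group: HBr
    reference: "alkyl halide + amine"
  - id: sonogashira_coupling
    name: Sonogashira coupling
    smarts: "[c:1][Br].[CX2H1:2]#[CX2:3]>>[c:1][C:2]#[C:3]"
    dummy_fragments: ["Brc1ccccc1", "C#C"]
    leaving_group: HBr
    reference: "Pd/Cu aryl halide + terminal alkyne"
  - id: reductive_amination
    name: Reductive amination
    smarts: "[CX3H1:1]=[OX1].[NX3;H2;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):2]>>[CH2:1][NH1:2]"
    dummy_fragments: ["CC=O", "CN"]
    leaving_group: H2O
    reagent_gain: H2
    reference: "aldehyde + primary amine, borohydride reduction"
  - id: carbamate_formation
    name: Carbamate formation
    smarts: "[Cl][CX3:1](=[OX1:2])[OX2:3].[NX3;H2,H1;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):4]>>[N:4][C:1](=[O:2])[O:3]"
    dummy_fragments: ["COC(=O)Cl", "CN"]
    leaving_group: HCl
    reference: "chloroformate + amine"
  - id: urea_formation
    name: Urea formation
    smarts: "[NX2:1]=[CX2:2]=[OX1:3].[NX3;H2,H1;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):4]>>[NH1:1][C:2](=[O:3])[N:4]"
    dummy_fragments: ["CN=C=O", "CN"]
    reference: "isocyanate + amine"
  - id: thiourea_formation
    name: Thiourea formation
    smarts: "[NX2:1]=[CX2:2]=[SX1:3].[NX3;H2,H1;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):4]>>[NH1:1][C:2](=[S:3])[N:4]"
    dummy_fragments: ["CN=C=S", "CN"]
    reference: "isothiocyanate + amine"
  - id: acylhydrazone_formation
    name: Acylhydrazone formation
    smarts: "[CX3H1:1]=[OX1].[CX3:4](=[OX1:5])[NX3H1:6][NX3H2:7]>>[C:4](=[O:5])[N:6][N:7]=[CH1:1]"
    dummy_fragments: ["CC=O", "NNC=O"]
    leaving_group: H2O
    reference: "aldehyde + acylhydrazide condensation"
  - id: paal_knorr_pyrrole
    name: Paal-Knorr pyrrole synthesis
    smarts: "[#6:3][CX3:1](=[OX1])[CX4H2:4][CX4H2:5][CX3:6](=[OX1])[#6:8].[NX3;H2;+0;!$(N[C,S,P]=[O,S,N]);!$(NN);!$(N=*):9]>>[#6:3][C:1]1=[CH1:4][CH1:5]=[C:6]([#6:8])[NH0:9]1"
    dummy_fragments: ["CC(=O)CCC(=O)C", "CN"]
    ring_forming: true
    leaving_group: H4O2
    reference: "1,4-diketone + primary amine cyclocondensation"
  - id: benzimidazole_formation
    name: Benzimidazole formation
    smarts: "[NX3H2:7][c:2]1[c:3]([NX3H2:8])[c:4][c:5][c:6][c:1]1.[CX3:9](=[OX1])[OX2H1]>>[NH1:7]1[c:2]2[c:1][c:6][c:5][c:4][c:3]2[NH0:8]=[C:9]1"
    dummy_fragments: ["Nc1ccccc1N", "OC=O"]
    ring_forming: true
    leaving_group: H4O2
    reference: "1,2-arylenediamine + carboxylic acid cyclocondensation"
  - id: hantzsch_thiazole
    name: Hantzsch thiazole synthesis
    smarts: "[#6:1][CX3:2](=[OX1])[CX4H2:3][Br].[NX3H2:4][CX3:5](=[SX1:6])[#6:7]>>[#6:1][C:2]1=[CH1:3][S:6][C:5]([#6:7])=[NH0:4]1"
    dummy_fragments: ["CC(=O)CBr", "CC(N)=S"]
    ring_forming: true
    leaving_group: H3BrO
    reference: "alpha-bromoketone + thioamide cyclization"
  - id: pyrazole_formation_a
    name: Pyrazole formation (N1 at first carbonyl)
    smarts: "[#6:1][CX3:2](=[OX1])[CX4H2:3][CX3:4](=[OX1])[#6:5].[NX3H2:6][NX3H1:7][#6;!$([#6]=[O,S,N]):8]>>[#6:1][C:2]1=[NH0:6][N:7]([#6:8])[C:4]([#6:5])=[CH1:3]1"
    dummy_fragments: ["CC(=O)CC(=O)C", "CNN"]
    ring_forming: true
    regioisomer_group: pyrazole_condensation
    leaving_group: H4O2
    reference: "1,3-diketone + monosubstituted hydrazine"
  - id: pyrazole_formation_b
    name: Pyrazole formation (N1 at second carbonyl)
    smarts: "[#6:1][CX3:2](=[OX1])[CX4H2:3][CX3:4](=[OX1])[#6:5].[NX3H2:6][NX3H1:7][#6;!$([#6]=[O,S,N]):8]>>[#6:5][C:4]1=[NH0:6][N:7]([#6:8])[C:2]([#6:1])=[CH1:3]1"
    dummy_fragments: ["CC(=O)CC(=O)C", "CNN"]
    ring_forming: true
    regioisomer_group: pyrazole_condensation
    leaving_group: H4O2
    reference: "1,3-diketone + monosubstituted hydrazine"
  - id: triazole_click_14
    name: Azide-alkyne cycloaddition (1,4-triazole)
    smarts: "[#6:6][NX2:1]=[NX2+:2]=[NX1-:3].[CX2H1:4]#[CX2:5]>>[#6:6][N+0:1]1[CH1:4]=[C:5][N+0:3]=[N+0:2]1"
    dummy_fragments: ["CN=[N+]=[N-]", "C#C"]
    ring_forming: true
    regioisomer_group: azide_alkyne_cycloaddition
    reference: "Cu(I)-catalyzed click cycloaddition, 1,4-regioisomer"
  - id: triazole_click_15
    name: Azide-alkyne cycloaddition (1,5-triazole)
    smarts: "[#6:6][NX2:1]=[NX2+:2]=[NX1-:3].[CX2H1:4]#[CX2:5]>>[#6:6][N+0:1]1[C:5]=[CH1:4][N+0:3]=[N+0:2]1"
    dummy_fragments: ["CN=[N+]=[N-]", "C#C"]
    ring_forming: true
    regioisomer_group: azide_alkyne_cycloaddition
    reference: "Ru-catalyzed click cycloaddition, 1,5-regioisomer"
  - id: tetrazole_from_nitrile
    name: Tetrazole formation from nitrile
    smarts: "[#6:1][CX2:2]#[NX1:3]>>[#6:1][C:2]1=[N:3][N]=[N][NH1]1"
    dummy_fragments: ["CC#N"]
    ring_forming: true
    reagent_gain: HN3
    reference: "nitrile + azide [3+2] cycloaddition"
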