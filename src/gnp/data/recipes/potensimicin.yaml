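# Synthetic reconstruction of the potensimicin (N. potens) library: a
# narbonolide-type polyketide backbone either macrocyclized on the distal
# hydroxyl or left linear; the linear form glycosylated with angolosamine
# and mycaminose/ravidosamine, either alone, or neither (two independent
# hydroxyl sites); the lone free hydroxyl of the macrolide glycosylated
# with either sugar or left bare; and all methylmalonates interchangeable
# with malonate, read as the all-methyl backbone plus each single swap.
# Diastereomers (mycaminose/ravidosamine) share one constitution, so one
# option covers both. 6 x 2 x 2 + 6 x 3 = 42 structures.
name: potensimicin
blocks:
  - name: potensimicin-linear
    scaffolds:
      - id: linear
        smiles: "CCC([*:10])C(O[*:21])C([*:11])C(O[*:20])C([*:12])C(=O)C([*:13])CC([*:14])C(=O)O"
    axes:
      - label: backbone
        sites: [10, 11, 12, 13, 14]
        description: all-methylmalonate backbone plus each single malonate swap
        options:
          - {name: all-mmal, groups: ["[*:10]C", "[*:11]C", "[*:12]C", "[*:13]C", "[*:14]C"]}
          - {name: mal-1, groups: ["[*:10][H]", "[*:11]C", "[*:12]C", "[*:13]C", "[*:14]C"]}
          - {name: mal-2, groups: ["[*:10]C", "[*:11][H]", "[*:12]C", "[*:13]C", "[*:14]C"]}
          - {name: mal-3, groups: ["[*:10]C", "[*:11]C", "[*:12][H]", "[*:13]C", "[*:14]C"]}
          - {name: mal-4, groups: ["[*:10]C", "[*:11]C", "[*:12]C", "[*:13][H]", "[*:14]C"]}
          - {name: mal-5, groups: ["[*:10]C", "[*:11]C", "[*:12]C", "[*:13]C", "[*:14][H]"]}
      - label: glyco-proximal
        sites: [20]
        options:
          - {name: bare, groups: ["[*:20][H]"]}
          - {name: angolosamine, groups: ["[*:20]C1CC(N(C)C)C(O)C(C)O1"]}
      - label: glyco-distal
        sites: [21]
        options:
          - {name: bare, groups: ["[*:21][H]"]}
          - {name: mycaminose, groups: ["[*:21]C1OC(C)C(O)C(N(C)C)C1O"]}
  - name: potensimicin-macro
    scaffolds:
      - id: macrolide
        smiles: "CCC([*:10])C(O8)C([*:11])C(O[*:20])C([*:12])C(=O)C([*:13])CC([*:14])C8=O"
    axes:
      - label: backbone
        sites: [10, 11, 12, 13, 14]
        options:
          - {name: all-mmal, groups: ["[*:10]C", "[*:11]C", "[*:12]C", "[*:13]C", "[*:14]C"]}
          - {name: mal-1, groups: ["[*:10][H]", "[*:11]C", "[*:12]C", "[*:13]C", "[*:14]C"]}
          - {name: mal-2, groups: ["[*:10]C", "[*:11][H]", "[*:12]C", "[*:13]C", "[*:14]C"]}
          - {name: mal-3, groups: ["[*:10]C", "[*:11]C", "[*:12][H]", "[*:13]C", "[*:14]C"]}
          - {name: mal-4, groups: ["[*:10]C", "[*:11]C", "[*:12]C", "[*:13][H]", "[*:14]C"]}
          - {name: mal-5, groups: ["[*:10]C", "[*:11]C", "[*:12]C", "[*:13]C", "[*:14][H]"]}
      - label: glyco
        sites: [20]
        options:
          - {name: bare, groups: ["[*:20][H]"]}
          - {name: angolosamine, groups: ["[*:20]C1CC(N(C)C)C(O)C(C)O1"]}
          - {name: mycaminose, groups: ["[*:20]C1OC(C)C(O)C(N(C)C)C1O"]}
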