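# Synthetic reconstruction of the acidobactin (A. citrulli) library:
# linear and peptide-macrocycle forms, two interchangeable Ser/Thr
# positions, malonate/methylmalonate at the ketide alpha carbon, and two
# ornithines whose side-chain amines are free, N-hydroxylated, N-formylated,
# N-acetylated, or hydroxylated-plus-acylated.
# 2 x 2 x 2 x 2 x 6 x 6 = 576 structures.
name: acidobactin
blocks:
  - name: acidobactin
    scaffolds:
      - id: linear
        smiles: "CCCCCCCC(=O)NC([*:2])C(=O)NC([*:4])C(O)C([*:6])C(=O)NC([*:3])C(=O)NC([*:5])C(=O)NC(C(O)C(=O)O)C(=O)O"
      - id: macrocycle
        smiles: "CCCCCCCC(=O)NC([*:2])C(=O)NC([*:4])C(O9)C([*:6])C(=O)NC([*:3])C(=O)NC([*:5])C(=O)NC(C(O)C(=O)O)C9=O"
    axes:
      - label: st1
        sites: [2]
        options:
          - {name: ser, groups: ["[*:2]CO"]}
          - {name: thr, groups: ["[*:2]C(C)O"]}
      - label: st2
        sites: [3]
        options:
          - {name: ser, groups: ["[*:3]CO"]}
          - {name: thr, groups: ["[*:3]C(C)O"]}
      - label: ketide
        sites: [6]
        options:
          - {name: mal, groups: ["[*:6][H]"]}
          - {name: mmal, groups: ["[*:6]C"]}
      - label: orn1
        sites: [4]
        options:
          - {name: free, groups: ["[*:4]CCCN"]}
          - {name: n-oh, groups: ["[*:4]CCCNO"]}
          - {name: n-cho, groups: ["[*:4]CCCNC=O"]}
          - {name: n-ac, groups: ["[*:4]CCCNC(C)=O"]}
          - {name: n-oh-cho, groups: ["[*:4]CCCN(O)C=O"]}
          - {name: n-oh-ac, groups: ["[*:4]CCCN(O)C(C)=O"]}
      - label: orn2
        sites: [5]
        options:
          - {name: free, groups: ["[*:5]CCCN"]}
          - {name: n-oh, groups: ["[*:5]CCCNO"]}
          - {name: n-cho, groups: ["[*:5]CCCNC=O"]}
          - {name: n-ac, groups: ["[*:5]CCCNC(C)=O"]}
          - {name: n-oh-cho, groups: ["[*:5]CCCN(O)C=O"]}
          - {name: n-oh-ac, groups: ["[*:5]CCCN(O)C(C)=O"]}
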