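# Synthetic reconstruction of the variobactin (V. paradoxus P4B) library:
# linear lipopeptide and lipodepsipeptide macrocycle forms, interchangeable
# Ser/Thr, malonate/methylmalonate incorporation, and the predicted
# N-hydroxyornithine left free, N-formylated, N-acetylated or as the plain
# amine. 2 x 2 x 2 x 4 = 32 structures.
name: variobactin
blocks:
  - name: variobactin
    scaffolds:
      - id: linear
        smiles: "CCCCCCCCCCCC(=O)NC(CO)C(=O)NC(CCN)C(=O)NC([*:4])C(O)C([*:3])C(=O)NC([*:2])C(=O)NC(C(O)C(=O)O)C(=O)O"
      - id: macrocycle
        smiles: "CCCCCCCCCCCC(=O)NC(CO8)C(=O)NC(CCN)C(=O)NC([*:4])C(O)C([*:3])C(=O)NC([*:2])C(=O)NC(C(O)C(=O)O)C8=O"
    axes:
      - label: st
        sites: [2]
        options:
          - {name: ser, groups: ["[*:2]CO"]}
          - {name: thr, groups: ["[*:2]C(C)O"]}
      - label: ketide
        sites: [3]
        options:
          - {name: mal, groups: ["[*:3][H]"]}
          - {name: mmal, groups: ["[*:3]C"]}
      - label: orn
        sites: [4]
        options:
          - {name: n-oh, groups: ["[*:4]CCCNO"]}
          - {name: n-oh-cho, groups: ["[*:4]CCCN(O)C=O"]}
          - {name: n-oh-ac, groups: ["[*:4]CCCN(O)C(C)=O"]}
          - {name: free, groups: ["[*:4]CCCN"]}
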