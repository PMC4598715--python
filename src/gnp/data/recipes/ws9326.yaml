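# Synthetic reconstruction of the WS9326 (S. calvus) combinatorialization:
# 4 base scaffolds (two trans-didomain placements of the Asn/Thr pair, each
# as linear lipopeptide or cyclic lipodepsipeptide), an N-acyl axis of
# C8/C10/C12 fatty acids, and binary residue interchanges (Ser/Thr,
# Val/Leu-Ile, Phe/Tyr) at each scaffold position bearing those residues.
# 4 x 3 x 2^6 = 768 structures.
name: ws9326
blocks:
  - name: ws9326
    scaffolds:
      - id: linear-asn6-thr7
        smiles: "[*:1]NC([*:2])C(=O)NC([*:3])C(=O)NC([*:4])C(=O)NC([*:5])C(=O)NC(C)C(=O)NC(CC(N)=O)C(=O)NC(C(C)O)C(=O)NC([*:6])C(=O)NC([*:7])C(=O)O"
      - id: linear-thr6-asn7
        smiles: "[*:1]NC([*:2])C(=O)NC([*:3])C(=O)NC([*:4])C(=O)NC([*:5])C(=O)NC(C)C(=O)NC(C(C)O)C(=O)NC(CC(N)=O)C(=O)NC([*:6])C(=O)NC([*:7])C(=O)O"
      - id: cyclic-asn6-thr7
        smiles: "[*:1]NC([*:2])C(=O)NC([*:3])C(=O)NC([*:4])C(=O)NC([*:5])C(=O)NC(C)C(=O)NC(CC(N)=O)C(=O)NC(C(C)O8)C(=O)NC([*:6])C(=O)NC([*:7])C8=O"
      - id: cyclic-thr6-asn7
        smiles: "[*:1]NC([*:2])C(=O)NC([*:3])C(=O)NC([*:4])C(=O)NC([*:5])C(=O)NC(C)C(=O)NC(C(C)O8)C(=O)NC(CC(N)=O)C(=O)NC([*:6])C(=O)NC([*:7])C8=O"
    axes:
      - label: acyl
        sites: [1]
        options:
          - {name: c8, groups: ["[*:1]C(=O)CCCCCCC"]}
          - {name: c10, groups: ["[*:1]C(=O)CCCCCCCCC"]}
          - {name: c12, groups: ["[*:1]C(=O)CCCCCCCCCCC"]}
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
      - label: vl1
        sites: [4]
        options:
          - {name: val, groups: ["[*:4]C(C)C"]}
          - {name: leu, groups: ["[*:4]CC(C)C"]}
      - label: vl2
        sites: [5]
        options:
          - {name: val, groups: ["[*:5]C(C)C"]}
          - {name: leu, groups: ["[*:5]CC(C)C"]}
      - label: fy1
        sites: [6]
        options:
          - {name: phe, groups: ["[*:6]Cc1ccccc1"]}
          - {name: tyr, groups: ["[*:6]Cc1ccc(O)cc1"]}
      - label: fy2
        sites: [7]
        options:
          - {name: phe, groups: ["[*:7]Cc1ccccc1"]}
          - {name: tyr, groups: ["[*:7]Cc1ccc(O)cc1"]}
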