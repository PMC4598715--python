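# Synthetic reconstruction of the thanamycin (P. fluorescens) library on a
# syringomycin-type macrolactone scaffold (closed on the conserved serine
# hydroxyl, with dehydrobutyrate, beta-hydroxyaspartate and
# 4-chlorothreonine fixed): position 2 in {diaminobutyrate, ornithine,
# arginine}; position 3 in {aspartate, asparagine}; position 4 in {serine,
# threonine/homoserine}; N-acyl fatty acids C12 through C16 with one or two
# hydroxyls. 3 x 2 x 2 x (5 x 2) = 120 structures.
name: thanamycin
blocks:
  - name: thanamycin
    scaffolds:
      - id: core
        smiles: "[*:1]NC(CO5)C(=O)NC([*:2])C(=O)NC([*:3])C(=O)NC([*:4])C(=O)NC(CCN)C(=O)NC(=CC)C(=O)NC(C(O)C(=O)O)C(=O)NC(C(O)CCl)C5=O"
    axes:
      - label: pos2
        sites: [2]
        options:
          - {name: dab, groups: ["[*:2]CCN"]}
          - {name: orn, groups: ["[*:2]CCCN"]}
          - {name: arg, groups: ["[*:2]CCCNC(=N)N"]}
      - label: pos3
        sites: [3]
        options:
          - {name: asp, groups: ["[*:3]CC(=O)O"]}
          - {name: asn, groups: ["[*:3]CC(N)=O"]}
      - label: pos4
        sites: [4]
        options:
          - {name: ser, groups: ["[*:4]CO"]}
          - {name: thr, groups: ["[*:4]C(C)O"]}
      - label: acyl
        sites: [1]
        options:
          - {name: c12-oh, groups: ["[*:1]C(=O)CC(O)CCCCCCCCC"]}
          - {name: c12-2oh, groups: ["[*:1]C(=O)CC(O)C(O)CCCCCCCC"]}
          - {name: c13-oh, groups: ["[*:1]C(=O)CC(O)CCCCCCCCCC"]}
          - {name: c13-2oh, groups: ["[*:1]C(=O)CC(O)C(O)CCCCCCCCC"]}
          - {name: c14-oh, groups: ["[*:1]C(=O)CC(O)CCCCCCCCCCC"]}
          - {name: c14-2oh, groups: ["[*:1]C(=O)CC(O)C(O)CCCCCCCCCC"]}
          - {name: c15-oh, groups: ["[*:1]C(=O)CC(O)CCCCCCCCCCCC"]}
          - {name: c15-2oh, groups: ["[*:1]C(=O)CC(O)C(O)CCCCCCCCCCC"]}
          - {name: c16-oh, groups: ["[*:1]C(=O)CC(O)CCCCCCCCCCCCC"]}
          - {name: c16-2oh, groups: ["[*:1]C(=O)CC(O)C(O)CCCCCCCCCCCC"]}
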