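name: cephalexin_classic_triad
ts:
  name: cephalexin_tetrahedral_intermediate
  charge_set: charmm
  atoms:
  - name: OX
    element: O
    charge: -0.4
  - name: C1
    element: C
    charge: 0.6
  - name: O1
    element: O
    charge: -0.9
  - name: CA7
    element: C
    charge: 0.1
  - name: NL
    element: N
    charge: -0.47
  - name: N7
    element: N
    charge: -0.3
  - name: CP
    element: C
    charge: 0.0
  - name: HN71
    element: H
    charge: 0.33
  - name: HN72
    element: H
    charge: 0.33
  - name: HN73
    element: H
    charge: 0.33
  - name: C8
    element: C
    charge: 0.1
  - name: S1
    element: S
    charge: -0.2
  zmatrix:
  - atom: OX
  - atom: C1
    length: 1.5
  - atom: O1
    length: 1.3
    angle: 109.5
  - atom: CA7
    frame:
    - O1
    - OX
    - C1
    length: 1.52
    angle: 109.5
    torsion: 120.0
  - atom: NL
    frame:
    - O1
    - OX
    - C1
    length: 1.45
    angle: 109.5
    torsion: -120.0
  - atom: N7
    frame:
    - OX
    - C1
    - CA7
    length: 1.49
    angle: 109.5
    torsion: 180.0
  - atom: CP
    frame:
    - OX
    - C1
    - CA7
    length: 1.52
    angle: 109.5
    torsion: 60.0
  - atom: HN71
    frame:
    - C1
    - CA7
    - N7
    length: 1.04
    angle: 109.5
    torsion: 60.0
  - atom: HN72
    frame:
    - C1
    - CA7
    - N7
    length: 1.04
    angle: 109.5
    torsion: 180.0
  - atom: HN73
    frame:
    - C1
    - CA7
    - N7
    length: 1.04
    angle: 109.5
    torsion: -60.0
  - atom: C8
    frame:
    - OX
    - C1
    - NL
    length: 1.47
    angle: 120.0
    torsion: 180.0
  - atom: S1
    frame:
    - C1
    - NL
    - C8
    length: 1.81
    angle: 110.0
    torsion: 90.0
  rotatable: []
residues:
- role: SER1
  aa:
  - SER
  class: catalytic
  via: side_chain
  triple:
  - CB
  - CA
  - N
- role: HIS2
  aa:
  - HIS
  class: catalytic
  via: side_chain
  triple:
  - NE2
  - CE1
  - ND1
- role: ASP3
  aa:
  - ASP
  class: catalytic
  via: side_chain
  triple:
  - OD1
  - CG
  - CB
- role: ALA4
  aa:
  - ANY
  class: stabilizes_TS
  via: backbone
  triple:
  - H
  - N
  - CA
- role: ALA5
  aa:
  - ANY
  class: stabilizes_TS
  via: backbone
  triple:
  - H
  - N
  - CA
- role: ALA6
  aa:
  - ANY
  class: stabilizes_catalytic
  via: backbone
  triple:
  - H
  - N
  - CA
- role: ASP7
  aa:
  - ASP
  class: stabilizes_TS
  via: side_chain
  triple:
  - OD1
  - CG
  - CB
constraints:
- kind: distance
  atoms:
  - - SER1
    - CB
  - - TS
    - OX
  optimal: 1.417
  tolerance: 0.1
- kind: angle
  atoms:
  - - SER1
    - CA
  - - SER1
    - CB
  - - TS
    - OX
  optimal: 110.7
  tolerance: 8.0
- kind: angle
  atoms:
  - - SER1
    - CB
  - - TS
    - OX
  - - TS
    - C1
  optimal: 115.0
  tolerance: 15.0
- kind: improper_dihedral
  atoms:
  - - SER1
    - CB
  - - TS
    - OX
  - - TS
    - C1
  - - TS
    - O1
  optimal: -60.0
  tolerance: 45.0
- kind: distance
  atoms:
  - - HIS2
    - NE2
  - - TS
    - OX
  optimal: 2.8
  tolerance: 0.3
- kind: angle
  atoms:
  - - HIS2
    - CE1
  - - HIS2
    - NE2
  - - TS
    - OX
  optimal: 127.0
  tolerance: 15.0
- kind: angle
  atoms:
  - - HIS2
    - NE2
  - - TS
    - OX
  - - TS
    - C1
  optimal: 109.0
  tolerance: 15.0
- kind: improper_dihedral
  atoms:
  - - HIS2
    - NE2
  - - TS
    - OX
  - - TS
    - C1
  - - TS
    - O1
  optimal: 150.0
  tolerance: 60.0
- kind: improper_dihedral
  atoms:
  - - HIS2
    - CE1
  - - HIS2
    - NE2
  - - TS
    - OX
  - - TS
    - C1
  optimal: 100.0
  tolerance: 70.0
- kind: improper_dihedral
  atoms:
  - - HIS2
    - ND1
  - - HIS2
    - CE1
  - - HIS2
    - NE2
  - - TS
    - OX
  optimal: 180.0
  tolerance: 15.0
- kind: distance
  atoms:
  - - ASP3
    - OD1
  - - HIS2
    - ND1
  optimal: 2.8
  tolerance: 0.3
- kind: angle
  atoms:
  - - ASP3
    - CG
  - - ASP3
    - OD1
  - - HIS2
    - ND1
  optimal: 120.0
  tolerance: 15.0
- kind: angle
  atoms:
  - - ASP3
    - OD1
  - - HIS2
    - ND1
  - - HIS2
    - CE1
  optimal: 126.0
  tolerance: 15.0
- kind: improper_dihedral
  atoms:
  - - ASP3
    - OD1
  - - HIS2
    - ND1
  - - HIS2
    - CE1
  - - HIS2
    - NE2
  optimal: 180.0
  tolerance: 15.0
- kind: improper_dihedral
  atoms:
  - - ASP3
    - CB
  - - ASP3
    - CG
  - - ASP3
    - OD1
  - - HIS2
    - ND1
  optimal: 180.0
  tolerance: 60.0
- kind: distance
  atoms:
  - - ALA4
    - H
  - - TS
    - O1
  optimal: 1.95
  tolerance: 0.3
- kind: angle
  atoms:
  - - ALA4
    - N
  - - ALA4
    - H
  - - TS
    - O1
  optimal: 160.0
  tolerance: 15.0
- kind: angle
  atoms:
  - - ALA4
    - H
  - - TS
    - O1
  - - TS
    - C1
  optimal: 120.0
  tolerance: 15.0
- kind: improper_dihedral
  atoms:
  - - ALA4
    - H
  - - TS
    - O1
  - - TS
    - C1
  - - TS
    - OX
  optimal: 150.0
  tolerance: 60.0
- kind: distance
  atoms:
  - - ALA5
    - H
  - - TS
    - O1
  optimal: 2.1
  tolerance: 0.3
- kind: angle
  atoms:
  - - ALA5
    - N
  - - ALA5
    - H
  - - TS
    - O1
  optimal: 160.0
  tolerance: 15.0
- kind: angle
  atoms:
  - - ALA5
    - H
  - - TS
    - O1
  - - TS
    - C1
  optimal: 120.0
  tolerance: 15.0
- kind: improper_dihedral
  atoms:
  - - ALA5
    - H
  - - TS
    - O1
  - - TS
    - C1
  - - TS
    - OX
  optimal: -90.0
  tolerance: 60.0
- kind: distance
  atoms:
  - - ALA6
    - H
  - - ASP3
    - OD2
  optimal: 1.95
  tolerance: 0.3
- kind: angle
  atoms:
  - - ALA6
    - N
  - - ALA6
    - H
  - - ASP3
    - OD2
  optimal: 160.0
  tolerance: 15.0
- kind: angle
  atoms:
  - - ALA6
    - H
  - - ASP3
    - OD2
  - - ASP3
    - CG
  optimal: 120.0
  tolerance: 15.0
- kind: improper_dihedral
  atoms:
  - - ALA6
    - H
  - - ASP3
    - OD2
  - - ASP3
    - CG
  - - ASP3
    - OD1
  optimal: 180.0
  tolerance: 60.0
- kind: distance
  atoms:
  - - ASP7
    - OD1
  - - TS
    - N7
  optimal: 2.9
  tolerance: 0.3
- kind: angle
  atoms:
  - - ASP7
    - CG
  - - ASP7
    - OD1
  - - TS
    - N7
  optimal: 120.0
  tolerance: 15.0
- kind: angle
  atoms:
  - - ASP7
    - OD1
  - - TS
    - N7
  - - TS
    - CA7
  optimal: 109.5
  tolerance: 15.0
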