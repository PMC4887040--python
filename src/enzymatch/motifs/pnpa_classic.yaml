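name: pnpa_classic_triad
ts:
  name: pnpa_tetrahedral_intermediate
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
  - name: CM
    element: C
    charge: 0.0
  - name: OL
    element: O
    charge: -0.4
  - name: C2
    element: C
    charge: 0.1
  - name: C3
    element: C
    charge: 0.0
  - name: C7
    element: C
    charge: 0.0
  - name: C4
    element: C
    charge: 0.0
  - name: C6
    element: C
    charge: 0.0
  - name: C5
    element: C
    charge: 0.1
  - name: N1
    element: N
    charge: 0.6
  - name: O2
    element: O
    charge: -0.4
  - name: O3
    element: O
    charge: -0.4
  zmatrix:
  - atom: OX
  - atom: C1
    length: 1.5
  - atom: O1
    length: 1.3
    angle: 109.5
  - atom: CM
    frame:
    - O1
    - OX
    - C1
    length: 1.52
    angle: 109.5
    torsion: 120.0
  - atom: OL
    frame:
    - O1
    - OX
    - C1
    length: 1.45
    angle: 109.5
    torsion: -120.0
  - atom: C2
    frame:
    - OX
    - C1
    - OL
    length: 1.4
    angle: 117.0
    torsion: 180.0
  - atom: C3
    frame:
    - C1
    - OL
    - C2
    length: 1.39
    angle: 120.0
    torsion: 0.0
  - atom: C7
    frame:
    - C1
    - OL
    - C2
    length: 1.39
    angle: 120.0
    torsion: 180.0
  - atom: C4
    frame:
    - OL
    - C2
    - C3
    length: 1.39
    angle: 120.0
    torsion: 180.0
  - atom: C6
    frame:
    - OL
    - C2
    - C7
    length: 1.39
    angle: 120.0
    torsion: 180.0
  - atom: C5
    frame:
    - C2
    - C3
    - C4
    length: 1.39
    angle: 120.0
    torsion: 0.0
  - atom: N1
    frame:
    - C3
    - C4
    - C5
    length: 1.47
    angle: 120.0
    torsion: 180.0
  - atom: O2
    frame:
    - C4
    - C5
    - N1
    length: 1.22
    angle: 120.0
    torsion: 0.0
  - atom: O3
    frame:
    - C4
    - C5
    - N1
    length: 1.22
    angle: 120.0
    torsion: 180.0
  rotatable:
  - - OL
    - C2
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
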