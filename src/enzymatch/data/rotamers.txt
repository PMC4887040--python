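# Compact backbone-independent rotamer library.
# One rotamer per line: residue name followed by its chi angles in degrees.
# Chi values are canonical gauche/trans wells (sp3) and planar-group
# orientations (sp2), a coarse summary of standard side-chain chi statistics.
# The loader also accepts any file in this format, e.g. a larger external
# backbone-independent library.
SER -60
SER 60
SER 180
CYS -60
CYS 60
CYS 180
THR -60
THR 60
THR 180
VAL -60
VAL 60
VAL 180
LEU -60 180
LEU 180 60
LEU -60 60
LEU 180 180
ILE -60 180
ILE -60 -60
ILE 180 180
ILE 60 180
ASP -60 0
ASP -60 90
ASP 60 0
ASP 60 90
ASP 180 0
ASP 180 90
ASN -60 0
ASN -60 90
ASN -60 180
ASN -60 -90
ASN 60 0
ASN 60 180
ASN 180 0
ASN 180 90
ASN 180 180
ASN 180 -90
GLU -60 -60 0
GLU -60 -60 90
GLU -60 180 0
GLU -60 180 90
GLU 180 -60 0
GLU 180 -60 90
GLU 180 180 0
GLU 180 180 90
GLN -60 -60 0
GLN -60 -60 180
GLN -60 180 0
GLN -60 180 180
GLN 180 -60 0
GLN 180 180 0
GLN 180 180 180
GLN 60 180 0
HIS -60 90
HIS -60 -90
HIS -60 0
HIS -60 180
HIS 60 90
HIS 60 -90
HIS 180 90
HIS 180 -90
HIS 180 0
HIS 180 180
PHE -60 90
PHE -60 0
PHE 60 90
PHE 180 90
PHE 180 0
TYR -60 90
TYR -60 0
TYR 60 90
TYR 180 90
TYR 180 0
TRP -60 90
TRP -60 -90
TRP 60 -90
TRP 180 90
TRP 180 -90
MET -60 -60 -60
MET -60 -60 180
MET -60 180 -60
MET -60 180 180
MET -60 180 60
MET 180 -60 -60
MET 180 180 -60
MET 180 180 180
MET 180 180 60
MET 60 180 180
LYS -60 180 180 180
LYS -60 180 180 -60
LYS -60 180 180 60
LYS 180 180 180 180
LYS 180 180 180 -60
LYS 180 180 180 60
ARG -60 180 180 90
ARG -60 180 180 -90
ARG -60 180 180 180
ARG 180 180 180 90
ARG 180 180 180 -90
ARG 180 180 180 180
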