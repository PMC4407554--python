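# Common six-cutter restriction enzymes: name, IUPAC recognition site
# (top strand), top-strand cut offset within the site.
ApaI	GGGCCC	5
BamHI	GGATCC	1
BglII	AGATCT	1
ClaI	ATCGAT	2
DraI	TTTAAA	3
EcoRI	GAATTC	1
EcoRV	GATATC	3
HindIII	AAGCTT	1
HpaI	GTTAAC	3
KpnI	GGTACC	5
NcoI	CCATGG	1
NdeI	CATATG	2
NsiI	ATGCAT	5
PstI	CTGCAG	5
SacI	GAGCTC	5
SalI	GTCGAC	1
ScaI	AGTACT	3
SmaI	CCCGGG	3
SpeI	ACTAGT	1
SphI	GCATGC	5
XbaI	TCTAGA	1
XhoI	CTCGAG	1
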