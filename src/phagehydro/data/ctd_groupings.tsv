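# Thirteen physicochemical groupings, each partitioning the 20 residues into
# three classes, for the CTD composition descriptor (iFeature CTDC partitions).
grouping	class	residues
hydrophobicity_PRAM900101	polar	RKEDQN
hydrophobicity_PRAM900101	neutral	GASTPHY
hydrophobicity_PRAM900101	hydrophobic	CLVIMFW
hydrophobicity_ARGP820101	polar	QSTNGDE
hydrophobicity_ARGP820101	neutral	RAHCKMV
hydrophobicity_ARGP820101	hydrophobic	LYPFIW
hydrophobicity_ZIMJ680101	polar	QNGSWTDERA
hydrophobicity_ZIMJ680101	neutral	HMCKV
hydrophobicity_ZIMJ680101	hydrophobic	LPFYI
hydrophobicity_PONP930101	polar	KPDESNQT
hydrophobicity_PONP930101	neutral	GRHA
hydrophobicity_PONP930101	hydrophobic	YMFWLCVI
hydrophobicity_CASG920101	polar	KDEQPSRNTG
hydrophobicity_CASG920101	neutral	AHYMLV
hydrophobicity_CASG920101	hydrophobic	FIWC
hydrophobicity_ENGD860101	polar	RDKENQHYP
hydrophobicity_ENGD860101	neutral	SGTAW
hydrophobicity_ENGD860101	hydrophobic	CVLIMF
hydrophobicity_FASG890101	polar	KERSQD
hydrophobicity_FASG890101	neutral	NTPG
hydrophobicity_FASG890101	hydrophobic	AYHWVMFLIC
normwaalsvolume	small	GASTPDC
normwaalsvolume	medium	NVEQIL
normwaalsvolume	large	MHKFRYW
polarity	low	LIFWCMVY
polarity	medium	PATGS
polarity	high	HQRKNED
polarizability	low	GASDT
polarizability	medium	CPNVEQIL
polarizability	high	KMHFRYW
charge	positive	KR
charge	neutral	ANCQGHILMFPSTWYV
charge	negative	DE
secondarystruct	helix	EALMQKRH
secondarystruct	strand	VIYCWFT
secondarystruct	coil	GNPSD
solventaccess	buried	ALFCGIVW
solventaccess	exposed	RKQEND
solventaccess	intermediate	MSPTHY
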