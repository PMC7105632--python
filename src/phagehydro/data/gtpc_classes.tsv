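# Five physicochemical residue classes for grouped tripeptide composition,
# following the iFeature GTPC partition.
class	description	residues
g1	aliphatic	GAVLMI
g2	aromatic	FYW
g3	positive_charge	KRH
g4	negative_charge	DE
g5	uncharged	STCPNQ
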