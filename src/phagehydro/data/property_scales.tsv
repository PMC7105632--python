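# Ten amino-acid property scales used by the lag-correlation (PseAAC) encoder.
# One row per property; columns are the 20 standard residues.
# Values are raw published scale values; the encoder z-normalizes each row
# (mean 0, variance 1 over the 20 residues) before computing correlations.
# Sources:
#   hydrophobicity        Kyte & Doolittle (1982) hydropathy index
#   hydrophilicity        Hopp & Woods (1981)
#   side_chain_mass       residue side-chain mass (Da), glycine side chain = H
#   pK1_COOH              alpha-carboxyl dissociation constant (pK1), CRC Handbook
#   pK2_NH3               alpha-amino dissociation constant (pK2), CRC Handbook
#   isoelectric_point     pI at 25 C, CRC Handbook
#   rigidity              Charton (1981) side-chain steric parameter (used as a rigidity scale)
#   flexibility           Bhaskaran & Ponnuswamy (1988) average flexibility index
#   irreplaceability      Dayhoff et al. (1978) relative mutability, sign-inverted
#   polarity              Grantham (1974) polarity
property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
hydrophilicity	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
side_chain_mass	15.0	47.0	59.0	73.0	91.0	1.0	81.0	57.0	72.0	57.0	75.0	58.0	41.0	72.0	100.0	31.0	45.0	43.0	130.0	107.0
pK1_COOH	2.35	1.71	1.88	2.19	2.58	2.34	1.78	2.32	2.20	2.36	2.28	2.18	1.99	2.17	2.18	2.21	2.15	2.29	2.38	2.20
pK2_NH3	9.87	10.78	9.60	9.67	9.24	9.60	8.97	9.76	8.90	9.60	9.21	9.09	10.60	9.13	9.09	9.15	9.12	9.72	9.39	9.11
isoelectric_point	6.00	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.60	5.96	5.89	5.66
rigidity	0.52	0.62	0.76	0.68	0.70	0.00	0.70	1.02	0.68	0.98	0.78	0.76	0.36	0.68	0.68	0.53	0.50	0.76	0.70	0.70
flexibility	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
irreplaceability	-100.0	-20.0	-106.0	-102.0	-41.0	-49.0	-66.0	-96.0	-56.0	-40.0	-94.0	-134.0	-56.0	-93.0	-65.0	-120.0	-97.0	-74.0	-18.0	-41.0
polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
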