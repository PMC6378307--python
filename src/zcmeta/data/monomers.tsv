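# zcmeta monomer table, version 1
# Standard-state (25 C, 1 bar, aqueous) Gibbs energies of formation.
# Sources: "codata" = CODATA-consistent inorganic values; "compilation" =
# aqueous amino-acid compilation lineage (Amend & Helgeson 1997 / Dick et al. 2006);
# "estimate" = additive condensation estimate built in this package from base,
# sugar, water and HPO4-2 values (see docs/methods.md). Nucleotide monophosphates
# are the fully deprotonated (charge -2) ions.
id	formula	charge	gibbs_energy	gibbs_units	source
Ala	C3H7NO2	0	-371.0	kJ/mol	compilation
Arg	C6H14N4O2	0	-240.4	kJ/mol	compilation
Asn	C4H8N2O3	0	-525.9	kJ/mol	compilation
Asp	C4H7NO4	0	-721.3	kJ/mol	compilation
Cys	C3H7NO2S	0	-339.8	kJ/mol	compilation
Gln	C5H10N2O3	0	-529.7	kJ/mol	compilation
Glu	C5H9NO4	0	-727.4	kJ/mol	compilation
Gly	C2H5NO2	0	-380.8	kJ/mol	compilation
His	C6H9N3O2	0	-226.8	kJ/mol	compilation
Ile	C6H13NO2	0	-343.9	kJ/mol	compilation
Leu	C6H13NO2	0	-352.3	kJ/mol	compilation
Lys	C6H14N2O2	0	-336.1	kJ/mol	compilation
Met	C5H11NO2S	0	-502.9	kJ/mol	compilation
Phe	C9H11NO2	0	-207.1	kJ/mol	compilation
Pro	C5H9NO2	0	-315.3	kJ/mol	compilation
Ser	C3H7NO3	0	-518.1	kJ/mol	compilation
Thr	C4H9NO3	0	-550.1	kJ/mol	compilation
Trp	C11H12N2O2	0	-112.1	kJ/mol	compilation
Tyr	C9H11NO3	0	-370.0	kJ/mol	compilation
Val	C5H11NO2	0	-356.9	kJ/mol	compilation
adenine	C5H5N5	0	312.4	kJ/mol	compilation
cytosine	C4H5N3O	0	-27.3	kJ/mol	compilation
guanine	C5H5N5O	0	47.4	kJ/mol	compilation
thymine	C5H6N2O2	0	-317.6	kJ/mol	compilation
uracil	C4H4N2O2	0	-299.1	kJ/mol	compilation
ribose	C5H10O5	0	-757.3	kJ/mol	compilation
deoxyribose	C5H10O4	0	-607.2	kJ/mol	estimate
dA	C10H13N5O3	0	-57.7	kJ/mol	estimate
dC	C9H13N3O4	0	-397.4	kJ/mol	estimate
dG	C10H13N5O4	0	-322.7	kJ/mol	estimate
dT	C10H14N2O5	0	-687.7	kJ/mol	estimate
rA	C10H13N5O4	0	-207.8	kJ/mol	estimate
rC	C9H13N3O5	0	-547.5	kJ/mol	estimate
rG	C10H13N5O5	0	-472.8	kJ/mol	estimate
rU	C9H12N2O6	0	-819.3	kJ/mol	estimate
rT	C10H14N2O6	0	-837.8	kJ/mol	estimate
dAMP	C10H12N5O6P	-2	-909.7	kJ/mol	estimate
dCMP	C9H12N3O7P	-2	-1249.4	kJ/mol	estimate
dGMP	C10H12N5O7P	-2	-1174.7	kJ/mol	estimate
dTMP	C10H13N2O8P	-2	-1539.7	kJ/mol	estimate
AMP	C10H12N5O7P	-2	-1059.8	kJ/mol	estimate
CMP	C9H12N3O8P	-2	-1399.5	kJ/mol	estimate
GMP	C10H12N5O8P	-2	-1324.8	kJ/mol	estimate
UMP	C9H11N2O9P	-2	-1671.3	kJ/mol	estimate
TMP	C10H13N2O9P	-2	-1689.8	kJ/mol	estimate
H2O	H2O	0	-237.1	kJ/mol	codata
HCO3-	CHO3	-1	-586.8	kJ/mol	codata
H2PO4-	H2PO4	-1	-1130.3	kJ/mol	codata
NH4+	NH4	1	-79.3	kJ/mol	codata
HS-	HS	-1	12.1	kJ/mol	codata
H+	H	1	0.0	kJ/mol	codata
e-		-1	0.0	kJ/mol	codata
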