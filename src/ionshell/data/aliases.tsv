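# ionshell modified-residue alias table, version 1
# alias_residue_name	parent_residue_name
# Modified nucleotides are mapped onto the role template of their parent base,
# e.g. pseudouridine O2 is treated as a nucleobase carbonyl (Ob).
# N7-alkylated purines (e.g. 7MG) are deliberately absent: their N7 is
# substituted and must not be counted as a coordinating ring nitrogen.
PSU	U
5MU	U
H2U	U
4SU	U
5MC	C
OMC	C
OMG	G
2MG	G
M2G	G
1MA	A
OMU	U
UR3	U
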