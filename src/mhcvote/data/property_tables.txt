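# Fixed physicochemical lookup tables for the sequence descriptors.
#
# Format: three TAB-separated columns
#     section <TAB> key <TAB> value
# Sections:
#   ctd_partition   value = three '|'-separated residue groups (class 1|2|3)
#   sidechain_group value = residue group for one of the five side-chain classes
#   triad_class     key = class index 1..7, value = residue group
#   scale           value = comma-separated RESIDUE:NUMBER pairs (raw values;
#                   standardized to mean 0 / unit population SD at load time)
# Every partition section must cover the 20 standard residues exactly once.

ctd_partition	hydrophobicity	RKEDQN|GASTPHY|CLVIMFW
ctd_partition	vdw_volume	GASTPDC|NVEQIL|MHKFRYW
ctd_partition	polarity	LIFWCMVY|PATGS|HQRKNED
ctd_partition	polarizability	GASDT|CPNVEQIL|KMHFRYW
ctd_partition	charge	KR|ANCQGHILMFPSTWYV|DE
ctd_partition	surface_tension	GQDNAHR|KTSEC|ILMFPWYV
ctd_partition	secondary_structure	EALMQKRH|VIYCWFT|GNPSD
ctd_partition	solvent_accessibility	ALFCGIVW|RKQEND|MSPTHY

sidechain_group	aliphatic	GAVLMI
sidechain_group	aromatic	FYW
sidechain_group	positive	KRH
sidechain_group	negative	DE
sidechain_group	uncharged	STCPNQ

triad_class	1	AGV
triad_class	2	ILFP
triad_class	3	YMTS
triad_class	4	HNQW
triad_class	5	RK
triad_class	6	DE
triad_class	7	C

scale	hydrophobicity	A:0.62,C:0.29,D:-0.90,E:-0.74,F:1.19,G:0.48,H:-0.40,I:1.38,K:-1.50,L:1.06,M:0.64,N:-0.78,P:0.12,Q:-0.85,R:-2.53,S:-0.18,T:-0.05,V:1.08,W:0.81,Y:0.26
scale	hydrophilicity	A:-0.5,C:-1.0,D:3.0,E:3.0,F:-2.5,G:0.0,H:-0.5,I:-1.8,K:3.0,L:-1.8,M:-1.3,N:0.2,P:0.0,Q:0.2,R:3.0,S:0.3,T:-0.4,V:-1.5,W:-3.4,Y:-2.3
scale	sidechain_mass	A:15.0,C:47.0,D:59.0,E:73.0,F:91.0,G:1.0,H:82.0,I:57.0,K:73.0,L:57.0,M:75.0,N:58.0,P:42.0,Q:72.0,R:101.0,S:31.0,T:45.0,V:43.0,W:130.0,Y:107.0
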