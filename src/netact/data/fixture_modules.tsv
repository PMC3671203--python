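# Reduced demonstration network (synthetic fixture; NOT the full curated
# 558-gene network, which must be supplied by the user).  Module membership is
# restricted to genes explicitly tied to their modules in the literature on
# RTK-pathway module stratification; the MAPK-Inhibitor module is padded to 20
# genes with additional DUSP/SPRY/SPRED/RASA family symbols (fixture-only
# padding, chosen for family plausibility, not curated evidence).
gene	module	pathway	role
PDGFA	PDGFR-Ligand	PDGFR	Ligand
PDGFB	PDGFR-Ligand	PDGFR	Ligand
PDGFC	PDGFR-Ligand	PDGFR	Ligand
PDGFD	PDGFR-Ligand	PDGFR	Ligand
PDGFRA	PDGFR-RTK	PDGFR	Receptor
PDGFRB	PDGFR-RTK	PDGFR	Receptor
PLAT	PDGFR-CoActivator	PDGFR	CoActivator
IGF1	INSR-Ligand	INSR	Ligand
IGF2	INSR-Ligand	INSR	Ligand
IGF1R	INSR-RTK	INSR	Receptor
IGF2R	INSR-RTK	INSR	Receptor
INSR	INSR-RTK	INSR	Receptor
SHC1	TGF/BMP-Adaptor	TGF/BMP	Adaptor
GRB2	TGF/BMP-Adaptor	TGF/BMP	Adaptor
MAP2K1	Downstream-MAPK	MAPK	Downstream
MAP2K2	Downstream-MAPK	MAPK	Downstream
MAPK1	Downstream-MAPK	MAPK	Downstream
MAPK3	Downstream-MAPK	MAPK	Downstream
RAF1	Downstream-MAPK	MAPK	Downstream
ARAF	Downstream-MAPK	MAPK	Downstream
BRAF	Downstream-MAPK	MAPK	Downstream
HRAS	Downstream-MAPK	MAPK	Downstream
KRAS	Downstream-MAPK	MAPK	Downstream
NRAS	Downstream-MAPK	MAPK	Downstream
DUSP1	MAPK-Inhibitor	MAPK	Inhibitor
DUSP4	MAPK-Inhibitor	MAPK	Inhibitor
DUSP5	MAPK-Inhibitor	MAPK	Inhibitor
DUSP6	MAPK-Inhibitor	MAPK	Inhibitor
RASA1	MAPK-Inhibitor	MAPK	Inhibitor
DUSP2	MAPK-Inhibitor	MAPK	Inhibitor
DUSP3	MAPK-Inhibitor	MAPK	Inhibitor
DUSP7	MAPK-Inhibitor	MAPK	Inhibitor
DUSP8	MAPK-Inhibitor	MAPK	Inhibitor
DUSP9	MAPK-Inhibitor	MAPK	Inhibitor
DUSP10	MAPK-Inhibitor	MAPK	Inhibitor
DUSP14	MAPK-Inhibitor	MAPK	Inhibitor
DUSP16	MAPK-Inhibitor	MAPK	Inhibitor
SPRY1	MAPK-Inhibitor	MAPK	Inhibitor
SPRY2	MAPK-Inhibitor	MAPK	Inhibitor
SPRY4	MAPK-Inhibitor	MAPK	Inhibitor
SPRED1	MAPK-Inhibitor	MAPK	Inhibitor
SPRED2	MAPK-Inhibitor	MAPK	Inhibitor
RASA2	MAPK-Inhibitor	MAPK	Inhibitor
RASA3	MAPK-Inhibitor	MAPK	Inhibitor
FOS	AP1	AP1	TranscriptionFactor
FOSB	AP1	AP1	TranscriptionFactor
FOSL1	AP1	AP1	TranscriptionFactor
FOSL2	AP1	AP1	TranscriptionFactor
JUN	AP1	AP1	TranscriptionFactor
JUNB	AP1	AP1	TranscriptionFactor
JUND	AP1	AP1	TranscriptionFactor
NFKB1	NFkB-SignalingComplex	NFkB	Downstream
NFKB2	NFkB-SignalingComplex	NFkB	Downstream
RELA	NFkB-SignalingComplex	NFkB	Downstream
RELB	NFkB-SignalingComplex	NFkB	Downstream
REL	NFkB-SignalingComplex	NFkB	Downstream
IRAK1	NFkB-SignalingComplex	NFkB	Downstream
MYD88	NFkB-SignalingComplex	NFkB	Downstream
NFKBIA	NFkB-Inhibitor	NFkB	Inhibitor
NFKBIB	NFkB-Inhibitor	NFkB	Inhibitor
NFKBIE	NFkB-Inhibitor	NFkB	Inhibitor
NFKBIZ	NFkB-Inhibitor	NFkB	Inhibitor
	activeERK	MAPK	Effector
	activeAKT	PI3K/AKT	Effector
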