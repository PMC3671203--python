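# Signed module-level edges of the reduced demonstration network.
source	target	sign
PDGFR-Ligand	PDGFR-RTK	activation
PDGFR-CoActivator	PDGFR-RTK	activation
PDGFR-RTK	Downstream-MAPK	activation
PDGFR-RTK	NFkB-SignalingComplex	activation
INSR-Ligand	INSR-RTK	activation
INSR-RTK	Downstream-MAPK	activation
INSR-RTK	activeAKT	activation
TGF/BMP-Adaptor	Downstream-MAPK	activation
MAPK-Inhibitor	Downstream-MAPK	inhibition
Downstream-MAPK	activeERK	activation
activeERK	AP1	activation
NFkB-Inhibitor	NFkB-SignalingComplex	inhibition
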