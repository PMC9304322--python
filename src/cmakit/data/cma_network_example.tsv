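gene_id	weight	direction	note
LAMP2A	2	1	illustrative example network; rate-limiting CMA receptor, hence weight 2
HSPA8	1	1	substrate-targeting chaperone hsc70
HSP90AA1	1	1	chaperone assisting translocation-complex stability
DNAJB1	1	1	hsc70 co-chaperone
BAG1	1	1	nucleotide-exchange co-chaperone
ST13	1	1	hsc70 co-chaperone (Hip)
NFE2L2	1	1	transcriptional activator of LAMP2A expression
PHLPP1	1	1	phosphatase relieving Akt-mediated CMA inhibition
RAB11A	1	1	endosomal trafficking supporting receptor dynamics
VAMP8	1	1	lysosomal SNARE supporting membrane dynamics
RARA	1	-1	retinoic acid receptor alpha, transcriptional CMA inhibitor
MTOR	1	-1	TORC2-axis negative regulator
AKT1	1	-1	phosphorylates translocation-complex components, inhibitory
GFAP	1	-1	stabilizes translocation complex disassembly dynamics, net inhibitory here
EEF1A1	1	-1	GFAP-axis negative modulator
CTSA	1	-1	protease degrading the receptor at the lysosomal membrane
STUB1	1	-1	CHIP ubiquitin ligase routing chaperone clients away from CMA
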