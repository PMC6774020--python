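"""Default capture panel and resistance-panel definitions.

The analyses operate on a fixed 168-gene pan-cancer capture panel; calls in
genes outside the panel are discarded by the filter chain. The resistance
panel holds the four frameshift point mutations in ARID1A and BRCA2 whose
presence at baseline flags likely primary resistance.
"""

from __future__ import annotations

_PANEL_GENES_RAW = """
ABL1 AKT1 AKT2 AKT3 ALK APC AR ARAF ARID1A ARID1B ARID2 ATM ATR ATRX AURKA
AURKB AXL BAP1 BARD1 BCL2 BCL2L1 BCL6 BRAF BRCA1 BRCA2 BRIP1 BTK CBL CCND1
CCND2 CCND3 CCNE1 CDH1 CDK12 CDK4 CDK6 CDKN1A CDKN1B CDKN2A CDKN2B CHEK1
CHEK2 CREBBP CSF1R CTCF CTNNB1 DDR2 DNMT3A EGFR EP300 EPHA2 ERBB2 ERBB3
ERBB4 ERCC2 ERG ESR1 EZH2 FANCA FANCC FANCD2 FBXW7 FGFR1
FGFR2 FGFR3 FGFR4 FLT1 FLT3 FLT4 FOXL2 GATA3 GNA11 GNAQ GNAS HGF HNF1A HRAS
IDH1 IDH2 IGF1R IKZF1 JAK1 JAK2 JAK3 KDM5C KDM6A KDR KEAP1 KIT KMT2A KMT2C
KMT2D KRAS MAP2K1 MAP2K2 MAP2K4 MAP3K1 MCL1 MDM2 MDM4 MET MLH1 MPL MSH2
MSH6 MTOR MYC MYCL MYCN NBN NF1 NF2 NFE2L2 NKX2-1 NOTCH1 NOTCH2 NOTCH3 NPM1
NRAS NTRK1 NTRK2 NTRK3 PALB2 PBRM1 PDGFRA PDGFRB PIK3CA PIK3CB PIK3R1 PMS2
POLD1 POLE PTCH1 PTEN PTPN11 RAD50 RAD51 RAF1 RB1 RET RICTOR RNF43 ROS1
RUNX1 SDHA SDHB SETD2 SMAD2 SMAD4 SMARCA4 SMARCB1 SMO SOX2 SPOP SRC STAG2
STK11 SUFU TERT TET2 TGFBR2 TP53 TSC1 TSC2 VHL WT1 XPO1 ZNF217
"""

#: 168 gene symbols; always includes ARID1A, BRCA2, TGFBR2 and IDH1.
DEFAULT_PANEL_GENES: tuple[str, ...] = tuple(_PANEL_GENES_RAW.split())

#: Genes whose positivity (EGFR mutation, ALK fusion, ROS1 rearrangement)
#: defines "driver gene positive" status in the clinical table.
DRIVER_GENES: tuple[str, ...] = ("EGFR", "ALK", "ROS1")
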