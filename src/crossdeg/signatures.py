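"""Curated acute ischemia-reperfusion gene signatures.

Literature-consensus lists of the most consistently up- and down-regulated
genes reported across acute (<=48 h) ischemia-reperfusion injury models;
used as regression fixtures for list formatting and ranking, and as
realistic symbol material for examples.  Symbols are given in rodent title
case as usually printed; canonicalize before cross-referencing.
"""

from __future__ import annotations

#: Consistently up-regulated in acute ischemia-reperfusion injury:
#: inflammatory response, programmed cell death, and stress-response genes.
ACUTE_IRI_UP = (
    "Itga5", "Atf3", "Cyr61", "Litaf", "Stat3", "Icam1", "Sik1", "Tlr2",
    "Zc3h12a", "Epha2", "Maff", "Nes", "Hmox1", "Myc", "Cd44", "Hbegf",
    "Ifrd1", "Pdpn", "Cd14", "Jun", "Csf1", "Gadd45a", "Ccl2", "Klf6",
    "Hspb1", "Olr1", "Mafk", "Zyx", "Osmr", "Tifa", "Bcl3", "Irf1",
    "Tnfrsf1a", "Cxcl1", "Txnrd1", "Spon2", "Myd88", "Bach1",
)

#: Consistently down-regulated: predominantly ion channels and synaptic genes.
ACUTE_IRI_DOWN = (
    "Cabp1", "Pclo", "Npy1r", "Tenm2", "Cbx7", "Camk4", "Kcng1", "L1cam",
    "Dlg2", "Scn4b", "Kcnab1", "Rasgrp1", "Kcnt1", "Adora2a", "Phactr1",
    "Lzts3", "Stard8", "Agrn", "Cacnb3", "Cobl",
)
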