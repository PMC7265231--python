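"""Curated mouse gene sets used for module scoring.

``STRESS_GENES`` are immediate-early and heat-shock genes induced by warm
tissue dissociation; the stress score is a binned-control module score over
this set.  ``S_GENES`` / ``G2M_GENES`` are the cell-cycle phase sets used by
:func:`dbk.stats.cell_cycle_phase`.  ``HEMOGLOBIN_GENES`` mark erythrocyte
contamination.
"""

from __future__ import annotations

#: Immediate-early / heat-shock stress-response genes (17 genes).
STRESS_GENES: tuple[str, ...] = (
    "Fosb", "Fos", "Jun", "Junb", "Jund", "Atf3", "Egr1",
    "Hspa1a", "Hspa1b", "Hsp90ab1", "Hspa8", "Hspb1",
    "Ier3", "Ier2", "Btg1", "Btg2", "Dusp1",
)

#: S-phase marker genes (42 genes).
S_GENES: tuple[str, ...] = (
    "Atad2", "Blm", "Brip1", "Casp8ap2", "Ccne2", "Cdc45", "Cdc6", "Cdca7",
    "Chaf1b", "Clspn", "Dscc1", "Dtl", "E2f8", "Exo1", "Fen1", "Gins2",
    "Gmnn", "Hells", "Mcm2", "Mcm4", "Mcm5", "Mcm6", "Msh2", "Nasp",
    "Pcna", "Pcna-ps2", "Pola1", "Pold3", "Prim1", "Rad51ap1", "Rfc2",
    "Rpa2", "Rrm1", "Rrm2", "Slbp", "Tipin", "Tyms", "Ubr7", "Uhrf1",
    "Ung", "Usp1", "Wdr76",
)

#: G2/M-phase marker genes (52 genes).
G2M_GENES: tuple[str, ...] = (
    "Anln", "Anp32e", "Aurka", "Aurkb", "Birc5", "Bub1", "Cbx5", "Ccnb2",
    "Cdc20", "Cdc25c", "Cdca2", "Cdca3", "Cdca8", "Cdk1", "Cenpa", "Cenpe",
    "Cenpf", "Ckap2", "Ckap2l", "Ckap5", "Cks1brt", "Cks2", "Ctcf",
    "Dlgap5", "Ect2", "G2e3", "Gas2l3", "Gtse1", "Hjurp", "Hmgb2", "Hmmr",
    "Kif11", "Kif20b", "Kif23", "Kif2c", "Lbr", "Mki67", "Ncapd2", "Ndc80",
    "Nek2", "Nuf2", "Nusap1", "Psrc1", "Rangap1", "Smc4", "Tacc3", "Tmpo",
    "Top2a", "Tpx2", "Ttk", "Tubb4b", "Ube2c",
)

#: Hemoglobin transcripts flagging erythrocyte / ambient contamination.
HEMOGLOBIN_GENES: tuple[str, ...] = ("Hbb-bs", "Hba-a1", "Hba-a2")
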