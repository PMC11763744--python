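"""Published top-20 correlating gene lists for the three oxidant treatments.

These are the reported top-20 positively and negatively correlating
genes (sorted by two-sided p-value, with Spearman r rounded to two
decimals) from a 35-cell-line basal-expression screen against IC25
values for gas plasma, H2O2 and HOCl exposure. They serve as a fixed
reference input for set-arithmetic analyses: the screen itself cannot be
re-run here because the underlying per-line measurements are not public,
but the printed lists fully determine the top-20 overlap structure.

Each entry is ``(gene_symbol, p_value, spearman_r)``.
"""

from __future__ import annotations

from rospanel.overlap import GeneSet

REFERENCE_TOP20: dict[str, dict[str, list[tuple[str, float, float]]]] = {
    "plasma": {
        "positive": [
            ("ME1", 4.39e-05, 0.63),
            ("CSNK1A1L", 5.65e-05, 0.63),
            ("DCTN1", 1.32e-04, 0.60),
            ("BLVRB", 2.99e-04, 0.58),
            ("CFAP36", 6.47e-04, 0.55),
            ("CAPZA2", 9.08e-04, 0.54),
            ("SOCS6", 1.01e-03, 0.53),
            ("KRTAP6-2", 1.07e-03, 0.53),
            ("AREG", 1.26e-03, 0.52),
            ("ASPH", 1.51e-03, 0.52),
            ("DEPP1", 1.53e-03, 0.52),
            ("CFAP300", 1.56e-03, 0.51),
            ("MOS", 1.76e-03, 0.51),
            ("FTHL17", 1.78e-03, 0.51),
            ("PDK4", 1.81e-03, 0.51),
            ("CACNG6", 1.88e-03, 0.51),
            ("PTGR1", 1.88e-03, 0.51),
            ("PTCH2", 1.93e-03, 0.51),
            ("TMEM52", 2.31e-03, 0.50),
            ("GPR31", 2.57e-03, 0.49),
        ],
        "negative": [
            ("PSMC2", 3.63e-10, -0.84),
            ("GTSE1", 6.72e-08, -0.77),
            ("PPP2R3B", 1.23e-07, -0.76),
            ("NAA40", 2.16e-07, -0.75),
            ("CEP135", 3.27e-07, -0.74),
            ("SAFB", 4.52e-07, -0.74),
            ("CXXC1", 5.03e-07, -0.73),
            ("MLF1IP", 6.11e-07, -0.73),
            ("FAM193A", 7.40e-07, -0.73),
            ("ILF3", 7.51e-07, -0.73),
            ("RBM15", 1.06e-06, -0.72),
            ("RBM10", 1.09e-06, -0.72),
            ("NOP14", 1.37e-06, -0.72),
            ("RBM14", 1.39e-06, -0.72),
            ("AGAP2", 1.61e-06, -0.71),
            ("WDR82", 1.82e-06, -0.71),
            ("MCM5", 2.00e-06, -0.71),
            ("MYLK2", 2.11e-06, -0.71),
            ("SRRT", 2.20e-06, -0.71),
            ("MBD3", 2.23e-06, -0.71),
        ],
    },
    "h2o2": {
        "positive": [
            ("RAB26", 4.65e-06, 0.69),
            ("PERP", 1.20e-05, 0.67),
            ("ME1", 1.39e-05, 0.66),
            ("MOCOS", 2.01e-05, 0.65),
            ("BLVRB", 2.96e-05, 0.64),
            ("ANXA9", 3.32e-05, 0.64),
            ("LCN2", 4.13e-05, 0.64),
            ("CFAP300", 4.62e-05, 0.63),
            ("TPD52L1", 5.99e-05, 0.62),
            ("TOM1L1", 7.95e-05, 0.62),
            ("AREG", 8.91e-05, 0.61),
            ("CFB", 1.03e-04, 0.61),
            ("TSPAN1", 1.04e-04, 0.61),
            ("KLF4", 1.19e-04, 0.60),
            ("POLD4", 1.68e-04, 0.59),
            ("YIF1B", 1.68e-04, 0.59),
            ("SLC35A3", 1.93e-04, 0.59),
            ("MTFR1", 1.97e-04, 0.59),
            ("DSP", 1.99e-04, 0.59),
            ("OSGIN1", 1.99e-04, 0.59),
        ],
        "negative": [
            ("SEPTIN6", 4.80e-07, -0.74),
            ("NREP", 6.20e-07, -0.73),
            ("SIRPG", 1.59e-06, -0.71),
            ("RFTN1", 4.60e-06, -0.69),
            ("CPXM1", 8.45e-06, -0.68),
            ("C4orf46", 9.29e-06, -0.67),
            ("STMN1", 9.29e-06, -0.67),
            ("DTL", 1.07e-05, -0.67),
            ("TUBB", 1.26e-05, -0.67),
            ("CCDC28B", 1.31e-05, -0.66),
            ("ZNF692", 1.97e-05, -0.65),
            ("PET100", 3.19e-05, -0.64),
            ("BLM", 5.16e-05, -0.63),
            ("CDC25A", 5.59e-05, -0.63),
            ("PLEKHO1", 6.11e-05, -0.62),
            ("PTGR3", 6.55e-05, -0.62),
            ("SLA", 8.66e-05, -0.61),
            ("ZKSCAN4", 9.00e-05, -0.61),
            ("MCM10", 9.25e-05, -0.61),
            ("H2BW2", 9.61e-05, -0.61),
        ],
    },
    "hocl": {
        "positive": [
            ("ACSM3", 3.43e-03, 0.48),
            ("SLC17A9", 4.15e-03, 0.47),
            ("BCL2L10", 6.15e-03, 0.45),
            ("VASP", 6.15e-03, 0.45),
            ("RPH3AL", 9.99e-03, 0.43),
            ("ARHGAP18", 1.13e-02, 0.42),
            ("LIAS", 1.17e-02, 0.42),
            ("TNIK", 1.20e-02, 0.42),
            ("CD86", 1.24e-02, 0.42),
            ("PTH2", 1.43e-02, 0.42),
            ("SFXN1", 1.34e-02, 0.41),
            ("EBI3", 1.43e-02, 0.41),
            ("CCL2", 1.49e-02, 0.41),
            ("PRAG1", 1.49e-02, 0.41),
            ("HSPA4L", 1.68e-02, 0.40),
            ("KLK1", 1.69e-02, 0.40),
            ("ZG16B", 1.95e-02, 0.39),
            ("MYRF", 2.06e-02, 0.39),
            ("GPAT3", 2.16e-02, 0.39),
            ("GPR20", 2.32e-02, 0.38),
        ],
        "negative": [
            ("ZNF777", 7.22e-05, -0.62),
            ("FZD3", 1.16e-04, -0.61),
            ("ZNF23", 1.18e-04, -0.61),
            ("ZNF14", 2.11e-04, -0.59),
            ("PEX19", 3.82e-04, -0.57),
            ("ZNF77", 3.20e-04, -0.57),
            ("ZNF606", 3.84e-04, -0.57),
            ("ZNF391", 4.00e-04, -0.57),
            ("ZNF728", 4.23e-04, -0.56),
            ("MLLT10", 4.33e-04, -0.56),
            ("KDM2B", 5.20e-04, -0.56),
            ("TP53BP2", 5.85e-04, -0.55),
            ("ZNF160", 6.37e-04, -0.55),
            ("CLUAP1", 6.77e-04, -0.55),
            ("CFDP1", 7.25e-04, -0.54),
            ("FAM220A", 7.48e-04, -0.54),
            ("ZNF256", 8.75e-04, -0.54),
            ("TULP4", 8.88e-04, -0.54),
            ("ZNF175", 9.85e-04, -0.53),
            ("BOLA1", 1.02e-03, -0.53),
        ],
    },
}

#: Sample size of the published screen (34 cancer lines + HaCaT).
REFERENCE_N_LINES = 35


def reference_gene_set(treatment: str, direction: str) -> GeneSet:
    """The published top-20 list for one treatment/direction as a GeneSet."""
    try:
        entries = REFERENCE_TOP20[treatment][direction]
    except KeyError as exc:
        raise KeyError(
            f"unknown treatment/direction ({treatment!r}, {direction!r}); "
            f"treatments: {sorted(REFERENCE_TOP20)}, directions: positive/negative"
        ) from exc
    return GeneSet.from_iterable(f"{treatment}_{direction}_top20", [g for g, _, _ in entries])


def reference_gene_sets(direction: str) -> list[GeneSet]:
    """The three treatments' published top-20 lists for one direction."""
    return [reference_gene_set(t, direction) for t in REFERENCE_TOP20]
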