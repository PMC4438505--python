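"""Published summary statistics of the breast-cancer methylation study.

These constants describe the 21 genes whose CpG-island methylation passed
the differential screen (absolute fold change >= 1.5, p < 0.05) between
relapsing and non-relapsing tumors, the seven-gene prognostic panel chosen
by PLS, and the panel-level power-analysis parameters. They parameterize the
synthetic cohort generator and serve as reference values in tests.
"""
from __future__ import annotations

#: (gene_id, two-sided p-value, absolute fold change, member of 7-gene panel)
TABLE1_SCREEN = (
    ("BRCA1", 1.53e-05, 5.52, True),
    ("CALCA", 1.96e-04, 1.66, False),
    ("CASP8", 3.54e-03, 1.82, False),
    ("CCND2", 2.81e-04, 1.62, False),
    ("DAPK1", 1.13e-06, 12.37, True),
    ("EDNRB", 2.00e-04, 2.42, False),
    ("FHIT", 6.95e-03, 1.79, False),
    ("ICAM1", 1.60e-04, 2.06, False),
    ("MCTS1", 3.36e-02, 1.56, False),
    ("FABP3", 3.04e-04, 2.78, False),
    ("DNAJC15", 2.03e-03, 3.01, False),
    ("MSH2", 3.10e-05, 13.66, True),
    ("MYOD1", 1.40e-04, 1.74, False),
    ("CDKN2A", 1.29e-02, 1.83, True),
    ("PAX5", 6.82e-03, 1.77, False),
    ("PGK1", 1.77e-03, 1.79, False),
    ("PGR", 2.54e-03, 2.90, True),
    ("RARB", 1.39e-04, 2.05, False),
    ("PRKCDBP", 7.68e-04, 3.63, True),
    ("THBS1", 1.26e-03, 2.08, False),
    ("RANKL", 1.10e-02, 2.14, True),
)

TABLE1_GENES = tuple(row[0] for row in TABLE1_SCREEN)

#: The seven prognostic genes selected by the PLS classifier.
PANEL_GENES = tuple(row[0] for row in TABLE1_SCREEN if row[3])

#: Panel-level power-analysis inputs: difference of group means of the
#: per-sample 7-gene average (log2-ratio units) and within-group standard
#: deviations of the relapse (BCR) and non-relapse (BCS) groups.
PANEL_MEAN_DIFF = 2.112189
PANEL_SD_RELAPSE = 1.16809
PANEL_SD_CONTROL = 0.708074

#: Study cohort composition: 123 patients, 19 with metastatic relapse.
N_RELAPSE = 19
N_CONTROL = 104
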