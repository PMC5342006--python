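"""Bundled reference data from the published 131-patient lung-adenocarcinoma study.

Two small tables travel with the package:

* the default immunohistochemistry (IHC) marker panel — 23 antibodies against
  20 proteins (BRCA2, FEN1 and MSH2 were each stained at two cellular
  locations), each with its per-marker criterion of abnormality on the ordinal
  staining scale ``0 < ± < 1+ < 2+ < 3+`` or as a percent-stained threshold,
  plus the fraction of the 131 patients scored abnormal; and

* the published synergy-screen rows — the 26 (marker pair, clinical feature)
  records that survived the paired Fisher screen, with the two single-marker
  p-values, the pair p-value, the pair q-value and the pair log-rank p-value
  as printed.

These are inputs for regression tests and worked examples; nothing in the
screening code depends on them.
"""

from __future__ import annotations

import io

import pandas as pd

from .synergy import MarkerDef

# protein, location (C=cytoplasm, N=nucleus, M=membrane), criterion, abnormal fraction
_PANEL_TSV = """\
protein\tlocation\tcriterion\tabnormal_rate
ABL1\tC\t>=2+\t0.24
AURKB\tC\t>=1+\t0.91
BCR\tC\t>=2+\t0.27
BRCA1\tC\t<1+\t0.77
BRCA2\tC\t<2+\t0.67
BRCA2\tN\t<2+\t0.19
CDH1\tM\t>=70%\t0.62
CSNK1E\tC\t<2+\t0.94
CTNNB1\tN\t>=1+\t0.06
EGFR\tC\t>=1+\t0.19
FEN1\tC\t>=2+\t0.58
FEN1\tN\t>=2+\t0.50
MSH2\tC\t<1+\t0.31
MSH2\tN\t<1+\t0.20
MYC\tN\t>=2+\t0.42
PARP1\tN\t>=1+\t0.87
POLB\tN\t>=1+\t0.91
RAD54B\tN\t>=1+\t0.33
RB1\tN\t<1+\t0.55
SGK2\tC\t<2+\t0.96
SKP2\tC\t>=2+\t0.10
TP53\tN\t>=1+\t0.51
WNT5A\tC\t>=1+\t0.60
"""

# The 26 screen records as printed: feature family, the two markers, the two
# single-marker Fisher p-values, the pair Fisher p-value, the pair q-value and
# the pair log-rank p-value.  "ARK2" in the published table is the AURKB(C)
# antibody of the panel.
_SYNERGY_ROWS_TSV = """\
feature\tmarker1\tmarker2\tp_single1\tp_single2\tp_pair\tq_pair\tlogrank_pair
survival3y\tFEN1(N)\tRAD54B(N)\t0.357\t0.002\t0.001\t0.126\t0.000
survival3y\tBRCA1(C)\tRAD54B(N)\t0.442\t0.002\t0.001\t0.126\t0.000
survival3y\tPARP1(N)\tRAD54B(N)\t0.252\t0.002\t0.002\t0.162\t0.000
survival3y\tBRCA1(C)\tFEN1(N)\t0.442\t0.357\t0.016\t0.356\t0.056
metastasis\tCSNK1E(C)\tTP53(N)\t0.682\t0.012\t0.003\t0.369\t0.420
metastasis\tBRCA1(C)\tTP53(N)\t0.281\t0.012\t0.005\t0.369\t0.129
metastasis\tPOLB(N)\tTP53(N)\t0.485\t0.012\t0.007\t0.369\t0.108
metastasis\tPARP1(N)\tTP53(N)\t0.299\t0.012\t0.008\t0.369\t0.414
metastasis\tRB1(N)\tTP53(N)\t0.114\t0.012\t0.008\t0.369\t0.092
metastasis\tBRCA1(C)\tRB1(N)\t0.281\t0.114\t0.037\t0.897\t0.756
nodal\tCDH1(M)\tMSH2(C)\t0.472\t0.084\t0.007\t0.973\t0.280
nodal\tBRCA2(C)\tMSH2(C)\t0.245\t0.084\t0.016\t0.973\t0.520
nodal\tFEN1(N)\tMSH2(C)\t0.212\t0.084\t0.022\t0.973\t0.502
nodal\tBRCA1(C)\tEGFR(C)\t0.355\t0.103\t0.033\t0.973\t0.857
nodal\tBRCA2(N)\tTP53(N)\t0.190\t0.351\t0.045\t0.973\t0.483
nodal\tMSH2(C)\tRB1(N)\t0.084\t0.220\t0.045\t0.973\t0.306
grade\tABL1(C)\tCTNNB1(N)\t0.781\t0.169\t0.021\t0.931\t0.842
grade\tAURKB(C)\tBRCA2(N)\t0.380\t0.108\t0.031\t0.931\t0.720
grade\tBRCA2(N)\tPOLB(N)\t0.108\t0.384\t0.039\t0.931\t0.985
grade\tMSH2(C)\tMYC(N)\t0.058\t0.448\t0.047\t0.931\t0.347
grade\tBRCA1(C)\tBRCA2(N)\t0.407\t0.108\t0.049\t0.931\t0.338
stage\tCDH1(M)\tRB1(N)\t0.346\t0.107\t0.012\t0.974\t0.632
stage\tEGFR(C)\tRB1(N)\t0.268\t0.107\t0.031\t0.974\t0.882
stage\tFEN1(N)\tMSH2(C)\t0.538\t0.395\t0.033\t0.974\t0.502
stage\tBRCA1(C)\tTP53(N)\t0.217\t0.144\t0.038\t0.974\t0.129
stage\tPARP1(N)\tRB1(N)\t0.381\t0.107\t0.048\t0.974\t0.234
"""


def ladc_marker_panel() -> list[MarkerDef]:
    """The default 23-marker lung-adenocarcinoma IHC panel.

    Returns marker definitions carrying protein symbol, cellular location and
    the per-marker abnormality criterion (direction + threshold on the ordinal
    staining scale, or a percent-stained cutoff for CDH1).
    """
    df = pd.read_csv(io.StringIO(_PANEL_TSV), sep="\t")
    return [
        MarkerDef.from_criterion(row.protein, row.location, row.criterion)
        for row in df.itertuples()
    ]


def ladc_marker_rates() -> dict[str, float]:
    """Observed abnormal-IHC fraction per marker in the 131-patient cohort.

    Keys are marker names like ``"RAD54B(N)"``; used as realistic marginal
    abnormality rates by the synthetic-cohort generator.
    """
    df = pd.read_csv(io.StringIO(_PANEL_TSV), sep="\t")
    return {
        f"{row.protein}({row.location})": float(row.abnormal_rate)
        for row in df.itertuples()
    }


def ladc_synergy_rows() -> pd.DataFrame:
    """The 26 published (marker pair, clinical feature) screen records."""
    return pd.read_csv(io.StringIO(_SYNERGY_ROWS_TSV), sep="\t")
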