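"""Published reference values for validating the statistics.

These are the system-organ-class and preferred-term level disproportionality
statistics reported in a published FAERS analysis of epirubicin
(reports received 2014Q1–2023Q1), transcribed to the printed precision.
They are used as *inputs* for internal-consistency checks: under the
formulas implemented here, IC = log2(EBGM) exactly, and every 95% interval
is log-symmetric, so the printed values must reproduce each other.  The
underlying multi-gigabyte extract (and the licensed MedDRA dictionary) is
not shipped, so the absolute counts themselves are not recomputable here.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["epirubicin_soc_reference", "epirubicin_pt_reference", "gabapentin_gait_apraxia_reference"]

_SOC_ROWS = [
    # soc_name, soc_code, a, ror, ror_lo, ror_hi, prr, prr_lo, prr_hi, chi2, ic, ic025, ebgm, ebgm05
    ("Blood and lymphatic system disorders", 10005329, 1011,
     7.00, 6.56, 7.47, 6.47, 6.10, 6.87, 4732.73, 2.69, 2.59, 6.46, 6.06),
    ("Cardiac disorders", 10007541, 731,
     3.29, 3.05, 3.54, 3.14, 2.93, 3.37, 1089.17, 1.65, 1.54, 3.14, 2.91),
    ("Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 10029104, 564,
     3.58, 3.29, 3.90, 3.46, 3.19, 3.75, 998.42, 1.79, 1.66, 3.46, 3.17),
    ("Hepatobiliary disorders", 10019805, 506,
     7.27, 6.65, 7.95, 7.00, 6.42, 7.62, 2610.84, 2.80, 2.66, 6.98, 6.39),
    ("Pregnancy, puerperium and perinatal conditions", 10036585, 87,
     4.71, 3.81, 5.82, 4.68, 3.80, 5.77, 252.03, 2.23, 1.86, 4.68, 3.79),
    ("Congenital, familial and genetic disorders", 10010331, 33,
     6.37, 4.53, 8.97, 6.36, 4.52, 8.94, 148.68, 2.67, 1.96, 6.34, 4.51),
]

_PT_ROWS = [
    # pt, soc_name, a, ebgm, ebgm05
    ("Hepatic artery stenosis", "Hepatobiliary disorders", 8, 468.01, 219.99),
    ("Endocardial fibrosis", "Cardiac disorders", 3, 426.22, 125.53),
    ("Gait apraxia", "Nervous system disorders", 3, 426.22, 125.53),
    ("Cardiac perfusion defect", "Cardiac disorders", 3, 331.50, 99.81),
    ("Hepatic artery occlusion", "Hepatobiliary disorders", 3, 308.64, 93.40),
    ("Administration site oedema", "General disorders and administration site conditions", 4, 284.15, 101.40),
    ("Post embolisation syndrome", "Injury, poisoning and procedural complications", 4, 195.64, 70.97),
    ("Menopausal disorder", "Reproductive system and breast disorders", 3, 142.07, 44.55),
    ("Granulocyte count decreased", "Investigations", 26, 138.27, 93.24),
    ("Intestinal atresia", "Congenital, familial and genetic disorders", 3, 127.87, 40.21),
    ("Biliary fistula", "Hepatobiliary disorders", 3, 119.34, 37.60),
    ("Acute cutaneous lupus erythematosus", "Skin and subcutaneous tissue disorders", 4, 110.50, 40.70),
    ("Miller Fisher syndrome", "Nervous system disorders", 4, 102.00, 37.62),
    ("Right atrial dilatation", "Cardiac disorders", 7, 97.59, 45.94),
    ("Administration site extravasation", "General disorders and administration site conditions", 19, 86.02, 54.49),
    ("Xerophthalmia", "Eye disorders", 8, 83.16, 41.17),
    ("Placental disorder", "Pregnancy, puerperium and perinatal conditions", 10, 76.11, 40.61),
    ("Neutrophil percentage decreased", "Investigations", 4, 70.20, 26.04),
    ("Cardiac dysfunction", "Cardiac disorders", 49, 68.67, 51.70),
    ("Bladder irritation", "Renal and urinary disorders", 8, 62.81, 31.17),
    ("Refractory cancer", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 3, 62.59, 19.94),
    ("Metastases to thorax", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 3, 59.28, 18.90),
    ("Pseudocirrhosis", "Hepatobiliary disorders", 4, 53.52, 19.90),
    ("Merycism", "Psychiatric disorders", 3, 52.96, 16.91),
    ("Dilated cardiomyopathy", "Cardiac disorders", 43, 50.79, 37.55),
    ("Catheter site related reaction", "General disorders and administration site conditions", 5, 49.40, 20.41),
    ("Metastases to the mediastinum", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 4, 48.71, 18.13),
    ("Subclavian vein thrombosis", "Vascular disorders", 8, 44.45, 22.11),
    ("Carbohydrate antigen 15-3 increased", "Investigations", 6, 43.03, 19.22),
    ("Psychotic behaviour", "Psychiatric disorders", 7, 42.45, 20.12),
]


def epirubicin_soc_reference() -> pd.DataFrame:
    """SOC-level reference statistics (six SOCs, all four estimators)."""
    return pd.DataFrame(
        _SOC_ROWS,
        columns=["soc_name", "soc_code", "a", "ror", "ror_lo", "ror_hi",
                 "prr", "prr_lo", "prr_hi", "chi2", "ic", "ic025", "ebgm", "ebgm05"],
    )


def epirubicin_pt_reference() -> pd.DataFrame:
    """Top-30 PT-level reference rows ranked by EBGM."""
    return pd.DataFrame(_PT_ROWS, columns=["pt", "soc_name", "a", "ebgm", "ebgm05"])


def gabapentin_gait_apraxia_reference() -> dict:
    """Reference reverse-screen row: gabapentin against gait apraxia."""
    return {"drug": "GABAPENTIN", "pt": "Gait apraxia", "a": 3,
            "ror": 35.32, "ror_lo": 10.54, "prr": 35.22, "prr_lo": 10.54,
            "ic": 4.50, "ic025": 3.41, "ebgm": 162.03, "ebgm05": 38.72}
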