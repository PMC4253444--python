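"""Small built-in example datasets (generated in code, no files).

``hcc_clinical_sheet`` reproduces the clinical-features table of a
27-patient HCC cohort (12 HCV-associated, 15 alcohol-associated
tumors) used as the worked example for
:func:`hepmeth.cohort.summarize_clinical`: differentiation grade,
gender, TNM stage, multifocality, vascularization, tumor size class
and underlying cirrhosis, with the marginal counts of the published
cohort description.
"""

from __future__ import annotations

import pandas as pd

from .io import validate_sample_sheet

# per-etiology criterion counts; each feature is assigned independently
_FEATURES: dict[str, dict[str, tuple[int, int]]] = {
    # feature -> criterion -> (n HCV, n EtOH)
    "differentiation": {"1": (4, 6), "2": (7, 7), "3": (1, 2)},
    "gender": {"Male": (9, 12), "Female": (3, 3)},
    "tnm_stage": {"T1": (4, 6), "T2": (4, 3), "T3": (4, 5), "T4": (0, 1)},
    "multifocality": {"yes": (4, 9), "no": (8, 6)},
    "vascularization": {"yes": (6, 8), "no": (6, 7)},
    "tumor_size_class": {">5 cm": (4, 7), "<5 cm": (8, 8)},
    "cirrhosis_flag": {"yes": (12, 14), "no": (0, 1)},
}


def hcc_clinical_sheet() -> pd.DataFrame:
    """27-patient HCC sample sheet (12 HCV, 15 EtOH) with clinical
    covariates distributed by the published marginal counts."""
    cohorts = {"HCV": 12, "EtOH": 15}
    rows = {}
    for ei, (etiology, n) in enumerate(cohorts.items()):
        for i in range(n):
            sid = f"HCC_{etiology}_{i + 1:02d}"
            rows[sid] = {"tissue_class": "HCC", "etiology": etiology}
    sheet = pd.DataFrame.from_dict(rows, orient="index")
    sheet.index.name = "sample_id"
    for feature, criteria in _FEATURES.items():
        for col, etiology in enumerate(cohorts):
            values = []
            for criterion, counts in criteria.items():
                values.extend([criterion] * counts[col])
            idx = sheet.index[sheet["etiology"] == etiology]
            assert len(values) == len(idx)
            sheet.loc[idx, feature] = values
    return validate_sample_sheet(sheet)
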