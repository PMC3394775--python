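"""Published benchmark accuracy tables used by the rank-comparison demos.

Average cross-validated accuracies (percent) of five classifiers — a
linear-kernel SVM, a random forest (RF), nearest shrunken centroids (PAM),
and the two evolutionary rule learners (BioHEL, GAssist) — under three
feature selectors (CFS, PLSS, RFS) on three public two-class cancer
expression cohorts: prostate (52 tumor / 50 normal), diffuse large B-cell
lymphoma (58 DLBCL / 19 follicular), and breast (84 luminal / 44
non-luminal).  The "none" rows are BioHEL trained on all genes without
external selection.

These tables are *inputs*: feeding them to
:func:`rulexp.evaluate.friedman_average_ranks` reproduces the published
average-rank comparisons of classifiers and of selectors.
"""

from __future__ import annotations

import pandas as pd

CLASSIFIERS = ["SVM", "RF", "PAM", "BioHEL", "GAssist"]
SELECTORS = ["CFS", "PLSS", "RFS"]
DATASETS = ["prostate", "lymphoma", "breast"]

# (dataset, selector) -> {classifier: avg accuracy %}
TENFOLD_ACCURACY = {
    ("prostate", "CFS"): {"BioHEL": 91, "GAssist": 93, "SVM": 90, "RF": 92, "PAM": 91},
    ("prostate", "PLSS"): {"BioHEL": 92, "GAssist": 93, "SVM": 90, "RF": 92, "PAM": 94},
    ("prostate", "RFS"): {"BioHEL": 89, "GAssist": 92, "SVM": 88, "RF": 93, "PAM": 90},
    ("lymphoma", "CFS"): {"BioHEL": 81, "GAssist": 80, "SVM": 87, "RF": 87, "PAM": 78},
    ("lymphoma", "PLSS"): {"BioHEL": 93, "GAssist": 94, "SVM": 91, "RF": 87, "PAM": 86},
    ("lymphoma", "RFS"): {"BioHEL": 91, "GAssist": 89, "SVM": 91, "RF": 89, "PAM": 86},
    ("breast", "CFS"): {"BioHEL": 84, "GAssist": 87, "SVM": 86, "RF": 86, "PAM": 89},
    ("breast", "PLSS"): {"BioHEL": 84, "GAssist": 85, "SVM": 84, "RF": 89, "PAM": 88},
    ("breast", "RFS"): {"BioHEL": 86, "GAssist": 88, "SVM": 80, "RF": 89, "PAM": 88},
}

LOOCV_ACCURACY = {
    ("prostate", "CFS"): {"BioHEL": 92, "GAssist": 93, "SVM": 89, "RF": 95, "PAM": 90},
    ("prostate", "PLSS"): {"BioHEL": 94, "GAssist": 92, "SVM": 93, "RF": 93, "PAM": 93},
    ("prostate", "RFS"): {"BioHEL": 88, "GAssist": 93, "SVM": 89, "RF": 91, "PAM": 91},
    ("lymphoma", "CFS"): {"BioHEL": 84, "GAssist": 87, "SVM": 88, "RF": 87, "PAM": 84},
    ("lymphoma", "PLSS"): {"BioHEL": 92, "GAssist": 92, "SVM": 94, "RF": 90, "PAM": 86},
    ("lymphoma", "RFS"): {"BioHEL": 88, "GAssist": 88, "SVM": 90, "RF": 92, "PAM": 83},
    ("breast", "CFS"): {"BioHEL": 82, "GAssist": 84, "SVM": 84, "RF": 84, "PAM": 90},
    ("breast", "PLSS"): {"BioHEL": 84, "GAssist": 84, "SVM": 81, "RF": 88, "PAM": 86},
    ("breast", "RFS"): {"BioHEL": 82, "GAssist": 85, "SVM": 86, "RF": 87, "PAM": 88},
}

# BioHEL without external feature selection ("none" rows); not part of the
# classifier rank comparison, which conditions on shared selectors.
TENFOLD_NONE_BIOHEL = {"prostate": 94, "lymphoma": 95, "breast": 88}
LOOCV_NONE_BIOHEL = {"prostate": 92, "lymphoma": 94, "breast": 86}


def classifier_table(scheme: str = "10fold") -> pd.DataFrame:
    """Blocks (dataset x selector) by classifier accuracy table."""
    src = TENFOLD_ACCURACY if scheme == "10fold" else LOOCV_ACCURACY
    rows = {f"{d}/{s}": {c: src[(d, s)][c] for c in CLASSIFIERS}
            for d in DATASETS for s in SELECTORS}
    return pd.DataFrame.from_dict(rows, orient="index")[CLASSIFIERS]


def selector_table(scheme: str = "10fold") -> pd.DataFrame:
    """Blocks (dataset x classifier) by selector accuracy table."""
    src = TENFOLD_ACCURACY if scheme == "10fold" else LOOCV_ACCURACY
    rows = {f"{d}/{c}": {s: src[(d, s)][c] for s in SELECTORS}
            for d in DATASETS for c in CLASSIFIERS}
    return pd.DataFrame.from_dict(rows, orient="index")[SELECTORS]
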