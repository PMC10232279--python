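"""Reference values from a published reduced-LVEF ECG-classifier study.

These constants reproduce the worked example used throughout the package
documentation and validation suite: a hospital study in which a tabular ECG
classifier of reduced LVEF was trained on ~30k ECG/echo pairs, its attribution
clusters were interpreted into ECG criteria, and seven cardiologists read 100
ECGs (half with reduced LVEF) before and after being taught those criteria.
Only printed summary numbers appear here -- counts and per-reader percentages
-- never patient-level data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evalstats import ReaderStudy

#: dataset counts: records (and reduced-LVEF records) per split
STUDY_COUNTS = {
    "train_records": 29_907,
    "train_reduced": 2_764,
    "test_records": 7_196,
    "test_reduced": 737,
    "total_records": 37_103,
    # explanation cohort: predicted-positive test ECGs, paced excluded
    "test_predicted_positive": 429,
    "test_predicted_positive_paced": 237,
    "external_predicted_positive": 1_876,
    "external_predicted_positive_paced": 632,
}

#: per-reader accuracy / sensitivity / specificity (percent), before and
#: after criteria teaching; 100 ECGs per reader, 50 with reduced LVEF
READER_PERFORMANCE = pd.DataFrame(
    {
        "reader": [f"R{i}" for i in range(1, 8)],
        "accuracy_before": [62.0, 57.0, 64.0, 63.0, 61.0, 71.0, 62.0],
        "sensitivity_before": [52.0, 26.0, 36.0, 36.0, 34.0, 50.0, 28.0],
        "specificity_before": [72.0, 88.0, 92.0, 90.0, 88.0, 92.0, 96.0],
        "accuracy_after": [72.0, 76.0, 71.0, 74.0, 71.0, 77.0, 76.0],
        "sensitivity_after": [66.0, 70.0, 84.0, 60.0, 64.0, 74.0, 80.0],
        "specificity_after": [78.0, 82.0, 58.0, 88.0, 78.0, 80.0, 72.0],
    }
)

#: the published Mean (SD) row of the same table (population-SD convention)
READER_SUMMARY_PUBLISHED = {
    "before": {"mean": {"accuracy": 62.9, "sensitivity": 37.4, "specificity": 88.3},
               "sd": {"accuracy": 3.9, "sensitivity": 9.3, "specificity": 7.1}},
    "after": {"mean": {"accuracy": 73.9, "sensitivity": 71.1, "specificity": 76.6},
              "sd": {"accuracy": 2.4, "sensitivity": 8.1, "specificity": 8.8}},
}

N_ECGS_PER_READER = 100
N_POSITIVE_PER_READER = 50


def reader_study_from_table(table: pd.DataFrame = READER_PERFORMANCE) -> ReaderStudy:
    """Reconstruct a reader study realising the printed per-reader rates.

    Each reader rates the same 100 ECGs (50 reduced-LVEF).  Correct calls are
    assigned to the lowest-indexed ECGs of each class, which reproduces every
    printed sensitivity/specificity exactly; per-ECG pairing between phases is
    arbitrary, so only margin-based statistics (summaries, discordance counts
    up to pairing) should be read from the result.
    """
    n_pos = N_POSITIVE_PER_READER
    n_neg = N_ECGS_PER_READER - n_pos
    truth = np.array([True] * n_pos + [False] * n_neg)
    frames = []
    for _, row in table.iterrows():
        calls = {}
        for phase in ("before", "after"):
            tp = int(round(row[f"sensitivity_{phase}"] / 100 * n_pos))
            tn = int(round(row[f"specificity_{phase}"] / 100 * n_neg))
            correct = np.r_[np.arange(n_pos) < tp, np.arange(n_neg) < tn]
            calls[phase] = np.where(correct, truth, ~truth)
        frames.append(pd.DataFrame({
            "reader_id": row["reader"],
            "ecg_id": [f"E{i:03d}" for i in range(N_ECGS_PER_READER)],
            "truth": truth,
            "call_before": calls["before"],
            "call_after": calls["after"],
        }))
    return ReaderStudy(pd.concat(frames, ignore_index=True))
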