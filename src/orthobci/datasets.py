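"""Bundled reference benchmark tables.

Per-subject performance figures from a published evaluation of a six-option
P300 hand-orthosis interface on 18 healthy subjects (HS) and 8 ALS patients:
offline cross-validated classification accuracies, online selection
accuracies, average selection times, and information transfer rates, each
under the without-orthosis and with-orthosis conditions.  They serve as
worked-example inputs for the evaluation statistics (summary statistics,
ITR recomputation, paired condition comparisons); ``None`` marks subjects
who did not perform a condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "cv_accuracy_table",
    "online_accuracy_table",
    "online_timing_table",
    "paired_selection_times",
    "paired_itrs",
    "paired_accuracies",
]

# Offline five-fold CV accuracies (%) per class: (target, non-target).
_CV_ACCURACY = {
    "HS1": (76.1, 85.1), "HS2": (76.2, 85.3), "HS3": (85.3, 90.4),
    "HS4": (81.4, 88.6), "HS5": (78.7, 85.3), "HS6": (93.3, 98.4),
    "HS7": (90.5, 95.2), "HS8": (86.3, 90.5), "HS9": (83.8, 87.9),
    "HS10": (87.0, 94.4), "HS11": (77.2, 85.5), "HS12": (75.7, 81.3),
    "HS13": (72.5, 78.9), "HS14": (87.2, 91.2), "HS15": (71.9, 79.4),
    "HS16": (73.7, 80.4), "HS17": (61.6, 76.1), "HS18": (71.2, 81.5),
    "ALS1": (80.9, 87.6), "ALS2": (71.5, 76.3), "ALS3": (63.2, 69.8),
    "ALS4": (79.5, 86.7), "ALS5": (73.0, 83.4), "ALS6": (86.5, 91.5),
    "ALS7": (84.5, 89.9), "ALS8": (77.8, 86.5),
}

# Online selection accuracy (%): (without orthosis, with orthosis, total).
_ONLINE_ACCURACY = {
    "HS1": (75.00, 83.33, 80.00), "HS2": (100.00, 88.89, 94.44),
    "HS3": (100.00, 100.00, 100.00), "HS4": (100.00, 100.00, 100.00),
    "HS5": (100.00, 100.00, 100.00), "HS6": (100.00, 100.00, 100.00),
    "HS7": (100.00, 100.00, 100.00), "HS8": (100.00, 100.00, 100.00),
    "HS9": (100.00, 91.67, 96.67), "HS10": (100.00, 100.00, 100.00),
    "HS11": (88.89, 100.00, 94.44), "HS12": (94.44, 88.89, 91.67),
    "HS13": (83.33, 83.33, 83.33), "HS14": (100.00, 100.00, 100.00),
    "HS15": (72.22, 77.78, 75.00), "HS16": (66.67, 58.33, 63.33),
    "HS17": (50.00, 44.44, 47.22), "HS18": (88.89, 66.67, 83.33),
    "ALS1": (None, 83.33, 83.33), "ALS2": (None, 75.00, 75.00),
    "ALS3": (None, 100.00, 100.00), "ALS4": (None, 100.00, 100.00),
    "ALS5": (77.78, 66.67, 73.33), "ALS6": (100.00, 100.00, 100.00),
    "ALS7": (100.00, 88.89, 94.44), "ALS8": (100.00, 100.00, 100.00),
}

# Average selection time (s) and ITR (bit/min), each (without, with, total).
_ONLINE_TIMING = {
    "HS1": ((10.22, 11.26, 10.87), (7.01, 8.25, 7.72)),
    "HS2": ((10.67, 12.47, 11.52), (14.53, 8.78, 11.18)),
    "HS3": ((5.43, 7.62, 6.74), (28.56, 20.37, 23.01)),
    "HS4": ((6.35, 6.72, 6.54), (24.43, 23.08, 23.73)),
    "HS5": ((8.68, 13.56, 11.12), (17.86, 11.44, 13.95)),
    "HS6": ((2.94, 3.03, 2.98), (52.83, 51.20, 52.00)),
    "HS7": ((4.18, 4.61, 4.40), (37.08, 33.63, 35.27)),
    "HS8": ((4.33, 6.49, 5.41), (35.82, 23.91, 28.67)),
    "HS9": ((10.56, 12.21, 11.18), (14.69, 9.72, 12.32)),
    "HS10": ((3.10, 4.93, 4.02), (50.01, 31.43, 38.60)),
    "HS11": ((10.13, 11.05, 10.62), (10.80, 14.04, 12.13)),
    "HS12": ((7.61, 8.50, 8.04), (16.92, 12.87, 14.75)),
    "HS13": ((13.41, 12.34, 13.14), (6.93, 7.52, 7.07)),
    "HS14": ((3.57, 5.94, 4.76), (43.45, 26.10, 32.61)),
    "HS15": ((9.54, 11.19, 10.40), (6.84, 7.00, 6.89)),
    "HS16": ((11.28, 15.50, 12.84), (4.75, 2.47, 3.67)),
    "HS17": ((7.51, 12.61, 9.91), (3.39, 1.45, 2.19)),
    "HS18": ((13.84, 10.40, 13.15), (7.91, 5.15, 7.06)),
    "ALS1": ((None, 9.80, 9.80), (None, 9.48, 9.48)),
    "ALS2": ((None, 8.72, 8.72), (None, 8.21, 8.21)),
    "ALS3": ((None, 7.40, 7.40), (None, 20.96, 20.96)),
    "ALS4": ((None, 10.12, 10.12), (None, 15.33, 15.33)),
    "ALS5": ((9.56, 14.83, 11.47), (8.19, 3.61, 5.91)),
    "ALS6": ((4.39, 5.72, 5.06), (35.31, 27.10, 30.66)),
    "ALS7": ((4.84, 7.19, 5.94), (32.05, 15.23, 21.67)),
    "ALS8": ((6.16, 5.56, 5.86), (25.17, 27.90, 26.46)),
}


def cv_accuracy_table() -> pd.DataFrame:
    """Offline CV accuracies (%) with columns target/non_target/mean."""
    frame = pd.DataFrame.from_dict(_CV_ACCURACY, orient="index",
                                   columns=["target", "non_target"])
    frame.index.name = "subject"
    frame["mean"] = 0.5 * (frame["target"] + frame["non_target"])
    return frame


def online_accuracy_table() -> pd.DataFrame:
    """Online selection accuracy (%) per condition."""
    frame = pd.DataFrame.from_dict(
        _ONLINE_ACCURACY, orient="index",
        columns=["without_orthosis", "with_orthosis", "total"]).astype(float)
    frame.index.name = "subject"
    return frame


def online_timing_table() -> pd.DataFrame:
    """Average selection time (s) and ITR (bit/min) per condition."""
    rows = {}
    for subject, (times, itrs) in _ONLINE_TIMING.items():
        rows[subject] = {
            "time_without": times[0], "time_with": times[1],
            "time_total": times[2],
            "itr_without": itrs[0], "itr_with": itrs[1], "itr_total": itrs[2],
        }
    frame = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    frame.index.name = "subject"
    return frame


def _paired(col_a: str, col_b: str,
            frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sub = frame[[col_a, col_b]].dropna()
    return sub[col_a].to_numpy(), sub[col_b].to_numpy()


def paired_selection_times() -> tuple[np.ndarray, np.ndarray]:
    """(without, with) selection times of subjects who ran both conditions."""
    return _paired("time_without", "time_with", online_timing_table())


def paired_itrs() -> tuple[np.ndarray, np.ndarray]:
    """(without, with) ITRs of subjects who ran both conditions."""
    return _paired("itr_without", "itr_with", online_timing_table())


def paired_accuracies() -> tuple[np.ndarray, np.ndarray]:
    """(without, with) online accuracies of subjects who ran both conditions."""
    return _paired("without_orthosis", "with_orthosis", online_accuracy_table())
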