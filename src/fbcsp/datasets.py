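"""Published per-subject decoding accuracies for the ten-pilot cohort.

The study behind this package reported, for each of its 10 participants,
the leave-one-event-pair-out accuracy of six classifier families; the raw
EEG was never deposited, so these printed percentages are the only
cohort-level data available and serve as the input to the cohort
statistics (:mod:`fbcsp.report`).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_accuracies"]

_SUBJECTS = [f"S{i}" for i in range(1, 11)]

_ACCURACIES = {
    "LDA":     [79.41, 84.21, 78.57, 82.69, 66.67, 69.57, 68.18, 73.21, 66.67, 60.87],
    "KNN":     [79.41, 84.21, 59.52, 80.77, 66.67, 56.52, 68.18, 80.36, 66.67, 52.17],
    "SVM_LIN": [76.47, 84.21, 64.29, 80.77, 63.89, 56.52, 68.18, 69.64, 52.38, 56.52],
    "SVM_RBF": [73.53, 84.21, 73.81, 84.62, 69.44, 56.52, 73.21, 65.91, 61.90, 50.00],
    "RF":      [76.47, 86.84, 54.76, 84.62, 69.44, 60.87, 65.91, 78.57, 61.90, 47.83],
    "NN":      [88.23, 92.10, 78.57, 86.53, 77.77, 67.39, 68.18, 80.35, 69.04, 69.56],
}


def published_accuracies() -> pd.DataFrame:
    """Classifiers x subjects accuracy matrix in percent (10 subjects)."""
    return pd.DataFrame(_ACCURACIES, index=_SUBJECTS).T
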