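"""Functional front-end for single-session and cohort validation runs.

Thin wrappers over :class:`~fbcsp.model.EventPairDecoder`: one call per
subject session, and a cohort runner assembling the classifiers x subjects
accuracy matrix that the cohort statistics consume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .classify import ClassifierSpec
from .io import EventList, Recording
from .model import DecodingResults, EventPairDecoder

__all__ = ["run_validation", "run_cohort"]


def run_validation(recording: Recording, events: EventList,
                   classifier: str | ClassifierSpec = "LDA",
                   **decoder_kwargs) -> DecodingResults:
    """Validate one session with leave-one-event-pair-out cross-validation.

    Accepts every :class:`EventPairDecoder` keyword (bank, csp_components,
    artifact_threshold, ...).  Returns the per-fold results and subject
    accuracy.
    """
    decoder = EventPairDecoder(recording, events, classifier=classifier,
                               **decoder_kwargs)
    return decoder.fit()


def run_cohort(subjects: dict[str, tuple[Recording, EventList]],
               classifiers: list[str | ClassifierSpec],
               **decoder_kwargs) -> pd.DataFrame:
    """Validate every (classifier, subject) pair.

    Returns a classifiers x subjects DataFrame of subject accuracies in
    percent.  A failing cell is recorded as NaN with a warning and the run
    continues.
    """
    if not subjects or not classifiers:
        raise ValueError("need at least one subject and one classifier")
    names = [c.family if isinstance(c, ClassifierSpec) else c for c in classifiers]
    matrix = pd.DataFrame(index=names, columns=list(subjects), dtype=float)
    for clf, name in zip(classifiers, names):
        for subject, (recording, events) in subjects.items():
            try:
                result = run_validation(recording, events, classifier=clf,
                                        **decoder_kwargs)
                matrix.loc[name, subject] = 100.0 * result.accuracy
            except Exception as exc:
                warnings.warn(f"subject {subject!r} with {name} failed: {exc}",
                              stacklevel=2)
                matrix.loc[name, subject] = np.nan
    return matrix
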