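"""The decoding model: filter bank -> CSP -> log-bandpower -> MI -> classifier.

:class:`EventPairDecoder` ties the whole pipeline to one recording session
and one classifier family.  Its :meth:`~EventPairDecoder.fit` runs the
chronology-preserving *leave-one-event-pair-out* validation: each fold
holds out the pre-event/event-related trial pair of a single cue and trains
everything stateful — the per-band CSP projections, the feature
standardizer, the MI ranking and the hyperparameter search — on the
remaining events only.  Zero-phase band-pass filtering is stateless and is
applied once to the continuous recording, outside the fold loop; epoching
happens after filtering.

The returned :class:`DecodingResults` carries per-fold predictions and
chosen hyperparameters, the subject-level accuracy (mean over folds), and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import csp as _csp
from .classify import ClassifierSpec, TunedModel, tune_and_fit
from .features import (FeatureTable, MIRanking, Standardizer,
                       assemble_features, mi_rank)
from .filterbank import (DEFAULT_KAISER_BETA, DEFAULT_N_TAPS, BandSpec,
                         apply_bank, default_bank)
from .io import (EVENT_RELATED, PRE_EVENT, EpochedTrials, EventList,
                 Recording, extract_trials, screen_artifacts)

__all__ = ["EventPairDecoder", "DecodingResults", "FoldResult", "FoldModel"]


@dataclass(frozen=True)
class FoldResult:
    """Outcome of one leave-one-event-pair-out fold."""

    event: int
    true_labels: tuple[str, str]
    predicted_labels: tuple[str, str]
    accuracy: float
    n_sel: int
    params: dict
    cv_accuracy: float


@dataclass
class FoldModel:
    """Everything fitted on one fold's training events."""

    csp_models: dict[str, _csp.CSPModel]
    standardizer: Standardizer
    ranking: MIRanking
    tuned: TunedModel

    def predict(self, band_trials: dict[str, EpochedTrials]) -> np.ndarray:
        projected = {
            band: _csp.transform(model, band_trials[band].data)
            for band, model in self.csp_models.items()
        }
        labels = next(iter(band_trials.values())).labels
        table = assemble_features(projected, labels)
        table = self.standardizer.transform(table)
        return self.tuned.predict(table)


class EventPairDecoder:
    """Decode pre-cue anticipation vs cue reaction from one EEG session.

    Parameters
    ----------
    recording
        Continuous multichannel recording (microvolts).
    events
        Cue-onset sample indices.
    classifier
        Family name (``"LDA"``, ``"KNN"``, ``"SVM_LIN"``, ``"SVM_RBF"``,
        ``"RF"``, ``"NN"``) or a full :class:`ClassifierSpec`.
    bank
        Band definitions; defaults to the ten canonical bands.
    csp_components
        ``"all"`` keeps every spatial component per band (14 channels give
        K = 140 features); ``"pairs"`` keeps ``n_pairs`` filter pairs from
        both ends of the eigenvalue spectrum (3 pairs give K = 60).
    artifact_threshold
        Peak-amplitude screening threshold in microvolts; ``None`` (default)
        disables screening.
    """

    def __init__(
        self,
        recording: Recording,
        events: EventList,
        classifier: str | ClassifierSpec = "LDA",
        bank: list[BandSpec] | None = None,
        n_taps: int = DEFAULT_N_TAPS,
        kaiser_beta: float = DEFAULT_KAISER_BETA,
        csp_components: str = "all",
        n_pairs: int = 3,
        mi_neighbors: int = 3,
        artifact_threshold: float | None = None,
        window_s: float = 1.5,
        seed: int = 0,
    ) -> None:
        if csp_components not in ("all", "pairs"):
            raise ValueError('csp_components must be "all" or "pairs"')
        self.recording = recording
        self.events = events
        self.spec = (
            classifier
            if isinstance(classifier, ClassifierSpec)
            else ClassifierSpec(family=classifier, seed=seed)
        )
        self.bank = bank if bank is not None else default_bank(recording.fs)
        self.n_taps = n_taps
        self.kaiser_beta = kaiser_beta
        self.csp_components = csp_components
        self.n_pairs = n_pairs
        self.mi_neighbors = mi_neighbors
        self.artifact_threshold = artifact_threshold
        self.window_s = window_s
        self.seed = seed

    # -- pipeline stages ----------------------------------------------------

    def prepare_trials(self) -> dict[str, EpochedTrials]:
        """Filter the continuous recording per band, then epoch each band.

        Artifact screening (when enabled) is decided on the broadband
        epochs and the same events are dropped from every band.
        """
        broadband = extract_trials(self.recording, self.events, self.window_s)
        _, dropped = screen_artifacts(broadband, self.artifact_threshold)
        filtered = apply_bank(self.recording, self.bank,
                              n_taps=self.n_taps, kaiser_beta=self.kaiser_beta)
        band_trials: dict[str, EpochedTrials] = {}
        for band, rec in zip(self.bank, filtered):
            trials = extract_trials(rec, self.events, self.window_s)
            if dropped:
                keep = ~np.isin(trials.event_index, dropped)
                trials = trials.subset(keep)
            band_trials[band.name] = trials
        if next(iter(band_trials.values())).n_events < 4:
            raise ValueError("need at least 4 retained events for validation")
        return band_trials

    def fit_fold(self, train: dict[str, EpochedTrials]) -> FoldModel:
        """Fit every stateful stage on one fold's training trials only."""
        csp_models: dict[str, _csp.CSPModel] = {}
        projected: dict[str, np.ndarray] = {}
        for band, trials in train.items():
            model = _csp.fit_csp(
                trials.class_data(PRE_EVENT),
                trials.class_data(EVENT_RELATED),
                band_name=band,
            )
            if self.csp_components == "pairs":
                model = _csp.select_pairs(model, self.n_pairs)
            csp_models[band] = model
            projected[band] = _csp.transform(model, trials.data)
        labels = next(iter(train.values())).labels
        table = assemble_features(projected, labels)
        scaler = Standardizer()
        table = scaler.fit_transform(table)
        ranking = mi_rank(table, k=self.mi_neighbors, seed=self.seed)
        tuned = tune_and_fit(table, ranking, self.spec)
        return FoldModel(csp_models=csp_models, standardizer=scaler,
                         ranking=ranking, tuned=tuned)

    def fit(self, verbose: bool = False) -> "DecodingResults":
        """Run the full leave-one-event-pair-out validation."""
        band_trials = self.prepare_trials()
        events = next(iter(band_trials.values())).events
        fold_results: list[FoldResult] = []
        for event in events:
            train, test = {}, {}
            for band, trials in band_trials.items():
                train[band], test[band] = trials.split_event(event)
            fold = self.fit_fold(train)
            pred = fold.predict(test)
            true = next(iter(test.values())).labels
            acc = float(np.mean(pred == true))
            fold_results.append(FoldResult(
                event=int(event),
                true_labels=tuple(true),
                predicted_labels=tuple(pred),
                accuracy=acc,
                n_sel=fold.tuned.n_sel,
                params=dict(fold.tuned.params),
                cv_accuracy=fold.tuned.cv_accuracy,
            ))
            if verbose:
                print(f"event {event}: fold accuracy {acc:.2f} "
                      f"(n_sel={fold.tuned.n_sel})")
        return DecodingResults(
            classifier=self.spec.family,
            fold_results=fold_results,
            n_channels=self.recording.n_channels,
            bank_names=[b.name for b in self.bank],
        )


@dataclass
class DecodingResults:
    """Per-fold and subject-level outcome of one validated session."""

    classifier: str
    fold_results: list[FoldResult]
    n_channels: int
    bank_names: list[str]
    subject: str | None = None

    @property
    def n_events(self) -> int:
        return len(self.fold_results)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.fold_results])

    @property
    def accuracy(self) -> float:
        """Subject accuracy: mean of the per-fold (per-event) accuracies."""
        return float(self.fold_accuracies.mean())

    @property
    def n_correct(self) -> int:
        return int(round(self.fold_accuracies.sum() * 2))

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event": [f.event for f in self.fold_results],
                "accuracy": [f.accuracy for f in self.fold_results],
                "n_sel": [f.n_sel for f in self.fold_results],
                "cv_accuracy": [f.cv_accuracy for f in self.fold_results],
                "params": [f.params for f in self.fold_results],
            }
        )

    def summary(self) -> str:
        lines = [
            "Leave-one-event-pair-out decoding",
            "=" * 40,
            f"classifier        {self.classifier}",
            f"events (folds)    {self.n_events}",
            f"test trials       {2 * self.n_events}",
            f"correct trials    {self.n_correct}",
            f"subject accuracy  {100 * self.accuracy:.2f}%",
            "",
            "per-fold accuracy: "
            + " ".join(f"{a:.1f}" for a in self.fold_accuracies),
            "chosen n_sel:      "
            + " ".join(str(f.n_sel) for f in self.fold_results),
        ]
        return "\n".join(lines)
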