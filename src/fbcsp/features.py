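"""Log-bandpower features, standardization and mutual-information selection.

After band-pass and spatial filtering each trial component is summarized by
the natural log of its sample variance (band-limited EEG is zero-mean, so
variance is power; the log makes the feature distribution near-Gaussian).
With ``F`` bands and all ``N`` spatial components kept this yields
``K = F * N`` features per trial (140 for 14 channels and 10 bands).

Feature relevance is scored by the mutual information between each
(continuous) feature and the binary class label, estimated with the
Kraskov-style k-nearest-neighbor-distance entropy estimator; higher MI
means a more discriminative feature, and an independent feature scores
(up to estimator noise) zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

__all__ = [
    "VAR_EPS",
    "FeatureTable",
    "MIRanking",
    "Standardizer",
    "log_bandpower",
    "assemble_features",
    "mi_rank",
    "select_top",
]

#: Guard added to the variance before the log, so constant components yield a
#: finite (very negative) feature instead of -inf.
VAR_EPS = 1e-12


def log_bandpower(x: np.ndarray) -> float | np.ndarray:
    """Natural log of the sample variance along the last axis.

    Accepts any array whose last axis is time; reduces that axis.  A
    (near-)constant signal triggers a warning and the epsilon guard.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 samples to estimate a variance")
    v = x.var(axis=-1)
    if np.any(v < VAR_EPS):
        warnings.warn("zero-variance signal in log_bandpower; epsilon guard applied",
                      stacklevel=2)
    out = np.log(v + VAR_EPS)
    return float(out) if out.ndim == 0 else out


@dataclass
class FeatureTable:
    """Trials x K feature matrix with (band, component) column provenance."""

    values: np.ndarray
    provenance: list[tuple[str, int]]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        if len(self.provenance) != self.values.shape[1]:
            raise ValueError("provenance length must equal the feature count")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal the trial count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{band}:{comp}" for band, comp in self.provenance]

    def take_columns(self, indices) -> "FeatureTable":
        indices = list(indices)
        return FeatureTable(
            values=self.values[:, indices],
            provenance=[self.provenance[i] for i in indices],
            labels=self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.column_names)
        frame.insert(0, "label", self.labels)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path)
        prov = []
        for col in frame.columns[1:]:
            band, comp = str(col).rsplit(":", 1)
            prov.append((band, int(comp)))
        return cls(
            values=frame.iloc[:, 1:].to_numpy(dtype=float),
            provenance=prov,
            labels=frame["label"].to_numpy(),
        )


def assemble_features(projected: dict[str, np.ndarray],
                      labels: np.ndarray) -> FeatureTable:
    """Build the feature table from per-band projected trial tensors.

    ``projected`` maps band name -> (n_trials, n_components, n_samples)
    array of spatially filtered trials; one log-bandpower column is emitted
    per (band, component), bands in dict order.
    """
    if not projected:
        raise ValueError("no bands provided")
    counts = {band: arr.shape[0] for band, arr in projected.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"inconsistent trial counts across bands: {counts}")
    columns, provenance = [], []
    for band, arr in projected.items():
        power = log_bandpower(np.asarray(arr, dtype=float))  # (n_trials, n_comp)
        for comp in range(power.shape[1]):
            columns.append(power[:, comp])
            provenance.append((band, comp))
    return FeatureTable(values=np.column_stack(columns), provenance=provenance,
                        labels=np.asarray(labels))


class Standardizer:
    """Column-wise zero-mean unit-variance scaling, fitted on training rows.

    Zero-variance training columns are centered only (with a warning), never
    divided by zero.  Test rows must be transformed with the training
    statistics; fitting on them would leak label-free but fold-specific
    information into the model.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, table: FeatureTable) -> "Standardizer":
        self.mean_ = table.values.mean(axis=0)
        sd = table.values.std(axis=0)
        degenerate = sd < VAR_EPS
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance feature column(s): "
                "centered but not scaled", stacklevel=2)
            sd = np.where(degenerate, 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.mean_ is None:
            raise RuntimeError("Standardizer must be fitted before transform")
        if table.n_features != len(self.mean_):
            raise ValueError("feature count differs from the fitted table")
        return replace(table, values=(table.values - self.mean_) / self.scale_)

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        return self.fit(table).transform(table)


@dataclass(frozen=True)
class MIRanking:
    """Per-feature MI estimates (nats, clipped at 0) and the descending order."""

    mi: np.ndarray
    order: np.ndarray
    k: int

    def top(self, n_sel: int) -> np.ndarray:
        return self.order[:n_sel]


def mi_rank(table: FeatureTable, labels: np.ndarray | None = None,
            k: int = 3, seed: int | None = 0) -> MIRanking:
    """Rank features by mutual information with the class label.

    Uses the kNN-distance entropy estimator (``k`` neighbors, default 3) for
    continuous features against a discrete target.  ``k`` is reduced with a
    warning when a class has too few members.  Ties in MI are broken by
    original column index (stable descending sort).
    """
    y = np.asarray(table.labels if labels is None else labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 trials per class for MI estimation")
    k_eff = int(k)
    if k_eff >= counts.min():
        k_eff = int(counts.min()) - 1
        warnings.warn(f"MI neighbor count reduced from {k} to {k_eff} "
                      "(smallest class too small)", stacklevel=2)
    mi = mutual_info_classif(
        table.values, y, discrete_features=False, n_neighbors=k_eff,
        random_state=seed,
    )
    mi = np.clip(mi, 0.0, None)
    order = np.argsort(-mi, kind="stable")
    return MIRanking(mi=mi, order=order, k=k_eff)


def select_top(ranking: MIRanking, table: FeatureTable, n_sel: int) -> FeatureTable:
    """Keep the ``n_sel`` highest-MI columns (a prefix of the ranking)."""
    if not 1 <= n_sel <= table.n_features:
        raise ValueError(f"n_sel must be in [1, {table.n_features}], got {n_sel}")
    return table.take_columns(ranking.top(n_sel))
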