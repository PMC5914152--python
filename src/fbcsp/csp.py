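"""Common Spatial Patterns: supervised spatial filtering for two-class EEG.

The CSP transform finds a projection ``W`` whose leading components have
maximal variance for one class and minimal variance for the other, and vice
versa for the trailing components.  Per-trial spatial covariances ``X X^T``
are trace-normalized, averaged within class to ``C1`` and ``C2``, and ``W``
solves the symmetric-definite generalized eigenproblem

    C1 w = lambda (C1 + C2) w,

so each eigenvalue is the fraction of composite-covariance variance that
class 1 explains along its filter: eigenvalues live in [0, 1], 0.5 means
"no class difference in this direction", and the two ends of the sorted
spectrum carry the discriminative filters.  ``W`` whitens the composite
covariance: ``W^T (C1 + C2) W = I``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import linalg

__all__ = ["CSPModel", "fit_csp", "select_pairs", "transform"]


@dataclass(frozen=True)
class CSPModel:
    """Fitted CSP projection for one frequency band.

    ``filters`` holds the spatial filters column-wise (``W``, N x N), sorted
    by descending eigenvalue; ``eigenvalues`` are the class-1 variance
    fractions in [0, 1].  ``selected_indices`` restricts :func:`transform`
    to a subset of components when set (pairs from both spectrum ends).
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    selected_indices: tuple[int, ...] | None = None
    band_name: str | None = None

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]

    @property
    def n_components(self) -> int:
        """Number of components produced by :func:`transform`."""
        if self.selected_indices is None:
            return self.n_channels
        return len(self.selected_indices)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "band_name": self.band_name,
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "selected_indices": (
                None if self.selected_indices is None else list(self.selected_indices)
            ),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CSPModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        payload = json.loads(source)
        sel = payload["selected_indices"]
        return cls(
            filters=np.asarray(payload["filters"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            selected_indices=None if sel is None else tuple(sel),
            band_name=payload["band_name"],
        )


def _mean_covariance(trials: np.ndarray, normalize_trace: bool) -> np.ndarray:
    """Class covariance: per-trial X X^T, trace-normalized if requested, averaged."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be (n_trials, n_channels, n_samples)")
    covs = np.einsum("tcm,tdm->tcd", trials, trials)
    if normalize_trace:
        traces = np.trace(covs, axis1=1, axis2=2)
        if np.any(traces <= 0):
            raise ValueError("a trial has zero power; cannot normalize covariance")
        covs = covs / traces[:, None, None]
    return covs.mean(axis=0)


def fit_csp(trials_a: np.ndarray, trials_b: np.ndarray,
            band_name: str | None = None,
            normalize_trace: bool = True) -> CSPModel:
    """Fit the CSP projection from two sets of trials.

    ``trials_a`` and ``trials_b`` are (n_trials, n_channels, n_samples)
    arrays of the two classes.  Class *a* orients the eigenvalues: the first
    filter maximizes class-a variance fraction.  Requires at least two
    trials per class and a full-rank composite covariance (otherwise more
    trials, longer windows or shrinkage are needed).

    ``normalize_trace=True`` (the default, and the standard CSP estimator)
    divides each trial covariance by its trace, making the transform
    insensitive to trial-to-trial global power.  When the class contrast IS
    a global band-power change — the case the ground-truth simulator
    constructs — that normalization deliberately discards part of the
    contrast; pass ``normalize_trace=False`` to keep absolute power, in
    which case the extreme filter converges on the modulated source.
    """
    trials_a = np.asarray(trials_a, dtype=float)
    trials_b = np.asarray(trials_b, dtype=float)
    if trials_a.shape[0] < 2 or trials_b.shape[0] < 2:
        raise ValueError("need at least 2 trials per class to estimate covariances")
    if trials_a.shape[1:] != trials_b.shape[1:]:
        raise ValueError("classes must share channel count and trial length")
    c1 = _mean_covariance(trials_a, normalize_trace)
    c2 = _mean_covariance(trials_b, normalize_trace)
    composite = c1 + c2
    # guard: the generalized eigensolver needs a positive-definite composite
    eigvals_comp = linalg.eigvalsh(composite)
    if eigvals_comp[0] <= 1e-10 * eigvals_comp[-1]:
        raise np.linalg.LinAlgError(
            "composite covariance is rank-deficient; use more trials, longer "
            "windows, or a shrinkage estimator"
        )
    evals, evecs = linalg.eigh(c1, composite)
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, 1.0)
    w = evecs[:, order]
    # eigenvectors are sign-ambiguous: make the largest-|coefficient| positive
    flip = np.sign(w[np.abs(w).argmax(axis=0), np.arange(w.shape[1])])
    flip[flip == 0] = 1.0
    w = w * flip
    return CSPModel(filters=w, eigenvalues=evals, band_name=band_name)


def select_pairs(model: CSPModel, n_pairs: int = 3) -> CSPModel:
    """Keep ``n_pairs`` filters from each end of the eigenvalue spectrum.

    ``n_pairs = 0`` clears the selection, so :func:`transform` falls back to
    all components.
    """
    n = model.n_channels
    if n_pairs < 0:
        raise ValueError("n_pairs must be nonnegative")
    if n_pairs == 0:
        return replace(model, selected_indices=None)
    if 2 * n_pairs > n:
        raise ValueError(f"2 * {n_pairs} pairs exceed {n} available components")
    idx = tuple(range(n_pairs)) + tuple(range(n - n_pairs, n))
    return replace(model, selected_indices=idx)


def transform(model: CSPModel, trials: np.ndarray) -> np.ndarray:
    """Project trials onto the (selected) spatial filters: ``W^T X``.

    Accepts a single trial (n_channels, n_samples) or a batch
    (n_trials, n_channels, n_samples); the channel axis becomes the
    component axis.
    """
    trials = np.asarray(trials, dtype=float)
    single = trials.ndim == 2
    if single:
        trials = trials[np.newaxis]
    if trials.shape[1] != model.n_channels:
        raise ValueError(
            f"trial has {trials.shape[1]} channels, model expects {model.n_channels}"
        )
    w = model.filters
    if model.selected_indices is not None:
        w = w[:, list(model.selected_indices)]
    out = np.einsum("ck,tcm->tkm", w, trials)
    return out[0] if single else out
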