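"""Continuous recordings -> clean 2-s epoch sets.

Stage order: band-pass filter (0.5–70 Hz, zero-phase) -> segment into
non-overlapping 2-s epochs -> per-epoch baseline correction (mean
subtraction) -> automated artifact rejection -> optional ICA cleaning.
Baseline correction is defined per epoch, so it must follow segmentation;
rejection replaces visual screening with reproducible amplitude/gradient
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .bands import CHANNELS
from .exceptions import (
    AllEpochsRejectedError,
    EmptyInputError,
    InvalidParameterError,
    NumericalDegeneracyError,
)
from .synth import Recording


@dataclass(frozen=True)
class EpochSet:
    """Segmented recording: all original epochs plus a retention mask.

    ``epochs`` keeps every segmented epoch (n_epochs, 4, samples_per_epoch);
    ``retained`` marks which survived rejection so provenance is never lost.
    Downstream feature code reads :attr:`retained_epochs`.
    """

    participant_id: str
    condition: str
    fs: float
    epochs: np.ndarray
    retained: np.ndarray
    epoch_length: float
    channel_names: tuple[str, ...] = CHANNELS
    rejection_reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float)
        mask = np.asarray(self.retained, dtype=bool)
        if ep.ndim != 3 or ep.shape[1] != len(CHANNELS):
            raise InvalidParameterError(f"epochs must be (n, 4, s), got {ep.shape}")
        if ep.shape[2] != int(round(self.fs * self.epoch_length)):
            raise InvalidParameterError(
                "samples_per_epoch inconsistent with fs * epoch_length"
            )
        if mask.shape != (ep.shape[0],):
            raise InvalidParameterError("retained mask length != n_epochs")
        object.__setattr__(self, "epochs", ep)
        object.__setattr__(self, "retained", mask)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def retained_epochs(self) -> np.ndarray:
        return self.epochs[self.retained]


@dataclass(frozen=True)
class RejectionCriteria:
    """Automated per-epoch artifact thresholds (any channel trips any rule)."""

    peak_to_peak_max: float = 200.0  # uV
    abs_amplitude_max: float = 100.0  # uV
    gradient_max: float = 50.0  # uV/sample
    flatline_min_range: float = 0.5  # uV

    def __post_init__(self) -> None:
        for name in (
            "peak_to_peak_max",
            "abs_amplitude_max",
            "gradient_max",
            "flatline_min_range",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


def bandpass_filter(
    recording: Recording, low_hz: float = 0.5, high_hz: float = 70.0
) -> Recording:
    """Zero-phase 0.5–70 Hz band-pass (4th-order Butterworth, forward-backward)."""
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise InvalidParameterError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise InvalidParameterError(
            f"high_hz {high_hz} must be below Nyquist {nyq} Hz"
        )
    sos = butter(4, [low_hz, high_hz], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sosfiltfilt(sos, recording.signal, axis=1)
    return replace(recording, signal=np.ascontiguousarray(filtered))


def segment_epochs(recording: Recording, epoch_length: float = 2.0) -> EpochSet:
    """Cut into floor(duration / epoch_length) consecutive non-overlapping epochs."""
    if epoch_length <= 0:
        raise InvalidParameterError("epoch_length must be > 0")
    spe = int(round(recording.fs * epoch_length))
    n_ep = recording.n_samples // spe
    if n_ep < 1:
        raise EmptyInputError(
            f"recording shorter ({recording.duration} s) than one epoch"
        )
    trimmed = recording.signal[:, : n_ep * spe]
    epochs = trimmed.reshape(len(CHANNELS), n_ep, spe).transpose(1, 0, 2)
    return EpochSet(
        participant_id=recording.participant_id,
        condition=recording.condition,
        fs=recording.fs,
        epochs=np.ascontiguousarray(epochs),
        retained=np.ones(n_ep, dtype=bool),
        epoch_length=epoch_length,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each (epoch, channel) trace's own mean. Idempotent."""
    if epochs.n_epochs == 0:
        raise EmptyInputError("no epochs to baseline-correct")
    corrected = epochs.epochs - epochs.epochs.mean(axis=2, keepdims=True)
    return replace(epochs, epochs=corrected)


def _epoch_violation(epoch: np.ndarray, c: RejectionCriteria) -> str | None:
    """First tripped criterion for one (channels x samples) epoch, or None."""
    ptp = epoch.max(axis=1) - epoch.min(axis=1)
    if np.any(np.abs(epoch).max(axis=1) > c.abs_amplitude_max):
        return "abs_amplitude"
    if np.any(ptp > c.peak_to_peak_max):
        return "peak_to_peak"
    if np.any(np.abs(np.diff(epoch, axis=1)).max(axis=1) > c.gradient_max):
        return "gradient"
    if np.any(ptp < c.flatline_min_range):
        return "flatline"
    return None


def reject_epochs(
    epochs: EpochSet, criteria: RejectionCriteria | None = None
) -> EpochSet:
    """Drop epochs where any channel violates any criterion.

    Only currently-retained epochs are screened; decisions are recorded in the
    mask and reason map, preserving epoch order.
    """
    if epochs.n_epochs == 0:
        raise EmptyInputError("no epochs to screen")
    criteria = criteria or RejectionCriteria()
    mask = epochs.retained.copy()
    reasons = dict(epochs.rejection_reasons)
    for i in np.flatnonzero(mask):
        reason = _epoch_violation(epochs.epochs[i], criteria)
        if reason is not None:
            mask[i] = False
            reasons[i] = reason
    if not mask.any():
        raise AllEpochsRejectedError(
            f"{epochs.participant_id}/{epochs.condition}: every epoch rejected; "
            "thresholds or data are pathological"
        )
    return replace(epochs, retained=mask, rejection_reasons=reasons)


def retention_report(epochs: EpochSet) -> pd.DataFrame:
    """Per-epoch retention table: ``epoch_index, retained, reason``."""
    return pd.DataFrame(
        {
            "epoch_index": np.arange(epochs.n_epochs),
            "retained": epochs.retained,
            "reason": [
                epochs.rejection_reasons.get(i, "") for i in range(epochs.n_epochs)
            ],
        }
    )


def ica_clean(
    epochs: EpochSet,
    artifact_templates: dict[str, np.ndarray],
    threshold: float = 0.8,
    seed: int = 0,
) -> EpochSet:
    """Remove independent components correlated with artifact templates.

    Concatenated retained epochs are unmixed into <= 4 maximally independent
    components (FastICA); any component whose absolute Pearson correlation
    with an artifact template exceeds ``threshold`` is zeroed before
    reconstruction. Templates are time series over the concatenated retained
    data. Off by default in the pipeline: the decomposition is stochastic
    and the rejection thresholds already handle the injected artifact classes.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if epochs.n_retained < 4:
        raise EmptyInputError("ICA needs >= 4 retained epochs")
    kept = epochs.retained_epochs  # (k, 4, s)
    k, n_ch, spe = kept.shape
    X = kept.transpose(1, 0, 2).reshape(n_ch, k * spe).T  # (samples, channels)
    for name, tmpl in artifact_templates.items():
        if len(tmpl) != X.shape[0]:
            raise InvalidParameterError(
                f"template {name!r} length {len(tmpl)} != concatenated length {X.shape[0]}"
            )
    ica = FastICA(n_components=n_ch, random_state=seed, max_iter=1000)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(X)  # (samples, components)
    except Exception as exc:  # rank-deficient input
        raise NumericalDegeneracyError(f"ICA decomposition failed: {exc}") from exc

    removed = []
    for comp in range(sources.shape[1]):
        s = sources[:, comp]
        if s.std() == 0:
            raise NumericalDegeneracyError("degenerate (constant) IC source")
        for tmpl in artifact_templates.values():
            t = np.asarray(tmpl, dtype=float)
            if t.std() == 0:
                continue
            r = np.corrcoef(s, t)[0, 1]
            if abs(r) > threshold:
                removed.append(comp)
                break
    sources[:, removed] = 0.0
    cleaned = ica.inverse_transform(sources)  # (samples, channels)

    new_epochs = epochs.epochs.copy()
    new_epochs[epochs.retained] = (
        cleaned.T.reshape(n_ch, k, spe).transpose(1, 0, 2)
    )
    return replace(epochs, epochs=new_epochs)


def preprocess_recording(
    recording: Recording,
    low_hz: float = 0.5,
    high_hz: float = 70.0,
    epoch_length: float = 2.0,
    criteria: RejectionCriteria | None = None,
) -> EpochSet:
    """Full default chain: filter -> segment -> baseline-correct -> reject."""
    filtered = bandpass_filter(recording, low_hz, high_hz)
    epochs = segment_epochs(filtered, epoch_length)
    epochs = baseline_correct(epochs)
    return reject_epochs(epochs, criteria)
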