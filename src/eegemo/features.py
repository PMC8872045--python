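"""The 54-feature set: band powers, asymmetries, correlations, fractal dimension.

Per clean 2-s epoch and channel, absolute power in each of the five canonical
bands is the sum of one-sided periodogram power over the band's frequency bins
(rectangular window, 0.5 Hz resolution at 2 s), in uV^2. Per recording:

* FP   (20): per-channel band power averaged over retained epochs.
* DASM (10): right-minus-left difference of FP over symmetric pairs
             (TP10-TP9, AF8-AF7).
* RASM (10): right-over-left ratio of FP over the same pairs.
* CC   (10): Pearson correlation between the two electrodes' per-epoch
             band-power series, per band and pair.
* FD    (4): Katz fractal dimension of the waveform, per epoch and channel,
             averaged over retained epochs.

Total 54 = 20 + 10 + 10 + 10 + 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from . import bands as B
from .bands import BandDefinition
from .exceptions import (
    DegenerateSignalError,
    EmptyInputError,
    InvalidParameterError,
)
from .preprocess import EpochSet

#: Per-epoch band-power series keyed (channel, band): arrays of length n_retained.
BandPowerSeries = dict[tuple[str, str], np.ndarray]


@dataclass(frozen=True)
class FeatureVector:
    """One participant-condition row of the 54 canonically named features."""

    participant_id: str
    condition: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != B.FEATURE_NAMES:
            raise InvalidParameterError(
                "feature names/order must match the canonical 54-name scheme"
            )


def epoch_band_power(trace: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Absolute power (uV^2) of one epoch trace in ``[band.low_hz, band.high_hz)``.

    One-sided rectangular-window periodogram in 'spectrum' scaling, so the sum
    over all bins equals the trace's mean square and an in-band sinusoid of
    amplitude A contributes A^2/2.
    """
    trace = np.asarray(trace, dtype=float)
    if band.high_hz > fs / 2:
        raise InvalidParameterError(
            f"band [{band.low_hz}, {band.high_hz}) exceeds Nyquist {fs / 2} Hz"
        )
    freqs, pxx = periodogram(trace, fs=fs, window="boxcar", scaling="spectrum")
    sel = (freqs >= band.low_hz) & (freqs < band.high_hz)
    return float(pxx[sel].sum())


def band_power_features(epochs: EpochSet) -> tuple[dict[str, float], BandPowerSeries]:
    """FP values (mean over retained epochs) plus the unaveraged per-epoch series."""
    kept = epochs.retained_epochs
    if kept.shape[0] < 2:
        raise EmptyInputError(
            "need >= 2 retained epochs (correlation features need a series)"
        )
    series: BandPowerSeries = {}
    fp: dict[str, float] = {}
    for band_name in B.BAND_ORDER:
        band = B.BANDS[band_name]
        for ci, ch in enumerate(B.CHANNELS):
            powers = np.array(
                [epoch_band_power(kept[e, ci], epochs.fs, band) for e in range(kept.shape[0])]
            )
            series[(ch, band_name)] = powers
            fp[B.fp_name(band_name, ch)] = float(powers.mean())
    return fp, series


def dasm_features(fp_values: dict[str, float]) -> dict[str, float]:
    """Differential asymmetry: FP(right) - FP(left), per band and pair."""
    out = {}
    for band in B.BAND_ORDER:
        for pair in B.PAIR_ORDER:
            left, right = B.PAIRS[pair]
            out[B.dasm_name(band, pair)] = (
                fp_values[B.fp_name(band, right)] - fp_values[B.fp_name(band, left)]
            )
    return out


def rasm_features(fp_values: dict[str, float]) -> dict[str, float]:
    """Rational asymmetry: FP(right) / FP(left), per band and pair."""
    out = {}
    for band in B.BAND_ORDER:
        for pair in B.PAIR_ORDER:
            left, right = B.PAIRS[pair]
            denom = fp_values[B.fp_name(band, left)]
            if denom <= 0:
                raise DegenerateSignalError(
                    f"non-positive band power in {B.fp_name(band, left)}"
                )
            out[B.rasm_name(band, pair)] = fp_values[B.fp_name(band, right)] / denom
    return out


def cc_features(series: BandPowerSeries) -> dict[str, float]:
    """Pearson correlation of paired electrodes' per-epoch band-power series."""
    out = {}
    for band in B.BAND_ORDER:
        for pair in B.PAIR_ORDER:
            left, right = B.PAIRS[pair]
            a, b = series[(left, band)], series[(right, band)]
            if len(a) < 2:
                raise EmptyInputError("correlation needs series length >= 2")
            if a.std() == 0 or b.std() == 0:
                raise DegenerateSignalError(
                    f"zero-variance band-power series for CC_{band}_{pair}"
                )
            out[B.cc_name(band, pair)] = float(np.corrcoef(a, b)[0, 1])
    return out


def katz_fd(trace: np.ndarray) -> float:
    """Katz fractal dimension of a waveform.

        D = log10(n) / (log10(n) + log10(d / L))

    with L the curve length (sum of successive amplitude distances
    ``|x[i+1] - x[i]|``), d the waveform extent (maximum ``|x[i] - x[0]|``)
    and n the number of steps (len - 1). This is the standard waveform
    formulation used for EEG complexity: amplitude-scale invariant, exactly
    1 for any monotone-linear trace, and growing as irregularity raises L
    at fixed extent d.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("Katz FD needs >= 3 samples")
    n = x.size - 1
    L = float(np.sum(np.abs(np.diff(x))))
    d = float(np.max(np.abs(x[1:] - x[0])))
    if L == 0 or d == 0:
        raise DegenerateSignalError("constant trace has no curve extent")
    return np.log10(n) / (np.log10(n) + np.log10(d / L))


def fd_features(epochs: EpochSet) -> dict[str, float]:
    """Per-channel Katz FD averaged over retained epochs."""
    kept = epochs.retained_epochs
    if kept.shape[0] < 1:
        raise EmptyInputError("no retained epochs")
    out = {}
    for ci, ch in enumerate(B.CHANNELS):
        try:
            vals = [katz_fd(kept[e, ci]) for e in range(kept.shape[0])]
        except DegenerateSignalError as exc:
            raise DegenerateSignalError(f"channel {ch}: {exc}") from exc
        out[B.fd_name(ch)] = float(np.mean(vals))
    return out


def extract_all(epochs: EpochSet) -> FeatureVector:
    """Compose the full 54-entry feature vector for one recording."""
    fp, series = band_power_features(epochs)
    dasm = dasm_features(fp)
    rasm = rasm_features(fp)
    cc = cc_features(series)
    fd = fd_features(epochs)
    merged = {**fp, **dasm, **rasm, **cc, **fd}
    values = {name: merged[name] for name in B.FEATURE_NAMES}
    return FeatureVector(epochs.participant_id, epochs.condition, values)


def extract_table(epoch_sets: list[EpochSet]) -> pd.DataFrame:
    """Feature table: one row per (participant, condition), 54 feature columns."""
    rows = []
    for es in epoch_sets:
        fv = extract_all(es)
        rows.append(
            {"participant_id": fv.participant_id, "condition": fv.condition, **fv.values}
        )
    return pd.DataFrame(rows, columns=["participant_id", "condition", *B.FEATURE_NAMES])
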