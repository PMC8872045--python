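"""Canonical channels, frequency bands and feature-name scheme.

The montage is the 4-channel dry-electrode headband layout: temporoparietal
TP9/TP10 and anterior-frontal AF7/AF8 (10-20 positions). Five classical
frequency bands partition [0.5, 50) Hz with half-open edges so that a spectral
bin is counted in exactly one band.

Feature names follow the scheme used throughout the package and its reports:

    FP_<Band>_<Channel>    absolute band power, one per band x channel   (20)
    DASM_<Band>_<Pair>     differential asymmetry, right minus left      (10)
    RASM_<Band>_<Pair>     rational asymmetry, right over left           (10)
    CC_<Band>_<Pair>       epoch-wise band-power Pearson correlation     (10)
    FD_<Channel>           Katz fractal dimension                         (4)

with <Pair> in {TP, AF}: TP pairs TP9 (left) with TP10 (right), AF pairs
AF7 (left) with AF8 (right).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidParameterError

#: Canonical channel order used by every signal array in the package.
CHANNELS: tuple[str, ...] = ("TP9", "AF7", "AF8", "TP10")

#: Symmetric electrode pairs as (left, right).
PAIRS: dict[str, tuple[str, str]] = {"TP": ("TP9", "TP10"), "AF": ("AF7", "AF8")}

PAIR_ORDER: tuple[str, ...] = ("TP", "AF")

#: The four experimental conditions, in increasing-arousal order.
CONDITIONS: tuple[str, ...] = (
    "baseline",
    "low_arousal",
    "high_arousal",
    "social_anxiety",
)

#: Numeric encoding of conditions used as the regression response.
CONDITION_CODE: dict[str, int] = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open interval [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise InvalidParameterError(
                f"band {self.name!r}: need 0 <= low < high, "
                f"got [{self.low_hz}, {self.high_hz})"
            )


BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 50.0),
}


def _cap(band: str) -> str:
    return band.capitalize()


def fp_name(band: str, channel: str) -> str:
    return f"FP_{_cap(band)}_{channel}"


def dasm_name(band: str, pair: str) -> str:
    return f"DASM_{_cap(band)}_{pair}"


def rasm_name(band: str, pair: str) -> str:
    return f"RASM_{_cap(band)}_{pair}"


def cc_name(band: str, pair: str) -> str:
    return f"CC_{_cap(band)}_{pair}"


def fd_name(channel: str) -> str:
    return f"FD_{channel}"


def feature_names() -> list[str]:
    """The canonical 54-name feature order: 20 FP, 10 DASM, 10 RASM, 10 CC, 4 FD."""
    names = [fp_name(b, ch) for b in BAND_ORDER for ch in CHANNELS]
    names += [dasm_name(b, p) for b in BAND_ORDER for p in PAIR_ORDER]
    names += [rasm_name(b, p) for b in BAND_ORDER for p in PAIR_ORDER]
    names += [cc_name(b, p) for b in BAND_ORDER for p in PAIR_ORDER]
    names += [fd_name(ch) for ch in CHANNELS]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())
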