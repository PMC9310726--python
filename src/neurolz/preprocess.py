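"""Epoching and cleaning of continuous multichannel recordings.

Turns raw electrophysiology (microvolt time series per cortical channel)
into fixed-length, artifact-screened epochs annotated with their
animal / session / condition hierarchy. Default geometry follows the
reference acquisition: 1024 Hz sampling, 5-s epochs of 5120 samples,
0.5-200 Hz analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ConditionLabel",
    "Recording",
    "SignalEpoch",
    "bandpass",
    "segment",
    "reject_artifacts",
]

SLEEP_STATES = ("W", "LS", "SWS", "REM")
DOSES_MG_KG = (0, 5, 10, 15)


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition of an epoch: sleep state or ketamine dose.

    Exactly one of ``state`` / ``dose`` is set. Dose 0 denotes the
    pre-injection baseline; ``stimulated`` flags auditory click stimulation.
    """

    kind: str  # "sleep" | "dose"
    state: str | None = None
    dose: int | None = None
    stimulated: bool = False

    def __post_init__(self) -> None:
        if self.kind == "sleep":
            if self.state not in SLEEP_STATES or self.dose is not None:
                raise ValueError(f"sleep condition needs state in {SLEEP_STATES}")
        elif self.kind == "dose":
            if self.dose not in DOSES_MG_KG or self.state is not None:
                raise ValueError(f"dose condition needs dose in {DOSES_MG_KG}")
        else:
            raise ValueError(f"unknown condition kind {self.kind!r}")

    @property
    def label(self) -> str:
        return self.state if self.kind == "sleep" else str(self.dose)


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel signal with hierarchy annotations.

    ``samples`` has shape (n_channels, n_samples), in microvolts.
    """

    samples: np.ndarray
    fs: float
    channels: tuple[str, ...]
    cat: str
    session: str
    condition: ConditionLabel

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 2:
            raise ValueError("samples must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != x.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique within a recording")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass(frozen=True)
class SignalEpoch:
    """One fixed-length window of one channel's signal."""

    samples: np.ndarray
    fs: float
    channel: str
    condition: ConditionLabel
    cat: str
    session: str
    epoch_index: int

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("epoch samples must be one-dimensional")
        if not np.isfinite(x).all():
            raise ValueError(
                f"non-finite values in epoch {self.epoch_index} "
                f"(cat={self.cat}, session={self.session}, channel={self.channel})"
            )
        object.__setattr__(self, "samples", x)

    @property
    def annotations(self) -> dict[str, Any]:
        c = self.condition
        return {
            "cat": self.cat,
            "session": self.session,
            "channel": self.channel,
            "condition": c.label,
            "state": c.state if c.kind == "sleep" else None,
            "dose": c.dose if c.kind == "dose" else None,
            "stim": c.stimulated,
            "epoch": self.epoch_index,
        }


def bandpass(recording: Recording, lo: float = 0.5, hi: float = 200.0) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    A 4th-order Butterworth is run forward and backward (``sosfiltfilt``)
    so the filter adds no phase distortion that could shift zero crossings
    before binarization. Length is preserved.
    """
    nyq = recording.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(
            f"high edge {hi} Hz >= Nyquist {nyq} Hz for channels "
            f"{list(recording.channels)} at fs={recording.fs} Hz"
        )
    sos = butter(4, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sosfiltfilt(sos, recording.samples, axis=1)
    return replace(recording, samples=filtered)


def segment(recording: Recording, epoch_samples: int = 5120) -> list[SignalEpoch]:
    """Split each channel into consecutive non-overlapping epochs.

    Windows are half-open sample ranges ``[k*T, (k+1)*T)``; a trailing
    remainder shorter than one epoch is dropped, never zero-padded
    (padding would bias the complexity estimate downward). A recording
    shorter than one epoch yields an empty list.
    """
    if epoch_samples < 2:
        raise ValueError("epoch_samples must be >= 2")
    n = recording.samples.shape[1]
    n_epochs = n // epoch_samples
    epochs: list[SignalEpoch] = []
    for ch_i, ch in enumerate(recording.channels):
        for k in range(n_epochs):
            win = recording.samples[ch_i, k * epoch_samples : (k + 1) * epoch_samples]
            epochs.append(
                SignalEpoch(
                    samples=win,
                    fs=recording.fs,
                    channel=ch,
                    condition=recording.condition,
                    cat=recording.cat,
                    session=recording.session,
                    epoch_index=k,
                )
            )
    return epochs


def _mad_scale(x: np.ndarray) -> float:
    """Robust amplitude scale: 1.4826 * median absolute deviation."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def reject_artifacts(
    epochs: list[SignalEpoch], z_max: float = 6.0
) -> tuple[list[SignalEpoch], list[dict[str, Any]]]:
    """Drop epochs with amplitude excursions beyond a robust threshold.

    The original recordings were screened for movement artifacts by eye;
    this deterministic stand-in rejects any epoch whose peak absolute
    amplitude exceeds ``z_max`` times the MAD-based scale of its channel's
    full-session signal (all epochs of the same cat/session/channel pooled,
    after median centering). Returns the surviving epochs in their original
    order and a log describing every epoch's fate.
    """
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    if not epochs:
        return [], []

    groups: dict[tuple[str, str, str], list[SignalEpoch]] = {}
    for ep in epochs:
        groups.setdefault((ep.cat, ep.session, ep.channel), []).append(ep)

    thresholds: dict[tuple[str, str, str], tuple[float, float]] = {}
    for key, eps in groups.items():
        pooled = np.concatenate([ep.samples for ep in eps])
        scale = _mad_scale(pooled)
        center = float(np.median(pooled))
        thresholds[key] = (center, scale)

    kept: list[SignalEpoch] = []
    log: list[dict[str, Any]] = []
    for ep in epochs:
        center, scale = thresholds[(ep.cat, ep.session, ep.channel)]
        peak = float(np.max(np.abs(ep.samples - center)))
        ok = scale == 0.0 or peak <= z_max * scale
        entry = dict(ep.annotations)
        entry.update(
            kept=ok,
            reject_reason="" if ok else f"peak {peak:.3g} > {z_max:g} x scale {scale:.3g}",
        )
        log.append(entry)
        if ok:
            kept.append(ep)
    return kept, log
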