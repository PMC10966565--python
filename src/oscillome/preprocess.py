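"""Deterministic signal conditioning: filtering, epoching, rejection, QC.

The standard chain is high-pass (0.5 Hz cutoff), 50 Hz notch, low-pass
(101.25 Hz cutoff), all linear-phase FIR applied once with the group
delay compensated (zero phase), followed by segmentation into
non-overlapping 2-s epochs
and rejection of any epoch whose absolute amplitude exceeds 100 uV.
Subjects with more than 15% bad channels or more than 50% rejected
epochs fail quality control.

Filter tap counts are specified at fs = 500 Hz (1651-point high-pass
and notch, 75-point low-pass) and rescale proportionally at other
rates.  Bad-channel detection/interpolation and ICA artifact removal
are interactive steps outside this package; QC consumes their counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

REFERENCE_FS = 500.0
HP_TAPS, HP_CUTOFF = 1651, 0.5          # -6 dB at 0.5 Hz
NOTCH_TAPS, NOTCH_EDGES = 1651, (49.5, 50.5)
LP_TAPS, LP_CUTOFF = 75, 101.25         # -6 dB at 101.25 Hz


@dataclass
class Recording:
    """Sensor-space multichannel time series in microvolts."""

    data: np.ndarray            # (n_channels, n_samples), uV
    fs: float
    channel_labels: list[str] | None = None
    channel_positions: np.ndarray | None = None
    subject_id: str = ""
    paradigm: str = "eyes_closed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if np.isnan(self.data).any():
            raise ValueError("Recording contains NaNs")
        if self.fs <= 2 * 90:
            raise ValueError(
                f"fs={self.fs} Hz cannot resolve the 90 Hz analysis ceiling"
            )
        if self.channel_labels is None:
            self.channel_labels = [f"E{i+1}" for i in range(self.data.shape[0])]
        if self.paradigm not in ("eyes_open", "eyes_closed"):
            raise ValueError("paradigm must be eyes_open or eyes_closed")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochedData:
    """Epoch x channel x sample array plus the kept/rejected bookkeeping."""

    epochs: np.ndarray          # (n_epochs, n_channels, n_samples)
    fs: float
    epoch_len: float = 2.0
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    rejection_threshold: float | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        if self.epochs.shape[2] != int(round(self.epoch_len * self.fs)):
            raise ValueError("samples per epoch != epoch_len * fs")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != (self.epochs.shape[0],):
            raise ValueError("kept_mask length != epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def rejected_fraction(self) -> float:
        return 1.0 - self.kept_mask.mean() if self.n_epochs else 0.0

    def kept(self) -> np.ndarray:
        return self.epochs[self.kept_mask]


@dataclass
class SubjectQC:
    """Keep/drop decision from bad-channel and rejected-epoch fractions."""

    bad_channel_fraction: float
    rejected_epoch_fraction: float
    keep: bool


def _scaled_taps(n_ref: int, fs: float) -> int:
    """Rescale a 500-Hz tap count to fs, keeping it odd (type-I FIR)."""
    n = int(round(n_ref * fs / REFERENCE_FS))
    return n if n % 2 else n + 1


def design_standard_filters(fs: float) -> dict[str, np.ndarray]:
    """Hamming-window FIR kernels for the high-pass/notch/low-pass chain.

    Cutoffs are -6 dB points, which for a windowed linear-phase FIR sit
    at the firwin cutoff argument itself.
    """
    hp = signal.firwin(
        _scaled_taps(HP_TAPS, fs), HP_CUTOFF, pass_zero=False, window="hamming", fs=fs
    )
    notch = signal.firwin(
        _scaled_taps(NOTCH_TAPS, fs), NOTCH_EDGES, pass_zero=True, window="hamming", fs=fs
    )
    lp_cut = min(LP_CUTOFF, 0.99 * fs / 2)
    lp = signal.firwin(
        _scaled_taps(LP_TAPS, fs), lp_cut, pass_zero=True, window="hamming", fs=fs
    )
    return {"highpass": hp, "notch": notch, "lowpass": lp}


def apply_standard_filters(rec: Recording) -> Recording:
    """Zero-phase application of the standard chain, in printed order."""
    kernels = design_standard_filters(rec.fs)
    longest = max(len(k) for k in kernels.values())
    if rec.n_samples < 3 * longest:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than 3x the longest "
            f"filter ({longest} taps); edge effects would dominate"
        )
    # Single-pass linear-phase FIR with the group delay compensated by
    # centering ('same' convolution of an odd symmetric kernel): the
    # effective response is zero-phase and the -6 dB points sit at the
    # designed cutoffs (a forward-backward pass would square the
    # response and move them).
    data = rec.data
    for name in ("highpass", "notch", "lowpass"):
        k = kernels[name]
        data = signal.fftconvolve(data, k[None, :], mode="same", axes=-1)
    return Recording(
        data=data,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        channel_positions=rec.channel_positions,
        subject_id=rec.subject_id,
        paradigm=rec.paradigm,
    )


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the grand average (subtract the mean over channels)."""
    return Recording(
        data=rec.data - rec.data.mean(axis=0, keepdims=True),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        channel_positions=rec.channel_positions,
        subject_id=rec.subject_id,
        paradigm=rec.paradigm,
    )


def epoch_signal(rec: Recording, epoch_len: float = 2.0) -> EpochedData:
    """Cut into consecutive non-overlapping epochs; drop the remainder."""
    n_per = int(round(epoch_len * rec.fs))
    if rec.n_samples < n_per:
        raise ValueError(
            f"recording of {rec.duration:.3f}s shorter than epoch_len={epoch_len}s"
        )
    n_epochs = rec.n_samples // n_per
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochedData(epochs=epochs.copy(), fs=rec.fs, epoch_len=epoch_len)


def reject_epochs(ep: EpochedData, threshold: float = 100.0) -> EpochedData:
    """Reject epochs whose max absolute amplitude strictly exceeds threshold (uV)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    peaks = np.abs(ep.epochs).max(axis=(1, 2))
    mask = ep.kept_mask & ~(peaks > threshold)
    return EpochedData(
        epochs=ep.epochs,
        fs=ep.fs,
        epoch_len=ep.epoch_len,
        kept_mask=mask,
        rejection_threshold=threshold,
    )


def subject_qc(
    bad_channel_fraction: float, rejected_epoch_fraction: float
) -> SubjectQC:
    """Keep unless >15% bad channels or >50% rejected epochs (strict >)."""
    for name, frac in (
        ("bad_channel_fraction", bad_channel_fraction),
        ("rejected_epoch_fraction", rejected_epoch_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name}={frac} outside [0, 1]")
    keep = not (bad_channel_fraction > 0.15 or rejected_epoch_fraction > 0.50)
    return SubjectQC(bad_channel_fraction, rejected_epoch_fraction, keep)
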