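"""Scalp-level ERP pipeline: EOG correction, filtering, epoching with
artifact rejection, condition averages, N1 quantification and the paired
condition contrast.

The processing order is fixed: EOG regression -> band-pass filter ->
epoching -> baseline correction -> +-50 uV rejection -> averaging. Epochs
span -100..+400 ms around vocalisation onset; the baseline is the -100..0 ms
pre-stimulus mean; the N1 is the most negative deflection 50-150 ms
post-onset at the vertex channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

EOG_CHANNELS = ("VEOG", "HEOG")
EPOCH_WINDOW_MS = (-100.0, 400.0)
BASELINE_WINDOW_MS = (-100.0, 0.0)
N1_WINDOW_MS = (50.0, 150.0)
REJECT_UV = 50.0

CONDITIONS = ("passive", "cued")


@dataclass
class Recording:
    """Continuous multichannel recording (uV) with condition-labelled events."""

    data: np.ndarray  # channels x samples
    fs: float
    ch_names: list[str]
    events: list[tuple[int, str]]  # (sample index, condition label)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        n = self.data.shape[1]
        for s, label in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} outside recording")
            if label not in CONDITIONS:
                raise ValueError(f"unknown condition label {label!r}")

    @property
    def eeg_picks(self) -> list[int]:
        return [i for i, c in enumerate(self.ch_names) if c not in EOG_CHANNELS]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.ch_names), list(self.events))


@dataclass
class EpochSet:
    """Trial-segmented data with a rejection mask."""

    epochs: np.ndarray  # trials x channels x samples
    times_ms: np.ndarray
    fs: float
    ch_names: list[str]
    labels: list[str]
    rejected: np.ndarray  # bool per trial
    reject_reasons: list[str | None]

    @property
    def surviving(self) -> np.ndarray:
        return ~self.rejected

    def n_surviving(self, condition: str | None = None) -> int:
        keep = self.surviving
        if condition is not None:
            keep = keep & (np.asarray(self.labels) == condition)
        return int(keep.sum())


@dataclass
class ERPWaveform:
    data: np.ndarray  # channels x samples, uV
    times_ms: np.ndarray
    fs: float
    ch_names: list[str]
    condition: str
    n_trials: int


@dataclass(frozen=True)
class N1Measure:
    amplitude: float  # uV (waveform value at the trough)
    latency: float  # ms post-onset, within the search window
    channel: str


@dataclass(frozen=True)
class ContrastResult:
    t: float
    df: int
    p: float
    cohens_d: float
    pairs: pd.DataFrame = field(repr=False)  # per-subject (cued, passive)


def eog_regress(rec: Recording) -> Recording:
    """Subtract the OLS projection of each EEG channel onto [VEOG, HEOG].

    Coefficients are estimated on the whole recording (with an intercept,
    which is not subtracted); EOG channels are passed through unchanged.
    """
    for ch in EOG_CHANNELS:
        if ch not in rec.ch_names:
            raise ValueError(f"missing EOG channel {ch}")
    veog = rec.channel("VEOG")
    heog = rec.channel("HEOG")
    X = np.column_stack([veog, heog, np.ones_like(veog)])
    out = rec.copy()
    picks = rec.eeg_picks
    # one shared least-squares solve for all EEG channels
    beta, *_ = np.linalg.lstsq(X, rec.data[picks].T, rcond=None)
    out.data[picks] = rec.data[picks] - (X[:, :2] @ beta[:2]).T
    return out


def _butter_zero_phase(low: float, high: float, fs: float, order: int = 4):
    """Butterworth HP+LP cascade with corner frequencies pre-warped so the
    two-pass (zero-phase) magnitude is -3 dB at the nominal band edges."""
    # single pass must be -1.5 dB at the edge: shift each corner accordingly
    shift = (np.sqrt(2.0) - 1.0) ** (-1.0 / (2.0 * order))
    sos_hp = signal.butter(order, low / shift, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(order, high * shift, btype="lowpass", fs=fs, output="sos")
    return sos_hp, sos_lp


def bandpass(rec: Recording, low: float = 0.5, high: float = 30.0) -> Recording:
    """Zero-phase 0.5-30 Hz band-pass (forward-backward 4th-order Butterworth)."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError("invalid band for this sampling rate")
    sos_hp, sos_lp = _butter_zero_phase(low, high, rec.fs)
    out = rec.copy()
    x = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
    out.data = np.ascontiguousarray(signal.sosfiltfilt(sos_lp, x, axis=1))
    return out


def rereference(rec: Recording, reference_channels: list[str]) -> Recording:
    """Re-reference EEG channels to the mean of the given channels (e.g.
    mastoids). Optional for synthetic montages that lack mastoid electrodes."""
    idx = [rec.ch_names.index(c) for c in reference_channels]
    ref = rec.data[idx].mean(axis=0)
    out = rec.copy()
    out.data[rec.eeg_picks] -= ref
    return out


def epoch_and_reject(rec: Recording, log: list[str] | None = None) -> EpochSet:
    """Cut -100..+400 ms epochs, baseline-correct, mask +-50 uV artifacts.

    Rejection applies after baseline correction, on EEG channels only.
    Events too close to the recording edge are skipped (logged).
    """
    if not rec.events:
        raise ValueError("no events to epoch around")
    n_len = int(round(0.5 * rec.fs))
    start_off = int(round(EPOCH_WINDOW_MS[0] / 1000.0 * rec.fs))
    times = (np.arange(n_len) + start_off) / rec.fs * 1000.0
    base = (times >= BASELINE_WINDOW_MS[0]) & (times <= BASELINE_WINDOW_MS[1])
    picks = rec.eeg_picks

    epochs, labels, rejected, reasons = [], [], [], []
    for s, label in rec.events:
        i0 = s + start_off
        i1 = i0 + n_len
        if i0 < 0 or i1 > rec.data.shape[1]:
            if log is not None:
                log.append(f"event at sample {s} ({label}): too close to edge, skipped")
            continue
        ep = rec.data[:, i0:i1].copy()
        ep -= ep[:, base].mean(axis=1, keepdims=True)
        peak = float(np.abs(ep[picks]).max())
        bad = peak > REJECT_UV
        epochs.append(ep)
        labels.append(label)
        rejected.append(bad)
        reasons.append(f"amplitude {peak:.1f} uV exceeds +-{REJECT_UV:.0f} uV" if bad else None)

    if not epochs:
        raise ValueError("no epochs could be formed")
    return EpochSet(
        epochs=np.stack(epochs),
        times_ms=times,
        fs=rec.fs,
        ch_names=list(rec.ch_names),
        labels=labels,
        rejected=np.asarray(rejected),
        reject_reasons=reasons,
    )


def average_erp(epochs: EpochSet, condition: str) -> ERPWaveform:
    """Mean over surviving trials of one condition."""
    keep = epochs.surviving & (np.asarray(epochs.labels) == condition)
    n = int(keep.sum())
    if n == 0:
        raise ValueError(f"no surviving trials in condition {condition!r}")
    return ERPWaveform(
        data=epochs.epochs[keep].mean(axis=0),
        times_ms=epochs.times_ms,
        fs=epochs.fs,
        ch_names=list(epochs.ch_names),
        condition=condition,
        n_trials=n,
    )


def n1_peak(erp: ERPWaveform, channel: str = "Cz") -> N1Measure:
    """Most negative deflection 50-150 ms post-onset; ties -> earliest."""
    ci = erp.ch_names.index(channel)
    win = (erp.times_ms >= N1_WINDOW_MS[0]) & (erp.times_ms <= N1_WINDOW_MS[1])
    if not win.any():
        raise ValueError("N1 window not covered by the epoch")
    seg = erp.data[ci, win]
    t_seg = erp.times_ms[win]
    k = int(np.argmin(seg))  # first occurrence = earliest latency on ties
    return N1Measure(amplitude=float(seg[k]), latency=float(t_seg[k]), channel=channel)


def paired_contrast(n1_cued: np.ndarray, n1_passive: np.ndarray) -> ContrastResult:
    """Paired-samples t-test (two-sided) with Cohen's d on cued - passive."""
    cued = np.asarray(n1_cued, dtype=float)
    passive = np.asarray(n1_passive, dtype=float)
    if cued.shape != passive.shape or cued.ndim != 1 or len(cued) < 2:
        raise ValueError("need two equal-length per-subject lists (n >= 2)")
    diff = cued - passive
    sd = diff.std(ddof=1)
    n = len(diff)
    if sd == 0:
        if np.all(diff == 0):  # identical lists: no effect, by convention
            pairs = pd.DataFrame({"cued": cued, "passive": passive, "diff": diff})
            return ContrastResult(t=0.0, df=n - 1, p=1.0, cohens_d=0.0, pairs=pairs)
        raise ValueError("zero variance of differences")
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    pairs = pd.DataFrame({"cued": cued, "passive": passive, "diff": diff})
    return ContrastResult(t=float(t), df=df, p=float(p), cohens_d=float(diff.mean() / sd), pairs=pairs)


def cohort_n1_table(erps: dict[str, dict[str, ERPWaveform]], channel: str = "Cz") -> pd.DataFrame:
    """Long-format N1 table: one row per subject x condition."""
    rows = []
    for subject, by_cond in erps.items():
        for cond, erp in by_cond.items():
            m = n1_peak(erp, channel)
            rows.append(
                {
                    "subject": subject,
                    "condition": cond,
                    "amplitude": m.amplitude,
                    "latency": m.latency,
                    "channel": m.channel,
                }
            )
    return pd.DataFrame(rows)


def preprocess(rec: Recording, log: list[str] | None = None) -> EpochSet:
    """Full fixed-order pipeline from a raw recording to clean epochs."""
    if log is not None:
        log.append("eog_regress")
    rec = eog_regress(rec)
    if log is not None:
        log.append("bandpass 0.5-30 Hz")
    rec = bandpass(rec)
    if log is not None:
        log.append("epoch_and_reject")
    return epoch_and_reject(rec, log=log)


def condition_erps(epochs: EpochSet) -> dict[str, ERPWaveform]:
    return {c: average_erp(epochs, c) for c in CONDITIONS}


def write_erp_csv(erp: ERPWaveform, path: str) -> None:
    df = pd.DataFrame(erp.data.T, columns=erp.ch_names)
    df.insert(0, "time_ms", erp.times_ms)
    df.to_csv(path, index=False)
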