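"""Synthetic study generator: multi-subject two-condition EEG emulating the
cued/passive vocalisation-listening task, plus synthetic log-evidence
matrices for exercising the group-level model selection in isolation.

The cohort generator embeds a known ground truth: by default the fully
recurrent bilateral arcuate model (L3b/L3b, forward+backward modulation)
with backward gains attenuated by exp(-0.4) in the cued condition, so the
cued N1 is reliably smaller than the passive N1 -- the qualitative effect
the scalp pipeline should recover. Each subject jitters the log connection
gains and condition effects; trials are the noiseless subject ERP tiled at
1-3 s intervals into a continuous recording with band-limited noise
(70% white / 30% 1/f power) at a target ERP-to-noise RMS ratio, plus
stereotyped blinks on VEOG that propagate to frontal channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bms import LogEvidenceMatrix
from .erp_analysis import EOG_CHANNELS, EPOCH_WINDOW_MS, Recording
from .model_space import ModelSpec, find_model
from .neural_mass import (
    LeadField,
    NetworkParams,
    StimulusSpec,
    default_network_params,
    make_leadfield,
    resample_to_epoch,
    simulate_erp_pair,
)

DEFAULT_TRUE_B_BACKWARD = -0.4
DEFAULT_TRUE_B_INTRINSIC = -0.2


def default_ground_truth() -> ModelSpec:
    """The generating model: bilateral direct+indirect arcuate pathways with
    forward and backward condition modulation."""
    return find_model("L3b", "L3b", modulation="forward_and_backward")


@dataclass
class CohortSpec:
    n_subjects: int = 20
    trials_per_condition: tuple[int, int] = (75, 125)  # uniform range per subject
    ground_truth_model: ModelSpec = field(default_factory=default_ground_truth)
    true_b_backward: float = DEFAULT_TRUE_B_BACKWARD
    true_b_intrinsic: float = DEFAULT_TRUE_B_INTRINSIC
    snr: float = 0.3  # ERP RMS / single-trial noise RMS
    blink_rate: float = 8.0  # per minute
    subject_sd: float = 0.1  # sd of per-subject log-gain jitter
    b_jitter_sd: float = 0.15  # sd of per-subject jitter on condition gains
    fs: float = 256.0
    iti_s: tuple[float, float] = (1.0, 3.0)
    seed: int = 0
    dt: float = 0.5
    stim: StimulusSpec = field(default_factory=StimulusSpec)
    leadfield: LeadField = field(default_factory=make_leadfield)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        lo, hi = self.trials_per_condition
        if not 1 <= lo <= hi:
            raise ValueError("invalid trials_per_condition range")


@dataclass
class SubjectTruth:
    """Per-subject generating parameters (for recovery analyses)."""

    params: NetworkParams
    b_true: dict[str, float]  # parameter name -> generating log gain
    n_trials: dict[str, int]


@dataclass
class Cohort:
    recordings: list[Recording]
    truths: list[SubjectTruth]
    spec: CohortSpec
    noiseless_erps: list[dict[str, np.ndarray]]  # per subject, epoch-grid ERPs

    def sidecar(self) -> dict:
        s = self.spec
        return {
            "seed": s.seed,
            "n_subjects": s.n_subjects,
            "fs": s.fs,
            "snr": s.snr,
            "blink_rate_per_min": s.blink_rate,
            "subject_sd": s.subject_sd,
            "ground_truth_model_id": s.ground_truth_model.model_id,
            "true_b_backward": s.true_b_backward,
            "true_b_intrinsic": s.true_b_intrinsic,
            "trials_per_condition": list(s.trials_per_condition),
            "stimulus": {
                "onset_ms": s.stim.onset,
                "width_ms": s.stim.width,
                "amplitude": s.stim.amplitude,
            },
            "channels": s.leadfield.ch_names + list(EOG_CHANNELS),
        }


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude-shaped Gaussian noise."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.normal(size=(n_ch, len(freqs))) + 1j * rng.normal(size=(n_ch, len(freqs)))) * shaping
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _blink_waveform(fs: float) -> np.ndarray:
    """Stereotyped ~300 ms blink transient (raised cosine), 180 uV on VEOG."""
    n = int(round(0.3 * fs))
    return 180.0 * np.hanning(n)


def _jittered_params(spec: CohortSpec, rng: np.random.Generator) -> tuple[NetworkParams, dict[str, float]]:
    base = default_network_params(
        spec.ground_truth_model,
        b_backward=spec.true_b_backward,
        b_intrinsic=spec.true_b_intrinsic,
    )
    par = base.copy()
    fwd_mask = par.A_fwd != 0
    bwd_mask = par.A_bwd != 0
    par.A_fwd[fwd_mask] *= np.exp(rng.normal(0, spec.subject_sd, fwd_mask.sum()))
    par.A_bwd[bwd_mask] *= np.exp(rng.normal(0, spec.subject_sd, bwd_mask.sum()))
    b_true: dict[str, float] = {}
    # jitter every condition gain the model modulates (forward gains jitter
    # around 0, backward around the group-level attenuation)
    from .model_space import EdgeKind, modulated_edge_pairs

    for si, ti, kind in modulated_edge_pairs(spec.ground_truth_model):
        if kind is EdgeKind.FORWARD:
            par.B_fwd[ti, si] += rng.normal(0, spec.b_jitter_sd)
            b_true[f"b:fwd:{si}->{ti}"] = float(par.B_fwd[ti, si])
        else:
            par.B_bwd[ti, si] += rng.normal(0, spec.b_jitter_sd)
            b_true[f"b:bwd:{si}->{ti}"] = float(par.B_bwd[ti, si])
    bi_mask = par.B_intrinsic != 0
    par.B_intrinsic[bi_mask] += rng.normal(0, spec.b_jitter_sd, bi_mask.sum())
    for i in np.nonzero(bi_mask)[0]:
        b_true[f"b_int:{i}"] = float(par.B_intrinsic[i])
    return par, b_true


def gen_subject(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[Recording, SubjectTruth, dict[str, np.ndarray]]:
    """One subject: jittered ground truth -> noiseless ERP pair -> trials
    tiled into a continuous noisy recording with events and blinks."""
    par, b_true = _jittered_params(spec, rng)
    erp_passive, erp_cued = simulate_erp_pair(
        spec.ground_truth_model, par, spec.stim, spec.leadfield, dt=spec.dt
    )
    ep_pass, _ = resample_to_epoch(erp_passive, spec.dt, spec.stim, spec.fs, EPOCH_WINDOW_MS)
    ep_cued, t_ep = resample_to_epoch(erp_cued, spec.dt, spec.stim, spec.fs, EPOCH_WINDOW_MS)

    n_pass = int(rng.integers(spec.trials_per_condition[0], spec.trials_per_condition[1] + 1))
    n_cued = int(rng.integers(spec.trials_per_condition[0], spec.trials_per_condition[1] + 1))
    labels = ["passive"] * n_pass + ["cued"] * n_cued
    rng.shuffle(labels)

    fs = spec.fs
    pad = int(round(1.0 * fs))
    itis = rng.uniform(spec.iti_s[0], spec.iti_s[1], size=len(labels))
    onsets = pad + np.cumsum((itis * fs).astype(int))
    n_samp = int(onsets[-1] + pad + int(round(0.5 * fs)))

    n_eeg = len(spec.leadfield.ch_names)
    ch_names = spec.leadfield.ch_names + list(EOG_CHANNELS)
    data = np.zeros((n_eeg + 2, n_samp))

    # tile noiseless single-trial signal at each onset
    epoch_by_cond = {"passive": ep_pass, "cued": ep_cued}
    start_off = int(round(EPOCH_WINDOW_MS[0] / 1000.0 * fs))
    for onset, label in zip(onsets, labels):
        seg = epoch_by_cond[label]
        i0 = onset + start_off
        data[:n_eeg, i0 : i0 + seg.shape[1]] += seg

    # band-limited background noise at the target single-trial SNR
    erp_rms = float(np.sqrt(np.mean(ep_pass**2)))
    noise_rms = erp_rms / spec.snr
    white = rng.normal(size=(n_eeg + 2, n_samp))
    pink = _pink_noise(rng, n_eeg + 2, n_samp, fs)
    data += noise_rms * (np.sqrt(0.7) * white + np.sqrt(0.3) * pink)

    # stereotyped blinks: VEOG transient with scaled frontal propagation
    if spec.blink_rate > 0:
        blink = _blink_waveform(fs)
        n_blinks = rng.poisson(spec.blink_rate * n_samp / fs / 60.0)
        veog_row = n_eeg + list(EOG_CHANNELS).index("VEOG")
        # propagation falls off from the anterior edge of the montage
        from .neural_mass import scalp_montage

        pos, _ = scalp_montage()
        prop = 0.18 * np.clip(pos[:, 1], 0, None) ** 2
        for start in rng.integers(0, n_samp - len(blink), size=n_blinks):
            data[veog_row, start : start + len(blink)] += blink
            data[:n_eeg, start : start + len(blink)] += prop[:, None] * blink[None, :]

    events = [(int(s), label) for s, label in zip(onsets, labels)]
    rec = Recording(data=data, fs=fs, ch_names=ch_names, events=events)
    truth = SubjectTruth(params=par, b_true=b_true, n_trials={"passive": n_pass, "cued": n_cued})
    return rec, truth, {"passive": ep_pass, "cued": ep_cued, "times_ms": t_ep}


def gen_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Fully seed-reproducible synthetic cohort."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    recs, truths, erps = [], [], []
    for _ in range(spec.n_subjects):
        rec, truth, erp = gen_subject(spec, rng)
        recs.append(rec)
        truths.append(truth)
        erps.append(erp)
    return Cohort(recordings=recs, truths=truths, spec=spec, noiseless_erps=erps)


def write_cohort(cohort: Cohort, outdir: str) -> None:
    """Per-subject delimited matrix + events TSV + manifest JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for i, rec in enumerate(cohort.recordings):
        stem = os.path.join(outdir, f"sub-{i + 1:02d}")
        np.savetxt(stem + "_eeg.tsv", rec.data.T, delimiter="\t", fmt="%.4f")
        with open(stem + "_events.tsv", "w") as fh:
            fh.write("sample\tcondition\n")
            for s, label in rec.events:
                fh.write(f"{s}\t{label}\n")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(cohort.sidecar(), fh, indent=2)


def read_recording(eeg_path: str, events_path: str, fs: float, ch_names: list[str]) -> Recording:
    data = np.loadtxt(eeg_path, delimiter="\t").T
    events = []
    with open(events_path) as fh:
        next(fh)
        for line in fh:
            s, label = line.split()
            events.append((int(s), label))
    return Recording(data=data, fs=fs, ch_names=ch_names, events=events)


@dataclass
class EvidenceSpec:
    """Synthetic subjects x models log-evidence matrices for BMS tests."""

    n_subjects: int = 20
    n_models: int = 8
    true_frequencies: np.ndarray | None = None  # default: uniform
    effect: float = 3.0  # nats favouring each subject's generating model
    noise_sd: float = 1.0
    seed: int = 0

    def frequencies(self) -> np.ndarray:
        if self.true_frequencies is None:
            return np.full(self.n_models, 1.0 / self.n_models)
        f = np.asarray(self.true_frequencies, dtype=float)
        if len(f) != self.n_models or not np.isclose(f.sum(), 1.0):
            raise ValueError("true_frequencies must be a length-n_models simplex vector")
        return f

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect must be nonnegative")


def gen_evidence(spec: EvidenceSpec | None = None) -> tuple[LogEvidenceMatrix, np.ndarray]:
    """Sample generating models from the true frequencies; each subject's
    row is iid noise plus `effect` nats on the generating model's column.
    Returns the matrix and the generating-model assignment."""
    spec = spec or EvidenceSpec()
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies()
    gen = rng.choice(spec.n_models, size=spec.n_subjects, p=freqs)
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_subjects, spec.n_models))
    values[np.arange(spec.n_subjects), gen] += spec.effect
    L = LogEvidenceMatrix(
        values,
        [f"sub-{i + 1:02d}" for i in range(spec.n_subjects)],
        list(range(1, spec.n_models + 1)),
    )
    return L, gen
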