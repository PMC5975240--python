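"""Jansen-Rit neural-mass network: the generative model for evoked responses.

Each source is a lumped cortical column of three populations -- pyramidal
output cells, excitatory interneurons and inhibitory interneurons -- coupled
through second-order synaptic kinetics

    v'' = (H/tau) * u  -  (2/tau) * v'  -  v / tau**2

and a zero-centred sigmoidal potential-to-rate conversion. Sources are
coupled by extrinsic forward and backward connections following the
hierarchical convention: forward afferents drive the excitatory-interneuron
population, backward afferents drive the pyramidal and inhibitory
populations. The stimulus (a Gaussian bump standing in for the vocalisation
onset) enters at the A1 nodes.

Condition 2 ("cued") multiplies every modulated extrinsic gain g by
exp(B_edge) and the intrinsic excitatory gain at A1 by exp(B_intrinsic);
condition 1 ("passive") is the baseline with all multipliers at 1.

Integration is a fixed-step explicit 4th-order Runge-Kutta scheme with a
ring-buffer for axonal conduction delays (nearest-sample lookup, delayed
drives frozen over each step). The simulator is batched over parameter
sets so that finite-difference Jacobians cost a single vectorised run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .model_space import (
    EdgeKind,
    ModelSpec,
    Region,
    edges_of,
    modulated_edge_pairs,
    node_index,
    node_table,
)

N_SOURCES = 10


@dataclass(frozen=True)
class JRParams:
    """Jansen-Rit column constants (canonical literature values)."""

    He: float = 3.25  # excitatory synaptic gain, mV
    Hi: float = 22.0  # inhibitory synaptic gain, mV
    tau_e: float = 10.0  # excitatory time constant, ms
    tau_i: float = 20.0  # inhibitory time constant, ms
    gamma: tuple[float, float, float, float] = (135.0, 108.0, 33.75, 33.75)
    e0: float = 2.5  # half of max firing rate, s^-1
    v0: float = 6.0  # sigmoid midpoint, mV
    r: float = 0.56  # sigmoid steepness, mV^-1
    delay_intrinsic: float = 2.0  # ms (intra-columnar; not used dynamically)
    delay_extrinsic: float = 16.0  # ms (inter-areal conduction)
    # afferent targeting weights: backward input reaches pyramidal cells via
    # an amplified excitatory relay and inhibitory interneurons weakly, so
    # recurrent (top-down) coupling is net amplifying at rest -- the regime
    # in which attenuating backward gains attenuates the evoked response
    kappa_bwd_pyr: float = 10.0
    kappa_bwd_inh: float = 0.1

    def __post_init__(self) -> None:
        if min(self.He, self.Hi, self.tau_e, self.tau_i, self.r) <= 0:
            raise ValueError("gains, time constants and r must be positive")


@dataclass
class NetworkParams:
    """Connectivity and modulation parameters for one model instance.

    Gain matrices are (target, source)-indexed over the canonical node
    ordering; nonzero only where the model's edge list permits.
    """

    A_fwd: np.ndarray  # forward extrinsic gains
    A_bwd: np.ndarray  # backward extrinsic gains
    C_in: np.ndarray  # per-node stimulus weights (nonzero at A1)
    B_fwd: np.ndarray  # log condition gains on forward edges
    B_bwd: np.ndarray  # log condition gains on backward edges
    B_intrinsic: np.ndarray  # per-node log intrinsic condition gain (A1 only)
    jr: JRParams = field(default_factory=JRParams)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.A_fwd.copy(), self.A_bwd.copy(), self.C_in.copy(),
            self.B_fwd.copy(), self.B_bwd.copy(), self.B_intrinsic.copy(), self.jr,
        )


@dataclass(frozen=True)
class StimulusSpec:
    """Gaussian input bump; onset is relative to the simulation start."""

    onset: float = 60.0  # ms
    width: float = 16.0  # ms (Gaussian sigma)
    amplitude: float = 60.0  # arbitrary drive units (s^-1 rate equivalents)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("stimulus width must be positive")

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((t_ms - self.onset) / self.width) ** 2)


DEFAULT_FORWARD_GAIN = 24.0
DEFAULT_BACKWARD_GAIN = 8.0
DEFAULT_SMA_GAIN = 8.0
DEFAULT_INPUT_WEIGHT = 1.0


def default_network_params(
    model: ModelSpec,
    forward_gain: float = DEFAULT_FORWARD_GAIN,
    backward_gain: float = DEFAULT_BACKWARD_GAIN,
    b_backward: float = 0.0,
    b_forward: float = 0.0,
    b_intrinsic: float = 0.0,
    jr: JRParams | None = None,
) -> NetworkParams:
    """Populate gain matrices from a model's edge list.

    ``b_backward``/``b_forward`` seed the log condition gains on the
    *modulated* edges of the model (per its modulation scheme); the
    intrinsic A1 gain ``b_intrinsic`` is always free to differ between
    conditions, as every model in the space allows.
    """
    n = N_SOURCES
    A_fwd = np.zeros((n, n))
    A_bwd = np.zeros((n, n))
    C_in = np.zeros(n)
    B_fwd = np.zeros((n, n))
    B_bwd = np.zeros((n, n))
    B_int = np.zeros(n)

    for e in edges_of(model):
        si = node_index(e.source.region, e.source.hemisphere)
        ti = node_index(e.target.region, e.target.hemisphere)
        if e.kind is EdgeKind.FORWARD:
            g = DEFAULT_SMA_GAIN if e.target.region is Region.SMA else forward_gain
            A_fwd[ti, si] = g
        elif e.kind is EdgeKind.BACKWARD:
            g = DEFAULT_SMA_GAIN if e.source.region is Region.SMA else backward_gain
            A_bwd[ti, si] = g
        elif e.kind is EdgeKind.INPUT:
            C_in[ti] = DEFAULT_INPUT_WEIGHT
        elif e.kind is EdgeKind.INTRINSIC_MODULATED:
            B_int[ti] = b_intrinsic

    for si, ti, kind in modulated_edge_pairs(model):
        if kind is EdgeKind.FORWARD:
            B_fwd[ti, si] = b_forward
        else:
            B_bwd[ti, si] = b_backward

    return NetworkParams(A_fwd, A_bwd, C_in, B_fwd, B_bwd, B_int, jr or JRParams())


def sigmoid(v: np.ndarray | float, params: JRParams | None = None) -> np.ndarray | float:
    """Zero-centred logistic rate function: S(0) = 0, saturating at +-2*e0."""
    p = params or JRParams()
    offset = 2.0 * p.e0 * expit(-p.r * p.v0)
    return 2.0 * p.e0 * expit(p.r * (np.asarray(v) - p.v0)) - offset


class IntegrationError(RuntimeError):
    """Raised when the network state becomes non-finite."""


def _simulate_batch(
    A_fwd: np.ndarray,  # (B, n, n) condition-effective forward gains
    A_bwd: np.ndarray,  # (B, n, n)
    C_in: np.ndarray,  # (B, n)
    gamma2_scale: np.ndarray,  # (B, n) intrinsic gain multiplier per node
    jr: JRParams,
    stim: StimulusSpec,
    dt: float,
    T: float,
    raise_on_nonfinite: bool = True,
) -> np.ndarray:
    """Integrate the delayed network ODEs; returns (B, n, n_steps) pyramidal
    potentials (mV) sampled at t = 0, dt, ..., T."""
    Bn, n = C_in.shape
    n_steps = int(round(T / dt)) + 1
    d_ext = max(1, int(round(jr.delay_extrinsic / dt)))

    # integrate in SI units: time constants/steps in s, rates in s^-1
    dt_s = dt * 1e-3
    tau_e, tau_i = jr.tau_e * 1e-3, jr.tau_i * 1e-3
    g1, g2, g3, g4 = jr.gamma
    ke, ki = jr.He / tau_e, jr.Hi / tau_i
    ae, ai = 1.0 / tau_e, 1.0 / tau_i
    two_e0 = 2.0 * jr.e0
    s_off = two_e0 * expit(-jr.r * jr.v0)
    rr, v0 = jr.r, jr.v0
    k_bp, k_bi = jr.kappa_bwd_pyr, jr.kappa_bwd_inh

    def S(v: np.ndarray) -> np.ndarray:
        return two_e0 * expit(rr * (v - v0)) - s_off

    g2_eff = g2 * gamma2_scale

    # states: y0/y1/y2 synaptic potentials and their derivatives, each (B, n)
    y = np.zeros((6, Bn, n))
    vhist = np.zeros((Bn, n, n_steps))  # pyramidal potential history
    out = np.zeros((Bn, n, n_steps))

    t_grid = np.arange(n_steps) * dt  # ms, for the stimulus waveform
    p_of_t = stim.waveform
    half_ms = 0.5 * dt
    half_s = 0.5 * dt_s

    def deriv(y: np.ndarray, u_fwd: np.ndarray, u_bwd: np.ndarray, p_val: float) -> np.ndarray:
        y0, y1, y2, dy0, dy1, dy2 = y
        vp = y1 - y2
        dd = np.empty_like(y)
        dd[0] = dy0
        dd[1] = dy1
        dd[2] = dy2
        dd[3] = ke * S(vp) - 2.0 * ae * dy0 - ae * ae * y0
        dd[4] = (
            ke * (C_in * p_val + g2_eff * S(g1 * y0 + u_fwd) + k_bp * u_bwd)
            - 2.0 * ae * dy1
            - ae * ae * y1
        )
        dd[5] = ki * g4 * S(g3 * y0 + k_bi * u_bwd) - 2.0 * ai * dy2 - ai * ai * y2
        return dd

    zeros = np.zeros((Bn, n))
    for k in range(n_steps - 1):
        t = t_grid[k]
        kd = k - d_ext
        # delayed drives at the start and end of the step (kd + 1 <= k is
        # always in the past since the delay spans >= 1 step); stages use
        # linear interpolation between them
        s0 = S(vhist[:, :, kd]) if kd >= 0 else zeros
        s1 = S(vhist[:, :, kd + 1]) if kd + 1 >= 0 else zeros
        uf0 = np.einsum("bij,bj->bi", A_fwd, s0)
        ub0 = np.einsum("bij,bj->bi", A_bwd, s0)
        uf1 = np.einsum("bij,bj->bi", A_fwd, s1)
        ub1 = np.einsum("bij,bj->bi", A_bwd, s1)
        ufm, ubm = 0.5 * (uf0 + uf1), 0.5 * (ub0 + ub1)

        k1 = deriv(y, uf0, ub0, p_of_t(t))
        k2 = deriv(y + half_s * k1, ufm, ubm, p_of_t(t + half_ms))
        k3 = deriv(y + half_s * k2, ufm, ubm, p_of_t(t + half_ms))
        k4 = deriv(y + dt_s * k3, uf1, ub1, p_of_t(t + dt))
        y = y + (dt_s / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        vp = y[1] - y[2]
        vhist[:, :, k + 1] = vp
        out[:, :, k + 1] = vp

    if raise_on_nonfinite and not np.all(np.isfinite(out)):
        raise IntegrationError(
            "non-finite network state; parameter set is dynamically unstable"
        )
    return out


def condition_gains(
    params: NetworkParams, condition: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Effective (A_fwd, A_bwd, gamma2_scale) for a condition (1 = baseline)."""
    if condition == 1:
        return params.A_fwd, params.A_bwd, np.ones(N_SOURCES)
    if condition == 2:
        return (
            params.A_fwd * np.exp(params.B_fwd),
            params.A_bwd * np.exp(params.B_bwd),
            np.exp(params.B_intrinsic),
        )
    raise ValueError("condition must be 1 (baseline) or 2 (modulated)")


def simulate_sources(
    model: ModelSpec,
    params: NetworkParams,
    stim: StimulusSpec,
    condition: int = 1,
    dt: float = 0.5,
    T: float = 500.0,
) -> np.ndarray:
    """Source dynamics (n_sources x n_samples, mV) for one condition."""
    if dt > 1.0:
        raise ValueError("dt must be <= 1 ms")
    if T < stim.onset + 300.0:
        raise ValueError("T must cover at least 300 ms past stimulus onset")
    A_fwd, A_bwd, g2s = condition_gains(params, condition)
    out = _simulate_batch(
        A_fwd[None], A_bwd[None], params.C_in[None], g2s[None], params.jr, stim, dt, T
    )
    return out[0]


@dataclass
class LeadField:
    """Synthetic channels x sources projection (uV per unit source mV)."""

    gain: np.ndarray
    ch_names: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field must be finite")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("each source needs at least one nonzero channel gain")
        if self.gain.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch")


#: region-wise dipole polarity/strength at the scalp. Temporal generators
#: (A1, W, G) are negative so that the summed auditory response produces the
#: fronto-central N1 negativity; frontal/medial generators weakly positive.
_REGION_POLARITY = {
    Region.A1: -1.0,
    Region.W: -0.8,
    Region.G: -0.5,
    Region.B: 0.5,
    Region.SMA: 0.4,
}


def scalp_montage(n_rows: int = 7, n_cols: int = 9) -> tuple[np.ndarray, list[str]]:
    """Idealised rectangular scalp grid in normalised head coordinates
    (x: left->right, y: posterior->anterior). Odd dimensions place one
    electrode exactly at the vertex; it is named Cz."""
    xs = np.linspace(-0.9, 0.9, n_cols)
    ys = np.linspace(-0.8, 0.8, n_rows)
    pos = np.array([(x, y) for y in ys for x in xs])
    names = [f"E{i + 1:02d}" for i in range(len(pos))]
    d = np.linalg.norm(pos, axis=1)
    names[int(np.argmin(d))] = "Cz"
    return pos, names


def make_leadfield(
    sigma: float = 0.8,
    scale: float = 0.55,
    n_rows: int = 7,
    n_cols: int = 9,
) -> LeadField:
    """Gaussian spatial profiles over the idealised scalp grid.

    Each source projects a smooth bump centred at its (x, y) MNI position
    scaled into head coordinates, signed per region so the auditory sources
    generate a vertex-negative N1.
    """
    pos, names = scalp_montage(n_rows, n_cols)
    nodes = node_table()
    gain = np.zeros((len(pos), len(nodes)))
    for j, node in enumerate(nodes):
        cx, cy = node.mni[0] / 70.0, node.mni[1] / 70.0
        d2 = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2
        gain[:, j] = _REGION_POLARITY[node.region] * scale * np.exp(-d2 / (2.0 * sigma**2))
    return LeadField(gain=gain, ch_names=names)


def project_sensors(
    sources: np.ndarray,
    leadfield: LeadField,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sensor series (channels x samples, uV) = gain @ sources + white noise."""
    if sources.shape[0] != leadfield.gain.shape[1]:
        raise ValueError(
            f"source count mismatch: {sources.shape[0]} vs {leadfield.gain.shape[1]}"
        )
    sensors = leadfield.gain @ sources
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sensors = sensors + rng.normal(0.0, noise_sd, size=sensors.shape)
    return sensors


def simulate_erp_pair(
    model: ModelSpec,
    params: NetworkParams,
    stim: StimulusSpec | None = None,
    leadfield: LeadField | None = None,
    dt: float = 0.5,
    T: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless sensor-level evoked responses for both conditions."""
    stim = stim or StimulusSpec()
    leadfield = leadfield or make_leadfield()
    out = []
    for condition in (1, 2):
        src = simulate_sources(model, params, stim, condition, dt, T)
        out.append(project_sensors(src, leadfield))
    return out[0], out[1]


def erp_time_axis(dt: float, T: float, stim: StimulusSpec) -> np.ndarray:
    """Simulation sample times in ms relative to stimulus onset."""
    return np.arange(int(round(T / dt)) + 1) * dt - stim.onset


def resample_to_epoch(
    sensors: np.ndarray,
    dt: float,
    stim: StimulusSpec,
    fs: float,
    window: tuple[float, float] = (-100.0, 400.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate simulated sensors onto an epoch grid (ms around onset).

    Times before the simulation start are at the resting equilibrium (zero).
    Returns (channels x n_epoch_samples, epoch times in ms).
    """
    n = int(round((window[1] - window[0]) / 1000.0 * fs))
    t_ep = window[0] + np.arange(n) / fs * 1000.0
    t_sim = erp_time_axis(dt, sensors.shape[1] * dt - dt, stim)
    out = np.empty((sensors.shape[0], n))
    for c in range(sensors.shape[0]):
        out[c] = np.interp(t_ep, t_sim, sensors[c], left=0.0, right=sensors[c, -1])
    return out, t_ep
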