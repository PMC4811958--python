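"""Ground-truth networks and synthetic spike trains.

This module makes every estimator and the ROC benchmark testable without
external recordings: it builds random directed networks with a known
synaptic weight matrix (SWM), simulates their spiking dynamics with the
Izhikevich model (forward Euler, one integration step per sample), and
provides homogeneous-Poisson null fixtures plus a three-neuron
common-source motif.

Model summary.  Each neuron follows

    v' = 0.04 v^2 + 5 v + 140 - u + I,      u' = a (b v - u),

with a spike recorded when v >= 30 mV, after which v <- c and u <- u + d.
Excitatory cells use (a, b) = (0.02, 0.2), (c, d) = (-65 + 15 r^2, 8 - 6 r^2);
inhibitory cells use (a, b) = (0.02 + 0.08 r, 0.25 - 0.05 r), (c, d) = (-65, 2),
with r ~ U(0, 1) per neuron.  Spontaneous activity is driven by independent
per-step Gaussian current noise whose amplitude is given at a 1-ms reference
scale (4.5 for excitatory, 2 for inhibitory cells) and converted to the
integration step as sigma/sqrt(dt_ms), so the integrated drive per
millisecond is step-size independent.  A presynaptic spike injects the
synaptic weight as a current pulse of ``pulse_ms`` duration into each of its
targets, starting ``delay_ms`` after the spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import SpikeTrain, write_spike_train

__all__ = [
    "GroundTruthNetwork",
    "SimulationConfig",
    "generate_random_network",
    "simulate_izhikevich",
    "generate_poisson_trains",
    "make_motif_fixture",
    "calibrate_noise",
]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Directed synaptic weight matrix with neuron identities.

    ``swm[i, j]`` is the weight of the connection i -> j (0 = absent); the
    sign of every nonzero entry in row i matches neuron i's excitatory or
    inhibitory identity, and the diagonal is zero (no autapses).
    """

    swm: np.ndarray
    exc_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        swm = np.asarray(self.swm, dtype=np.float64)
        object.__setattr__(self, "swm", swm)
        object.__setattr__(self, "exc_mask", np.asarray(self.exc_mask, dtype=bool))
        if swm.ndim != 2 or swm.shape[0] != swm.shape[1]:
            raise ValueError("swm must be square")
        if np.any(np.diag(swm) != 0):
            raise ValueError("autapses are not allowed (nonzero diagonal)")

    @property
    def n_neurons(self) -> int:
        return self.swm.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.swm))


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation conditions; one integration step per recorded sample."""

    n_neurons: int = 60
    p_conn: float = 0.02
    duration_s: float = 600.0
    fs: float = 10000.0
    exc_frac: float = 0.8
    weight_scale: float = 300.0
    noise_exc: float = 4.5  # current s.d. at the 1-ms reference scale
    noise_inh: float = 2.0
    common_noise: float = 3.0  # shared slow drive, stationary s.d.
    common_tau_ms: float = 50.0  # correlation time of the shared drive
    delay_ms: float = 0.1
    pulse_ms: float = 0.2
    bias: float = 0.0  # constant injected current, for controlled protocols
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_conn <= 1.0:
            raise ValueError("p_conn must lie in [0, 1]")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def generate_random_network(
    n: int,
    p_conn: float,
    exc_frac: float = 0.8,
    weight_scale: float = 300.0,
    seed: int = 0,
) -> GroundTruthNetwork:
    """Erdos-Renyi directed network: each ordered off-diagonal pair is
    connected independently with probability ``p_conn``.

    Excitatory rows carry weights ``weight_scale * U(0.5, 1)``; inhibitory
    rows carry ``-2 * weight_scale * U(0.5, 1)`` (inhibition twice as strong
    on average, as in the reference cortical parameterization).
    """
    if n < 2:
        raise ValueError("a network needs at least 2 neurons")
    if not 0.0 <= p_conn <= 1.0:
        raise ValueError("p_conn must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_exc = int(round(exc_frac * n))
    exc_mask = np.zeros(n, dtype=bool)
    exc_mask[:n_exc] = True
    adj = rng.random((n, n)) < p_conn
    np.fill_diagonal(adj, False)
    mag = weight_scale * rng.uniform(0.5, 1.0, size=(n, n))
    sign = np.where(exc_mask, 1.0, -2.0)[:, None]
    swm = np.where(adj, mag * sign, 0.0)
    return GroundTruthNetwork(
        swm=swm,
        exc_mask=exc_mask,
        meta={"p_conn": p_conn, "exc_frac": exc_frac, "weight_scale": weight_scale, "seed": seed},
    )


def _izhikevich_params(exc_mask: np.ndarray, rng: np.random.Generator):
    n = exc_mask.size
    r = rng.random(n)
    a = np.where(exc_mask, 0.02, 0.02 + 0.08 * r)
    b = np.where(exc_mask, 0.2, 0.25 - 0.05 * r)
    c = np.where(exc_mask, -65.0 + 15.0 * r**2, -65.0)
    d = np.where(exc_mask, 8.0 - 6.0 * r**2, 2.0)
    return a, b, c, d


def _integrate_chunk(v, u, a, b, c, d, w, noise, syn, offset, delay_steps, pulse_steps, dt):
    """Forward-Euler integration of one chunk; returns (fired, new offset).

    ``syn`` is a ring buffer of scheduled synaptic currents, one row per
    future step modulo its length.  The membrane update uses two half-steps
    for v (the published discretization of the model) and one full step for
    u.
    """
    steps = noise.shape[0]
    ring = syn.shape[0]
    fired_out = np.zeros((steps, v.size), dtype=np.bool_)
    for t in range(steps):
        slot = (offset + t) % ring
        fired = v >= 30.0
        if fired.any():
            fired_out[t] = fired
            v[fired] = c[fired]
            u[fired] += d[fired]
            drive = w[fired].sum(axis=0)
            for k in range(delay_steps, delay_steps + pulse_steps):
                syn[(slot + k) % ring] += drive
        current = noise[t] + syn[slot]
        syn[slot] = 0.0
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        u += dt * a * (b * v - u)
    return fired_out, (offset + steps) % ring


try:  # optional acceleration; the numpy path is the reference implementation
    import numba as _numba

    @_numba.njit(cache=False)
    def _integrate_chunk_numba(
        v, u, a, b, c, d, w, noise, syn, offset, delay_steps, pulse_steps, dt
    ):  # pragma: no cover - exercised via equality test when numba is present
        steps = noise.shape[0]
        n = v.size
        ring = syn.shape[0]
        fired_out = np.zeros((steps, n), dtype=np.bool_)
        for t in range(steps):
            slot = (offset + t) % ring
            for i in range(n):
                if v[i] >= 30.0:
                    fired_out[t, i] = True
                    v[i] = c[i]
                    u[i] += d[i]
                    for j in range(n):
                        wij = w[i, j]
                        if wij != 0.0:
                            for k in range(delay_steps, delay_steps + pulse_steps):
                                syn[(slot + k) % ring, j] += wij
            for i in range(n):
                cur = noise[t, i] + syn[slot, i]
                syn[slot, i] = 0.0
                vi = v[i]
                vi += 0.5 * dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + cur)
                vi += 0.5 * dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + cur)
                v[i] = vi
                u[i] += dt * a[i] * (b[i] * v[i] - u[i])
        return fired_out, (offset + steps) % ring

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def simulate_izhikevich(
    net: GroundTruthNetwork,
    cfg: SimulationConfig,
    chunk_steps: int = 100_000,
    use_numba: bool | None = None,
) -> list:
    """Simulate the network and return one SpikeTrain per neuron.

    A spike is recorded at the sample where the membrane potential crosses
    30 mV; the state is then reset.  Fully reproducible under ``cfg.seed``;
    the optional numba kernel and the numpy reference produce identical
    spike trains.
    """
    n = net.n_neurons
    if cfg.n_neurons != n:
        raise ValueError("config n_neurons does not match network size")
    rng = np.random.default_rng(cfg.seed)
    a, b, c, d = _izhikevich_params(net.exc_mask, rng)
    v = np.full(n, -65.0)
    u = b * v
    dt = cfg.dt_ms
    delay_steps = max(1, int(round(cfg.delay_ms / dt)))
    pulse_steps = max(1, int(round(cfg.pulse_ms / dt)))
    ring = delay_steps + pulse_steps
    syn = np.zeros((ring, n))
    sigma = np.where(net.exc_mask, cfg.noise_exc, cfg.noise_inh) / np.sqrt(dt)
    total = cfg.n_samples
    kernel = _integrate_chunk
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba and _HAVE_NUMBA:
        kernel = _integrate_chunk_numba
    offset = 0
    spike_idx = [[] for _ in range(n)]
    w = np.ascontiguousarray(net.swm)
    done = 0
    # shared slow excitability drive: Ornstein-Uhlenbeck process common to
    # all neurons, emulating the culture-wide co-modulation of network
    # activity seen in vitro
    ou_decay = np.exp(-dt / cfg.common_tau_ms) if cfg.common_tau_ms > 0 else 0.0
    ou_kick = cfg.common_noise * np.sqrt(1.0 - ou_decay**2)
    ou_state = 0.0
    # separate stream so results are independent of the chunking
    rng_ou = np.random.default_rng([cfg.seed, 0x5EED])
    while done < total:
        steps = min(chunk_steps, total - done)
        noise = rng.standard_normal((steps, n)) * sigma + cfg.bias
        if cfg.common_noise > 0:
            from scipy.signal import lfilter

            shocks = ou_kick * rng_ou.standard_normal(steps)
            shared, zf = lfilter([1.0], [1.0, -ou_decay], shocks, zi=[ou_decay * ou_state])
            ou_state = shared[-1]
            noise += shared[:, None]
        fired, offset = kernel(
            v, u, a, b, c, d, w, noise, syn, offset, delay_steps, pulse_steps, dt
        )
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
            bad = int(np.flatnonzero(~np.isfinite(v) | ~np.isfinite(u))[0])
            raise FloatingPointError(
                f"non-finite state for neuron {bad} near step {done + steps}"
            )
        rows, cols = np.nonzero(fired)
        for i in range(n):
            sel = rows[cols == i]
            if sel.size:
                spike_idx[i].append(sel + done)
        done += steps
    trains = []
    for i in range(n):
        spikes = np.concatenate(spike_idx[i]) if spike_idx[i] else np.empty(0, dtype=np.int64)
        trains.append(
            SpikeTrain(n_samples=total, spikes=spikes, fs=cfg.fs, label=f"n{i:03d}")
        )
    return trains


def generate_poisson_trains(
    n: int, rate_hz: float, duration_s: float, fs: float, seed: int = 0
) -> list:
    """Independent homogeneous Poisson trains with at most one spike per sample."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    p = rate_hz / fs
    if p >= 1.0:
        raise ValueError(f"rate {rate_hz} Hz saturates the per-sample probability at fs={fs}")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    trains = []
    for i in range(n):
        if p == 0.0:
            spikes = np.empty(0, dtype=np.int64)
        else:
            target = int(p * n_samples * 1.2) + 64
            gaps = rng.geometric(p, size=target)
            idx = np.cumsum(gaps) - 1
            while idx.size and idx[-1] < n_samples:
                gaps = rng.geometric(p, size=target)
                idx = np.concatenate([idx, idx[-1] + np.cumsum(gaps)])
            spikes = idx[idx < n_samples]
        trains.append(
            SpikeTrain(n_samples=n_samples, spikes=spikes, fs=fs, label=f"p{i:03d}")
        )
    return trains


def make_motif_fixture(seed: int = 0, duration_s: float = 60.0, fs: float = 10000.0):
    """Three-neuron common-source motif: true edges 1->2 and 1->3 only.

    Trains 2 and 3 are randomly thinned, jittered and delayed copies of
    train 1 plus independent background spikes, so pairwise methods should
    flag (1,2) and (1,3) but not (2,3) beyond their common-source artifact.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    src = generate_poisson_trains(1, 3.0, duration_s, fs, seed=rng.integers(2**31))[0]

    def follower(delay_samples: int, label: str) -> SpikeTrain:
        keep = rng.random(src.n_spikes) < 0.6
        jitter = rng.integers(-3, 4, size=int(keep.sum()))
        driven = src.spikes[keep] + delay_samples + jitter
        bg = generate_poisson_trains(1, 2.0, duration_s, fs, seed=rng.integers(2**31))[0]
        spikes = np.unique(np.concatenate([driven, bg.spikes]))
        spikes = spikes[(spikes >= 0) & (spikes < n_samples)]
        return SpikeTrain(n_samples=n_samples, spikes=spikes, fs=fs, label=label)

    # equal transmission delays: the relative follower-follower timing is then
    # centred on zero lag, which the directed estimators must not mistake for
    # a connection
    t1 = SpikeTrain(n_samples=n_samples, spikes=src.spikes, fs=fs, label="1")
    t2 = follower(15, "2")  # 1.5 ms transmission delay
    t3 = follower(15, "3")
    swm = np.zeros((3, 3))
    swm[0, 1] = swm[0, 2] = 1.0
    net = GroundTruthNetwork(
        swm=swm, exc_mask=np.array([True, True, True]), meta={"seed": seed, "fixture": "motif"}
    )
    return net, [t1, t2, t3]


def calibrate_noise(
    net: GroundTruthNetwork,
    cfg: SimulationConfig,
    target: tuple = (0.5, 5.0),
    trial_s: float = 10.0,
    max_iter: int = 12,
) -> float:
    """Bisect a global noise multiplier until the population mean firing rate
    lands inside ``target`` spikes/s on a short trial simulation.

    Returns the multiplier to apply to (noise_exc, noise_inh).  At the sparse
    connection probabilities used here the background noise, not the
    recurrent weights, sets the network rate, so the noise amplitude is the
    calibrated quantity.
    """
    lo, hi = 0.25, 8.0

    def mfr(mult: float) -> float:
        trial = replace(
            cfg,
            duration_s=trial_s,
            noise_exc=cfg.noise_exc * mult,
            noise_inh=cfg.noise_inh * mult,
        )
        trains = simulate_izhikevich(net, trial)
        return float(np.mean([t.mfr for t in trains]))

    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        rate = mfr(mid)
        if target[0] <= rate <= target[1]:
            return float(mid)
        if rate < target[0]:
            lo = mid
        else:
            hi = mid
    return float(mid)


def save_simulation(out_dir, net: GroundTruthNetwork, cfg: SimulationConfig, trains) -> Path:
    """Write trains (spike-train text format), the SWM (dense whitespace
    matrix) and the config (key-value lines) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in trains:
        write_spike_train(t, out_dir / f"{t.label}.txt")
    np.savetxt(out_dir / "swm.txt", net.swm, fmt="%.10g")
    with open(out_dir / "config.txt", "w") as fh:
        for key, val in vars(cfg).items():
            fh.write(f"{key} {val}\n")
    return out_dir
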