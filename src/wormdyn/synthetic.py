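"""Synthetic calcium trace generator with known ground truth.

The population generator emulates the statistical structure of whole-head
recordings from immobilized worms: recurrent latent system states visited
in a (noisily) cyclic order through brief low-drive interludes, groups of
neurons driven positively or negatively by those states with per-visit
participation variability, independent per-neuron "private" transients,
slow calcium-indicator kinetics (difference-of-exponentials kernel), white
measurement noise, and intermittent bouts of global quiescence during which
the activity (not the baseline fluorescence) of every neuron is suppressed
through a gradual, slightly jittered envelope. Every stochastic draw flows
from a single seeded generator.

Two documented presets emulate young ("day 1") and senescent ("day 9")
adults qualitatively: the aged preset weakens inhibitory (negative)
loadings, weakens and prolongs and randomizes the system states, speeds up
private single-neuron activity, raises high-frequency noise, and makes
quiescence bouts far more frequent. The preset constants are design
choices for direction, not fits to any measured dataset.

The single-neuron generator plants tanh-shaped ON/OFF transitions with
known time constants for kinetics-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .kinetics import TransitionEvent, TANH_5_95
from .trace import CalciumTraceSet


@dataclass
class PopulationConfig:
    """Knobs of the population generator; defaults are the young-adult
    study conditions (120 neurons, 10 min at 2 Hz)."""

    n_neurons: int = 120
    n_active: int = 40
    duration: float = 600.0          # s
    sampling_rate: float = 2.0       # Hz
    n_states: int = 8
    state_ramp_s: float = 4.0        # s, Gaussian smoothing of state onsets
    state_participation: float = 0.7  # P(an assigned neuron joins a state visit)
    inter_state_gap_s: float = 6.0   # s, mean low-drive interlude between states
    dwell_mean: float = 10.0         # s, mean latent-state dwell
    dwell_shape: float = 4.0         # Gamma shape of dwell times
    transition_stochasticity: float = 0.05  # P(next state not the cycle successor)
    inhibitory_fraction: float = 0.3  # fraction of active neurons with negative loadings
    inhibition_scale: float = 1.0    # scales magnitude of negative loadings
    inhibitory_depth: float = 0.8    # x tonic_level, max suppression below pedestal
    drive_amplitude: float = 2.5     # dF/F0 scale of state loadings
    tonic_level: float = 1.0         # dF/F0 pedestal shared by all neurons
    private_amplitude: float = 0.2   # x drive_amplitude, per-neuron transients
    private_on_s: float = 15.0        # s, mean private-transient duration
    private_off_s: float = 20.0      # s, mean gap between private transients
    background_amplitude: float = 0.15  # x drive_amplitude, non-driven neurons
    bout_jitter_s: float = 2.0       # s, per-neuron quiescence entry/exit jitter
    hf_noise_sd: float = 0.008        # additive white noise, dF/F0
    quiescence_rate: float = 0.02    # bouts per minute (Poisson arrivals)
    quiescence_dwell: float = 30.0   # s, mean bout duration
    quiescence_min_s: float = 10.0   # s, minimum bout duration
    quiescence_max_s: float = 90.0   # s, maximum bout duration
    quiescence_total_max_s: float = 100.0  # s, cap on summed bout time per trial
    quiescence_factor: float = 0.05  # drive multiplier during bouts
    bout_ramp_s: float = 3.0         # s, gradual entry/exit of quiescence
    kernel_rise: float = 1.0         # s
    kernel_decay: float = 4.0        # s
    baseline_f: float = 100.0        # raw fluorescence units
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.n_active <= self.n_neurons):
            raise ValueError("need 0 < n_active <= n_neurons")
        for name in ("duration", "sampling_rate", "dwell_mean", "dwell_shape",
                     "drive_amplitude", "kernel_rise", "kernel_decay",
                     "baseline_f", "quiescence_dwell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("transition_stochasticity", "inhibitory_fraction",
                     "inhibition_scale", "quiescence_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hf_noise_sd < 0 or self.quiescence_rate < 0:
            raise ValueError("noise sd and quiescence rate must be >= 0")
        if self.n_states < 2:
            raise ValueError("need at least 2 latent states")


@dataclass
class SyntheticGroundTruth:
    """Latent structure underlying a generated population trial."""

    state_sequence: np.ndarray               # per-frame state index
    loadings: np.ndarray                     # neurons x states, signed
    quiescence_bouts: list[tuple[int, int]]  # frame intervals [start, end)
    active_neurons: np.ndarray
    inhibitory_neurons: np.ndarray
    noise_sd: float
    planted_transitions: list[TransitionEvent] = field(default_factory=list)

    @property
    def time_in_quiescence(self) -> float:
        n = self.state_sequence.size
        covered = sum(e - s for s, e in self.quiescence_bouts)
        return covered / n if n else 0.0


def _calcium_kernel(rise: float, decay: float, dt: float) -> np.ndarray:
    t = np.arange(0.0, 6.0 * decay, dt)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    s = k.sum()
    return k / s if s > 0 else k


def _state_sequence(cfg: PopulationConfig, rng: np.random.Generator
                    ) -> np.ndarray:
    """Semi-Markov state sequence; -1 marks the low-drive interludes that
    separate consecutive state visits (transitions pass through a brief
    quiet intermediate rather than jumping group-to-group)."""
    n_frames = int(round(cfg.duration * cfg.sampling_rate))
    seq = np.empty(n_frames, dtype=int)
    state = int(rng.integers(cfg.n_states))
    frame = 0
    scale = cfg.dwell_mean / cfg.dwell_shape
    while frame < n_frames:
        dwell_s = rng.gamma(cfg.dwell_shape, scale)
        dwell = max(1, int(round(dwell_s * cfg.sampling_rate)))
        seq[frame:frame + dwell] = state
        frame += dwell
        if cfg.inter_state_gap_s > 0 and frame < n_frames:
            gap_s = rng.gamma(cfg.dwell_shape,
                              cfg.inter_state_gap_s / cfg.dwell_shape)
            gap = max(1, int(round(gap_s * cfg.sampling_rate)))
            seq[frame:frame + gap] = -1
            frame += gap
        if rng.random() < cfg.transition_stochasticity:
            others = [s for s in range(cfg.n_states) if s != state]
            state = int(rng.choice(others))
        else:
            state = (state + 1) % cfg.n_states
    return seq


def _quiescence_bouts(cfg: PopulationConfig, rng: np.random.Generator,
                      n_frames: int) -> list[tuple[int, int]]:
    if cfg.quiescence_rate <= 0:
        return []
    fs = cfg.sampling_rate
    rate_per_s = cfg.quiescence_rate / 60.0
    bouts: list[tuple[int, int]] = []
    total = 0.0
    t = rng.exponential(1.0 / rate_per_s)
    while t < cfg.duration:
        extra = max(cfg.quiescence_dwell - cfg.quiescence_min_s, 1e-6)
        dur = min(cfg.quiescence_min_s + rng.exponential(extra),
                  cfg.quiescence_max_s)
        if total + dur > cfg.quiescence_total_max_s:
            break
        total += dur
        start = int(round(t * fs))
        end = min(n_frames, start + max(1, int(round(dur * fs))))
        if start < n_frames:
            if bouts and start <= bouts[-1][1]:
                bouts[-1] = (bouts[-1][0], max(bouts[-1][1], end))
            else:
                bouts.append((start, end))
        t += dur + rng.exponential(1.0 / rate_per_s)
    return bouts


def generate_population(config: PopulationConfig
                        ) -> tuple[CalciumTraceSet, SyntheticGroundTruth]:
    """Generate one population trial plus its ground truth.

    Neuron drive is ``tonic_level + loadings[neuron, state(t)]``; quiescence
    bouts multiply the whole drive by ``quiescence_factor``; the result is
    convolved with a unit-area difference-of-exponentials calcium kernel,
    white noise is added, and the trace is emitted as raw fluorescence
    ``baseline_f * (1 + dff)``. Bit-identical for identical configs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    dt = 1.0 / fs
    n_frames = int(round(config.duration * fs))

    seq = _state_sequence(config, rng)
    bouts = _quiescence_bouts(config, rng, n_frames)

    active = np.sort(rng.choice(config.n_neurons, size=config.n_active,
                                replace=False))
    loadings = np.zeros((config.n_neurons, config.n_states))
    primary_state = np.full(config.n_neurons, -1, dtype=int)
    inhibitory: list[int] = []
    per_state: dict[int, list[int]] = {s: [] for s in range(config.n_states)}
    for j, neuron in enumerate(active):
        per_state[j % config.n_states].append(int(neuron))
    for s, members in per_state.items():
        n_inh = int(round(config.inhibitory_fraction * len(members)))
        for rank, neuron in enumerate(members):
            het = 1.0 + 0.2 * rng.uniform(-1, 1)
            primary_state[neuron] = s
            if rank < n_inh:
                # suppression is bounded by the tonic pedestal: fluorescence
                # cannot fall below zero no matter how strong the drive
                depth = config.inhibitory_depth * config.tonic_level
                loadings[neuron, s] = -depth * het * config.inhibition_scale
                inhibitory.append(neuron)
            else:
                loadings[neuron, s] = config.drive_amplitude * het

    # private (idiosyncratic) transients: every active neuron also fires its
    # own ON/OFF transient train, independent of the system state. This is
    # what real head-region neurons do on top of the shared state dynamics,
    # and it keeps purely structural cross-state correlations moderate so
    # that the strong anti-correlations are the planted opposite-sign pairs.
    # state-visit runs, for per-neuron participation masking
    change = np.nonzero(np.diff(seq))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n_frames]])
    runs_by_state: dict[int, list[tuple[int, int]]] = \
        {s: [] for s in range(config.n_states)}
    for s0, e0 in zip(starts, ends):
        if seq[s0] >= 0:
            runs_by_state[int(seq[s0])].append((int(s0), int(e0)))

    sigma = config.state_ramp_s * fs

    drive = np.full((config.n_neurons, n_frames), config.tonic_level)
    for neuron in active:
        s = int(primary_state[neuron])
        ind = np.zeros(n_frames)
        for r0, r1 in runs_by_state[s]:
            # neurons do not join every visit of their state; participation
            # variability keeps pairwise correlations away from +/-1
            if (config.state_participation >= 1.0
                    or rng.random() < config.state_participation):
                ind[r0:r1] = 1.0
        if sigma > 0:
            ind = gaussian_filter1d(ind, sigma, mode="nearest")
        drive[neuron] += loadings[neuron, s] * ind
    active_set = set(int(n) for n in active)
    for neuron in range(config.n_neurons):
        factor = (config.private_amplitude if neuron in active_set
                  else config.background_amplitude)
        if factor <= 0:
            continue
        amp = (factor * config.drive_amplitude
               * (1.0 + 0.2 * rng.uniform(-1, 1)))
        on = rng.random() < (config.private_on_s
                             / (config.private_on_s + config.private_off_s))
        frame = 0
        while frame < n_frames:
            dwell_s = rng.exponential(config.private_on_s if on
                                      else config.private_off_s)
            dwell = max(1, int(round(dwell_s * fs)))
            if on:
                drive[neuron, frame:frame + dwell] += amp
            frame += dwell
            on = not on
    # quiescence bouts suppress the *activity* component of the drive (the
    # tonic fluorescence pedestal persists: sleep stops transients, it does
    # not dim the indicator) through a per-neuron envelope with gradual
    # (ramped) entry and exit plus small timing jitter: animals fall into
    # and out of quiescence near-concertedly but not frame-locked, and an
    # instantaneous frame-locked collapse would plant spurious positive
    # derivative correlations across every neuron pair
    if bouts:
        jit = config.bout_jitter_s
        ramp_sigma = config.bout_ramp_s * fs
        envelope = np.ones((config.n_neurons, n_frames))
        offs = np.round(rng.uniform(-jit, jit,
                                    size=(config.n_neurons, len(bouts), 2))
                        * fs).astype(int) if jit > 0 else \
            np.zeros((config.n_neurons, len(bouts), 2), dtype=int)
        for b, (start, end) in enumerate(bouts):
            for neuron in range(config.n_neurons):
                s = max(0, start + offs[neuron, b, 0])
                e = min(n_frames, max(s + 1, end + offs[neuron, b, 1]))
                envelope[neuron, s:e] = config.quiescence_factor
        if ramp_sigma > 0:
            envelope = gaussian_filter1d(envelope, ramp_sigma, axis=1,
                                         mode="nearest")
        drive = config.tonic_level + (drive - config.tonic_level) * envelope

    kernel = _calcium_kernel(config.kernel_rise, config.kernel_decay, dt)
    pad = kernel.size - 1
    padded = np.concatenate([np.repeat(drive[:, :1], pad, axis=1), drive],
                            axis=1)
    dff = np.empty_like(drive)
    for i in range(config.n_neurons):
        dff[i] = np.convolve(padded[i], kernel, mode="valid")
    dff += rng.normal(0.0, config.hf_noise_sd, size=dff.shape)

    values = np.maximum(config.baseline_f * (1.0 + dff), 0.0)
    traces = CalciumTraceSet(values=values, sampling_rate=fs,
                             trial_id=f"synthetic-{config.seed}",
                             condition="synthetic")
    truth = SyntheticGroundTruth(state_sequence=seq, loadings=loadings,
                                 quiescence_bouts=bouts,
                                 active_neurons=active,
                                 inhibitory_neurons=np.array(sorted(inhibitory),
                                                             dtype=int),
                                 noise_sd=config.hf_noise_sd)
    return traces, truth


#: Documented preset constants. Directions (not magnitudes) follow the aged
#: phenotype: weaker inhibition, longer and noisier state dwells, more
#: high-frequency noise, much more frequent quiescence. The quiescence
#: rate/dwell pairs put the expected time in global quiescence near 1%
#: (young) and 9% (aged) of a 10-min trial.
_PRESETS = {
    1: dict(dwell_mean=10.0, transition_stochasticity=0.05,
            state_ramp_s=4.0, inter_state_gap_s=6.0,
            state_participation=0.7,
            inhibition_scale=1.0, hf_noise_sd=0.008,
            drive_amplitude=2.5, private_amplitude=0.2,
            background_amplitude=0.15,
            private_on_s=20.0, private_off_s=28.0,
            quiescence_rate=0.015, quiescence_dwell=15.0,
            quiescence_max_s=25.0),
    9: dict(dwell_mean=24.0, transition_stochasticity=0.45,
            state_ramp_s=1.0, inter_state_gap_s=6.0,
            state_participation=0.7,
            inhibition_scale=0.15, hf_noise_sd=0.04,
            drive_amplitude=1.2, private_amplitude=1.0,
            background_amplitude=0.7,
            private_on_s=2.0, private_off_s=3.0,
            quiescence_rate=0.75, quiescence_dwell=24.0,
            quiescence_min_s=12.0, quiescence_max_s=45.0,
            bout_ramp_s=4.0),
}


def age_preset(day: int, seed: int = 0) -> PopulationConfig:
    """Return the documented young (day 1) or aged (day 9) configuration."""
    if day not in _PRESETS:
        raise ValueError(f"unknown preset day {day}; available: 1, 9")
    return PopulationConfig(seed=seed, **_PRESETS[day])


def generate_ava_trace(n_bouts: int = 5, tau_on: float = 1.0,
                       tau_off: float = 1.0, bout_dwell: float = 40.0,
                       inter_bout: float = 60.0, noise_sd: float = 0.0,
                       sampling_rate: float = 4.0, duration: float = 600.0,
                       amplitude: float = 1.0, baseline: float = 0.1,
                       seed: int = 0
                       ) -> tuple[np.ndarray, list[TransitionEvent]]:
    """Bistable single-neuron dF/F0 trace with planted tanh transitions.

    Bouts are laid out regularly (``inter_bout`` between offset and the next
    onset) with small seeded jitter; each bout contributes
    ``amplitude * h_on(t) * h_off(t)`` where the two tanh half-steps use the
    planted (t0, tau). Returns the trace and the ground-truth transition
    events (onset frames at the 5%/95% crossings of the planted curves).
    Raises ValueError if the requested bouts do not fit in ``duration``.
    """
    rng = np.random.default_rng(seed)
    period = bout_dwell + inter_bout
    if n_bouts * period > duration + 1e-9:
        raise ValueError("bouts do not fit within the trace duration")
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, duration, dt)
    trace = np.full_like(t, baseline)
    truth: list[TransitionEvent] = []
    guard = 4.0 * max(tau_on, tau_off)
    for b in range(n_bouts):
        jitter = rng.uniform(-0.05, 0.05) * inter_bout
        t_on = inter_bout / 2.0 + b * period + jitter
        t_off = t_on + bout_dwell
        if t_off + guard > duration:
            raise ValueError("bout overlaps the end of the trace")
        h_on = 0.5 * (1.0 + np.tanh((t - t_on) / tau_on))
        h_off = 0.5 * (1.0 - np.tanh((t - t_off) / tau_off))
        trace += amplitude * h_on * h_off
        for direction, t0, tau in (("on", t_on, tau_on),
                                   ("off", t_off, tau_off)):
            t_start = t0 - tau * math.atanh(0.9)
            truth.append(TransitionEvent(
                direction=direction, t0=t0, tau=tau, baseline=baseline,
                amplitude=amplitude,
                onset_frame=int(np.ceil(t_start * sampling_rate)),
                transition_time=TANH_5_95 * tau, fit_rmse=0.0))
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=trace.size)
    return trace, truth
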