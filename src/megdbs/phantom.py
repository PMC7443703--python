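"""Synthetic DBS-MEG phantom simulator.

Generates multichannel magnetometer recordings with the statistical structure
of a dry-phantom DBS experiment: a calibrated sinusoidal current dipole at
12 Hz inside a conducting sphere, a biphasic 130 Hz stimulation pulse train
that is under-sampled by the acquisition chain (producing aliased spectral
peaks), a movement-modulated wire-magnetisation artefact concentrated on
posterior sensors, line-noise sinusoids at 50 Hz and harmonics, and white
sensor noise.

Four linked conditions are produced from shared noise streams:

``empty_room``   sensor + line noise only
``reference``    empty room + dipole
``dmw``          reference + movement/wire artefact
``dsmw``         dmw + stimulation artefact (movement-coupled)

so that the decomposition ``dsmw = reference + wire term + stim term`` holds
exactly, sample for sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import signal

from .core import Recording, SensorArray
from .forward import dipole_field, magnetic_dipole_field


@dataclass
class SimConfig:
    """Parameters of the synthetic phantom session.

    The acquisition chain mirrors a high-rate MEG acquisition: pulses are
    rendered at ``fs_internal``, low-pass filtered with a 4th-order filter at
    ``0.4 * fs_intermediate``, decimated to ``fs_intermediate`` and then
    polyphase-decimated to ``fs_out``.  Because the pulse train has strong
    harmonics far above the filter cutoff, the first decimation folds pulse
    energy into the acquisition band, producing aliased peaks that are not
    multiples of the stimulation frequency.
    """

    f_dipole: float = 12.0           # Hz
    f_stim: float = 130.0            # Hz
    pulse_width: float = 140e-6      # s (per phase of the biphasic pulse)
    move_period: float = 2.5         # s between movement events
    move_rise: float = 0.040         # s inflation time
    move_decay: float = 0.75         # s nominal deflation time
    move_decay_jitter: tuple = (0.5, 1.0)  # uniform range of deflation times
    move_amplitude: float = 3e-3     # m peak vertical displacement
    duration: float = 120.0          # s
    fs_internal: float = 192000.0    # Hz pulse-rendering rate
    fs_intermediate: float = 19200.0  # Hz acquisition rate
    fs_out: float = 2400.0           # Hz analysis rate
    target_log_ratio: float = 1.75   # log10 DBS-peak / dipole-peak power
    line_freq: float = 50.0          # Hz
    line_max_harmonic: float = 550.0  # Hz
    sensor_noise_sd: float = 3e-15   # T/sqrt(Hz) white noise density
    seed: int = 0

    # geometry
    n_channels: int = 128
    helmet_radius: float = 0.12      # m
    sphere_radius: float = 0.075     # m
    dipole_depth_frac: float = 0.6   # dipole at this fraction of sphere radius
    dipole_moment_amp: float = 50e-9  # A*m
    dipole_detune_ppm: float = 100.0  # relative clock offset of the dipole generator

    # artefact sources
    electrode_pos: tuple = (0.015, -0.010, 0.040)  # m, DBS electrode contact
    stim_wire_fraction: float = 0.5  # share of stim sensor RMS radiated by the lead wires
    stim_gain: float | None = None   # T (RMS at sensors); None -> calibrate
    wire_gain: float = 1.1e-13       # T scale of the movement/wire artefact
    move_coupling_scale: float | None = None  # m; None -> move_amplitude
    line_amp: float = 2e-13          # T per line-noise harmonic
    dipole_leak: float = 0.05        # dipole leakage into the DBS reference channel

    def __post_init__(self):
        if self.fs_internal % self.fs_intermediate:
            raise ValueError("fs_internal must be an integer multiple of fs_intermediate")
        if self.fs_intermediate % self.fs_out:
            raise ValueError("fs_intermediate must be an integer multiple of fs_out")
        if self.pulse_width >= 0.5 / self.f_stim:
            raise ValueError("pulse_width must be shorter than half a stimulation period")
        if abs(self.fs_out / self.f_stim - round(self.fs_out / self.f_stim)) < 1e-9:
            warnings.warn(
                "stimulation period is an integer number of output samples; "
                "pulses will be sampled consistently and aliasing structure is lost"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs_out))

    @property
    def coupling_scale(self) -> float:
        return self.move_amplitude if self.move_coupling_scale is None else self.move_coupling_scale

    def to_dict(self) -> dict:
        d = asdict(self)
        d["move_decay_jitter"] = list(self.move_decay_jitter)
        d["electrode_pos"] = list(self.electrode_pos)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "move_decay_jitter" in d:
            d["move_decay_jitter"] = tuple(d["move_decay_jitter"])
        if "electrode_pos" in d:
            d["electrode_pos"] = tuple(d["electrode_pos"])
        return cls(**d)


@dataclass
class ConditionSet:
    """The four linked phantom recordings plus the DBS reference channel."""

    reference: Recording
    dmw: Recording
    dsmw: Recording
    empty_room: Recording
    dbs_reference_channel: np.ndarray
    config: SimConfig

    def __post_init__(self):
        recs = [self.reference, self.dmw, self.dsmw, self.empty_room]
        n = {r.n_samples for r in recs}
        fs = {r.fs for r in recs}
        if len(n) != 1 or len(fs) != 1:
            raise ValueError("conditions differ in length or sampling rate")
        if self.dbs_reference_channel.shape != (self.dsmw.n_samples,):
            raise ValueError("dbs_reference_channel must align with the recordings")

    @property
    def sensors(self) -> SensorArray:
        return self.reference.sensors

    @property
    def fs(self) -> float:
        return self.reference.fs


# ---------------------------------------------------------------------------
# geometry

def make_sensor_array(n_channels: int, helmet_radius: float = 0.12, seed: int = 0,
                      sphere_radius: float = 0.075,
                      tilt_sd: float = 0.15) -> SensorArray:
    """Quasi-uniform, nominally radial magnetometers on the upper ~60% of a
    sphere.

    Sensors are laid out on a golden-angle spiral over the spherical cap
    covering 60% of the full sphere area, with a small seeded jitter so that
    different seeds give slightly different (but reproducible) arrays.

    Orientations are radial up to a seeded mounting tilt of ``tilt_sd``
    radians (~8 degrees by default).  The tilt matters: for exactly radial
    sensors at a single radius the interior and exterior multipole fields
    have identical angular profiles, so the inner/outer separation used by
    signal space separation would be singular; the tangential sensitivity
    introduced by the tilt (present in any real helmet) makes the two
    expansions distinguishable.
    """
    if n_channels < 32:
        raise ValueError("need at least 32 channels (the order-8 interior "
                         "multipole basis would be underdetermined)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA55A]))
    frac = 0.6  # fraction of sphere area covered by the cap (from the top)
    i = np.arange(n_channels)
    z = 1.0 - (i + 0.5) * (2.0 * frac / n_channels)
    z = z + rng.uniform(-0.2, 0.2, n_channels) * (frac / n_channels)
    z = np.clip(z, -0.999, 0.999)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden + rng.uniform(0, 2 * np.pi)
    s = np.sqrt(1.0 - z**2)
    u = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    positions = helmet_radius * u
    tangential = rng.standard_normal((n_channels, 3))
    tangential -= np.sum(tangential * u, axis=1, keepdims=True) * u
    tangential /= np.linalg.norm(tangential, axis=1, keepdims=True)
    ori = u + tilt_sd * np.abs(rng.standard_normal((n_channels, 1))) * tangential
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    names = tuple(f"MEG{k:04d}" for k in range(n_channels))
    return SensorArray(positions=positions, orientations=ori, names=names,
                       sphere_center=np.zeros(3), sphere_radius=sphere_radius)


def _dipole_position(config: SimConfig) -> np.ndarray:
    return np.array([config.dipole_depth_frac * config.sphere_radius, 0.0, 0.0])


def _dipole_moment(config: SimConfig) -> np.ndarray:
    # tangential moment (along y) so the source is not magnetically silent
    return np.array([0.0, config.dipole_moment_amp, 0.0])


def _wire_dipoles(config: SimConfig, rng: np.random.Generator):
    """Magnetisation dipoles along the posterior wire path on the phantom surface."""
    n_wire = 3
    r_wire = config.sphere_radius * 1.04  # taped to the surface
    theta = rng.uniform(0.25 * np.pi, 0.45 * np.pi, n_wire)   # polar angle
    phi = -0.5 * np.pi + rng.uniform(-0.35, 0.35, n_wire)     # posterior (-y)
    pos = r_wire * np.column_stack([
        np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)
    ])
    mom = rng.standard_normal((n_wire, 3))
    mom /= np.linalg.norm(mom, axis=1, keepdims=True)
    return pos, mom


def _unit_rms(topo: np.ndarray) -> np.ndarray:
    return topo / np.sqrt(np.mean(topo**2))


# ---------------------------------------------------------------------------
# waveforms

def simulate_dbs_train(config: SimConfig) -> np.ndarray:
    """Biphasic rectangular pulse train at ``fs_internal`` (arbitrary units).

    Each stimulation period starts with a positive phase of ``pulse_width``
    followed immediately by an equal negative phase, so every pulse is
    charge-balanced (zero integral).
    """
    n = int(round(config.duration * config.fs_internal))
    t = np.arange(n) / config.fs_internal
    phase = np.mod(t, 1.0 / config.f_stim)
    out = np.zeros(n)
    out[phase < config.pulse_width] = 1.0
    out[(phase >= config.pulse_width) & (phase < 2 * config.pulse_width)] = -1.0
    return out


def simulate_movement_waveform(config: SimConfig, rng=None) -> np.ndarray:
    """Vertical displacement waveform (metres) at ``fs_out``.

    Every ``move_period`` seconds the phantom rises over ``move_rise`` with a
    raised-cosine ramp to ``move_amplitude`` and falls back with a
    raised-cosine decay whose duration is drawn uniformly from
    ``move_decay_jitter`` (seeded).  The spectrum is concentrated below 5 Hz.
    """
    if config.duration < config.move_period:
        raise ValueError("duration must cover at least one movement period")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x30FE]))
    fs = config.fs_out
    n = config.n_samples
    disp = np.zeros(n)
    n_events = int(np.floor(config.duration / config.move_period))
    lo, hi = config.move_decay_jitter
    for k in range(n_events):
        t_on = k * config.move_period
        decay = rng.uniform(lo, hi)
        i0 = int(round(t_on * fs))
        n_rise = max(int(round(config.move_rise * fs)), 2)
        n_fall = max(int(round(decay * fs)), 2)
        rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / n_rise))
        fall = 0.5 * (1 + np.cos(np.pi * np.arange(n_fall + 1) / n_fall))
        pulse = config.move_amplitude * np.concatenate([rise, fall])
        i1 = min(i0 + pulse.size, n)
        disp[i0:i1] += pulse[: i1 - i0]
    return disp


def _decimate_stim(train: np.ndarray, config: SimConfig) -> np.ndarray:
    """Acquisition chain: 4th-order low-pass, decimate to fs_intermediate,
    then polyphase decimation to fs_out."""
    q1 = int(round(config.fs_internal / config.fs_intermediate))
    sos = signal.butter(4, 0.4 * config.fs_intermediate,
                        fs=config.fs_internal, output="sos")
    x = signal.sosfilt(sos, train)[::q1]
    q2 = int(round(config.fs_intermediate / config.fs_out))
    x = signal.resample_poly(x, 1, q2)
    n = config.n_samples
    if x.size < n:
        x = np.pad(x, (0, n - x.size))
    return x[:n]


# ---------------------------------------------------------------------------
# component assembly

class _Components:
    """All seeded source terms for one session, in factored form."""

    def __init__(self, config: SimConfig, sensors: SensorArray | None = None):
        self.config = config
        if sensors is None:
            sensors = make_sensor_array(config.n_channels, config.helmet_radius,
                                        seed=config.seed,
                                        sphere_radius=config.sphere_radius)
        self.sensors = sensors
        n = config.n_samples
        t = np.arange(n) / config.fs_out
        ss = np.random.SeedSequence([int(config.seed), 0xC0DE])
        s_noise, s_line, s_move, s_wire, s_stimwire = ss.spawn(5)

        # dipole; its generator runs on its own clock, so its frequency is
        # never exactly commensurate with the stimulation frequency (with
        # exactly commensurate deterministic signals, mutual information
        # between dipole and stimulation would be spuriously high)
        rng_d = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xD1B0]))
        detune = 1.0 + config.dipole_detune_ppm * 1e-6 * rng_d.uniform(0.5, 1.0)
        self.f_dipole_actual = config.f_dipole * detune
        self.dipole_topo = dipole_field(_dipole_position(config),
                                        _dipole_moment(config), sensors)
        self.dipole_wave = np.sin(2 * np.pi * self.f_dipole_actual * t)

        # movement displacement and wire topography
        self.disp = simulate_movement_waveform(
            config, rng=np.random.default_rng(s_move))
        rng_w = np.random.default_rng(s_wire)
        wpos, wmom = _wire_dipoles(config, rng_w)
        wb = magnetic_dipole_field(wpos, wmom, sensors.positions)
        self.wire_topo = _unit_rms(np.sum(wb * sensors.orientations, axis=-1))
        self.wire_wave = config.wire_gain * self.disp / config.move_amplitude

        # stimulation: deep electrode dipole + field radiated by the lead wires
        elec = _unit_rms(dipole_field(np.asarray(config.electrode_pos),
                                      np.array([0.0, 0.0, 1.0]), sensors))
        rng_sw = np.random.default_rng(s_stimwire)
        swmom = rng_sw.standard_normal((wpos.shape[0], 3))
        swmom /= np.linalg.norm(swmom, axis=1, keepdims=True)
        swb = magnetic_dipole_field(wpos, swmom, sensors.positions)
        lead = _unit_rms(np.sum(swb * sensors.orientations, axis=-1))
        wf = config.stim_wire_fraction
        self.stim_topo = _unit_rms((1 - wf) * elec + wf * lead)
        stim_raw = _decimate_stim(simulate_dbs_train(config), config)
        self.stim_wave_plain = stim_raw / np.sqrt(np.mean(stim_raw**2))
        self.stim_wave_coupled = self.stim_wave_plain * (
            1.0 + self.disp / config.coupling_scale)

        # noise and line interference
        rng_n = np.random.default_rng(s_noise)
        sd = config.sensor_noise_sd * np.sqrt(config.fs_out / 2.0)
        self.noise = sd * rng_n.standard_normal((sensors.n_channels, n))
        rng_l = np.random.default_rng(s_line)
        nyq = config.fs_out / 2.0
        freqs = np.arange(config.line_freq,
                          min(config.line_max_harmonic, nyq - 1) + 1e-9,
                          config.line_freq)
        line_topos = rng_l.standard_normal((sensors.n_channels, freqs.size))
        line_topos /= np.sqrt(np.mean(line_topos**2, axis=0))
        phases = rng_l.uniform(0, 2 * np.pi, freqs.size)
        sines = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        self.line = config.line_amp * (line_topos @ sines)

    def assemble(self, include: set, stim_gain: float) -> np.ndarray:
        data = self.noise + self.line
        if "dipole" in include:
            data = data + np.outer(self.dipole_topo, self.dipole_wave)
        if "movement_wire" in include:
            data = data + np.outer(self.wire_topo, self.wire_wave)
        if "stim" in include:
            wave = (self.stim_wave_coupled if "movement_wire" in include
                    else self.stim_wave_plain)
            data = data + stim_gain * np.outer(self.stim_topo, wave)
        return data


def acquire(config: SimConfig, sensors: SensorArray | None = None,
            include: set = frozenset(), stim_gain: float | None = None) -> Recording:
    """Simulate one recording with the selected source terms enabled.

    ``include`` is a subset of ``{"dipole", "stim", "movement_wire"}``.  White
    sensor noise and line-noise sinusoids are always present.  All noise
    streams depend only on ``config.seed``, so recordings with different
    ``include`` flags share their noise sample for sample.
    """
    comp = _Components(config, sensors)
    gain = stim_gain if stim_gain is not None else (
        config.stim_gain if config.stim_gain is not None else _default_stim_gain(config))
    data = comp.assemble(set(include), gain)
    cond = {frozenset(): "empty_room",
            frozenset({"dipole"}): "reference",
            frozenset({"dipole", "movement_wire"}): "dmw",
            frozenset({"dipole", "stim", "movement_wire"}): "dsmw"}.get(
                frozenset(include), "custom")
    return Recording(data=data, fs=config.fs_out, sensors=comp.sensors,
                     condition=cond)


def _default_stim_gain(config: SimConfig) -> float:
    # rough physical scale used when no calibration has been run
    return 10.0 ** (0.5 * config.target_log_ratio) * 5e-13


# ---------------------------------------------------------------------------
# calibration

def _peak_ratio(data: np.ndarray, config: SimConfig) -> float:
    """log10 DBS-peak minus log10 dipole-peak of the channel-averaged
    log10 Welch spectrum."""
    from .spectral import welch_psd  # local import to avoid a cycle

    spec = welch_psd(data, fs=config.fs_out)
    mean_log = np.mean(np.log10(spec.power), axis=0)
    f = spec.freqs
    dip = mean_log[(f >= config.f_dipole - 1) & (f <= config.f_dipole + 1)].max()
    stim = mean_log[(f >= 120.0) & (f <= 140.0)].max()
    return stim - dip


def calibrate_stim_gain(config: SimConfig, sensors: SensorArray | None = None,
                        tol: float = 0.02, max_iter: int = 60) -> float:
    """Stimulation gain that realises the target DBS/dipole log-power ratio.

    Bisects on log10(gain) until the channel-averaged log10 Welch spectrum of
    a full-artefact (DSMW) simulation shows
    ``log10 P(stim peak) - log10 P(12 Hz peak) = target_log_ratio`` within
    ``tol`` (well inside the +/- 0.1 contract).
    """
    comp = _Components(config, sensors)
    include = {"dipole", "stim", "movement_wire"}
    target = config.target_log_ratio

    def ratio(log_g):
        return _peak_ratio(comp.assemble(include, 10.0 ** log_g), config) - target

    lo, hi = -16.0, -10.0
    f_lo, f_hi = ratio(lo), ratio(hi)
    it = 0
    while f_lo > 0 and it < 8:
        lo -= 2.0
        f_lo = ratio(lo)
        it += 1
    while f_hi < 0 and it < 16:
        hi += 2.0
        f_hi = ratio(hi)
        it += 1
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError(
            f"could not bracket the target ratio {target}: "
            f"ratio({lo})={f_lo + target:.2f}, ratio({hi})={f_hi + target:.2f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = ratio(mid)
        if abs(f_mid) <= tol:
            return 10.0 ** mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("stimulation-gain bisection did not converge")


def make_condition_set(config: SimConfig) -> ConditionSet:
    """Simulate the four linked conditions plus the DBS reference channel.

    All conditions share one sensor array and the same seeded noise streams,
    so ``reference == empty_room + dipole term`` exactly and
    ``dsmw == reference + wire term + stim term``.  The DBS reference channel
    carries the (movement-coupled) stimulation waveform, a movement term and
    a small 12 Hz dipole leakage.
    """
    comp = _Components(config)
    gain = config.stim_gain
    if gain is None:
        gain = calibrate_stim_gain(config, comp.sensors)
    fs = config.fs_out
    sens = comp.sensors

    def rec(include, cond):
        return Recording(data=comp.assemble(include, gain), fs=fs,
                         sensors=sens, condition=cond)

    empty = rec(set(), "empty_room")
    reference = rec({"dipole"}, "reference")
    dmw = rec({"dipole", "movement_wire"}, "dmw")
    dsmw = rec({"dipole", "stim", "movement_wire"}, "dsmw")

    ref_channel = (comp.stim_wave_coupled
                   + 0.3 * comp.disp / config.move_amplitude
                   + config.dipole_leak * comp.dipole_wave)
    return ConditionSet(reference=reference, dmw=dmw, dsmw=dsmw,
                        empty_room=empty, dbs_reference_channel=ref_channel,
                        config=config)
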