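"""Synthetic paired pre/post EEG cohorts with known ground truth.

Each recording is a sum of three ingredients per channel:

* ``1/f^β`` Gaussian background noise (β defaults to 1, typical of
  resting EEG), giving realistic broadband spectra without a head model;
* per-band narrow-band oscillations — band-pass-filtered white noise, not
  pure sinusoids, so the instantaneous phase is nondegenerate — whose
  variance is set by the pre/post band-power levels;
* coupled oscillations: every channel in a coupling group shares one
  band-limited carrier, rotated by a constant per-position phase lag and
  mixed against the channel's independent oscillation at the configured
  strength ``s`` (``sqrt(1-s²)·independent + s·carrier``), so a fully
  coupled pair (s = 1) at lag φ has phase-lag coupling ``|sin φ|``.

Per-channel amplitudes are jittered ±20% to exercise the
amplitude-invariance of the phase metrics, and subject/condition
log-normal jitters on band levels and coupling strengths give the paired
contrasts realistic between-subject variance. Matching VAS-F fatigue and
energy scores (0–100 scale) are drawn per subject and condition.

Everything is deterministic given the configuration seed: subjects,
conditions, and score draws use independent, named seed substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .connectivity import bandpass
from .io import CONDITIONS, Recording
from .montage import Montage, default_montage
from .spectral import get_band

__all__ = [
    "ConfigurationError",
    "CouplingGroup",
    "VasfSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "default_coupling",
    "simulate_recording",
    "simulate_cohort",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CouplingGroup:
    """A set of channels sharing one band-limited carrier.

    Channel at position ``m`` in the set receives the carrier rotated by
    ``m * lag`` radians, so adjacent members differ by ``lag``.
    ``strength`` holds the (pre, post) mixing strengths in [0, 1].
    """

    channels: tuple[str, ...]
    band: str
    lag: float
    strength: tuple[float, float]


@dataclass(frozen=True)
class VasfSpec:
    """Means and SDs of the VAS-F subscales per condition (0–100 scale)."""

    fatigue_pre: tuple[float, float] = (11.167, 3.821)
    fatigue_post: tuple[float, float] = (80.917, 4.187)
    energy_pre: tuple[float, float] = (41.833, 2.664)
    energy_post: tuple[float, float] = (19.688, 2.408)


def default_coupling(montage: Montage | None = None) -> tuple[CouplingGroup, ...]:
    """α-band coupling over the frontal-to-centro-parietal regions.

    One group per region, strength rising 0.3 → 0.6 after fatigue —
    the fatigue signature whose network consequences (higher efficiency
    and clustering, shorter paths, nodal-efficiency gains concentrated in
    these regions) the pipeline is meant to recover.
    """
    montage = montage or default_montage()
    regions = ("frontal", "fronto-central", "central", "centro-parietal")
    return tuple(
        CouplingGroup(channels=montage.regions[r], band="alpha", lag=0.5,
                      strength=(0.3, 0.6))
        for r in regions
    )


def _default_band_power() -> dict[str, tuple[float, float]]:
    # Oscillation variance (linear units) per band, (pre, post): increases
    # in all three bands with the α change largest and β weakest.
    return {"theta": (1.0, 1.2), "alpha": (1.0, 2.2), "beta": (0.5, 0.55)}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a paired pre/post cohort."""

    n_subjects: int = 48
    fs: float = 500.0
    duration: float = 180.0
    band_power: dict[str, tuple[float, float]] = field(
        default_factory=_default_band_power)
    coupling: tuple[CouplingGroup, ...] | None = None
    noise_exponent: float = 1.0
    noise_level: float = 1.0
    amp_jitter: float = 0.2
    band_level_jitter: float = 0.15     # sd of ln(level), per condition draw
    subject_band_jitter: float = 0.2    # sd of ln(level), per subject
    strength_jitter: float = 0.03       # sd of additive strength offsets
    vasf: VasfSpec = field(default_factory=VasfSpec)
    montage: Montage = field(default_factory=default_montage)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling is None:
            self.coupling = default_coupling(self.montage)
        self.validate()

    @property
    def n_samples(self) -> int:
        n = self.duration * self.fs
        return int(round(n))

    def validate(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigurationError("duration and fs must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"duration × fs = {n} is not an integer sample count")
        for name in self.band_power:
            get_band(name)  # raises on unknown band
        known = set(self.montage.channels)
        for g in self.coupling:
            get_band(g.band)
            unknown = set(g.channels) - known
            if unknown:
                raise ConfigurationError(
                    f"coupling group references unknown channels: {sorted(unknown)}")
            if not all(0 <= s <= 1 for s in g.strength):
                raise ConfigurationError("coupling strength must be in [0, 1]")
            if not -math.pi < g.lag <= math.pi:
                raise ConfigurationError("phase lag must be in (-π, π]")

    def truth_dict(self) -> dict:
        d = asdict(self)
        d["montage"] = {"n_channels": self.montage.n_channels}
        return d


def _powerlaw_noise(rng: np.random.Generator, shape: tuple[int, int],
                    beta: float, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^β power spectrum, per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * scale, n, axis=-1)
    return _unit_rms(x)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband(rng: np.random.Generator, shape: tuple[int, int],
                band, fs: float) -> np.ndarray:
    """Unit-RMS band-limited noise (filtered white noise), per row."""
    return _unit_rms(bandpass(rng.standard_normal(shape), band, fs))


def _recording_rngs(config: SimulationConfig, subject: int, condition: str):
    cond_idx = CONDITIONS.index(condition)
    subj_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, subject)))
    rec_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2, subject, cond_idx)))
    return subj_rng, rec_rng


def simulate_recording(config: SimulationConfig, subject: int,
                       condition: str) -> Recording:
    """One deterministic subject-condition recording (channels × samples).

    Identical ``(config, subject, condition)`` always produces a
    bit-identical array; the two conditions of a subject share the
    subject-level draws (band-level scale, amplitude jitter, strength
    offset) so that paired contrasts isolate the configured pre/post
    changes plus condition-level jitter.
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ConfigurationError(f"condition must be one of {CONDITIONS}")
    if not 0 <= subject < config.n_subjects:
        raise ConfigurationError(
            f"subject index {subject} outside 0..{config.n_subjects - 1}")
    cond_idx = CONDITIONS.index(condition)
    montage = config.montage
    n_ch = montage.n_channels
    n = config.n_samples
    subj_rng, rec_rng = _recording_rngs(config, subject, condition)

    # Subject-level draws: fixed order, independent of condition.
    band_names = sorted(config.band_power)
    subj_scale = {b: math.exp(subj_rng.normal(0.0, config.subject_band_jitter))
                  for b in band_names}
    amp = 1.0 + subj_rng.uniform(-config.amp_jitter, config.amp_jitter,
                                 size=n_ch)
    subj_strength_off = subj_rng.normal(0.0, config.strength_jitter,
                                        size=len(config.coupling))

    x = np.zeros((n_ch, n))
    if config.noise_level > 0:
        x += config.noise_level * _powerlaw_noise(
            rec_rng, (n_ch, n), config.noise_exponent, config.fs)

    for b in band_names:
        levels = config.band_power[b]
        level = levels[cond_idx] * subj_scale[b]
        if config.band_level_jitter > 0:
            level *= math.exp(rec_rng.normal(0.0, config.band_level_jitter))
        if level < 0:
            raise ConfigurationError(f"negative band power level for {b!r}")
        osc = _narrowband(rec_rng, (n_ch, n), b, config.fs)
        # mix shared carriers into coupled channels of this band
        for gi, g in enumerate(config.coupling):
            if g.band != b:
                continue
            s = g.strength[cond_idx] + subj_strength_off[gi]
            if config.strength_jitter > 0:
                s += rec_rng.normal(0.0, config.strength_jitter)
            s = min(max(s, 0.0), 1.0)
            carrier = _narrowband(rec_rng, (1, n), b, config.fs)[0]
            analytic = hilbert(carrier)
            for m, ch in enumerate(g.channels):
                idx = montage.index(ch)
                coupled = _unit_rms(np.real(analytic * np.exp(-1j * m * g.lag)))
                osc[idx] = math.sqrt(1.0 - s * s) * osc[idx] + s * coupled
        x += math.sqrt(level) * osc

    x *= amp[:, None]
    return Recording(channels=montage.channels, fs=config.fs, data=x,
                     subject=subject, condition=condition)


@dataclass
class SyntheticCohort:
    """Paired recordings plus VAS-F scores and retained ground truth.

    Recordings are generated lazily (and deterministically) on access so a
    full-size cohort never has to sit in memory at once.
    """

    config: SimulationConfig
    vasf: pd.DataFrame

    @property
    def subjects(self) -> list[int]:
        return list(range(self.config.n_subjects))

    @property
    def conditions(self) -> tuple[str, ...]:
        return CONDITIONS

    @property
    def truth(self) -> dict:
        return self.config.truth_dict()

    @property
    def n_recordings(self) -> int:
        return self.config.n_subjects * len(CONDITIONS)

    def recording(self, subject: int, condition: str) -> Recording:
        return simulate_recording(self.config, subject, condition)

    def iter_recordings(self):
        for subject in self.subjects:
            for condition in self.conditions:
                yield (subject, condition), self.recording(subject, condition)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Cohort of paired recordings plus per-subject VAS-F scores."""
    config.validate()
    if config.n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(3,)))
    rows = []
    spec = config.vasf
    for subject in range(config.n_subjects):
        for condition in CONDITIONS:
            f_mu, f_sd = getattr(spec, f"fatigue_{condition}")
            e_mu, e_sd = getattr(spec, f"energy_{condition}")
            rows.append({
                "subject": subject,
                "condition": condition,
                "fatigue": float(np.clip(rng.normal(f_mu, f_sd), 0.0, 100.0)),
                "energy": float(np.clip(rng.normal(e_mu, e_sd), 0.0, 100.0)),
            })
    return SyntheticCohort(config=config, vasf=pd.DataFrame(rows))
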