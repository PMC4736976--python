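"""Oddball-paradigm ERP simulator with controllable P300 and known ground truth.

Generates labeled epoch sets emulating a 10-electrode, 256 Hz, 800 ms
speller acquisition: a training set of 480 P300 + 2,400 non-P300 trials and
a validation set of 150 + 750. A P300 trial is band-limited background EEG
plus a smooth positive (Gaussian) deflection at a jittered latency around
350 ms, scaled per electrode by an amplitude profile that mimics the decay
of P300 amplitude with distance from the generating cortical area; a
non-P300 trial is background only. Background EEG is Gaussian noise
band-limited to the post-filter ERP band (0.1-12 Hz) — the simulator
produces signals as they stand *after* offline conditioning, so the
acquisition-side notch/anti-alias filters are not modeled.

Every random draw flows from the config seed, and the ground-truth record
stores each trial's injected latency and per-electrode amplitude, so
recovery tests have an exact answer key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .epochs import NONP300, P300, EpochSet
from .preprocess import butter_bandpass_zero_phase
from .shcc import Chain, parse_chains

__all__ = ["SimulationConfig", "simulate_dataset", "make_fixture_chains", "DEFAULT_ELECTRODES"]

#: 10-20-system montage of the reference acquisition.
DEFAULT_ELECTRODES = ("Fz", "C4", "Cz", "C3", "P4", "Pz", "P3", "PO8", "Oz", "PO7")

#: Default per-electrode amplitude multipliers: three electrodes see the full
#: P300, four a half-amplitude projection, three essentially none — giving
#: calibration recovery tests a known answer.
DEFAULT_AMPLITUDE_PROFILE = (1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0)


@dataclass
class SimulationConfig:
    """Acquisition regime and P300 morphology of the simulated subject."""

    n_electrodes: int = 10
    electrode_names: tuple[str, ...] | None = None
    sampling_rate_hz: float = 256.0
    epoch_ms: float = 800.0
    n_p300_train: int = 480
    n_nonp300_train: int = 2400
    n_p300_valid: int = 150
    n_nonp300_valid: int = 750
    p300_amplitude_uV: float = 10.0
    amplitude_profile: tuple[float, ...] | None = None
    p300_latency_ms: float = 350.0
    latency_jitter_sd_ms: float = 20.0
    p300_width_ms: float = 80.0
    noise_band_hz: tuple[float, float] = (0.1, 12.0)
    noise_sd_uV: float = 10.0
    n_bumps: int = 1
    second_bump_offset_ms: float = 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.electrode_names is None:
            if self.n_electrodes == len(DEFAULT_ELECTRODES):
                self.electrode_names = DEFAULT_ELECTRODES
            else:
                self.electrode_names = tuple(
                    f"E{i + 1}" for i in range(self.n_electrodes)
                )
        self.electrode_names = tuple(self.electrode_names)
        if len(self.electrode_names) != self.n_electrodes:
            raise ValueError("electrode_names length must equal n_electrodes")
        if self.amplitude_profile is None:
            if self.n_electrodes == len(DEFAULT_AMPLITUDE_PROFILE):
                self.amplitude_profile = DEFAULT_AMPLITUDE_PROFILE
            else:
                self.amplitude_profile = tuple([1.0] * self.n_electrodes)
        self.amplitude_profile = tuple(float(a) for a in self.amplitude_profile)
        if len(self.amplitude_profile) != self.n_electrodes:
            raise ValueError("amplitude_profile length must equal n_electrodes")
        for name in ("n_p300_train", "n_nonp300_train", "n_p300_valid", "n_nonp300_valid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        last_bump = self.p300_latency_ms + (
            self.second_bump_offset_ms if self.n_bumps > 1 else 0.0
        )
        if last_bump + 3 * self.p300_width_ms > self.epoch_ms:
            raise ValueError(
                "epoch too short: latency + 3 x width must fit inside the epoch"
            )
        if self.n_bumps not in (1, 2):
            raise ValueError("n_bumps must be 1 or 2")

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.epoch_ms * self.sampling_rate_hz / 1000.0))

    @property
    def amplitudes_uV(self) -> np.ndarray:
        return self.p300_amplitude_uV * np.asarray(self.amplitude_profile)


def _band_noise(
    shape: tuple[int, ...], cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise band-limited to the ERP band, scaled to the target SD."""
    white = rng.standard_normal(shape)
    if white.size == 0:
        return white
    low, high = cfg.noise_band_hz
    filtered = butter_bandpass_zero_phase(white, low, high, 4, cfg.sampling_rate_hz)
    sd = filtered.std()
    if sd > 0:
        filtered = filtered / sd
    return filtered * cfg.noise_sd_uV


def _bump(cfg: SimulationConfig, latency_ms: float) -> np.ndarray:
    """Unit-amplitude smooth positive deflection at *latency_ms*."""
    t_ms = np.arange(cfg.n_samples) / cfg.sampling_rate_hz * 1000.0
    out = np.exp(-0.5 * ((t_ms - latency_ms) / cfg.p300_width_ms) ** 2)
    if cfg.n_bumps == 2:
        out = out + np.exp(
            -0.5
            * ((t_ms - latency_ms - cfg.second_bump_offset_ms) / cfg.p300_width_ms) ** 2
        )
    return out


def _make_set(
    n_p300: int, n_nonp300: int, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[EpochSet, np.ndarray]:
    n = n_p300 + n_nonp300
    data = _band_noise((n, cfg.n_electrodes, cfg.n_samples), cfg, rng)
    latencies = rng.normal(cfg.p300_latency_ms, cfg.latency_jitter_sd_ms, n_p300)
    amps = cfg.amplitudes_uV
    for i, lat in enumerate(latencies):
        data[i] += amps[:, None] * _bump(cfg, lat)[None, :]
    labels = np.array([P300] * n_p300 + [NONP300] * n_nonp300, dtype=object)
    order = rng.permutation(n)
    epochs = EpochSet(
        data[order],
        labels[order],
        cfg.electrode_names,
        cfg.sampling_rate_hz,
        cfg.epoch_ms,
    )
    lat_full = np.full(n, np.nan)
    lat_full[:n_p300] = latencies
    return epochs, lat_full[order]


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[EpochSet, EpochSet, dict]:
    """Generate (train, validation, ground-truth) for one simulated subject.

    The ground-truth record holds the canonical unit bump shape, the
    per-electrode amplitudes, and each trial's injected latency (NaN for
    non-P300 trials), aligned with the returned trial order.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_train, ss_valid = ss.spawn(2)
    train, lat_train = _make_set(
        config.n_p300_train, config.n_nonp300_train, config,
        np.random.default_rng(ss_train),
    )
    valid, lat_valid = _make_set(
        config.n_p300_valid, config.n_nonp300_valid, config,
        np.random.default_rng(ss_valid),
    )
    truth = {
        "bump": _bump(config, config.p300_latency_ms),
        "amplitudes_uV": config.amplitudes_uV,
        "train_latencies_ms": lat_train,
        "valid_latencies_ms": lat_valid,
        "config": config,
    }
    return train, valid, truth


# ---------------------------------------------------------------------------
# Printed fixture chains (golden inputs for the worked examples)

_FIXTURES = {
    "fig1": "0.06 -0.02 -0.06 0.06 0.05 0.02 0.01 -0.04 0.04 -0.03 -0.09 0.04 0.05 -0.01 -0.02 0.04",
    "template": "0.05 -0.02 -0.05 0.08 0.07 -0.01 0.01 -0.03 0.04 -0.04 -0.09 0.01 0.05 -0.03 -0.04 0.04",
    "p300": "-0.01 -0.04 -0.05 0.04 0.05 0.05 0.02 -0.05 -0.02 -0.05 -0.02 0.05 0.02 0 -0.01 -0.01",
    "nonp300": "0.07 -0.03 0 -0.03 0.06 0.04 -0.10 0.06 0.01 -0.04 -0.04 0.06 -0.09 0.01 0.11 0.05",
}


def make_fixture_chains() -> dict[str, Chain]:
    """The four published 16-symbol example chains, for golden tests.

    Keys: ``"fig1"`` (the discretized ERP whose tortuosity is 0.64),
    ``"template"``, ``"p300"`` and ``"nonp300"`` (the worked distance
    examples: template-to-P300 0.55, template-to-non-P300 0.92).
    """
    return {name: parse_chains(text)[0] for name, text in _FIXTURES.items()}
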