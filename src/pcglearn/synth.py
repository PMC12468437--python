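"""Synthetic infant phonocardiogram (PCG) generator.

A heart-sound recording is modelled as a train of cardiac cycles.  Each
cycle carries two short transients — S1 (closure of the atrioventricular
valves) and S2 (closure of the semilunar valves) — rendered as
Gaussian-enveloped sinusoids.  Abnormal recordings additionally carry a
systolic murmur: band-limited noise injected between S1 and S2, the
acoustic signature of structural defects such as ventricular septal
defect (VSD) or pulmonary stenosis (PS).

The study-emulation corpus mirrors a public pediatric heart-sound
collection: 60 six-second recordings, 30 normal and 30 abnormal, heart
rates between 60 and 100 bpm, so that a six-second window captures
roughly 6 to 10 heartbeats.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "MurmurPreset",
    "CycleParams",
    "PCGRecording",
    "SynthDatasetConfig",
    "MURMUR_PRESETS",
    "ABNORMAL_CONDITIONS",
    "synth_transient",
    "synthesize_recording",
    "generate_dataset",
]

DEFAULT_SAMPLE_RATE = 4000
MANIFEST_COLUMNS = ["path", "label", "condition", "heart_rate_bpm", "duration_s", "seed"]


@dataclass(frozen=True)
class MurmurPreset:
    """Murmur characteristics of one abnormal condition.

    Parameters
    ----------
    condition_name:
        Clinical abbreviation (VSD, ASD, PDA, TOF, PS, AS) or ``"normal"``.
    murmur_band:
        Pass band of the murmur noise in Hz.
    murmur_gain:
        Murmur amplitude relative to the S1 transient; 0 for normal.
    systolic_fraction:
        Portion of the S1->S2 interval covered by the murmur, in (0, 1].
    """

    condition_name: str
    murmur_band: tuple[float, float]
    murmur_gain: float
    systolic_fraction: float = 0.9

    def __post_init__(self) -> None:
        lo, hi = self.murmur_band
        if not (20.0 < lo < hi):
            raise ValueError(f"murmur_band must lie above 20 Hz, got {self.murmur_band}")
        if self.murmur_gain < 0:
            raise ValueError("murmur_gain must be >= 0")
        if not (0 < self.systolic_fraction <= 1):
            raise ValueError("systolic_fraction must be in (0, 1]")


# Murmur bands/gains chosen to mimic the typical mid-frequency systolic
# murmurs of each lesion; the corpus being emulated describes them only
# qualitatively, so these are plausible textbook-style values.
MURMUR_PRESETS: dict[str, MurmurPreset] = {
    "VSD": MurmurPreset("VSD", (150.0, 400.0), 0.45, 0.95),
    "ASD": MurmurPreset("ASD", (120.0, 300.0), 0.30, 0.80),
    "PDA": MurmurPreset("PDA", (150.0, 450.0), 0.40, 1.00),
    "TOF": MurmurPreset("TOF", (140.0, 380.0), 0.40, 0.90),
    "PS": MurmurPreset("PS", (160.0, 420.0), 0.45, 0.85),
    "AS": MurmurPreset("AS", (180.0, 450.0), 0.45, 0.85),
}
ABNORMAL_CONDITIONS: tuple[str, ...] = tuple(MURMUR_PRESETS)

NORMAL_PRESET = MurmurPreset("normal", (150.0, 400.0), 0.0, 1.0)


@dataclass(frozen=True)
class CycleParams:
    """Timing and morphology of one cardiac cycle.

    S1 is lower-pitched and longer than S2; S2 is rendered at 0.8x the
    S1 amplitude.  ``systole_fraction`` is the S1-onset to S2-onset
    distance as a fraction of the cycle length 60/heart_rate.
    """

    heart_rate: float = 80.0
    s1_center_freq: float = 50.0
    s2_center_freq: float = 80.0
    s1_duration: float = 0.090
    s2_duration: float = 0.070
    s2_relative_amplitude: float = 0.8
    systole_fraction: float = 0.35
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if not (0 < self.systole_fraction < 1):
            raise ValueError("systole_fraction must be in (0, 1)")
        cycle = 60.0 / self.heart_rate
        if self.s1_duration >= cycle or self.s2_duration >= cycle:
            raise ValueError("transient durations must be shorter than the cycle")


@dataclass
class PCGRecording:
    """A mono heart-sound waveform with its provenance."""

    samples: np.ndarray
    sample_rate: int
    label: str
    condition: str
    cycle_onsets: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class SynthDatasetConfig:
    """Corpus-level generation settings.

    The default emulates the study corpus: 30 normal + 30 abnormal
    six-second recordings with heart rates drawn from 60-100 bpm.
    """

    n_normal: int = 30
    n_abnormal: int = 30
    duration: float = 6.0
    heart_rate_range: tuple[float, float] = (60.0, 100.0)
    sample_rate: int = DEFAULT_SAMPLE_RATE
    noise_sd: float = 0.01
    jitter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("recording counts must be non-negative")
        lo, hi = self.heart_rate_range
        if not (0 < lo <= hi):
            raise ValueError("heart_rate_range must be positive and ordered")


def synth_transient(
    center_freq: float,
    duration: float,
    amplitude: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> np.ndarray:
    """Gaussian-enveloped sinusoid used for the S1/S2 heart sounds.

    The envelope peaks at the segment midpoint and decays toward both
    ends (sigma = duration/6, so the edges sit at 3 sigma).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0 < center_freq < sample_rate / 2):
        raise ValueError(
            f"center_freq must be in (0, {sample_rate / 2}) Hz, got {center_freq}"
        )
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    mid = (n - 1) / (2 * sample_rate)
    envelope = np.exp(-0.5 * ((t - mid) / (duration / 6.0)) ** 2)
    return amplitude * envelope * np.sin(2 * np.pi * center_freq * (t - mid))


def _murmur_noise(
    n: int, band: tuple[float, float], sample_rate: int, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited white noise, unit peak, for the systolic murmur."""
    noise = rng.standard_normal(n)
    nyq = sample_rate / 2
    hi = min(band[1], 0.95 * nyq)
    sos = sps.butter(4, [band[0] / nyq, hi / nyq], btype="bandpass", output="sos")
    shaped = sps.sosfiltfilt(sos, noise)
    peak = np.max(np.abs(shaped))
    return shaped / peak if peak > 0 else shaped


def _resolve_preset(condition: str | MurmurPreset) -> MurmurPreset:
    if isinstance(condition, MurmurPreset):
        return condition
    if condition == "normal":
        return NORMAL_PRESET
    try:
        return MURMUR_PRESETS[condition]
    except KeyError:
        valid = ", ".join(["normal", *MURMUR_PRESETS])
        raise ValueError(f"unknown condition {condition!r}; valid: {valid}") from None


def synthesize_recording(
    condition: str | MurmurPreset = "normal",
    heart_rate: float = 80.0,
    duration: float = 6.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    noise_sd: float = 0.01,
    seed: int = 0,
    cycle: CycleParams | None = None,
) -> PCGRecording:
    """Synthesize one heart-sound recording.

    Cycles are placed at interval 60/heart_rate starting at t=0, so a
    recording of ``duration`` seconds contains
    ``floor(duration * heart_rate / 60)`` cycle onsets when the timing
    jitter is zero.  Abnormal conditions add a Hann-windowed burst of
    band-limited noise spanning ``systolic_fraction`` of each S1->S2
    interval.  The waveform is peak-normalized to 0.9.
    """
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    preset = _resolve_preset(condition)
    if cycle is None:
        cycle = CycleParams(heart_rate=heart_rate)
    else:
        cycle = CycleParams(
            heart_rate=heart_rate,
            s1_center_freq=cycle.s1_center_freq,
            s2_center_freq=cycle.s2_center_freq,
            s1_duration=cycle.s1_duration,
            s2_duration=cycle.s2_duration,
            s2_relative_amplitude=cycle.s2_relative_amplitude,
            systole_fraction=cycle.systole_fraction,
            jitter_sd=cycle.jitter_sd,
        )

    rng = np.random.default_rng(seed)
    n_total = round(duration * sample_rate)
    samples = np.zeros(n_total)

    period = 60.0 / heart_rate
    n_cycles = int(np.floor(duration * heart_rate / 60.0))
    s1 = synth_transient(cycle.s1_center_freq, cycle.s1_duration, 1.0, sample_rate)
    s2 = synth_transient(
        cycle.s2_center_freq, cycle.s2_duration, cycle.s2_relative_amplitude, sample_rate
    )

    onsets: list[float] = []
    for k in range(n_cycles):
        jitter = rng.normal(0.0, cycle.jitter_sd) if cycle.jitter_sd > 0 else 0.0
        onset = k * period + jitter
        onset = min(max(onset, 0.0), duration - cycle.s1_duration)
        onsets.append(onset)
        _add_at(samples, s1, round(onset * sample_rate))

        s2_onset = onset + cycle.systole_fraction * period
        _add_at(samples, s2, round(s2_onset * sample_rate))

        if preset.murmur_gain > 0:
            # Murmur occupies the central systolic_fraction of the
            # S1-offset -> S2-onset gap.
            gap_start = onset + cycle.s1_duration
            gap = s2_onset - gap_start
            if gap > 0.01:
                m_dur = preset.systolic_fraction * gap
                m_start = gap_start + 0.5 * (gap - m_dur)
                m_n = round(m_dur * sample_rate)
                if m_n > 8:
                    burst = _murmur_noise(m_n, preset.murmur_band, sample_rate, rng)
                    burst *= preset.murmur_gain * np.hanning(m_n)
                    _add_at(samples, burst, round(m_start * sample_rate))

    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, n_total)

    peak = np.max(np.abs(samples))
    if peak > 0:
        samples *= 0.9 / peak

    return PCGRecording(
        samples=samples,
        sample_rate=sample_rate,
        label="normal" if preset.murmur_gain == 0 else "abnormal",
        condition=preset.condition_name,
        cycle_onsets=onsets,
        seed=seed,
    )


def _add_at(target: np.ndarray, segment: np.ndarray, start: int) -> None:
    start = max(start, 0)
    stop = min(start + len(segment), len(target))
    if stop > start:
        target[start:stop] += segment[: stop - start]


def generate_dataset(config: SynthDatasetConfig, out_dir: str | Path):
    """Write a synthetic corpus of WAV files plus a CSV manifest.

    Abnormal recordings cycle round-robin through the six murmur
    presets.  Each recording gets an independent seed derived from the
    master seed, recorded in the manifest, so any file can be
    regenerated in isolation.

    Returns the manifest as a :class:`pcglearn.dataio.DatasetManifest`.
    """
    from .dataio import DatasetManifest, write_wav

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_total = config.n_normal + config.n_abnormal
    master = np.random.default_rng(config.seed)
    child_seeds = (
        np.random.SeedSequence(config.seed).generate_state(n_total).astype(np.int64)
        % (2**31)
        if n_total
        else np.array([], dtype=np.int64)
    )
    lo, hi = config.heart_rate_range

    rows: list[dict] = []
    plan = [("normal", "normal")] * config.n_normal + [
        ("abnormal", ABNORMAL_CONDITIONS[i % len(ABNORMAL_CONDITIONS)])
        for i in range(config.n_abnormal)
    ]
    for i, (label, condition) in enumerate(plan):
        heart_rate = float(master.uniform(lo, hi)) if hi > lo else float(lo)
        seed = int(child_seeds[i])
        rec = synthesize_recording(
            condition=condition,
            heart_rate=heart_rate,
            duration=config.duration,
            sample_rate=config.sample_rate,
            noise_sd=config.noise_sd,
            seed=seed,
            cycle=CycleParams(heart_rate=heart_rate, jitter_sd=config.jitter_sd),
        )
        fname = f"{label}_{condition}_{i:03d}.wav"
        write_wav(rec, out_dir / fname)
        rows.append(
            {
                "path": str(out_dir / fname),
                "label": label,
                "condition": condition,
                "heart_rate_bpm": round(heart_rate, 3),
                "duration_s": config.duration,
                "seed": seed,
            }
        )

    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return DatasetManifest.from_rows(rows, path=manifest_path)
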