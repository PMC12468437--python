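"""Time-frequency feature extraction for heart-sound waveforms.

Three extractors are provided, mirroring the usual choices for
biomedical audio classification:

* **MFCC** — mel-frequency cepstral coefficients per short frame; the
  frame-major coefficient matrix is the 1D sequence representation fed
  to recurrent models, and can also be rendered as an image.
* **STFT** — short-time Fourier magnitude spectrogram.
* **Wavelet** — continuous Morlet-wavelet scalogram over a log-spaced
  scale axis.

Any magnitude matrix can be turned into a fixed-size H x W x 3 image in
[0, 1] (log-compression, min-max normalization, bilinear resize,
grayscale replicated over three channels) — the 2D representation fed
to convolutional models.

All extractors are deterministic and guard their logarithms with a
floor, so no NaN or Inf is ever emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.fft import dct, rfft
from scipy.signal import ShortTimeFFT, get_window
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import PCGRecording

__all__ = [
    "FeatureConfig",
    "SequenceFeatures",
    "ImageFeatures",
    "mel_filterbank",
    "frame_signal",
    "compute_mfcc",
    "compute_stft_spectrogram",
    "compute_wavelet_scalogram",
    "to_image",
    "extract_image",
    "save_image_png",
    "MFCCSequenceExtractor",
    "SpectrogramImageExtractor",
    "EXTRACTORS",
]

EXTRACTORS = ("MFCC", "STFT", "WAVELET")


@dataclass(frozen=True)
class FeatureConfig:
    """Extractor settings.

    Defaults follow common practice for short biomedical audio: 25 ms
    Hann frames with 10 ms hop, 26 mel filters, 13 cepstral
    coefficients, 64 wavelet scales covering ~20 Hz up to Nyquist.
    """

    extractor: str = "MFCC"
    frame_length_s: float = 0.025
    hop_length_s: float = 0.010
    n_mfcc: int = 13
    n_mels: int = 26
    n_fft: int = 256
    n_scales: int = 64
    image_size: tuple[int, int] = (128, 128)
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.extractor not in EXTRACTORS:
            raise ValueError(f"extractor must be one of {EXTRACTORS}, got {self.extractor!r}")
        if self.hop_length_s > self.frame_length_s:
            raise ValueError("hop_length_s must be <= frame_length_s")
        if min(self.image_size) < 8:
            raise ValueError("image_size sides must be >= 8")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    def frame_samples(self, sample_rate: int) -> int:
        return round(self.frame_length_s * sample_rate)

    def hop_samples(self, sample_rate: int) -> int:
        return max(1, round(self.hop_length_s * sample_rate))


@dataclass
class SequenceFeatures:
    """Frame-major (n_frames x n_coeffs) feature matrix with frame times."""

    values: np.ndarray
    frame_times: np.ndarray
    label: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class ImageFeatures:
    """H x W x 3 image in [0, 1] (one magnitude matrix replicated x3)."""

    pixels: np.ndarray
    extractor: str = ""
    label: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


def _as_samples(signal, default_rate: int = 4000) -> tuple[np.ndarray, int]:
    """Accept a PCGRecording, an AudioSegment, or a bare array."""
    if isinstance(signal, PCGRecording):
        return np.asarray(signal.samples, dtype=np.float64), signal.sample_rate
    if hasattr(signal, "samples") and hasattr(signal, "sample_rate"):
        return np.asarray(signal.samples, dtype=np.float64), int(signal.sample_rate)
    return np.asarray(signal, dtype=np.float64), default_rate


def frame_signal(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """Slice a signal into overlapping frames (n_frames x frame).

    n_frames = 1 + floor((N - frame) / hop); the incomplete tail is
    discarded.  Raises if the signal is shorter than one frame.
    """
    n = len(x)
    if n < frame:
        raise ValueError(f"signal of {n} samples is shorter than one frame ({frame})")
    n_frames = 1 + (n - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate: int, fmin: float = 20.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank (n_mels x (n_fft//2 + 1))."""
    fmax = fmax if fmax is not None else sample_rate / 2
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, len(bins)))
    for m in range(n_mels):
        left, center, right = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bins - left) / max(center - left, 1e-12)
        down = (right - bins) / max(right - center, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_energies(signal, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Per-frame mel filterbank energies (pre-DCT stage of MFCC)."""
    x, sr = _as_samples(signal)
    frame = config.frame_samples(sr)
    hop = config.hop_samples(sr)
    frames = frame_signal(x, frame, hop) * get_window("hann", frame, fftbins=True)
    n_fft = max(config.n_fft, frame)
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(config.n_mels, n_fft, sr)
    return power @ fb.T


def compute_mfcc(signal, config: FeatureConfig = FeatureConfig()) -> SequenceFeatures:
    """Mel-frequency cepstral coefficients, frame-major.

    Pipeline: Hann-windowed frames -> power spectrum -> triangular mel
    filterbank -> log (floored at ``log_floor``) -> orthonormal DCT-II,
    keeping the first ``n_mfcc`` coefficients.
    """
    x, sr = _as_samples(signal)
    energies = mel_energies(signal, config)
    log_e = np.log(np.maximum(energies, config.log_floor))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, : config.n_mfcc]
    hop = config.hop_samples(sr)
    frame = config.frame_samples(sr)
    times = (np.arange(coeffs.shape[0]) * hop + frame / 2) / sr
    label = getattr(signal, "label", "")
    return SequenceFeatures(values=coeffs, frame_times=times, label=label)


def compute_stft_spectrogram(signal, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Short-time Fourier magnitude spectrogram (freq x frames).

    Frequency axis spans 0 .. sample_rate/2; magnitudes are
    non-negative.
    """
    x, sr = _as_samples(signal)
    frame = config.frame_samples(sr)
    hop = config.hop_samples(sr)
    if len(x) < frame:
        raise ValueError("signal is shorter than one frame")
    n_fft = max(config.n_fft, frame)
    stf = ShortTimeFFT(
        get_window("hann", frame, fftbins=True), hop=hop, fs=sr, mfft=n_fft, scale_to=None
    )
    # p0/p1 restrict to frames fully inside the signal, matching the
    # framing arithmetic of the other extractors.
    n_frames = 1 + (len(x) - frame) // hop
    return np.abs(stf.stft(x, p0=0, p1=n_frames))


def compute_wavelet_scalogram(signal, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Continuous Morlet-wavelet scalogram (scales x time).

    Scales are log-spaced so the corresponding pseudo-frequencies cover
    ~20 Hz up to Nyquist; row 0 is the highest frequency.
    """
    if config.n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    x, sr = _as_samples(signal)
    if len(x) < 2:
        raise ValueError("signal too short for a scalogram")
    fc = pywt.central_frequency("morl")
    freqs = np.logspace(np.log10(sr / 2), np.log10(20.0), config.n_scales)
    scales = fc * sr / freqs
    coefs, _ = pywt.cwt(x, scales, "morl", sampling_period=1.0 / sr, method="fft")
    return np.abs(coefs)


def to_image(
    matrix: np.ndarray,
    image_size: tuple[int, int] = (128, 128),
    log_floor: float = 1e-10,
) -> ImageFeatures:
    """Render a magnitude matrix as a fixed-size 3-channel image.

    Log-compress (floored), bilinear-resize to (H, W), min-max
    normalize to [0, 1] and replicate the single channel three times.
    Normalizing after the resize keeps the output range exactly [0, 1];
    a constant matrix maps to all zeros.
    """
    from skimage.transform import resize

    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise ValueError("cannot render an empty matrix")
    log_m = np.log(np.maximum(matrix, log_floor))
    resized = resize(log_m, image_size, order=1, mode="edge", anti_aliasing=False)
    lo, hi = resized.min(), resized.max()
    norm = np.zeros_like(resized) if hi == lo else (resized - lo) / (hi - lo)
    return ImageFeatures(pixels=np.repeat(norm[:, :, None], 3, axis=2))


def extract_image(signal, config: FeatureConfig = FeatureConfig()) -> ImageFeatures:
    """Run the configured extractor and render the result as an image."""
    if config.extractor == "MFCC":
        matrix = compute_mfcc(signal, config).values.T  # coeffs x frames
        # Cepstral coefficients are signed; image rendering expects a
        # magnitude-like matrix.
        matrix = np.abs(matrix)
    elif config.extractor == "STFT":
        matrix = compute_stft_spectrogram(signal, config)
    else:
        matrix = compute_wavelet_scalogram(signal, config)
    img = to_image(matrix, config.image_size, config.log_floor)
    img.extractor = config.extractor
    img.label = getattr(signal, "label", "")
    return img


def save_image_png(image: ImageFeatures, path) -> None:
    """Optional PNG export for visual inspection."""
    import imageio.v3 as iio

    iio.imwrite(path, (image.pixels * 255).astype(np.uint8))


class _ArrayInput:
    samples: np.ndarray
    sample_rate: int

    def __init__(self, samples: np.ndarray, sample_rate: int):
        self.samples = samples
        self.sample_rate = sample_rate


class MFCCSequenceExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: waveforms -> stacked MFCC sequences.

    ``transform`` accepts a list of recordings/segments (or 1D arrays at
    ``sample_rate``) and returns an (n, n_frames, n_mfcc) array — the 1D
    sequence representation consumed by recurrent classifiers.
    """

    def __init__(
        self,
        frame_length_s: float = 0.025,
        hop_length_s: float = 0.010,
        n_mfcc: int = 13,
        sample_rate: int = 4000,
    ):
        self.frame_length_s = frame_length_s
        self.hop_length_s = hop_length_s
        self.n_mfcc = n_mfcc
        self.sample_rate = sample_rate

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        config = FeatureConfig(
            extractor="MFCC",
            frame_length_s=self.frame_length_s,
            hop_length_s=self.hop_length_s,
            n_mfcc=self.n_mfcc,
        )
        seqs = [
            compute_mfcc(self._wrap(x), config).values for x in X
        ]
        n_frames = min(s.shape[0] for s in seqs)
        return np.stack([s[:n_frames] for s in seqs])

    def _wrap(self, x):
        if hasattr(x, "samples"):
            return x
        return _ArrayInput(np.asarray(x, dtype=np.float64), self.sample_rate)


class SpectrogramImageExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: waveforms -> stacked H x W x 3 images.

    ``extractor`` selects MFCC, STFT or WAVELET; the output is an
    (n, H, W, 3) array in [0, 1] — the 2D representation consumed by
    convolutional classifiers.
    """

    def __init__(
        self,
        extractor: str = "STFT",
        image_size: tuple[int, int] = (128, 128),
        frame_length_s: float = 0.025,
        hop_length_s: float = 0.010,
        n_scales: int = 64,
        sample_rate: int = 4000,
    ):
        self.extractor = extractor
        self.image_size = image_size
        self.frame_length_s = frame_length_s
        self.hop_length_s = hop_length_s
        self.n_scales = n_scales
        self.sample_rate = sample_rate

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        config = FeatureConfig(
            extractor=self.extractor,
            image_size=tuple(self.image_size),
            frame_length_s=self.frame_length_s,
            hop_length_s=self.hop_length_s,
            n_scales=self.n_scales,
        )
        imgs = [extract_image(self._wrap(x), config).pixels for x in X]
        return np.stack(imgs)

    def _wrap(self, x):
        if hasattr(x, "samples"):
            return x
        return _ArrayInput(np.asarray(x, dtype=np.float64), self.sample_rate)
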