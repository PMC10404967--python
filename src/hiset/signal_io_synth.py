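"""Reading ICBHI-style recordings and generating synthetic labeled respiratory cycles.

The synthetic generator produces the three canonical cycle types — band-limited
noise (normal), amplitude-modulated sustained tones (wheeze) and brief damped
transients (crackle) — so every downstream stage can be exercised without any
external dataset.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, resample_poly, sosfiltfilt

__all__ = [
    "AudioSignal",
    "CycleAnnotation",
    "LabeledCycle",
    "LabelScheme",
    "SynthConfig",
    "load_icbhi_recording",
    "segment_cycles",
    "normalize_minmax",
    "synthesize_cycle",
    "synthesize_dataset",
    "TWO_CLASS",
    "THREE_CLASS",
    "FOUR_CLASS",
    "get_scheme",
]

ANALYSIS_RATE = 4000.0  # Hz; all recordings resampled here before analysis


@dataclasses.dataclass
class AudioSignal:
    """A sampled sound with its rate and provenance tag."""

    samples: np.ndarray
    sample_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclasses.dataclass(frozen=True)
class CycleAnnotation:
    """One respiratory cycle: [start_s, end_s) plus adventitious-sound flags."""

    start_s: float
    end_s: float
    crackle: bool
    wheeze: bool

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid cycle interval [{self.start_s}, {self.end_s})"
            )


@dataclasses.dataclass(frozen=True)
class LabelScheme:
    name: str
    classes: tuple[str, ...]

    def index(self, label: str) -> int:
        return self.classes.index(label)


TWO_CLASS = LabelScheme("two_class", ("normal", "abnormal"))
THREE_CLASS = LabelScheme("three_class", ("normal", "crackle", "wheeze"))
FOUR_CLASS = LabelScheme("four_class", ("normal", "crackle", "wheeze", "both"))

_SCHEMES = {s.name: s for s in (TWO_CLASS, THREE_CLASS, FOUR_CLASS)}


def get_scheme(name: str) -> LabelScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown label scheme {name!r}") from None


@dataclasses.dataclass
class LabeledCycle:
    signal: AudioSignal
    label: str


@dataclasses.dataclass
class SynthConfig:
    """Knobs for the synthetic cycle generator."""

    n_per_class: int = 10
    duration_s: float = 2.5
    sample_rate: float = ANALYSIS_RATE
    snr_db: float = 10.0
    wheeze_freq_range: tuple[float, float] = (100.0, 1000.0)
    crackle_rate: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate < 2 * self.wheeze_freq_range[1]:
            raise ValueError(
                "sample_rate must be at least twice the upper wheeze frequency"
            )


# ---------------------------------------------------------------------------
# ICBHI-format reading


def _parse_annotation_text(text: str) -> list[CycleAnnotation]:
    annotations = []
    for idx, raw in enumerate(text.splitlines()):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(
                f"annotation row {idx}: expected 4 columns, got {len(parts)}"
            )
        try:
            start, end = float(parts[0]), float(parts[1])
            crackle, wheeze = int(parts[2]), int(parts[3])
        except ValueError:
            raise ValueError(f"annotation row {idx}: non-numeric field") from None
        if end <= start:
            raise ValueError(f"annotation row {idx}: end {end} <= start {start}")
        if crackle not in (0, 1) or wheeze not in (0, 1):
            raise ValueError(f"annotation row {idx}: flags must be 0/1")
        annotations.append(CycleAnnotation(start, end, bool(crackle), bool(wheeze)))
    annotations.sort(key=lambda a: a.start_s)
    return annotations


def load_icbhi_recording(
    wav_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    resample_to: float | None = ANALYSIS_RATE,
) -> tuple[AudioSignal, list[CycleAnnotation]]:
    """Read a WAV recording plus its 4-column cycle annotation file.

    Annotation rows are whitespace-delimited ``start end crackle wheeze``.
    The recording is resampled to `resample_to` Hz (pass ``None`` to skip).
    """
    if not os.path.exists(wav_path):
        raise FileNotFoundError(str(wav_path))
    if not os.path.exists(annotation_path):
        raise FileNotFoundError(str(annotation_path))
    rate, raw = wavfile.read(wav_path)
    was_int = np.issubdtype(raw.dtype, np.integer)
    data = np.asarray(raw, dtype=float)
    if data.ndim == 2:  # average channels
        data = data.mean(axis=1)
    if was_int and np.abs(data).max() > 0:
        data = data / np.abs(data).max()
    if resample_to is not None and rate != resample_to:
        from fractions import Fraction

        frac = Fraction(int(round(resample_to)), int(rate)).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator)
        rate = resample_to
    with open(annotation_path) as fh:
        annotations = _parse_annotation_text(fh.read())
    stem = os.path.splitext(os.path.basename(os.fspath(wav_path)))[0]
    return AudioSignal(data, float(rate), source_id=stem), annotations


def _map_label(crackle: bool, wheeze: bool, scheme: LabelScheme) -> str | None:
    """Flag pair -> class name; ``None`` marks exclusion (both, three_class)."""
    if scheme.name == "two_class":
        return "normal" if not (crackle or wheeze) else "abnormal"
    if crackle and wheeze:
        return "both" if scheme.name == "four_class" else None
    if crackle:
        return "crackle"
    if wheeze:
        return "wheeze"
    return "normal"


def segment_cycles(
    signal: AudioSignal,
    annotations: Iterable[CycleAnnotation],
    scheme: LabelScheme,
) -> list[LabeledCycle]:
    """Cut [start, end) windows out of `signal` and label them under `scheme`."""
    cycles: list[LabeledCycle] = []
    n = signal.samples.size
    for ann in annotations:
        i0 = int(round(ann.start_s * signal.sample_rate))
        i1 = int(round(ann.end_s * signal.sample_rate))
        if i1 > n:
            raise ValueError(
                f"annotation [{ann.start_s}, {ann.end_s}) extends past the "
                f"recording ({signal.duration_s:.3f} s)"
            )
        label = _map_label(ann.crackle, ann.wheeze, scheme)
        if label is None:
            continue
        seg = AudioSignal(
            signal.samples[i0:i1],
            signal.sample_rate,
            source_id=f"{signal.source_id}[{ann.start_s:.3f}:{ann.end_s:.3f}]",
        )
        cycles.append(LabeledCycle(seg, label))
    return cycles


def normalize_minmax(signal: AudioSignal | np.ndarray) -> AudioSignal | np.ndarray:
    """Affine-map samples onto [0, 1]. Rejects constant signals."""
    arr = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant signal")
    out = (arr - lo) / (hi - lo)
    if isinstance(signal, AudioSignal):
        return AudioSignal(out, signal.sample_rate, signal.source_id)
    return out


# ---------------------------------------------------------------------------
# Synthesis


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float = 100.0, hi: float = 1000.0) -> np.ndarray:
    noise = rng.standard_normal(n)
    hi = min(hi, 0.45 * fs)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = sosfiltfilt(sos, noise)
    return out / out.std()


def _crackle_train(rng: np.random.Generator, n: int, fs: float,
                   rate: float) -> tuple[np.ndarray, int]:
    """Poisson-placed exponentially damped transients; returns (signal, count)."""
    duration = n / fs
    count = rng.poisson(rate * duration)
    out = np.zeros(n)
    for _ in range(count):
        t0 = int(rng.uniform(0, max(n - 1, 1)))
        width_s = rng.uniform(0.005, 0.010)  # 5-10 ms
        width = max(int(width_s * fs), 4)
        t = np.arange(width) / fs
        f0 = rng.uniform(200.0, min(800.0, 0.4 * fs))
        burst = np.exp(-t / (width_s / 4)) * np.sin(2 * np.pi * f0 * t)
        stop = min(t0 + width, n)
        out[t0:stop] += burst[: stop - t0]
    peak = np.abs(out).max()
    if peak > 0:
        out = out / peak
    return out, count


def _cycle_seed(master_seed: int, index: int) -> np.random.Generator:
    # counter-based splitting: reproducible regardless of generation order
    return np.random.Generator(np.random.Philox(key=master_seed, counter=index))


def synthesize_cycle(
    class_name: str,
    config: SynthConfig,
    seed: int | None = None,
    _return_detail: bool = False,
):
    """Generate one labeled synthetic cycle.

    normal  : Gaussian noise band-passed 100-1000 Hz
    wheeze  : normal + AM sinusoid at a seeded frequency, scaled to snr_db
    crackle : normal + Poisson-placed damped transients, scaled to snr_db
    both    : wheeze + crackle components
    """
    if class_name not in ("normal", "crackle", "wheeze", "both", "abnormal"):
        raise ValueError(f"unknown class name {class_name!r}")
    rng = _cycle_seed(config.seed if seed is None else seed, 0)
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    base = _bandlimited_noise(rng, n, fs)
    amp = 10.0 ** (config.snr_db / 20.0)  # component RMS relative to noise RMS
    detail: dict = {}

    sig = base.copy()
    effective = class_name
    if class_name == "abnormal":  # two_class stand-in: random adventitious type
        effective = ("crackle", "wheeze", "both")[rng.integers(3)]
    if effective in ("wheeze", "both"):
        f0 = rng.uniform(*config.wheeze_freq_range)
        t = np.arange(n) / fs
        am = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(2.0, 6.0) * t)
        tone = am * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        tone = tone / tone.std()
        sig = sig + amp * tone
        detail["wheeze_freq"] = f0
    if effective in ("crackle", "both"):
        train, count = _crackle_train(rng, n, fs, config.crackle_rate)
        if train.std() > 0:
            train = train / max(train.std(), 1e-12)
        sig = sig + amp * train
        detail["crackle_count"] = count

    out = LabeledCycle(
        AudioSignal(sig, fs, source_id=f"synth:{class_name}"), class_name
    )
    return (out, detail) if _return_detail else out


def synthesize_dataset(config: SynthConfig, scheme: LabelScheme) -> list[LabeledCycle]:
    """Balanced, seeded and shuffled synthetic dataset: n_per_class per label."""
    if config.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    cycles: list[LabeledCycle] = []
    counter = 1  # counter 0 reserved for single-cycle calls
    for label in scheme.classes:
        for _ in range(config.n_per_class):
            # derive a per-cycle integer seed from (master, counter)
            sub = int(
                _cycle_seed(config.seed, counter).integers(0, 2**31 - 1)
            )
            cycles.append(synthesize_cycle(label, config, seed=sub))
            counter += 1
    perm_rng = np.random.Generator(np.random.Philox(key=config.seed, counter=0))
    order = perm_rng.permutation(len(cycles))
    return [cycles[i] for i in order]


def pad_or_truncate(cycle: LabeledCycle, length_s: float = 2.5) -> LabeledCycle:
    """Zero-pad or truncate a cycle to a fixed analysis length."""
    fs = cycle.signal.sample_rate
    target = int(round(length_s * fs))
    x = cycle.signal.samples
    if x.size >= target:
        x = x[:target]
    else:
        x = np.pad(x, (0, target - x.size))
    return LabeledCycle(AudioSignal(x, fs, cycle.signal.source_id), cycle.label)


def write_wav(path: str | os.PathLike, signal: AudioSignal) -> None:
    x = signal.samples
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    wavfile.write(path, int(signal.sample_rate), (x * 32767).astype(np.int16))
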