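"""Signal decomposition: EMD sifting, paired-noise ensemble EMD (SEEMD),
variational mode decomposition (VMD) and distance-metric-driven mode-number
selection.

SEEMD adds q pairs of sign-opposed Gaussian white noises to the signal,
decomposes every noisy copy by plain EMD and averages matching modes over all
2q members, which cancels the injected noise in the ensemble mean.

VMD extracts K band-limited modes concurrently by alternating a spectral
Wiener-filter mode update with a centre-of-gravity frequency update under dual
ascent on the reconstruction constraint.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

from .signal_io_synth import AudioSignal, normalize_minmax

__all__ = [
    "IMFSet",
    "SEEMDConfig",
    "VMDConfig",
    "VMDResult",
    "DMVMDSelection",
    "emd",
    "seemd",
    "vmd",
    "similarity_index",
    "select_vmd_modes",
    "SIMILARITY_METRICS",
]


@dataclasses.dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the residual trend."""

    modes: list[np.ndarray]
    residual: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        for m in self.modes:
            if m.shape != (self.source_length,):
                raise ValueError("mode length != source_length")
        if self.residual.shape != (self.source_length,):
            raise ValueError("residual length != source_length")

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for m in self.modes:
            out += m
        return out

    @property
    def n_modes(self) -> int:
        return len(self.modes)


@dataclasses.dataclass
class SEEMDConfig:
    noise_std_fraction: float = 0.2
    ensemble_size: int = 10
    seed: int = 0
    max_imfs: int = 8

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not (0.02 <= self.noise_std_fraction <= 0.4):
            warnings.warn(
                "noise_std_fraction outside the recommended range [0.02, 0.4]",
                stacklevel=2,
            )


@dataclasses.dataclass
class VMDConfig:
    K: int = 3
    alpha: float = 300.0
    tau: float = 0.5
    tol: float = 1e-3
    max_iters: int = 500
    init: str = "uniform"  # center frequencies uniformly spaced over (0, Nyquist)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.tol <= 0:
            raise ValueError("alpha and tol must be positive")


@dataclasses.dataclass
class VMDResult:
    modes: np.ndarray  # (K, n)
    center_freqs: np.ndarray  # Hz, length K
    iterations: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return self.modes.sum(axis=0)


@dataclasses.dataclass
class DMVMDSelection:
    metric: str
    K_selected: int
    similarity_trace: dict[int, float]
    threshold: float
    converged: bool


# ---------------------------------------------------------------------------
# EMD


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    maxima = argrelextrema(x, np.greater_equal, order=1)[0]
    minima = argrelextrema(x, np.less_equal, order=1)[0]
    # drop plateaus duplicated by >=/<= comparators
    maxima = maxima[np.insert(np.diff(maxima) > 1, 0, True)] if maxima.size else maxima
    minima = minima[np.insert(np.diff(minima) > 1, 0, True)] if minima.size else minima
    # strict interior extrema only
    maxima = maxima[(maxima > 0) & (maxima < x.size - 1)]
    minima = minima[(minima > 0) & (minima < x.size - 1)]
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirrored end conditions."""
    n = x.size
    # mirror the first/last extremum across the signal ends
    pts = np.concatenate(([-idx[0]], idx, [2 * (n - 1) - idx[-1]]))
    vals = np.concatenate(([x[idx[0]]], x[idx], [x[idx[-1]]]))
    order = np.argsort(pts)
    pts, vals = pts[order], vals[order]
    keep = np.insert(np.diff(pts) > 0, 0, True)
    cs = CubicSpline(pts[keep], vals[keep])
    return cs(np.arange(n))


def _sift(x: np.ndarray, max_sifts: int = 50, sd_tol: float = 0.2) -> np.ndarray | None:
    """Extract one IMF by sifting; None when x has too few extrema."""
    h = x.copy()
    for _ in range(max_sifts):
        maxima, minima = _extrema_indices(h)
        if maxima.size < 2 or minima.size < 2:
            return None if h is x else h
        upper = _envelope(h, maxima)
        lower = _envelope(h, minima)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = np.sum(h**2)
        sd = np.sum(mean**2) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_tol:
            break
    return h


def emd(signal: AudioSignal | np.ndarray, max_imfs: int = 10) -> IMFSet:
    """Plain EMD. modes + residual reconstructs the input to float precision."""
    x = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, float)
    if x.size < 4:
        raise ValueError("signal too short for EMD")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    modes: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _extrema_indices(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        imf = _sift(residual)
        if imf is None:
            break
        modes.append(imf)
        residual = residual - imf
    return IMFSet(modes=modes, residual=residual, source_length=x.size)


def seemd(signal: AudioSignal | np.ndarray, config: SEEMDConfig) -> IMFSet:
    """Paired-noise ensemble EMD.

    For each ensemble member i a white noise N_i with std equal to
    ``noise_std_fraction * std(signal)`` is both added and subtracted; all 2q
    noisy copies are EMD-decomposed and matching modes averaged. Members with
    surplus modes have them folded into their residual so mode counts align
    at the ensemble minimum.
    """
    x = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, float)
    if x.std() == 0:
        raise ValueError("signal must be non-constant")
    q = config.ensemble_size
    rng = np.random.default_rng(config.seed)
    noise_std = config.noise_std_fraction * x.std()
    decomps: list[IMFSet] = []
    for _ in range(q):
        noise = rng.standard_normal(x.size) * noise_std
        decomps.append(emd(x + noise, config.max_imfs))
        decomps.append(emd(x - noise, config.max_imfs))
    n_modes = min(d.n_modes for d in decomps)
    modes = []
    for j in range(n_modes):
        modes.append(np.mean([d.modes[j] for d in decomps], axis=0))
    # fold surplus modes of deeper decompositions into their residuals
    residual = np.mean(
        [d.residual + sum(d.modes[n_modes:], np.zeros(x.size)) for d in decomps],
        axis=0,
    )
    return IMFSet(modes=modes, residual=residual, source_length=x.size)


# ---------------------------------------------------------------------------
# VMD


def vmd(
    signal: AudioSignal | np.ndarray,
    config: VMDConfig,
    sample_rate: float | None = None,
) -> VMDResult:
    """Variational mode decomposition by ADMM in the spectral domain.

    Each iteration applies the Wiener-filter mode update
    ``b_k = (d - sum_{j!=k} b_j + lam/2) / (1 + 2 alpha (w - w_k)^2)`` on the
    positive half-spectrum, recentres ``w_k`` at the mode's spectral centre of
    gravity, and dual-ascends the multiplier with step tau.
    """
    if isinstance(signal, AudioSignal):
        x = signal.samples
        fs = signal.sample_rate if sample_rate is None else sample_rate
    else:
        x = np.asarray(signal, float)
        fs = 1.0 if sample_rate is None else sample_rate
    K = config.K
    if x.size < 2 * K:
        raise ValueError("signal too short for the requested mode count")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")

    n0 = x.size
    # mirror extension halves boundary artefacts
    half = n0 // 2
    xm = np.concatenate([x[:half][::-1], x, x[-(n0 - half):][::-1]])
    n = xm.size
    freqs = np.arange(n // 2 + 1) / n  # cycles/sample, positive half
    f_hat = np.fft.rfft(xm)

    u_hat = np.zeros((K, freqs.size), dtype=complex)
    if config.init == "peaks":
        omega = _peak_frequencies(f_hat, freqs, K)
    else:  # uniform over (0, Nyquist)
        omega = (np.arange(K) + 1) / (K + 1) * 0.5
    lam = np.zeros(freqs.size, dtype=complex)

    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        u_prev = u_hat.copy()
        for k in range(K):
            others = u_hat.sum(axis=0) - u_hat[k]
            # bandwidth penalty in angular frequency (rad/sample)
            u_hat[k] = (f_hat - others + lam / 2) / (
                1 + 2 * config.alpha * (2 * np.pi * (freqs - omega[k])) ** 2
            )
            power = np.abs(u_hat[k]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = float((freqs * power).sum() / denom)
        lam = lam + config.tau * (f_hat - u_hat.sum(axis=0))
        num = np.sum(np.abs(u_hat - u_prev) ** 2)
        den = np.sum(np.abs(u_prev) ** 2)
        # relative L2 change of the mode set per iteration
        if den > 0 and np.sqrt(num / den) < config.tol:
            converged = True
            break
        if den == 0 and num == 0:
            converged = True
            break

    modes_m = np.fft.irfft(u_hat, n=n, axis=1)
    modes = modes_m[:, half : half + n0]
    order = np.argsort(omega)
    return VMDResult(
        modes=modes[order],
        center_freqs=omega[order] * fs,
        iterations=it,
        converged=converged,
    )


def _peak_frequencies(f_hat: np.ndarray, freqs: np.ndarray, K: int) -> np.ndarray:
    """K strongest well-separated spectral peaks (fallback: uniform grid)."""
    power = np.abs(f_hat) ** 2
    # light smoothing so side lobes do not count as peaks
    kernel = np.ones(5) / 5
    smooth = np.convolve(power, kernel, mode="same")
    order = np.argsort(smooth)[::-1]
    min_sep = max(freqs.size // (8 * K), 2)
    chosen: list[int] = []
    for idx in order:
        if all(abs(idx - j) >= min_sep for j in chosen):
            chosen.append(int(idx))
        if len(chosen) == K:
            break
    if len(chosen) < K:
        return (np.arange(K) + 1) / (K + 1) * 0.5
    return np.sort(freqs[np.array(chosen)])


# ---------------------------------------------------------------------------
# Distance-metric similarity


def _sim_euclidean(x: np.ndarray, y: np.ndarray) -> float:
    return 1.0 - float(np.sqrt(np.mean((x - y) ** 2)))


def _sim_manhattan(x: np.ndarray, y: np.ndarray) -> float:
    return 1.0 - float(np.mean(np.abs(x - y)))


def _sim_chebyshev(x: np.ndarray, y: np.ndarray) -> float:
    return 1.0 - float(np.max(np.abs(x - y)))


def _sim_jaccard(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.maximum(x, y).sum()
    if denom == 0:
        raise ValueError("jaccard similarity undefined for all-zero inputs")
    return float(np.minimum(x, y).sum() / denom)


def _sim_dice(x: np.ndarray, y: np.ndarray) -> float:
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("dice similarity undefined for all-zero inputs")
    return float(2 * np.minimum(x, y).sum() / denom)


SIMILARITY_METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "euclidean": _sim_euclidean,
    "manhattan": _sim_manhattan,
    "chebyshev": _sim_chebyshev,
    "jaccard": _sim_jaccard,
    "dice": _sim_dice,
}

_NORMALIZED_METRICS = {"euclidean", "manhattan", "chebyshev"}


def similarity_index(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Bounded [0, 1] similarity between two equal-length sequences.

    Metric distances (euclidean/manhattan/chebyshev) are applied to min-max
    normalized copies and mapped to ``1 - mean-per-sample distance``; Jaccard
    and Dice use the generalized fuzzy-set forms and need nonnegative inputs.
    Identical inputs give exactly 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if metric not in SIMILARITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric in _NORMALIZED_METRICS:
        if np.array_equal(x, y):
            return 1.0
        # each signal min-max normalized by its own range; constants pass
        # through unchanged (their range is degenerate)
        if x.max() > x.min():
            x = (x - x.min()) / (x.max() - x.min())
        if y.max() > y.min():
            y = (y - y.min()) / (y.max() - y.min())
    else:
        if (x < 0).any() or (y < 0).any():
            raise ValueError(f"{metric} requires nonnegative inputs")
    return max(0.0, min(1.0, SIMILARITY_METRICS[metric](x, y)))


def select_vmd_modes(
    signal: AudioSignal | np.ndarray,
    metric: str = "manhattan",
    threshold: float = 0.99,
    K_max: int = 8,
    vmd_config: VMDConfig | None = None,
    sample_rate: float | None = None,
) -> DMVMDSelection:
    """Pick the smallest K in 2..K_max whose VMD reconstruction reaches the
    similarity threshold; fall back to K_max (converged=False) otherwise."""
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    base = vmd_config or VMDConfig()
    # dual ascent forces exact reconstruction at ANY K, which would make the
    # similarity trace uninformative; the K search runs the constraint-free
    # (tau = 0) variant so the residual reflects what K modes actually cover.
    # Spectral-peak init keeps low-frequency components reachable.
    base = dataclasses.replace(base, tau=0.0, init="peaks")
    y = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, float)
    trace: dict[int, float] = {}
    for K in range(2, K_max + 1):
        cfg = dataclasses.replace(base, K=K)
        result = vmd(signal, cfg, sample_rate=sample_rate)
        y_hat = result.reconstruct()
        if metric in ("jaccard", "dice"):
            # fuzzy-set metrics need nonnegative sequences
            yh = y_hat if y_hat.max() == y_hat.min() else normalize_minmax(y_hat)
            sim = similarity_index(
                normalize_minmax(y), np.clip(yh, 0, 1), metric
            )
        else:
            sim = similarity_index(y, y_hat, metric)
        trace[K] = sim
        if sim >= threshold:
            return DMVMDSelection(metric, K, trace, threshold, converged=True)
    return DMVMDSelection(metric, K_max, trace, threshold, converged=False)


def normalize_minmax_like(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Apply ref's min-max affine map to x (shared scale for comparisons)."""
    lo, hi = ref.min(), ref.max()
    if hi == lo:
        raise ValueError("constant reference")
    return (x - lo) / (hi - lo)
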