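"""Per-mode descriptor features, the ensemble Granger+IMF feature vector,
and SVM-driven recursive feature elimination."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import kurtosis, skew
from sklearn.svm import LinearSVC

from .decomposition import IMFSet, SEEMDConfig, seemd
from .granger_mvar import granger_features
from .signal_io_synth import LabeledCycle

__all__ = [
    "FeatureMatrix",
    "RFERanking",
    "imf_features",
    "imf_feature_names",
    "ensemble_gssr_features",
    "svm_rfe",
    "spectral_band_features",
]

DESCRIPTORS_PER_MODE = 6


@dataclasses.dataclass
class FeatureMatrix:
    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


@dataclasses.dataclass
class RFERanking:
    ranked_indices: np.ndarray  # best -> worst
    elimination_trace: list[tuple[int, float]]  # (feature index, criterion)

    def top(self, k: int) -> np.ndarray:
        return self.ranked_indices[:k]


def _spectral_centroid(x: np.ndarray, fs: float) -> float:
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = spec.sum()
    return float((freqs * spec).sum() / total) if total > 0 else 0.0


def _mode_descriptors(x: np.ndarray, fs: float) -> np.ndarray:
    """energy, variance, skewness, kurtosis, zero-crossing rate, centroid."""
    energy = float(np.sum(x**2))
    var = float(np.var(x))
    if var > 0:
        sk = float(skew(x))
        ku = float(kurtosis(x))
    else:
        sk = ku = 0.0
    zcr = float(np.mean(np.abs(np.diff(np.signbit(x).astype(int)))))
    centroid = _spectral_centroid(x, fs)
    return np.array([energy, var, sk, ku, zcr, centroid])


def imf_features(imfset: IMFSet, sample_rate: float = 1.0) -> np.ndarray:
    """Six descriptors per mode, concatenated in mode order."""
    if imfset.n_modes == 0:
        raise ValueError("empty IMF set")
    return np.concatenate(
        [_mode_descriptors(m, sample_rate) for m in imfset.modes]
    )


def imf_feature_names(n_modes: int) -> list[str]:
    stats = ["energy", "variance", "skewness", "kurtosis", "zcr", "centroid"]
    return [f"imf{j}_{s}" for j in range(n_modes) for s in stats]


def ensemble_gssr_features(
    cycle: LabeledCycle,
    seemd_config: SEEMDConfig,
    mvar_order: int = 4,
) -> np.ndarray:
    """Concatenate MVAR coefficient features and per-mode descriptors computed
    from one shared SEEMD decomposition of the cycle."""
    x = cycle.signal.samples
    if x.std() == 0:
        raise ValueError("constant cycle")
    imfset = seemd(x, seemd_config)
    if imfset.n_modes < 2:
        raise ValueError("decomposition produced fewer than 2 modes")
    gr = granger_features(imfset, mvar_order)
    de = imf_features(imfset, cycle.signal.sample_rate)
    return np.concatenate([gr, de])


def spectral_band_features(x: np.ndarray, fs: float, n_bands: int = 16,
                           fmax: float | None = None) -> np.ndarray:
    """Log power in n_bands equal-width bands up to fmax (default Nyquist).

    Lightweight generic descriptor used by pipelines that need a feature
    space but whose contribution lies elsewhere (mask selection, DR, SRC).
    """
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    top = fmax if fmax is not None else fs / 2
    edges = np.linspace(0, top, n_bands + 1)
    out = np.empty(n_bands)
    for b in range(n_bands):
        mask = (freqs >= edges[b]) & (freqs < edges[b + 1])
        out[b] = np.log10(spec[mask].sum() + 1e-12)
    return out


def svm_rfe(
    features: np.ndarray,
    labels: np.ndarray,
    eliminate_per_round: int = 1,
    C: float = 1.0,
) -> RFERanking:
    """Recursive feature elimination ranked by linear-SVM weight magnitude.

    Each round trains a linear SVM on the surviving (z-scored) features,
    scores feature j by the squared weight w_j^2 (summed over one-vs-rest
    classifiers for multiclass) and removes the lowest-scoring features.
    Ties break toward the lower feature index. Constant features are
    eliminated first by convention.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if eliminate_per_round < 1:
        raise ValueError("eliminate_per_round must be >= 1")

    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    trace: list[tuple[int, float]] = []

    # constant columns carry no signal: drop them first
    const = [j for j in surviving if X[:, j].std() == 0]
    for j in sorted(const, reverse=False):
        trace.append((j, 0.0))
    eliminated.extend(const)
    surviving = [j for j in surviving if j not in set(const)]

    while surviving:
        if len(surviving) == 1:
            trace.append((surviving[0], np.inf))
            eliminated.append(surviving.pop())
            break
        sub = X[:, surviving]
        mu, sd = sub.mean(axis=0), sub.std(axis=0)
        sd[sd == 0] = 1.0
        sub = (sub - mu) / sd
        clf = LinearSVC(C=C, dual=False, max_iter=5000)
        clf.fit(sub, y)
        w = np.atleast_2d(clf.coef_)
        crit = (w**2).sum(axis=0)
        k = min(eliminate_per_round, len(surviving))
        # stable ties: argsort is stable, so equal criteria drop lower index first
        drop_local = np.argsort(crit, kind="stable")[:k]
        for loc in sorted(drop_local, key=lambda i: (crit[i], surviving[i])):
            trace.append((surviving[loc], float(crit[loc])))
        dropped = {surviving[loc] for loc in drop_local}
        eliminated.extend(sorted(dropped, key=lambda j: trace_index(trace, j)))
        surviving = [j for j in surviving if j not in dropped]

    ranked = np.array(eliminated[::-1], dtype=int)
    return RFERanking(ranked_indices=ranked, elimination_trace=trace)


def trace_index(trace: list[tuple[int, float]], j: int) -> int:
    for pos, (idx, _) in enumerate(trace):
        if idx == j:
            return pos
    raise KeyError(j)
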