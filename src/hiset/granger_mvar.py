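"""L2-norm multivariate autoregressive (MVAR) fitting and Granger-style
coefficient features.

For p channels and lag order l, each target channel k is regressed on the
lagged values of every channel via the normal equations; when the Gram matrix
is (near-)singular the Moore-Penrose pseudo-inverse branch is used instead.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .decomposition import IMFSet

__all__ = [
    "DesignMatrix",
    "MVARModel",
    "build_design_matrix",
    "fit_mvar",
    "granger_features",
    "granger_feature_names",
]

_RCOND_SINGULAR = 1e-10


@dataclasses.dataclass
class DesignMatrix:
    """(n-l) x (p*l) lagged-value regressor matrix, channel blocks stacked
    left to right, descending lags within each block."""

    C: np.ndarray
    order: int
    channels: int


@dataclasses.dataclass
class MVARModel:
    order: int
    channels: int
    coefficients: np.ndarray  # (p, p*l): row k = stacked X_k
    residual_variances: np.ndarray  # (p,)
    used_pseudo_inverse: bool


def build_design_matrix(channel_signals: list[np.ndarray] | np.ndarray,
                        order: int) -> DesignMatrix:
    """Build the lagged regressor matrix from equal-length channels.

    Block for channel i has rows ``z_i(l+r-1), ..., z_i(r)`` (r = 1..n-l),
    i.e. most recent lag first.
    """
    channels = [np.asarray(z, float) for z in channel_signals]
    n = channels[0].size
    if any(z.size != n for z in channels):
        raise ValueError("channels must have equal length")
    if order >= n:
        raise ValueError(f"order {order} >= signal length {n}")
    if order < 1:
        raise ValueError("order must be >= 1")
    blocks = []
    for z in channels:
        block = np.column_stack(
            [z[order - 1 - j : n - 1 - j] for j in range(order)]
        )
        blocks.append(block)
    return DesignMatrix(np.hstack(blocks), order, len(channels))


def fit_mvar(channel_signals: list[np.ndarray] | np.ndarray,
             order: int) -> MVARModel:
    """Least-squares MVAR fit per target channel."""
    channels = [np.asarray(z, float) for z in channel_signals]
    if any(not np.all(np.isfinite(z)) for z in channels):
        raise ValueError("non-finite inputs")
    design = build_design_matrix(channels, order)
    C = design.C
    p, l = design.channels, design.order
    n = channels[0].size
    if n - l < p * l:
        warnings.warn(
            f"underdetermined fit: {n - l} rows for {p * l} coefficients",
            stacklevel=2,
        )
    gram = C.T @ C
    rcond = 1.0 / np.linalg.cond(gram) if gram.size else 0.0
    use_pinv = not np.isfinite(rcond) or rcond < _RCOND_SINGULAR
    solver = np.linalg.pinv(gram) @ C.T if use_pinv else None

    coefs = np.empty((p, p * l))
    resid_var = np.empty(p)
    for k, z in enumerate(channels):
        y_k = z[l:]
        if use_pinv:
            x_k = solver @ y_k
        else:
            x_k = np.linalg.solve(gram, C.T @ y_k)
        coefs[k] = x_k
        resid = y_k - C @ x_k
        resid_var[k] = float(np.mean(resid**2))
    return MVARModel(l, p, coefs, resid_var, use_pinv)


def granger_features(imfset: IMFSet, order: int = 4) -> np.ndarray:
    """Treat the IMFs as MVAR channels and return all stacked coefficient
    vectors (length p^2 * l) followed by the p residual variances."""
    if imfset.n_modes < 2:
        raise ValueError("need at least 2 modes to fit a multichannel model")
    model = fit_mvar(imfset.modes, order)
    return np.concatenate([model.coefficients.ravel(), model.residual_variances])


def granger_feature_names(p: int, order: int) -> list[str]:
    names = [
        f"mvar_k{k}_p{i}_lag{j}"
        for k in range(p)
        for i in range(p)
        for j in range(1, order + 1)
    ]
    names += [f"mvar_residvar_k{k}" for k in range(p)]
    return names
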