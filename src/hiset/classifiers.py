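"""Learners: extreme learning machine, K-SVD dictionary learning, the
realm-revamping sparse-representation classifier, a KL-sparse autoencoder,
grey-wolf-tuned SVC, and the sensitivity/specificity/accuracy report."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.linear_model import orthogonal_mp_gram
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .metaheuristics import ObjectiveSpec, SwarmConfig, gwo

__all__ = [
    "ELMModel",
    "elm_train",
    "elm_predict",
    "SRCDictionary",
    "ksvd",
    "RealmModel",
    "rrsrc_fit",
    "rrsrc_classify",
    "src_classify",
    "SAEConfig",
    "SAEModel",
    "sae_train",
    "sae_encode",
    "sae_reconstruct",
    "gwo_svc_tune",
    "MetricsReport",
    "compute_metrics",
]


# ---------------------------------------------------------------------------
# Extreme learning machine


@dataclasses.dataclass
class ELMModel:
    input_weights: np.ndarray  # (L, n_features), uniform [-1, 1]
    biases: np.ndarray  # (L,)
    output_weights: np.ndarray  # (L, n_outputs)
    classes: np.ndarray | None  # None for regression targets


def _sigmoid(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def _elm_hidden(model_w: np.ndarray, b: np.ndarray, X: np.ndarray) -> np.ndarray:
    return _sigmoid(X @ model_w.T + b)


def elm_train(
    X: np.ndarray,
    targets: np.ndarray,
    hidden_count: int = 30,
    seed: int = 0,
    classification: bool = True,
) -> ELMModel:
    """Single-hidden-layer network: random sigmoid hidden layer, output
    weights solved in closed form via the pseudo-inverse.

    Classification targets are one-hot encoded internally; pass
    ``classification=False`` to regress on `targets` directly.
    """
    X = np.asarray(X, float)
    if hidden_count < 1:
        raise ValueError("hidden_count must be >= 1")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1, 1, size=(hidden_count, X.shape[1]))
    b = rng.uniform(-1, 1, size=hidden_count)
    if classification:
        classes = np.unique(targets)
        T = (np.asarray(targets)[:, None] == classes[None, :]).astype(float)
    else:
        classes = None
        T = np.atleast_2d(np.asarray(targets, float))
        if T.shape[0] == 1:
            T = T.T
    H = _elm_hidden(w, b, X)
    beta = np.linalg.pinv(H) @ T
    return ELMModel(w, b, beta, classes)


def elm_predict(
    model: ELMModel, X: np.ndarray, return_scores: bool = False
):
    X = np.asarray(X, float)
    if X.shape[1] != model.input_weights.shape[1]:
        raise ValueError("feature dimension mismatch")
    scores = _elm_hidden(model.input_weights, model.biases, X) @ model.output_weights
    if model.classes is None:
        return scores
    labels = model.classes[np.argmax(scores, axis=1)]
    return (labels, scores) if return_scores else labels


# ---------------------------------------------------------------------------
# K-SVD


@dataclasses.dataclass
class SRCDictionary:
    atoms: np.ndarray  # (d, m), unit-norm columns
    sparsity: int
    class_index: np.ndarray  # (m,) class id per atom; -1 when untagged
    objective_trace: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )


def _omp_codes(D: np.ndarray, X: np.ndarray, l0: int) -> np.ndarray:
    import warnings as _warnings

    gram = D.T @ D
    cov = D.T @ X
    with _warnings.catch_warnings():
        # near-duplicate atoms make OMP stop early; that is fine here
        _warnings.simplefilter("ignore", RuntimeWarning)
        codes = orthogonal_mp_gram(
            gram, cov, n_nonzero_coefs=min(l0, D.shape[1])
        )
    return np.atleast_2d(codes).reshape(D.shape[1], -1)


def ksvd(
    X: np.ndarray,
    n_atoms: int,
    l0: int,
    iters: int = 15,
    seed: int = 0,
) -> SRCDictionary:
    """Alternating OMP sparse coding and rank-1 SVD atom updates.

    The Frobenius objective ||X - DC||_F^2 is non-increasing across sweeps and
    atoms are renormalized to unit norm after every update.
    """
    X = np.asarray(X, float)
    d, n = X.shape
    if n_atoms > n:
        raise ValueError("n_atoms must not exceed the number of samples")
    if l0 < 1:
        raise ValueError("l0 must be >= 1")
    rng = np.random.default_rng(seed)
    # init atoms from random data columns
    D = X[:, rng.choice(n, size=n_atoms, replace=False)].astype(float).copy()
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = 1.0
    D /= norms

    trace = []
    C = _omp_codes(D, X, l0)
    for _ in range(iters):
        for k in range(n_atoms):
            users = np.nonzero(C[k])[0]
            if users.size == 0:
                # replace dead atom with the worst-represented sample
                errs = np.sum((X - D @ C) ** 2, axis=0)
                j = int(np.argmax(errs))
                atom = X[:, j]
                nrm = np.linalg.norm(atom)
                D[:, k] = atom / nrm if nrm > 0 else atom
                continue
            E = X[:, users] - D @ C[:, users] + np.outer(D[:, k], C[k, users])
            try:
                u, s, vt = np.linalg.svd(E, full_matrices=False)
            except np.linalg.LinAlgError:
                continue
            D[:, k] = u[:, 0]
            C[k, users] = s[0] * vt[0]
        C_new = _omp_codes(D, X, l0)
        # OMP is greedy and can occasionally worsen a column; keep the old
        # code there so the objective is monotone non-increasing
        err_old = np.sum((X - D @ C) ** 2, axis=0)
        err_new = np.sum((X - D @ C_new) ** 2, axis=0)
        keep_old = err_old < err_new
        C = np.where(keep_old[None, :], C, C_new)
        trace.append(float(np.sum((X - D @ C) ** 2)))
    return SRCDictionary(
        atoms=D,
        sparsity=l0,
        class_index=np.full(n_atoms, -1),
        objective_trace=np.array(trace),
    )


def ksvd_per_class(
    X: np.ndarray,
    y: np.ndarray,
    atoms_per_class: int = 10,
    l0: int = 3,
    iters: int = 10,
    seed: int = 0,
) -> SRCDictionary:
    """Class-tagged dictionary: an independent K-SVD per class, concatenated."""
    classes = np.unique(y)
    atom_blocks, tags = [], []
    for ci, c in enumerate(classes):
        Xc = X[:, y == c]
        m = min(atoms_per_class, Xc.shape[1])
        if m == Xc.shape[1]:
            block = Xc.copy().astype(float)
            norms = np.linalg.norm(block, axis=0)
            norms[norms == 0] = 1.0
            block = block / norms
        else:
            block = ksvd(Xc, m, min(l0, m), iters, seed=seed + ci).atoms
        atom_blocks.append(block)
        tags.extend([ci] * block.shape[1])
    return SRCDictionary(
        atoms=np.hstack(atom_blocks),
        sparsity=l0,
        class_index=np.array(tags),
    )


# ---------------------------------------------------------------------------
# Realm-revamping SRC


@dataclasses.dataclass
class RealmModel:
    source_projection: np.ndarray  # (d_sub, d), orthonormal rows
    target_projection: np.ndarray  # (d_sub, d)
    source_laplacian: np.ndarray
    target_laplacian: np.ndarray
    dictionary: SRCDictionary
    classes: np.ndarray
    kernel_sigma: float
    source_mean: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(0)
    )
    target_mean: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(0)
    )
    ridge: float = 1e-3


def _knn_gaussian_graph(
    X: np.ndarray, k: int, sigma: float, prune_below: float | None = None
) -> np.ndarray:
    """Symmetric Gaussian-kernel KNN similarity graph over columns of X."""
    n = X.shape[1]
    sq = np.sum(X**2, axis=0)
    d2 = sq[:, None] + sq[None, :] - 2 * X.T @ X
    np.fill_diagonal(d2, np.inf)
    H = np.zeros((n, n))
    k = min(k, n - 1)
    for j in range(n):
        nbrs = np.argsort(d2[:, j], kind="stable")[:k]
        H[nbrs, j] = np.exp(-d2[nbrs, j] / sigma)
    H = np.maximum(H, H.T)
    if prune_below is not None:
        H[H < prune_below] = 0.0
    return H


def _graph_laplacian(H: np.ndarray) -> np.ndarray:
    return np.diag(H.sum(axis=1)) - H


def _projection_from_graph(
    Z: np.ndarray, L: np.ndarray, alpha: float, d_sub: int
) -> np.ndarray:
    """Rows = eigenvectors of Z (L - alpha I) Z^T for the d_sub smallest
    eigenvalues; orthonormal by construction (symmetric eigenproblem)."""
    A = Z @ (L - alpha * np.eye(Z.shape[1])) @ Z.T
    A = 0.5 * (A + A.T)
    if d_sub > A.shape[0]:
        raise ValueError("subspace dimension exceeds feature dimension")
    vals, vecs = eigh(A, subset_by_index=(0, d_sub - 1))
    return vecs.T


def rrsrc_fit(
    Xs: np.ndarray,
    ys: np.ndarray,
    Xt: np.ndarray,
    yt: np.ndarray,
    d_sub: int = 50,
    alpha_reg: float = 1.0,
    sigma: float | None = None,
    knn_k: int = 5,
    edge_threshold: float = 0.6,
    atoms_per_class: int = 10,
    l0: int = 3,
    center: bool = True,
    basis_align_weight: float = 0.2,
    seed: int = 0,
) -> RealmModel:
    """Learn source/target projections and a shared class-tagged dictionary.

    Source similarity uses a Gaussian-kernel KNN graph (edges with similarity
    below `edge_threshold` pruned); the target graph connects same-class
    labelled pairs with unit weight. Each projection minimizes the graph-
    locality trace penalty minus an `alpha_reg`-weighted variance (PCA) term
    under row orthonormality, solved as a symmetric eigenproblem. The shared
    dictionary is learned per class on the projected labelled samples of both
    realms.
    """
    Xs = np.asarray(Xs, float)
    Xt = np.asarray(Xt, float)
    ys = np.asarray(ys)
    yt = np.asarray(yt)
    if Xs.shape[0] != Xt.shape[0]:
        raise ValueError("source and target must share the feature dimension")
    classes = np.unique(ys)
    if not set(np.unique(yt)) <= set(classes):
        raise ValueError("target labels outside the source label set")
    for c in classes:
        if not np.any(yt == c):
            raise ValueError(f"target realm has no labelled sample of class {c!r}")

    # per-realm centering removes the inter-realm mean offset up front;
    # disable to keep classification homogeneous in the raw query
    if center:
        mean_s = Xs.mean(axis=1)
        mean_t = Xt.mean(axis=1)
        Xs = Xs - mean_s[:, None]
        Xt = Xt - mean_t[:, None]
    else:
        mean_s = np.zeros(Xs.shape[0])
        mean_t = np.zeros(Xt.shape[0])

    if sigma is None:
        sq = np.sum(Xs**2, axis=0)
        d2 = sq[:, None] + sq[None, :] - 2 * Xs.T @ Xs
        sigma = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0

    Hs = _knn_gaussian_graph(Xs, knn_k, sigma, prune_below=edge_threshold)
    Ht = (yt[:, None] == yt[None, :]).astype(float)
    np.fill_diagonal(Ht, 0.0)
    Ls = _graph_laplacian(Hs)
    Lt = _graph_laplacian(Ht)

    Ms = _projection_from_graph(Xs, Ls, alpha_reg, d_sub)
    Mt = _projection_from_graph(Xt, Lt, alpha_reg, d_sub)

    # refinement pass: the two eigen-bases are each defined only up to an
    # orthogonal transform, so rotate the target basis onto the source frame
    # (orthogonal Procrustes on per-class means) before sharing a dictionary
    mus = np.column_stack([(Ms @ Xs[:, ys == c]).mean(axis=1) for c in classes])
    mut = np.column_stack([(Mt @ Xt[:, yt == c]).mean(axis=1) for c in classes])
    cross_mean = mus @ mut.T
    cross_basis = Ms @ Mt.T  # identity-direction correspondences
    nm = np.linalg.norm(cross_mean)
    nb = np.linalg.norm(cross_basis)
    # class means carry the label correspondence and dominate; the basis
    # gram only pins down rotation components the rank-|classes| mean
    # constraint leaves free
    corr = (cross_mean / nm if nm > 0 else 0) + basis_align_weight * (
        cross_basis / nb if nb > 0 else 0
    )
    u, _, vt = np.linalg.svd(corr)
    Mt = (u @ vt) @ Mt

    proj = np.hstack([Ms @ Xs, Mt @ Xt])
    labels = np.concatenate([ys, yt])
    tagged = ksvd_per_class(
        proj, labels, atoms_per_class=atoms_per_class, l0=l0, seed=seed
    )
    return RealmModel(
        source_projection=Ms,
        target_projection=Mt,
        source_laplacian=Ls,
        target_laplacian=Lt,
        dictionary=tagged,
        classes=classes,
        kernel_sigma=sigma,
        source_mean=mean_s,
        target_mean=mean_t,
    )


def _ridge_code(D: np.ndarray, v: np.ndarray, mu: float) -> np.ndarray:
    m = D.shape[1]
    return np.linalg.solve(D.T @ D + mu * np.eye(m), D.T @ v)


def _class_residual_label(
    D: np.ndarray, class_index: np.ndarray, classes: np.ndarray,
    v: np.ndarray, code: np.ndarray,
) -> object:
    best_label, best_score = None, np.inf
    for ci, c in enumerate(classes):
        mask = class_index == ci
        part = np.zeros_like(code)
        part[mask] = code[mask]
        nrm = float(np.sum(part**2))
        if nrm == 0:
            continue
        resid = float(np.sum((v - D @ part) ** 2)) / nrm
        if resid < best_score:
            best_score, best_label = resid, c
    if best_label is None:
        raise ValueError("all classes skipped: zero coefficient vector")
    return best_label


def rrsrc_classify(model: RealmModel, z: np.ndarray, mu: float = 1e-3):
    """Ridge-coded class-residual-ratio label for a target-realm query."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    z = np.asarray(z, float)
    if model.target_mean.size:
        z = z - model.target_mean
    v = model.target_projection @ z
    code = _ridge_code(model.dictionary.atoms, v, mu)
    return _class_residual_label(
        model.dictionary.atoms, model.dictionary.class_index, model.classes,
        v, code,
    )


def src_classify(
    dictionary: SRCDictionary, classes: np.ndarray, z: np.ndarray,
    mu: float = 1e-3,
) -> object:
    """Plain (projection-free) SRC baseline over a class-tagged dictionary."""
    z = np.asarray(z, float)
    code = _ridge_code(dictionary.atoms, z, mu)
    return _class_residual_label(
        dictionary.atoms, dictionary.class_index, classes, z, code
    )


# ---------------------------------------------------------------------------
# Sparse autoencoder


@dataclasses.dataclass
class SAEConfig:
    hidden: int = 16
    sparsity_target: float = 0.05
    sparsity_weight: float = 0.1
    learning_rate: float = 0.04
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sparsity_target < 1):
            raise ValueError("sparsity_target must lie in (0, 1)")


@dataclasses.dataclass
class SAEModel:
    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    loss_trace: np.ndarray
    config: SAEConfig


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    rho_hat = np.clip(rho_hat, 1e-12, 1 - 1e-12)
    return rho * np.log(rho / rho_hat) + (1 - rho) * np.log(
        (1 - rho) / (1 - rho_hat)
    )


def _sae_loss(X: np.ndarray, model_parts, rho: float, beta: float):
    W1, b1, W2, b2 = model_parts
    A = _sigmoid(X @ W1 + b1)
    out = np.maximum(A @ W2 + b2, 0.0)  # ReLU output layer
    rho_hat = A.mean(axis=0)
    recon = float(np.mean(np.sum((out - X) ** 2, axis=1)))
    return recon + beta * float(np.sum(kl_sparsity(rho, rho_hat))), A, out, rho_hat


def sae_train(X: np.ndarray, config: SAEConfig) -> SAEModel:
    """Minibatch gradient descent on reconstruction error plus a KL
    activation-sparsity penalty. Hidden layer is sigmoid (KL needs (0,1)
    activations); the output layer is ReLU. Inputs should be scaled to [0,1].
    """
    X = np.asarray(X, float)
    n, d = X.shape
    rng = np.random.default_rng(config.seed)
    h = config.hidden
    W1 = rng.normal(0, 0.3, size=(d, h))
    # centre hidden pre-activations at 0 where the sigmoid has gradient
    b1 = -(X.mean(axis=0) @ W1)
    W2 = rng.normal(0, 0.3, size=(h, d))
    # start the ReLU output at the data mean so units are born alive
    b2 = X.mean(axis=0).copy()
    rho, beta, eta = (
        config.sparsity_target,
        config.sparsity_weight,
        config.learning_rate,
    )

    losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb = X[idx]
            m = Xb.shape[0]
            Z1 = Xb @ W1 + b1
            A = _sigmoid(Z1)
            Z2 = A @ W2 + b2
            out = np.maximum(Z2, 0.0)
            rho_hat = np.clip(A.mean(axis=0), 1e-12, 1 - 1e-12)

            d_out = 2.0 * (out - Xb) * (Z2 > 0) / m
            gW2 = A.T @ d_out
            gb2 = d_out.sum(axis=0)
            dA = d_out @ W2.T
            dkl = beta * (-rho / rho_hat + (1 - rho) / (1 - rho_hat)) / m
            dZ1 = (dA + dkl) * A * (1 - A)
            gW1 = Xb.T @ dZ1
            gb1 = dZ1.sum(axis=0)

            W1 -= eta * gW1
            b1 -= eta * gb1
            W2 -= eta * gW2
            b2 -= eta * gb2
        losses[epoch], *_ = _sae_loss(X, (W1, b1, W2, b2), rho, beta)
    return SAEModel(W1, b1, W2, b2, losses, config)


def sae_encode(model: SAEModel, X: np.ndarray) -> np.ndarray:
    return _sigmoid(np.asarray(X, float) @ model.W_enc + model.b_enc)


def sae_reconstruct(model: SAEModel, X: np.ndarray) -> np.ndarray:
    return np.maximum(sae_encode(model, X) @ model.W_dec + model.b_dec, 0.0)


# ---------------------------------------------------------------------------
# GWO-tuned SVC


def gwo_svc_tune(
    X: np.ndarray,
    y: np.ndarray,
    wolves: int = 50,
    iters: int = 20,
    cv_folds: int = 3,
    seed: int = 0,
):
    """Search log10(c), log10(g) in [-3, 3] by GWO with inner-CV error as
    fitness; returns (refit Gaussian-kernel SVC, c, g)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")

    def cv_error(params: np.ndarray) -> float:
        c = 10.0 ** params[0]
        g = 10.0 ** params[1]
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        errs = []
        for tr, te in skf.split(X, y):
            clf = SVC(C=c, gamma=g, kernel="rbf")
            clf.fit(X[tr], y[tr])
            errs.append(1.0 - clf.score(X[te], y[te]))
        return float(np.mean(errs))

    spec = ObjectiveSpec(2, -3.0, 3.0, cv_error)
    result = gwo(spec, SwarmConfig(pop_size=wolves, max_iters=iters, seed=seed))
    c = 10.0 ** result.best_candidate[0]
    g = 10.0 ** result.best_candidate[1]
    clf = SVC(C=c, gamma=g, kernel="rbf")
    clf.fit(X, y)
    return clf, c, g


# ---------------------------------------------------------------------------
# Metrics


@dataclasses.dataclass
class MetricsReport:
    classes: list
    per_class: dict  # class -> dict(tp, tn, fp, fn, sensitivity, specificity, accuracy)
    sensitivity: float  # macro, percent
    specificity: float
    accuracy: float  # overall (correct / n), percent
    n_samples: int


def compute_metrics(y_true: Sequence, y_pred: Sequence,
                    classes: Sequence | None = None) -> MetricsReport:
    """One-vs-rest confusion counts per class; sensitivity TP/(TP+FN),
    specificity TN/(TN+FP), accuracy (TP+TN)/n, all in percent; macro
    averages across classes; overall accuracy = share of correct labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = list(classes)
    n = y_true.size
    per_class = {}
    sens, spec = [], []
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        tn = n - tp - fn - fp
        se = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
        acc = 100.0 * (tp + tn) / n
        per_class[c] = dict(
            tp=tp, tn=tn, fp=fp, fn=fn,
            sensitivity=se, specificity=sp, accuracy=acc,
        )
        sens.append(se)
        spec.append(sp)
    overall = 100.0 * float(np.mean(y_true == y_pred))
    return MetricsReport(
        classes=classes,
        per_class=per_class,
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spec)),
        accuracy=overall,
        n_samples=n,
    )
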