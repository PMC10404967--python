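"""End-to-end strategy pipelines with stratified cross-validation.

Six strategies share one harness:

* ``gssr``        — SEEMD + MVAR features, SVM-RFE, base classifier
* ``rrsrc``       — realm split, projection learning, shared-dictionary SRC
* ``dmvmd_elm``   — normalized signals, distance-metric VMD mode selection,
                    per-mode descriptors, ELM with three residual-correction
                    stages summed into the final score
* ``hho_sfpde``   — nested-metaheuristic binary feature mask, base classifier
* ``dr_gwo_svc``  — dimensionality reduction + grey-wolf-tuned SVC
* ``dr_goa_sae``  — dimensionality reduction + grasshopper feature mask +
                    sparse-autoencoder encoding + linear head

Everything fit inside a fold sees training samples only; feature extraction
itself is per-cycle and unsupervised.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import classifiers as clf
from . import decomposition as dec
from . import feature_selection as fs
from . import granger_mvar as gm
from . import metaheuristics as mh
from .signal_io_synth import LabeledCycle, LabelScheme, normalize_minmax

__all__ = [
    "StrategyConfig",
    "CVResult",
    "STRATEGIES",
    "run_strategy",
    "cross_validate",
]

STRATEGIES = ("gssr", "rrsrc", "dmvmd_elm", "hho_sfpde", "dr_gwo_svc", "dr_goa_sae")


@dataclasses.dataclass
class StrategyConfig:
    strategy: str
    scheme: LabelScheme
    cv_folds: int = 10
    seed: int = 0
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclasses.dataclass
class CVResult:
    fold_reports: list[clf.MetricsReport]
    fold_assignments: np.ndarray  # fold id per sample
    accuracy: float  # mean of per-fold overall accuracies, percent
    sensitivity: float  # mean of per-fold macro sensitivities
    specificity: float
    config_snapshot: dict

    def to_json(self) -> str:
        payload = dict(
            accuracy=self.accuracy,
            sensitivity=self.sensitivity,
            specificity=self.specificity,
            folds=[
                dict(
                    accuracy=r.accuracy,
                    sensitivity=r.sensitivity,
                    specificity=r.specificity,
                    n=r.n_samples,
                )
                for r in self.fold_reports
            ],
            config=self.config_snapshot,
        )
        return json.dumps(payload, indent=2)


def _base_classifier(name: str, seed: int):
    name = name.lower()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "nbc":
        return GaussianNB()
    if name == "svm":
        return SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed)
    raise ValueError(f"unknown base classifier {name!r}")


def _zscore_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


# ---------------------------------------------------------------------------
# Per-strategy feature extraction (per-cycle, unsupervised)


def _extract_gssr(dataset: Sequence[LabeledCycle], params: dict,
                  seed: int) -> np.ndarray:
    cfg = dec.SEEMDConfig(
        noise_std_fraction=params.get("noise_std_fraction", 0.2),
        ensemble_size=params.get("ensemble_size", 2),
        max_imfs=params.get("max_imfs", 5),
        seed=seed,
    )
    order = params.get("mvar_order", 2)
    n_modes = params.get("n_modes", 4)
    rows = []
    for cycle in dataset:
        imfset = dec.seemd(cycle.signal.samples, cfg)
        # fixed channel count so feature vectors are commensurate
        modes = imfset.modes[:n_modes]
        while len(modes) < n_modes:
            modes = modes + [imfset.residual]
        trimmed = dec.IMFSet(list(modes), imfset.residual, imfset.source_length)
        rows.append(
            np.concatenate(
                [
                    gm.granger_features(trimmed, order),
                    fs.imf_features(trimmed, cycle.signal.sample_rate),
                ]
            )
        )
    return np.vstack(rows)


def _extract_band(dataset: Sequence[LabeledCycle], params: dict) -> np.ndarray:
    n_bands = params.get("n_bands", 24)
    return np.vstack(
        [
            fs.spectral_band_features(
                c.signal.samples, c.signal.sample_rate, n_bands=n_bands
            )
            for c in dataset
        ]
    )


class _VMDFeatureCache:
    """Per-(cycle, K) VMD features so folds sharing a selected K reuse work."""

    def __init__(self, dataset: Sequence[LabeledCycle], vmd_cfg: dec.VMDConfig):
        self.dataset = dataset
        self.vmd_cfg = vmd_cfg
        self.normalized = [
            normalize_minmax(c.signal.samples) for c in dataset
        ]
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def features(self, idx: int, K: int) -> np.ndarray:
        key = (idx, K)
        if key not in self._cache:
            cfg = dataclasses.replace(self.vmd_cfg, K=K)
            fsr = self.dataset[idx].signal.sample_rate
            result = dec.vmd(self.normalized[idx], cfg, sample_rate=fsr)
            imfset = dec.IMFSet(
                list(result.modes),
                self.normalized[idx] - result.reconstruct(),
                self.normalized[idx].size,
            )
            feat = fs.imf_features(imfset, fsr)
            self._cache[key] = np.concatenate([feat, result.center_freqs])
        return self._cache[key]

    def matrix(self, indices: np.ndarray, K: int) -> np.ndarray:
        return np.vstack([self.features(int(i), K) for i in indices])


# ---------------------------------------------------------------------------
# Fold fitting: every builder returns predict(X_test_rows) -> labels


def _fit_generic(
    X: np.ndarray, y: np.ndarray, base: str, seed: int
) -> Callable[[np.ndarray], np.ndarray]:
    mu, sd = _zscore_fit(X)
    model = _base_classifier(base, seed)
    model.fit((X - mu) / sd, y)
    return lambda Xt: model.predict((Xt - mu) / sd)


def _fit_gssr(X, y, params, seed):
    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    keep = min(params.get("keep_features", 30), X.shape[1])
    ranking = fs.svm_rfe(Xz, y, eliminate_per_round=params.get(
        "eliminate_per_round", max(1, X.shape[1] // 20)))
    idx = ranking.top(keep)
    model = _base_classifier(params.get("base_classifier", "svm"), seed)
    model.fit(Xz[:, idx], y)
    return lambda Xt: model.predict(((Xt - mu) / sd)[:, idx])


def _fit_rrsrc(X, y, params, seed):
    mu, sd = _zscore_fit(X)
    Xz = ((X - mu) / sd).T  # columns = samples
    rng = np.random.default_rng(seed)
    n = Xz.shape[1]
    perm = rng.permutation(n)
    n_src = max(int(round(params.get("source_fraction", 0.7) * n)), 1)
    src, tgt = perm[:n_src], perm[n_src:]
    # ensure every class is present in both realms
    labels = np.asarray(y)
    for c in np.unique(labels):
        if not np.any(labels[src] == c):
            move = tgt[labels[tgt] == c][:1]
            src = np.concatenate([src, move])
            tgt = np.setdiff1d(tgt, move)
        if not np.any(labels[tgt] == c):
            move = src[labels[src] == c][:1]
            tgt = np.concatenate([tgt, move])
            src = np.setdiff1d(src, move)
    n_labelled = params.get("target_labelled_per_class", 5)
    t_lab = np.concatenate(
        [tgt[labels[tgt] == c][:n_labelled] for c in np.unique(labels)]
    )
    model = clf.rrsrc_fit(
        Xz[:, src], labels[src], Xz[:, t_lab], labels[t_lab],
        d_sub=min(params.get("d_sub", 16), X.shape[1]),
        alpha_reg=params.get("alpha_reg", 10.0),
        knn_k=params.get("knn_k", 5),
        edge_threshold=params.get("edge_threshold", 0.6),
        atoms_per_class=params.get("atoms_per_class", 40),
        l0=params.get("l0", 3),
        basis_align_weight=params.get("basis_align_weight", 0.2),
        seed=seed,
    )
    mu_ = params.get("mu", 0.5)

    def predict(Xt):
        Zt = ((Xt - mu) / sd).T
        return np.array(
            [clf.rrsrc_classify(model, Zt[:, j], mu_) for j in range(Zt.shape[1])]
        )

    return predict


def _fit_dmvmd_elm(train_idx, y, cache: _VMDFeatureCache, params, seed):
    metric = params.get("metric", "manhattan")
    threshold = params.get("threshold", 0.97)
    K_max = params.get("K_max", 6)
    n_probe = min(params.get("selection_probes", 5), len(train_idx))
    ks = []
    for i in train_idx[:n_probe]:
        sel = dec.select_vmd_modes(
            cache.normalized[int(i)],
            metric=metric,
            threshold=threshold,
            K_max=K_max,
            vmd_config=cache.vmd_cfg,
            sample_rate=cache.dataset[int(i)].signal.sample_rate,
        )
        ks.append(sel.K_selected)
    K = int(round(float(np.median(ks))))

    X = cache.matrix(train_idx, K)
    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    L = params.get("hidden_count", 30)
    stages = params.get("residual_stages", 3)

    classes = np.unique(y)
    T = (np.asarray(y)[:, None] == classes[None, :]).astype(float)
    models = []
    main = clf.elm_train(Xz, y, hidden_count=L, seed=seed)
    scores = clf.elm_predict(main, Xz, return_scores=True)[1]
    total = scores.copy()
    for s in range(stages):
        resid = T - total
        stage = clf.elm_train(
            Xz, resid, hidden_count=L, seed=seed + s + 1, classification=False
        )
        models.append(stage)
        total = total + clf.elm_predict(stage, Xz)

    def predict(test_idx):
        Xt = (cache.matrix(test_idx, K) - mu) / sd
        score = clf.elm_predict(main, Xt, return_scores=True)[1]
        for stage in models:
            score = score + clf.elm_predict(stage, Xt)
        return classes[np.argmax(score, axis=1)]

    predict.selected_K = K  # type: ignore[attr-defined]
    return predict


def _fit_hho_sfpde(X, y, params, seed):
    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    base_name = params.get("base_classifier", "knn")
    inner_folds = params.get("fitness_folds", 3)

    def mask_error(bits: np.ndarray) -> float:
        if bits.sum() == 0:
            return 1.0
        cols = np.nonzero(bits)[0]
        skf = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=seed
        )
        errs = []
        for tr, te in skf.split(Xz, y):
            model = _base_classifier(base_name, seed)
            model.fit(Xz[tr][:, cols], y[tr])
            errs.append(1.0 - model.score(Xz[te][:, cols], y[te]))
        return float(np.mean(errs)) + params.get("size_penalty", 1e-3) * bits.mean()

    spec = mh.ObjectiveSpec(X.shape[1], -2.0, 2.0, mask_error)
    hybrid = mh.HybridConfig(
        outer=mh.HHOConfig(
            pop_size=params.get("outer_pop", 3),
            max_iters=params.get("outer_iters", 2),
        ),
        inner=mh.SFPDEConfig(
            pop_size=params.get("inner_pop", 8),
            max_iters=params.get("inner_iters", 10),
            binary=True,
            stop_tol=1e-8,
        ),
        seed=seed,
    )
    result = mh.hho_sfpde(spec, hybrid)
    bits = result.extras.get("best_mask")
    if bits is None or bits.sum() == 0:
        bits = np.ones(X.shape[1], dtype=int)
    cols = np.nonzero(bits)[0]
    final = _base_classifier(params.get("final_classifier", "svm"), seed)
    final.fit(Xz[:, cols], y)
    predict = lambda Xt: final.predict(((Xt - mu) / sd)[:, cols])
    predict.mask = bits  # type: ignore[attr-defined]
    return predict


def _fit_dr_gwo_svc(X, y, params, seed):
    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    d = min(params.get("dr_dim", 8), X.shape[1], X.shape[0])
    pca = PCA(n_components=d, random_state=seed).fit(Xz)
    Xr = pca.transform(Xz)
    model, c, g = clf.gwo_svc_tune(
        Xr, y,
        wolves=params.get("wolves", 8),
        iters=params.get("gwo_iters", 8),
        seed=seed,
    )
    predict = lambda Xt: model.predict(pca.transform((Xt - mu) / sd))
    predict.svc_params = (c, g)  # type: ignore[attr-defined]
    return predict


def _fit_dr_goa_sae(X, y, params, seed):
    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    d = min(params.get("dr_dim", 8), X.shape[1], X.shape[0])
    pca = PCA(n_components=d, random_state=seed).fit(Xz)
    Xr = pca.transform(Xz)

    def mask_error(x: np.ndarray) -> float:
        bits = (x > 0).astype(int)
        if bits.sum() == 0:
            return 1.0
        cols = np.nonzero(bits)[0]
        model = KNeighborsClassifier(n_neighbors=3)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        errs = []
        for tr, te in skf.split(Xr, y):
            model.fit(Xr[tr][:, cols], y[tr])
            errs.append(1.0 - model.score(Xr[te][:, cols], y[te]))
        return float(np.mean(errs))

    spec = mh.ObjectiveSpec(d, -2.0, 2.0, mask_error)
    result = mh.goa(
        spec,
        mh.SwarmConfig(
            pop_size=params.get("goa_pop", 10),
            max_iters=params.get("goa_iters", 10),
            seed=seed,
        ),
    )
    bits = (result.best_candidate > 0).astype(int)
    if bits.sum() == 0:
        bits = np.ones(d, dtype=int)
    cols = np.nonzero(bits)[0]

    sel = Xr[:, cols]
    lo, hi = sel.min(axis=0), sel.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    sae_cfg = clf.SAEConfig(
        hidden=params.get("sae_hidden", 24),
        epochs=params.get("sae_epochs", 200),
        learning_rate=params.get("sae_lr", 0.1),
        batch_size=params.get("sae_batch", 32),
        sparsity_weight=params.get("sae_sparsity_weight", 0.01),
        sparsity_target=params.get("sae_sparsity_target", 0.15),
        seed=seed,
    )
    head_C = params.get("head_C", 10.0)
    sae = clf.sae_train((sel - lo) / span, sae_cfg)
    head = LogisticRegression(max_iter=2000, C=head_C, random_state=seed)
    head.fit(clf.sae_encode(sae, (sel - lo) / span), y)

    def predict(Xt):
        Zr = pca.transform((Xt - mu) / sd)[:, cols]
        enc = clf.sae_encode(sae, (Zr - lo) / span)
        return head.predict(enc)

    return predict


# ---------------------------------------------------------------------------
# Harness


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    estimator_factory: Callable[[np.ndarray, np.ndarray], Callable],
    folds: int = 10,
    seed: int = 0,
    classes: Sequence | None = None,
) -> CVResult:
    """Stratified seeded K-fold; the factory gets training rows only and
    returns a predictor applied to the held-out rows."""
    X = np.asarray(features)
    y = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
    starving = [c for c, k in counts.items() if k < folds]
    if starving:
        raise ValueError(f"classes with fewer members than folds: {starving}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments = np.empty(y.size, dtype=int)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignments[te] = fold
        predictor = estimator_factory(X[tr], y[tr])
        y_pred = predictor(X[te])
        reports.append(clf.compute_metrics(y[te], y_pred, classes=classes))
    return CVResult(
        fold_reports=reports,
        fold_assignments=assignments,
        accuracy=float(np.mean([r.accuracy for r in reports])),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        config_snapshot={},
    )


def run_strategy(dataset: Sequence[LabeledCycle], config: StrategyConfig) -> CVResult:
    """Run one strategy end-to-end under stratified seeded K-fold CV."""
    labels = np.array([c.label for c in dataset])
    params = config.params
    seed = config.seed
    classes = list(config.scheme.classes)

    snapshot = dict(
        strategy=config.strategy,
        scheme=config.scheme.name,
        cv_folds=config.cv_folds,
        seed=seed,
        params={k: v for k, v in params.items()},
        n_samples=len(dataset),
    )

    if config.strategy == "dmvmd_elm":
        cache = _VMDFeatureCache(
            dataset,
            dec.VMDConfig(
                alpha=params.get("alpha", 300.0),
                tau=params.get("tau", 0.5),
                tol=params.get("tol", 1e-3),
                max_iters=params.get("vmd_max_iters", 200),
            ),
        )
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=seed
        )
        indices = np.arange(len(dataset))
        assignments = np.empty(len(dataset), dtype=int)
        reports = []
        for fold, (tr, te) in enumerate(skf.split(indices, labels)):
            assignments[te] = fold
            predictor = _fit_dmvmd_elm(indices[tr], labels[tr], cache, params, seed)
            y_pred = predictor(indices[te])
            reports.append(clf.compute_metrics(labels[te], y_pred, classes=classes))
        result = CVResult(
            fold_reports=reports,
            fold_assignments=assignments,
            accuracy=float(np.mean([r.accuracy for r in reports])),
            sensitivity=float(np.mean([r.sensitivity for r in reports])),
            specificity=float(np.mean([r.specificity for r in reports])),
            config_snapshot=snapshot,
        )
        return result

    if config.strategy == "gssr":
        X = _extract_gssr(dataset, params, seed)
        factory = lambda Xtr, ytr: _fit_gssr(Xtr, ytr, params, seed)
    else:
        X = _extract_band(dataset, params)
        if config.strategy == "rrsrc":
            factory = lambda Xtr, ytr: _fit_rrsrc(Xtr, ytr, params, seed)
        elif config.strategy == "hho_sfpde":
            factory = lambda Xtr, ytr: _fit_hho_sfpde(Xtr, ytr, params, seed)
        elif config.strategy == "dr_gwo_svc":
            factory = lambda Xtr, ytr: _fit_dr_gwo_svc(Xtr, ytr, params, seed)
        else:
            factory = lambda Xtr, ytr: _fit_dr_goa_sae(Xtr, ytr, params, seed)

    result = cross_validate(
        X, labels, factory, folds=config.cv_folds, seed=seed, classes=classes
    )
    result.config_snapshot = snapshot
    return result
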