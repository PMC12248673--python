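"""Flight-state decoding from band-limited LFP windows.

Three baseline decoders classify acceleration / steady / deceleration
windows from one frequency band at a time: a margin classifier (RBF
support-vector machine), a shallow fully-connected network, and a 1-D
convolutional feature model (seeded random convolution kernels with
ReLU/pooling feeding a linear readout). Classes are balanced by random
undersampling, so the chance level of the three-class task is exactly
33.3%; performance is summarized as mean +/- SD accuracy over stratified
10-fold cross-validation repeated 10 times. Feature scaling lives inside
each model pipeline and is fitted on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import DEFAULT_BANDS
from .denoise import bandpass

__all__ = ["DecodingResult", "make_dataset", "build_model", "cross_validate",
           "permutation_chance", "empirical_chance"]

STATE_ORDER = ("acceleration", "steady", "deceleration")


@dataclass
class DecodingResult:
    band: str
    model: str
    fold_accuracies: np.ndarray     # % per fold x repeat
    mean_accuracy: float            # %
    sd_accuracy: float              # %
    confusion: np.ndarray           # 3x3 counts aggregated over folds
    chance: float = 100.0 / 3.0     # %
    macro_f1: float = float("nan")
    failed_folds: int = 0
    classes: tuple = STATE_ORDER


def make_dataset(lfp: np.ndarray, fs: float, segments, band: str | tuple,
                 bands: dict | None = None, balance: bool = True,
                 seed: int = 0, min_per_class: int = 10
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Band-filtered, per-window demeaned epochs with state labels.

    Each labelled (non-excluded) segment yields one epoch of shape
    (n_channels, window_samples), band-pass filtered to the requested band
    and demeaned per channel. With ``balance`` the majority classes are
    randomly undersampled to the minority count. Raises when any class has
    fewer than ``min_per_class`` windows (cross-validation would starve).
    """
    bands = bands or DEFAULT_BANDS
    lo, hi = bands[band] if isinstance(band, str) else band
    filtered = bandpass(lfp, lo, hi, fs)

    epochs, labels = [], []
    for seg in segments:
        if seg.label not in STATE_ORDER:
            continue
        i0 = int(round(seg.start_s * fs))
        i1 = int(round(seg.end_s * fs))
        if i1 > lfp.shape[1]:
            continue
        ep = filtered[:, i0:i1]
        epochs.append(ep - ep.mean(axis=1, keepdims=True))
        labels.append(seg.label)
    if not epochs:
        raise ValueError("no labelled windows in segments")
    X = np.stack(epochs)
    y = np.asarray(labels)

    counts = {s: int((y == s).sum()) for s in STATE_ORDER}
    if min(counts.values()) < min_per_class:
        raise ValueError(f"class too small for cross-validation: {counts}")

    if balance:
        rng = np.random.default_rng(seed)
        n_min = min(counts.values())
        keep = np.concatenate([
            rng.choice(np.nonzero(y == s)[0], size=n_min, replace=False)
            for s in STATE_ORDER
        ])
        keep.sort()
        X, y = X[keep], y[keep]
    return X, y


class MomentFeatures(BaseEstimator, TransformerMixin):
    """Per-channel log band power + inter-channel correlations.

    Stateless: per-epoch log variance (8 features) and the upper triangle
    of the channel correlation matrix (28 features for 8 channels).
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X)
        n, c, _ = X.shape
        logvar = np.log(X.var(axis=2) + 1e-12)
        iu = np.triu_indices(c, k=1)
        corrs = np.empty((n, iu[0].size))
        for i in range(n):
            cc = np.corrcoef(X[i])
            corrs[i] = cc[iu]
        return np.hstack([logvar, corrs])


class RandomConvFeatures(BaseEstimator, TransformerMixin):
    """Seeded random 1-D convolution kernels with ReLU + pooling.

    A compact convolutional feature map in the spirit of random-kernel
    time-series classifiers: each kernel is convolved with every channel
    and summarized by max activation and the proportion of positive
    values; a linear readout on top plays the role of a shallow CNN.
    """

    def __init__(self, n_kernels: int = 48, kernel_len: int = 32,
                 seed: int = 0):
        self.n_kernels = n_kernels
        self.kernel_len = kernel_len
        self.seed = seed

    def fit(self, X, y=None):
        return self

    def _kernels(self):
        rng = np.random.default_rng(self.seed)
        k = rng.standard_normal((self.n_kernels, self.kernel_len))
        return k - k.mean(axis=1, keepdims=True)

    def transform(self, X):
        from scipy.signal import fftconvolve

        X = np.asarray(X)
        n, c, L = X.shape
        kernels = self._kernels()
        feats = np.empty((n, c * self.n_kernels * 2))
        for ki, kern in enumerate(kernels):
            conv = fftconvolve(X, kern[None, None, :], mode="valid", axes=2)
            relu = np.maximum(conv, 0.0)
            fmax = relu.max(axis=2)
            ppv = (conv > 0).mean(axis=2)
            feats[:, (2 * ki) * c:(2 * ki + 1) * c] = fmax
            feats[:, (2 * ki + 1) * c:(2 * ki + 2) * c] = ppv
        return feats


def build_model(name: str, seed: int = 0) -> Pipeline:
    """Decoder pipelines; feature scaling is always fitted inside CV."""
    if name == "svm":
        return Pipeline([
            ("features", MomentFeatures()),
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", C=1.0, gamma="scale",
                        random_state=seed)),
        ])
    if name == "mlp":
        return Pipeline([
            ("features", MomentFeatures()),
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(hidden_layer_sizes=(32, 16), max_iter=800,
                                  random_state=seed)),
        ])
    if name == "cnn":
        return Pipeline([
            ("features", RandomConvFeatures(seed=seed)),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, C=0.5,
                                       random_state=seed)),
        ])
    raise ValueError(f"unknown model {name!r}")


def cross_validate(X: np.ndarray, y: np.ndarray, model_spec: str | Pipeline,
                   folds: int = 10, repeats: int = 10, seed: int = 0,
                   band: str = "gamma") -> DecodingResult:
    """Repeated stratified k-fold evaluation of one decoder.

    Partitions are re-drawn per repeat from a seeded stream; accuracy is
    aggregated as mean +/- SD over all folds x repeats, and the confusion
    matrix accumulates test-fold predictions (row sums equal per-class
    test counts). A model failure on a fold is recorded and excluded.
    """
    from sklearn.metrics import confusion_matrix, f1_score

    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` windows")

    model = build_model(model_spec, seed=seed) \
        if isinstance(model_spec, str) else model_spec
    rng = np.random.default_rng(seed)

    accs = []
    failed = 0
    confusion = np.zeros((len(STATE_ORDER), len(STATE_ORDER)), dtype=int)
    all_true, all_pred = [], []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for tr, te in skf.split(X, y):
            est = clone(model)
            try:
                est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
            except Exception:
                failed += 1
                continue
            accs.append(100.0 * float(np.mean(pred == y[te])))
            confusion += confusion_matrix(y[te], pred, labels=STATE_ORDER)
            all_true.append(y[te])
            all_pred.append(pred)

    accs = np.asarray(accs)
    f1 = f1_score(np.concatenate(all_true), np.concatenate(all_pred),
                  average="macro") if all_true else float("nan")
    return DecodingResult(
        band=band,
        model=model_spec if isinstance(model_spec, str) else "custom",
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()) if accs.size else float("nan"),
        sd_accuracy=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        confusion=confusion,
        macro_f1=float(100.0 * f1),
        failed_folds=failed,
    )


def permutation_chance(X: np.ndarray, y: np.ndarray,
                       model_spec: str = "svm", folds: int = 10,
                       repeats: int = 3, seed: int = 0,
                       permutation_seed: int = 7,
                       n_permutations: int = 20) -> tuple[float, np.ndarray]:
    """Empirical chance level: mean CV accuracy over permuted-label draws.

    A single permuted dataset carries realization luck of several
    percentage points at ~100 windows (the classifier finds, and then
    anti-generalizes, spurious structure of that one draw), so the chance
    level is estimated by averaging the repeated-CV mean accuracy over
    ``n_permutations`` independent label permutations drawn from the
    ``permutation_seed`` stream. For three balanced classes it converges
    to 33.3%.
    """
    rng = np.random.default_rng(permutation_seed)
    means = []
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        res = cross_validate(X, yp, model_spec, folds=folds,
                             repeats=repeats, seed=seed)
        means.append(res.mean_accuracy)
    means = np.asarray(means)
    return float(means.mean()), means


def empirical_chance(lfp: np.ndarray, fs: float, segments,
                     band: str = "gamma", model_spec: str = "svm",
                     folds: int = 10, repeats: int = 3, seed: int = 0,
                     permutation_seed: int = 7, n_permutations: int = 10,
                     n_subsamples: int = 4) -> float:
    """Chance level of a recording's state-decoding task, in percent.

    Averages :func:`permutation_chance` over several balanced-undersample
    draws of the window set: at ~100 windows the particular subsample
    contributes as much realization luck as the label permutation, so
    both are averaged out. Converges to 33.3% for three balanced classes.
    """
    vals = []
    for sub in range(1, n_subsamples + 1):
        X, y = make_dataset(lfp, fs, segments, band, seed=sub)
        c, _ = permutation_chance(
            X, y, model_spec=model_spec, folds=folds, repeats=repeats,
            seed=seed, permutation_seed=permutation_seed + sub,
            n_permutations=n_permutations)
        vals.append(c)
    return float(np.mean(vals))
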