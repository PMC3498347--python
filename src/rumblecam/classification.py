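"""Automatic nasal/oral rumble discrimination from averaged LPC spectra.

Each call is summarised by a 26-component descriptor: an order-8 LPC
spectrogram (300 ms windows, 30 ms steps) over 0-500 Hz is averaged
over time and the 260-bin envelope is block-averaged 10:1.  The same
parameters are applied to both rumble types by construction -- there is
one shared :class:`DescriptorConfig` object and no per-class branch in
the descriptor path.

Three linear-family classifiers (LDA, linear SVM, nearest neighbour)
are trained on a stratified 1/3 training split with 10-fold
cross-validated parameter tuning and scored on the held-out 2/3; the
swap replicate exchanges the two sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .audio_io import P_REF
from .call_acoustics import _resample_to
from .lpc import lpc_coefficients, lpc_envelope_db
from .synthetic_data import RumbleCall

__all__ = [
    "DescriptorConfig",
    "LPCDescriptor",
    "EvalReport",
    "lpc_spectrogram",
    "average_descriptor",
    "describe_call",
    "split_dataset",
    "tune_and_train",
    "evaluate",
    "run_protocol",
]


@dataclass(frozen=True)
class DescriptorConfig:
    """One shared parameter set for the descriptor of *both* call types."""

    window_s: float = 0.3
    step_s: float = 0.03
    order: int = 8
    fmax_hz: float = 500.0
    n_bins: int = 260
    n_components: int = 26

    def __post_init__(self) -> None:
        if self.n_bins % self.n_components != 0:
            raise ValueError("n_bins must be a multiple of n_components")

    @property
    def analysis_fs(self) -> int:
        # resampling to 2*fmax makes the order-8 model span exactly 0-fmax
        return int(round(2 * self.fmax_hz))

    def bin_freqs(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.fmax_hz / self.n_bins


DEFAULT_CONFIG = DescriptorConfig()


@dataclass
class LPCDescriptor:
    """26 non-negative averaged-envelope values (dB) for one call."""

    vector: np.ndarray
    call_id: str = ""
    label: str | None = None  # ground truth when known

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (DEFAULT_CONFIG.n_components,):
            raise ValueError(
                f"descriptor must have {DEFAULT_CONFIG.n_components} components"
            )


@dataclass
class EvalReport:
    """Held-out accuracies, confusions, CV tuning scores and the swap run."""

    accuracy: dict  # classifier name -> held-out accuracy
    confusion: dict  # name -> 2x2 counts [[tn, fp], [fn, tp]] (nasal=0, oral=1)
    cv_scores: dict  # name -> mean CV accuracy of the selected parameters
    swap_accuracy: dict = field(default_factory=dict)
    split_seed: int = 0
    n_train: int = 0
    n_eval: int = 0

    def min_accuracy(self) -> float:
        return min(self.accuracy.values())


def lpc_spectrogram(
    call: RumbleCall, config: DescriptorConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Order-8 LPC envelope per sliding window, shape (frames, n_bins), dB.

    The call is resampled so the modelled band 0-``fmax_hz`` is the
    full Nyquist range, then normalised to 1 Pa RMS so the descriptor
    captures spectral shape, not loudness.  Frame count is
    ``floor((len - window)/step) + 1``; calls shorter than one window
    fall back to a single whole-call frame with a warning.
    """
    fs = config.analysis_fs
    x = _resample_to(call.waveform, call.sample_rate, fs)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x / rms  # 1 Pa RMS
    win = int(round(config.window_s * fs))
    step = int(round(config.step_s * fs))
    if x.size < win:
        warnings.warn("call shorter than one window: single-frame descriptor")
        starts = [0]
        win = x.size
    else:
        starts = range(0, x.size - win + 1, step)
    freqs = config.bin_freqs()
    hamming = np.hamming(win)
    rows = []
    for s in starts:
        frame = x[s : s + win] * hamming
        a, g = lpc_coefficients(frame, config.order)
        env = lpc_envelope_db(a, g, freqs, fs)
        rows.append(env)
    # envelope in dB re 20 uPa of the 1 Pa-normalised call; clip at 0 dB
    out = np.asarray(rows) - 20 * np.log10(P_REF)
    return np.maximum(out, 0.0)


def average_descriptor(
    spectrogram: np.ndarray,
    config: DescriptorConfig = DEFAULT_CONFIG,
    call_id: str = "",
    label: str | None = None,
) -> LPCDescriptor:
    """Time-average the spectrogram, then block-average 260 -> 26 bins."""
    spec = np.atleast_2d(np.asarray(spectrogram, dtype=float))
    if spec.shape[0] < 1:
        raise ValueError("need at least one frame")
    mean_env = spec.mean(axis=0)
    block = config.n_bins // config.n_components
    vec = mean_env.reshape(config.n_components, block).mean(axis=1)
    return LPCDescriptor(vec, call_id=call_id, label=label)


def describe_call(
    call: RumbleCall,
    call_id: str = "",
    label: str | None = None,
    config: DescriptorConfig = DEFAULT_CONFIG,
) -> LPCDescriptor:
    """Spectrogram + averaging in one step."""
    return average_descriptor(lpc_spectrogram(call, config), config, call_id, label)


def _to_xy(descriptors: list[LPCDescriptor]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([d.vector for d in descriptors])
    y = np.array([d.label for d in descriptors])
    return X, y


def split_dataset(
    descriptors: list[LPCDescriptor],
    train_fraction: float = 1 / 3,
    seed: int = 0,
) -> tuple[list[LPCDescriptor], list[LPCDescriptor]]:
    """Stratified train/evaluation split (1/3 - 2/3 by default)."""
    labels = [d.label for d in descriptors]
    classes = set(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if min(labels.count(c) for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    idx = np.arange(len(descriptors))
    tr, ev = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    return [descriptors[i] for i in tr], [descriptors[i] for i in ev]


def tune_and_train(
    train: list[LPCDescriptor], k: int = 10
) -> tuple[dict, dict]:
    """Fit LDA, linear SVM and NN with k-fold CV tuning on the training set.

    SVM cost and the NN neighbourhood size are grid-searched with
    stratified k-fold CV; LDA has no tuned parameter (its CV score is
    still recorded).  Returns (fitted classifiers, mean CV accuracies).
    """
    if len(train) < k:
        raise ValueError(f"training set smaller than k={k}")
    X, y = _to_xy(train)
    cv = StratifiedKFold(n_splits=k)
    models: dict = {}
    cv_scores: dict = {}

    lda = LinearDiscriminantAnalysis()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", UserWarning)
            lda.fit(X, y)
    except (UserWarning, np.linalg.LinAlgError):
        warnings.warn("degenerate within-class covariance: shrinkage LDA fallback")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
    from sklearn.base import clone
    from sklearn.model_selection import cross_val_score

    cv_scores["lda"] = float(np.mean(cross_val_score(clone(lda), X, y, cv=cv)))
    models["lda"] = lda

    svm = GridSearchCV(
        SVC(kernel="linear"), {"C": [0.01, 0.1, 1.0, 10.0, 100.0]}, cv=cv
    )
    svm.fit(X, y)
    models["svm"] = svm.best_estimator_
    cv_scores["svm"] = float(svm.best_score_)

    max_k = max(1, min(7, min(np.bincount(np.unique(y, return_inverse=True)[1]))))
    nn = GridSearchCV(
        KNeighborsClassifier(),
        {"n_neighbors": [n for n in (1, 3, 5, 7) if n <= max_k]},
        cv=cv,
    )
    nn.fit(X, y)
    models["nn"] = nn.best_estimator_
    cv_scores["nn"] = float(nn.best_score_)
    return models, cv_scores


def evaluate(
    models: dict, eval_set: list[LPCDescriptor], labels_order=("nasal", "oral")
) -> tuple[dict, dict]:
    """Held-out accuracy and confusion counts per classifier."""
    X, y = _to_xy(eval_set)
    acc, conf = {}, {}
    for name, model in models.items():
        pred = model.predict(X)
        acc[name] = float(accuracy_score(y, pred))
        conf[name] = confusion_matrix(y, pred, labels=list(labels_order)).tolist()
    return acc, conf


def run_protocol(
    descriptors: list[LPCDescriptor],
    seed: int = 0,
    train_fraction: float = 1 / 3,
    k: int = 10,
) -> EvalReport:
    """Full published evaluation protocol, including the swap replicate.

    Stratified 1/3-2/3 split, 10-fold CV tuning on the training third,
    held-out scoring, then the same with training and evaluation sets
    exchanged.
    """
    train, evl = split_dataset(descriptors, train_fraction, seed)

    def min_class(group):
        labels = [d.label for d in group]
        return min(labels.count(c) for c in set(labels))

    k_eff = max(2, min(k, min_class(train), min_class(evl)))
    models, cv_scores = tune_and_train(train, k=k_eff)
    acc, conf = evaluate(models, evl)
    swap_models, _ = tune_and_train(evl, k=k_eff)
    swap_acc, _ = evaluate(swap_models, train)
    return EvalReport(
        accuracy=acc,
        confusion=conf,
        cv_scores=cv_scores,
        swap_accuracy=swap_acc,
        split_seed=seed,
        n_train=len(train),
        n_eval=len(evl),
    )
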