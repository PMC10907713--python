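"""Behavioral decoding of target direction from windowed neural activity.

Each channel contributes 34 candidate features — root mean square (RMS),
mean frequency (MF), waveform length (WL), and the periodogram power at
each integer frequency from 10 to 40 Hz — computed on the movement window.
Feature *types* are ranked by Fisher score averaged across channels, the
top-k types (14 for a single signal set, 28 when two sets are combined)
feed a linear discriminant analysis classifier evaluated with stratified
fourfold cross-validation, and chance level is estimated by label
shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .synthetic import RecordingSession

__all__ = [
    "FEATURE_TYPES",
    "FeatureTable",
    "DecodeResult",
    "extract_features",
    "build_feature_table",
    "fisher_score",
    "select_features",
    "train_eval_lda",
    "chance_level",
    "run_conditions",
    "CONDITIONS",
]

BAND_FREQS = tuple(range(10, 41))  # integer-Hz power features
FEATURE_TYPES: tuple[str, ...] = ("rms", "mf", "wl") + tuple(f"p{f}" for f in BAND_FREQS)

#: the seven decoder input conditions (which signal sets feed the classifier)
CONDITIONS = (
    "coarse",
    "recon_coarse",
    "fine",
    "recon_fine",
    "coarse+fine",
    "recon_coarse+fine",
    "coarse+recon_fine",
)


@dataclass
class FeatureTable:
    """Trials x features matrix with (channel, type) column names."""

    x: np.ndarray  # (n_trials, n_channels * 34)
    names: list[tuple[int, str]]  # (channel, feature type) per column
    labels: np.ndarray  # target directions 1..8

    @property
    def n_channels(self) -> int:
        return len({ch for ch, _ in self.names})


@dataclass(frozen=True)
class DecodeResult:
    fold_accuracy: np.ndarray  # (n_folds,)
    mean_accuracy: float
    confusion: np.ndarray  # (n_classes, n_classes), rows = true class
    condition: str = ""


def extract_features(trial: np.ndarray, fs: float) -> np.ndarray:
    """34 features per channel for a (n_channels, T') window, flattened per channel.

    RMS = sqrt(mean(Y^2)); WL = sum |Y(t) - Y(t-1)|; MF is the
    power-weighted mean frequency of the periodogram restricted to the
    10-40 Hz support; the 31 band powers are the periodogram values at the
    bins nearest each integer frequency 10..40 Hz.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    if trial.shape[-1] < 2:
        raise ValidationError("need at least 2 samples per trial window")
    rms = np.sqrt(np.mean(trial**2, axis=-1))
    wl = np.sum(np.abs(np.diff(trial, axis=-1)), axis=-1)
    freqs, pxx = sps.periodogram(trial, fs=fs, axis=-1)
    support = (freqs >= BAND_FREQS[0]) & (freqs <= BAND_FREQS[-1])
    p_sup = pxx[:, support]
    f_sup = freqs[support]
    denom = np.sum(p_sup, axis=-1)
    mf = np.where(denom > 0, np.sum(f_sup[None, :] * p_sup, axis=-1) / np.maximum(denom, 1e-300), 0.0)
    idx = [int(np.argmin(np.abs(freqs - f))) for f in BAND_FREQS]
    powers = pxx[:, idx]
    return np.column_stack([rms, mf, wl, powers])  # (n_channels, 34)


def build_feature_table(
    signals: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    labels: np.ndarray,
    window_s: float = 0.6,
) -> FeatureTable:
    """Feature table over the movement window of every trial of (n_trials, n_ch, T)."""
    signals = np.asarray(signals, dtype=float)
    t_win = int(round(window_s * fs))
    rows = []
    for k in range(signals.shape[0]):
        o = int(onsets[k])
        rows.append(extract_features(signals[k, :, o : o + t_win], fs).ravel())
    names = [(ch, ft) for ch in range(signals.shape[1]) for ft in FEATURE_TYPES]
    return FeatureTable(x=np.asarray(rows), names=names, labels=np.asarray(labels))


def fisher_score(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher score sum_j n_j (mu_j - mu)^2 / sum_j n_j sigma_j^2 per feature.

    Class standard deviations are population (ddof=0) within-class values.
    A feature with zero within-class variance but separated means scores
    +inf (it is a perfect discriminator and ranks first).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    mu = x.mean(axis=0)
    between = np.zeros(x.shape[1])
    within = np.zeros(x.shape[1])
    for cls in classes:
        xc = x[labels == cls]
        if xc.shape[0] < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 members")
        nj = xc.shape[0]
        between += nj * (xc.mean(axis=0) - mu) ** 2
        within += nj * xc.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = between / within
    score[np.isnan(score)] = 0.0  # 0/0: no separation and no spread
    return score


def select_features(
    table: FeatureTable, scores: np.ndarray, k: int = 14, per_column: bool = False
) -> np.ndarray:
    """Column indices of the top-k feature types (channel-averaged ranking).

    The default ranks the 34 feature *types* by their Fisher score averaged
    across channels and returns every channel's column for each of the top-k
    types; ``per_column`` instead returns the k highest-scoring individual
    columns.  Ties break deterministically toward the earlier type in
    ``FEATURE_TYPES`` order (i.e. lower frequency).
    """
    scores = np.asarray(scores, dtype=float)
    if per_column:
        if k > scores.size:
            raise ValidationError(f"k={k} exceeds {scores.size} columns")
        order = np.lexsort((np.arange(scores.size), -scores))
        return np.sort(order[:k])
    type_order: list[str] = []
    type_scores: dict[str, list[float]] = {}
    for col, (_, ftype) in enumerate(table.names):
        if ftype not in type_scores:
            type_scores[ftype] = []
            type_order.append(ftype)
        type_scores[ftype].append(scores[col])
    if k > len(type_order):
        raise ValidationError(f"k={k} exceeds {len(type_order)} feature types")
    avg = np.array([np.mean(type_scores[ft]) for ft in type_order])
    order = np.lexsort((np.arange(len(type_order)), -avg))
    top_types = {type_order[i] for i in order[:k]}
    return np.array([col for col, (_, ft) in enumerate(table.names) if ft in top_types])


def train_eval_lda(
    x: np.ndarray, labels: np.ndarray, folds: int = 4, seed: int = 0
) -> DecodeResult:
    """Shrinkage LDA with stratified fourfold cross-validation.

    Uses a shared within-class covariance with Ledoit-Wolf shrinkage (the
    feature count can approach the trial count at desk scale).  Fold
    assignment is seed-deterministic.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % 2**31)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    accs = []
    for train_idx, test_idx in skf.split(x, labels):
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(x[train_idx], labels[train_idx])
        pred = clf.predict(x[test_idx])
        accs.append(float(np.mean(pred == labels[test_idx])))
        for yt, yp in zip(labels[test_idx], pred):
            confusion[cls_index[yt], cls_index[yp]] += 1
    accs = np.asarray(accs)
    return DecodeResult(
        fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        confusion=confusion,
    )


def chance_level(
    x: np.ndarray, labels: np.ndarray, n_shuffles: int = 100, seed: int = 0, folds: int = 4
) -> float:
    """Mean cross-validated accuracy over label shuffles (~1/n_classes)."""
    if n_shuffles < 10:
        raise ValidationError("need at least 10 shuffles for a stable estimate")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    accs = []
    for i in range(n_shuffles):
        shuffled = rng.permutation(labels)
        accs.append(train_eval_lda(x, shuffled, folds=folds, seed=int(rng.integers(2**31))).mean_accuracy)
    return float(np.mean(accs))


def run_conditions(
    session: RecordingSession,
    recon_coarse: np.ndarray,
    recon_fine: np.ndarray,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> dict[str, DecodeResult]:
    """Decode target direction under the seven input conditions.

    Single-set conditions select the top 14 feature types; combined
    conditions select 28 (the candidate pool doubles).  Feature selection is
    re-run per condition on its own Fisher scores.
    """
    fs, onsets = session.fs, session.onsets()
    labels = session.targets()
    tables = {
        "coarse": build_feature_table(session.coarse, fs, onsets, labels),
        "fine": build_feature_table(session.fine, fs, onsets, labels),
        "recon_coarse": build_feature_table(np.asarray(recon_coarse), fs, onsets, labels),
        "recon_fine": build_feature_table(np.asarray(recon_fine), fs, onsets, labels),
    }
    results: dict[str, DecodeResult] = {}
    for cond in conditions:
        parts = cond.split("+")
        x = np.hstack([tables[p].x for p in parts])
        if len(parts) == 1:
            names = list(tables[parts[0]].names)
        else:  # candidate pool doubles: keep each set's types distinct
            names = [(ch, f"{p}:{ft}") for p in parts for ch, ft in tables[p].names]
        table = FeatureTable(x=x, names=names, labels=labels)
        k = 14 * len(parts)
        cols = select_features(table, fisher_score(x, labels), k=k)
        res = train_eval_lda(x[:, cols], labels, seed=seed)
        results[cond] = DecodeResult(
            fold_accuracy=res.fold_accuracy,
            mean_accuracy=res.mean_accuracy,
            confusion=res.confusion,
            condition=cond,
        )
    return results
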