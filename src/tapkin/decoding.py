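"""Attentional-condition decoding from pairwise wavelet-coherence features.

Per trial, WTC is computed between every two of the 14 tapping-finger
keypoints (91 unordered pairs) at 40 frequencies, giving a
time x (40 x 91 = 3640) feature block per trial. Features pooled over all
trials and conditions are reduced to 80 principal components, the time
points of each condition are cut (in trial order) into 6 contiguous,
near-equal datasets, sliding windows (60 points, step 4) form the samples,
and an RBF-kernel SVM (gamma = 0.014) is trained and tested under six-fold
cross-validation in which every dataset is held out exactly once. The
result is a row-normalized 4 x 4 confusion matrix and per-condition / mean
decoding accuracies (chance = 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import SVC

from .keypoints import CONDITIONS, TAPPING_KEYPOINTS
from .wavelet import (
    WaveletParams,
    _smooth_spectrum,
    coherence_from_spectra,
    cone_of_influence,
    cwt_morlet,
)

__all__ = [
    "DecoderParams",
    "FeatureMatrix",
    "DecodingResult",
    "pairwise_wtc_features",
    "build_feature_matrix",
    "reduce_dimensions",
    "split_datasets",
    "make_windows",
    "train_eval",
    "decode",
]

N_PAIRS = len(TAPPING_KEYPOINTS) * (len(TAPPING_KEYPOINTS) - 1) // 2  # 91


@dataclass(frozen=True)
class DecoderParams:
    """Decoding configuration (defaults follow the standard analysis)."""

    n_components: int = 80
    variance_floor: float = 0.80
    window_len: int = 60
    window_step: int = 4
    n_datasets: int = 6
    kernel_gamma: float = 0.014
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window_len >= self.window_step >= 1):
            raise ValueError("need window_len >= window_step >= 1")
        if self.n_datasets < 2:
            raise ValueError("need at least 2 datasets")
        if self.n_components > 40 * N_PAIRS:
            raise ValueError("n_components exceeds the raw feature count")


@dataclass
class FeatureMatrix:
    """Pooled time x pooled frequency feature matrix with row provenance."""

    X: np.ndarray  # (n_rows, n_features) float32
    labels: np.ndarray  # condition per row
    trial_ids: np.ndarray  # trial id per row
    conditions: tuple[str, ...] = CONDITIONS
    explained_variance: float | None = None


@dataclass
class DecodingResult:
    """Cross-validated decoding outcome.

    ``confusion`` rows (true condition) each sum to 1; ``mean_accuracy`` is
    the mean of its diagonal; chance is 1 / n_conditions.
    """

    confusion: np.ndarray
    per_condition_accuracy: np.ndarray
    mean_accuracy: float
    chance_level: float
    conditions: tuple[str, ...]
    n_samples_per_dataset: list[int] = field(default_factory=list)
    explained_variance: float | None = None


def pairwise_wtc_features(
    roi: np.ndarray, p: WaveletParams | None = None
) -> np.ndarray:
    """Pairwise-WTC feature block of one trial.

    Parameters
    ----------
    roi
        ``(n_times, 14)`` ROI vertical series of the tapping-finger
        keypoints, columns in ``TAPPING_KEYPOINTS`` order.
    p
        Wavelet parameters.

    Returns
    -------
    ``(n_times, 40 * 91)`` float32 array; column ``f * 91 + q`` holds the
    coherence of keypoint pair ``q`` (lexicographic unordered pairs) at
    frequency ``f``. COI-invalid entries are imputed with the per-column
    mean over valid times so that the matrix is complete without injecting
    condition information.
    """
    if p is None:
        p = WaveletParams()
    roi = np.asarray(roi, float)
    if roi.ndim != 2 or roi.shape[1] != len(TAPPING_KEYPOINTS):
        raise ValueError(
            f"expected (n_times, {len(TAPPING_KEYPOINTS)}) tapping-finger series; "
            f"got {roi.shape}"
        )
    n, k = roi.shape
    W = np.stack([cwt_morlet(roi[:, i], p) for i in range(k)]).astype(np.complex64)
    inv_s = (1.0 / p.scales[:, None]).astype(np.float32)
    Sauto = _smooth_spectrum((W.real**2 + W.imag**2) * inv_s, p)  # (k, nf, n)
    pairs_i, pairs_j = map(
        np.array, zip(*combinations(range(k), 2))
    )  # lexicographic unordered pairs
    cross = W[pairs_i] * np.conj(W[pairs_j]) * inv_s  # (91, nf, n)
    Sxy = _smooth_spectrum(cross, p)
    rsq, _ = coherence_from_spectra(
        Sauto[pairs_i], Sauto[pairs_j], Sxy
    )  # (91, nf, n)

    # impute outside-COI values with the per-frequency valid-time mean
    valid = cone_of_influence(n, p).T  # (nf, n)
    counts = np.maximum(valid.sum(axis=1), 1)
    means = (rsq * valid[None]).sum(axis=2) / counts[None]  # (91, nf)
    no_valid = ~valid.any(axis=1)
    if no_valid.any():  # fall back to the plain time mean at such frequencies
        means[:, no_valid] = rsq[:, no_valid, :].mean(axis=2)
    rsq = np.where(valid[None], rsq, means[:, :, None])

    # column f * 91 + q
    out = rsq.transpose(2, 1, 0).reshape(n, p.n_freqs * N_PAIRS)
    return np.ascontiguousarray(out, dtype=np.float32)


def build_feature_matrix(
    trial_features: list[tuple[np.ndarray, str, str]],
    conditions: tuple[str, ...] = CONDITIONS,
) -> FeatureMatrix:
    """Concatenate per-trial feature blocks into the pooled matrix.

    ``trial_features`` holds ``(block, condition, trial_id)`` tuples; rows
    are stacked condition-by-condition (canonical order) preserving trial
    order within condition.
    """
    blocks, labels, tids = [], [], []
    for cond in conditions:
        for block, c, tid in trial_features:
            if c != cond:
                continue
            blocks.append(np.asarray(block, dtype=np.float32))
            labels.append(np.full(len(block), c, dtype=object))
            tids.append(np.full(len(block), tid, dtype=object))
    if not blocks:
        raise ValueError("no trial features supplied")
    present = {c for _, c, _ in trial_features}
    missing = set(conditions) - present
    if missing:
        raise ValueError(f"conditions absent from the data: {sorted(missing)}")
    return FeatureMatrix(
        X=np.vstack(blocks),
        labels=np.concatenate(labels),
        trial_ids=np.concatenate(tids),
        conditions=conditions,
    )


def reduce_dimensions(fm: FeatureMatrix, p: DecoderParams) -> FeatureMatrix:
    """Project the pooled-frequency dimension onto the top principal components.

    PCA is fitted once on the participant's full pooled matrix (all
    conditions together); a warning is issued if the retained components
    explain less than ``variance_floor`` of the total variance.
    """
    X = fm.X
    if X.shape[0] < p.n_components:
        raise ValueError("fewer rows than requested components")
    if float(X.var(axis=0).max()) == 0.0:
        raise ValueError("feature matrix has zero variance; nothing to reduce")
    pca = PCA(
        n_components=min(p.n_components, min(X.shape) - 1),
        svd_solver="randomized",
        random_state=p.seed,
    )
    Z = pca.fit_transform(X).astype(np.float32)
    ev = float(pca.explained_variance_ratio_.sum())
    if ev < p.variance_floor:
        warnings.warn(
            f"retained components explain {ev:.1%} < floor {p.variance_floor:.0%}",
            stacklevel=2,
        )
    return FeatureMatrix(
        X=Z,
        labels=fm.labels,
        trial_ids=fm.trial_ids,
        conditions=fm.conditions,
        explained_variance=ev,
    )


def split_datasets(fm: FeatureMatrix, p: DecoderParams) -> list[dict[str, np.ndarray]]:
    """Cut each condition's trial-ordered rows into contiguous datasets.

    Per condition, the trial-ordered time points are cut into ``n_datasets``
    contiguous blocks and block k of every condition forms dataset k. Cuts
    are placed at trial boundaries (whole trials per dataset, point counts
    balanced as far as the trial graining allows): the coherence features
    are time-smoothed over seconds, so splitting one trial across datasets
    would leak its trial-wide signature across cross-validation folds.
    Windows never span dataset boundaries.
    """
    datasets: list[dict[str, np.ndarray]] = [dict() for _ in range(p.n_datasets)]
    for cond in fm.conditions:
        rows = np.flatnonzero(fm.labels == cond)
        if len(rows) < p.n_datasets * p.window_len:
            raise ValueError(
                f"condition {cond!r} has {len(rows)} time points; needs at least "
                f"{p.n_datasets * p.window_len} for {p.n_datasets} datasets of one window"
            )
        # contiguous runs of one trial, in pooled order
        tids = fm.trial_ids[rows]
        change = np.flatnonzero(tids[1:] != tids[:-1]) + 1
        run_bounds = np.concatenate(([0], change, [len(rows)]))
        n_trials = len(run_bounds) - 1
        if n_trials < p.n_datasets:
            raise ValueError(
                f"condition {cond!r} has {n_trials} trials; needs at least "
                f"{p.n_datasets} for trial-disjoint datasets"
            )
        # cut the run sequence where cumulative size best matches equal shares
        cum = run_bounds[1:]  # points up to and including each trial
        total = len(rows)
        cuts = [0]
        for k in range(1, p.n_datasets):
            target = total * k / p.n_datasets
            j = int(np.argmin(np.abs(cum - target))) + 1
            j = max(j, cuts[-1] + 1)
            j = min(j, n_trials - (p.n_datasets - k))  # leave >=1 trial each
            cuts.append(j)
        cuts.append(n_trials)
        for k in range(p.n_datasets):
            lo = run_bounds[cuts[k]]
            hi = run_bounds[cuts[k + 1]]
            datasets[k][cond] = rows[lo:hi]
    return datasets


def make_windows(
    fm: FeatureMatrix, dataset: dict[str, np.ndarray], p: DecoderParams
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window samples from one dataset.

    Each condition block of length N yields ``(N - window_len)//window_step + 1``
    flattened ``window_len x n_components`` samples (0 with a warning if the
    block is shorter than one window). Returns ``(samples, labels)``.
    """
    xs, ys = [], []
    n_feat = fm.X.shape[1]
    for cond, rows in dataset.items():
        N = len(rows)
        if N < p.window_len:
            warnings.warn(
                f"block of {N} points for {cond!r} is shorter than one window",
                stacklevel=2,
            )
            continue
        n_w = (N - p.window_len) // p.window_step + 1
        block = fm.X[rows]
        idx = np.arange(p.window_len)[None, :] + p.window_step * np.arange(n_w)[:, None]
        xs.append(block[idx].reshape(n_w, p.window_len * n_feat))
        ys.append(np.full(n_w, cond, dtype=object))
    if not xs:
        return np.empty((0, p.window_len * n_feat), np.float32), np.empty(0, object)
    return np.vstack(xs), np.concatenate(ys)


def _rbf_gram(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    d2 = euclidean_distances(A, B, squared=True)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-gamma * d2)


def train_eval(
    sample_sets: list[tuple[np.ndarray, np.ndarray]],
    p: DecoderParams,
    conditions: tuple[str, ...] = CONDITIONS,
    classifier: str = "svm",
) -> DecodingResult:
    """Six-fold cross-validated RBF-SVM decoding over pre-built datasets.

    In each fold one dataset is held out for testing and the rest train the
    classifier; over all folds every dataset is tested exactly once.
    Features enter the kernel in their raw (PCA-score) geometry — the
    variance ordering of the components is what concentrates class signal
    in the distance metric, and per-feature standardization would destroy
    it by amplifying low-variance noise dimensions. A single global scale,
    computed from training-fold statistics only, sets the fixed kernel
    width at its design operating point (gamma times the mean squared
    pairwise distance = 2, the regime the libsvm-default-style gamma is
    meant for); a scalar preserves all distance ratios. Multi-class
    handling is the conventional one-vs-one voting. The confusion matrix is
    aggregated over folds and row-normalized.

    ``classifier='centroid'`` swaps the SVM for a nearest-class-centroid
    rule on the same standardized samples — a heavily regularized readout
    provided as a sensitivity diagnostic: it measures whether class-mean
    pattern differences generalize across folds even when the sample-level
    margin structure (which the SVM fits) is dominated by trial-specific
    variability.
    """
    if classifier not in ("svm", "centroid"):
        raise ValueError(f"unknown classifier {classifier!r}")
    if len(sample_sets) < 2:
        raise ValueError("need at least 2 datasets")
    for k, (_, y) in enumerate(sample_sets):
        missing = set(conditions) - set(y)
        if missing:
            raise ValueError(f"dataset {k} lacks conditions {sorted(missing)}")
    cond_index = {c: i for i, c in enumerate(conditions)}
    counts = np.zeros((len(conditions), len(conditions)), dtype=float)

    for k_test in range(len(sample_sets)):
        X_test, y_test = sample_sets[k_test]
        train_parts = [sample_sets[k] for k in range(len(sample_sets)) if k != k_test]
        X_train = np.vstack([x for x, _ in train_parts])
        y_train = np.concatenate([y for _, y in train_parts])

        # mean squared pairwise distance of the training samples
        d2bar = 2.0 * X_train.astype(np.float64).var(axis=0).sum()
        if d2bar == 0:
            raise ValueError("training samples are all identical")
        scale = np.sqrt(p.kernel_gamma * d2bar / 2.0)
        Ztr = (X_train / scale).astype(np.float32)
        Zte = (X_test / scale).astype(np.float32)

        if classifier == "svm":
            clf = SVC(kernel="precomputed", C=p.svm_c)
            clf.fit(_rbf_gram(Ztr, Ztr, p.kernel_gamma), y_train)
            pred = clf.predict(_rbf_gram(Zte, Ztr, p.kernel_gamma))
        else:
            cents = np.stack([Ztr[y_train == c].mean(axis=0) for c in conditions])
            d2 = euclidean_distances(Zte, cents, squared=True)
            pred = np.asarray(conditions, dtype=object)[d2.argmin(axis=1)]
        for yt, yp in zip(y_test, pred):
            counts[cond_index[yt], cond_index[yp]] += 1

    row_sums = counts.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise ValueError("a condition produced no test samples")
    confusion = counts / row_sums
    per_cond = np.diag(confusion)
    return DecodingResult(
        confusion=confusion,
        per_condition_accuracy=per_cond,
        mean_accuracy=float(per_cond.mean()),
        chance_level=1.0 / len(conditions),
        conditions=conditions,
        n_samples_per_dataset=[len(y) for _, y in sample_sets],
    )


def decode(
    trial_rois: list[tuple[np.ndarray, str, str]],
    wavelet_params: WaveletParams | None = None,
    params: DecoderParams | None = None,
    classifier: str = "svm",
) -> DecodingResult:
    """Full decoding pipeline from per-trial tapping-keypoint ROI matrices.

    ``trial_rois`` holds ``(roi_matrix_14, condition, trial_id)`` tuples.
    ``classifier`` is forwarded to :func:`train_eval`.
    """
    if wavelet_params is None:
        wavelet_params = WaveletParams()
    if params is None:
        params = DecoderParams()
    feats = [
        (pairwise_wtc_features(roi, wavelet_params), cond, tid)
        for roi, cond, tid in trial_rois
    ]
    fm = build_feature_matrix(feats)
    fm = reduce_dimensions(fm, params)
    datasets = split_datasets(fm, params)
    sample_sets = [make_windows(fm, ds, params) for ds in datasets]
    result = train_eval(sample_sets, params, classifier=classifier)
    result.explained_variance = fm.explained_variance
    return result
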