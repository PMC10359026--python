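"""Time-resolved shrinkage-LDA decoding.

A linear discriminant classifier with the Gaussian equal-covariance rule is
trained and tested independently at every timepoint of every fold, on the
channel voltage pattern at that single timepoint.  The pooled within-class
covariance S is regularized toward a scaled identity,

    Sigma = (1 - gamma) * S + gamma * (trace(S) / p) * I,

with a small fixed shrinkage gamma by default (64 channels vs. tens of
training trials per class is near-singular territory); a Ledoit-Wolf
analytic-shrinkage option is available for single-timepoint fits.

For speed, :func:`decode_timecourse` evaluates all timepoints of a fold in
one batched linear-algebra pass, using a dual-space (Woodbury) solve when
the training set is smaller than the channel count.  The batched path is
algebraically identical to :func:`fit_lda`/:func:`predict_lda` and the test
suite checks the equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import FoldSpec
from .synth import EpochedData


@dataclass
class LDAModel:
    classes: np.ndarray
    class_means: np.ndarray  # (K, p)
    covariance: np.ndarray  # (p, p), regularized
    priors: np.ndarray  # (K,)
    shrinkage: float

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


def _class_stats(patterns: np.ndarray, labels: np.ndarray):
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("need >= 2 trials per class")
    return classes, y, counts


def _shrink(S: np.ndarray, gamma: float) -> np.ndarray:
    p = S.shape[0]
    mu = np.trace(S) / p
    if mu <= 0:
        # zero within-class variance (noiseless data): fall back to the
        # nearest-mean rule via an identity covariance
        return np.eye(p)
    return (1.0 - gamma) * S + gamma * mu * np.eye(p)


def _ledoit_wolf_gamma(X: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity toward mu*I for centered rows X (n, p)."""
    n, p = X.shape
    S = X.T @ X / n
    mu = np.trace(S) / p
    d2 = np.sum((S - mu * np.eye(p)) ** 2) / p
    b2 = 0.0
    for i in range(n):
        xi = X[i][:, None]
        b2 += np.sum((xi @ xi.T - S) ** 2) / p
    b2 = min(b2 / n**2, d2)
    return float(b2 / d2) if d2 > 0 else 1.0


def fit_lda(
    patterns: np.ndarray,
    labels: np.ndarray,
    shrinkage: float | str = 0.01,
    priors: str | np.ndarray = "equal",
) -> LDAModel:
    """Fit the shrinkage-regularized LDA model.

    ``shrinkage`` is the fixed intensity gamma in [0, 1], or
    ``"ledoit-wolf"`` for the analytic estimate from the pooled centered
    training data.  With gamma = 0 a singular pooled covariance raises.
    """
    X = np.asarray(patterns, dtype=float)
    y_raw = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y_raw):
        raise ValueError("patterns must be (n_trials, n_channels) matching labels")
    classes, y, counts = _class_stats(X, y_raw)
    n, p = X.shape
    K = len(classes)
    means = np.stack([X[y == k].mean(axis=0) for k in range(K)])
    Xc = X - means[y]
    S = Xc.T @ Xc / (n - K)

    if shrinkage == "ledoit-wolf":
        gamma = _ledoit_wolf_gamma(Xc)
    else:
        gamma = float(shrinkage)
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
    Sigma = _shrink(S, gamma)
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; use shrinkage > 0"
        ) from None

    if isinstance(priors, str):
        if priors == "equal":
            pr = np.full(K, 1.0 / K)
        elif priors == "empirical":
            pr = counts / n
        else:
            raise ValueError("priors must be 'equal', 'empirical', or an array")
    else:
        pr = np.asarray(priors, dtype=float)
        pr = pr / pr.sum()
    return LDAModel(classes, means, Sigma, pr, gamma)


def decision_values(model: LDAModel, patterns: np.ndarray) -> np.ndarray:
    """Per-class discriminant scores delta_k(x) = x' W_k - 0.5 m_k' W_k + log pi_k."""
    X = np.asarray(patterns, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"pattern dimension {X.shape[1]} does not match model ({model.class_means.shape[1]})"
        )
    W = np.linalg.solve(model.covariance, model.class_means.T)  # (p, K)
    bias = -0.5 * np.einsum("kp,pk->k", model.class_means, W) + np.log(model.priors)
    return X @ W + bias


def predict_lda(model: LDAModel, patterns: np.ndarray) -> np.ndarray:
    """Most probable class per pattern; ties break to the first class in order."""
    scores = decision_values(model, patterns)
    return model.classes[np.argmax(scores, axis=1)]


@dataclass
class AccuracyTimecourse:
    participant_id: str
    scheme: str
    times_ms: np.ndarray
    accuracy: np.ndarray  # mean over folds, per timepoint
    n_folds: int

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if len(self.accuracy) != len(self.times_ms):
            raise ValueError("accuracy length must match times_ms")
        if self.accuracy.size and (self.accuracy.min() < -1e-9 or self.accuracy.max() > 1 + 1e-9):
            raise ValueError("accuracy must lie in [0, 1]")


def _encode_labels(train_labels: np.ndarray, test_labels: np.ndarray):
    classes = np.unique(train_labels)
    lut = {c: i for i, c in enumerate(classes)}
    ytr = np.array([lut[c] for c in train_labels])
    yte = np.array([lut[c] for c in test_labels])
    return classes, ytr, yte


def _fold_accuracy_batched(
    data_t: np.ndarray,
    fold: FoldSpec,
    gamma: float,
    method: str = "auto",
) -> np.ndarray:
    """Fraction correct per timepoint for one fold (equal priors).

    ``data_t`` is time-major (T, n_trials, p).  The direct path builds the
    (T, p, p) regularized covariances; the dual path applies the Woodbury
    identity to Sigma = a I + U U' with U the scaled centered training
    data, and evaluates all discriminant scores in the n-dimensional dual
    space, which is much cheaper when n_train < p.
    """
    if gamma < 0 or gamma > 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    classes, ytr, yte = _encode_labels(fold.train_labels, fold.test_labels)
    K = len(classes)
    n = len(fold.train_idx)
    if np.bincount(ytr, minlength=K).min() < 2:
        raise ValueError("need >= 2 training trials per class")
    p = data_t.shape[2]

    X = data_t[:, fold.train_idx, :]  # (T, n, p)
    Xt = data_t[:, fold.test_idx, :]  # (T, m, p)

    onehot = np.eye(K, dtype=np.float32)[ytr]  # (n, K)
    counts = onehot.sum(axis=0)
    M = np.matmul(onehot.T / counts[:, None], X)  # (T, K, p) class means
    Xc = X - np.matmul(onehot, M)
    nu = n - K
    tr = np.einsum("tnp,tnp->t", Xc, Xc) / nu
    mu = (tr / p).astype(np.float32)
    degenerate = mu <= 0  # zero within-class variance -> nearest-mean rule

    use_dual = (method == "dual") or (method == "auto" and n < 2 * p)
    if gamma == 0.0:
        use_dual = False  # need an explicit PD check

    if use_dual:
        a = np.where(degenerate, np.float32(1.0), gamma * mu)  # Sigma = a I + U U'
        scale = np.float32(1.0 - gamma) / np.float32(nu)
        if degenerate.any():
            Xc = np.where(degenerate[:, None, None], np.float32(0.0), Xc)
        Mt = M.transpose(0, 2, 1)  # (T, p, K)
        G = scale * np.matmul(Xc, Xc.transpose(0, 2, 1))  # (T, n, n) = U'U
        G[:, np.arange(n), np.arange(n)] += a[:, None]
        UtM = np.matmul(Xc, Mt)  # (T, n, K)
        sol = np.linalg.solve(G, UtM)  # (T, n, K)
        # scores = (Xt Sigma^-1 M') via Woodbury, all in dual space
        XtM = np.matmul(Xt, Mt)  # (T, m, K)
        XtU = np.matmul(Xt, Xc.transpose(0, 2, 1))  # (T, m, n)
        inv_a = (np.float32(1.0) / a)[:, None, None]
        scores = (XtM - scale * np.matmul(XtU, sol)) * inv_a
        MM = np.einsum("tkp,tpk->tk", M, Mt)  # diag of M M'
        Msol = np.einsum("tnk,tnk->tk", UtM, sol)
        bias = np.float32(-0.5) * (MM - scale * Msol) * inv_a[:, :, 0]
    else:
        S = np.matmul(Xc.transpose(0, 2, 1), Xc) / np.float32(nu)  # (T, p, p)
        Sigma = (np.float32(1.0) - np.float32(gamma)) * S
        diag = np.arange(p)
        Sigma[:, diag, diag] += np.float32(gamma) * mu[:, None]
        if degenerate.any():
            Sigma[degenerate] = np.eye(p, dtype=np.float32)
        if gamma == 0.0:
            try:
                np.linalg.cholesky(Sigma.astype(np.float64))
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    "singular pooled covariance with shrinkage = 0; use shrinkage > 0"
                ) from None
        W = np.linalg.solve(Sigma, M.transpose(0, 2, 1))  # (T, p, K)
        bias = -0.5 * np.einsum("tkp,tpk->tk", M, W)
        scores = np.matmul(Xt, W) + bias[:, None, :]
        pred = scores.argmax(axis=2)
        return (pred == yte[None, :]).mean(axis=1)

    pred = (scores + bias[:, None, :]).argmax(axis=2)
    return (pred == yte[None, :]).mean(axis=1)


def compute_gram(d: EpochedData) -> np.ndarray:
    """Per-timepoint trial-by-trial Gram tensor (T, N, N), float32.

    Every fold's dual-space LDA is a function of submatrices of this
    tensor, so precomputing it once per participant amortizes all
    channel-dimension products across folds and schemes.
    """
    data_t = np.ascontiguousarray(d.data.transpose(2, 0, 1), dtype=np.float32)
    return np.matmul(data_t, data_t.transpose(0, 2, 1))


def _fold_accuracy_gram(gram: np.ndarray, fold: FoldSpec, gamma: float, p: int) -> np.ndarray:
    """Dual-space fold evaluation from the precomputed Gram tensor.

    Identical model to :func:`_fold_accuracy_batched` (dual path); requires
    gamma > 0.  ``p`` is the channel count (needed for the shrinkage
    target trace(S)/p).
    """
    if gamma <= 0 or gamma > 1:
        raise ValueError("gram path requires shrinkage in (0, 1]")
    classes, ytr, yte = _encode_labels(fold.train_labels, fold.test_labels)
    K = len(classes)
    n = len(fold.train_idx)
    if np.bincount(ytr, minlength=K).min() < 2:
        raise ValueError("need >= 2 training trials per class")
    nu = n - K

    GII = gram[:, fold.train_idx[:, None], fold.train_idx[None, :]]  # (T, n, n)
    GJI = gram[:, fold.test_idx[:, None], fold.train_idx[None, :]]  # (T, m, n)

    onehot = np.eye(K, dtype=np.float32)[ytr]
    counts = onehot.sum(axis=0)
    A = onehot / counts  # (n, K): class-averaging matrix
    C = np.eye(n, dtype=np.float32) - A @ onehot.T  # within-class centering

    CG = np.matmul(C, GII)  # (T, n, n) = Xc X_I'
    H = np.matmul(CG, C.T)  # (T, n, n) = Xc Xc'
    diag = np.arange(n)
    tr = H[:, diag, diag].sum(axis=1) / np.float32(nu)
    mu = tr / p
    degenerate = mu <= 0  # Xc == 0 there, so H, UtM vanish automatically
    a = np.where(degenerate, np.float32(1.0), np.float32(gamma) * mu)
    scale = np.float32(1.0 - gamma) / np.float32(nu)

    Gw = scale * H
    Gw[:, diag, diag] += a[:, None]
    GIIA = np.matmul(GII, A)  # (T, n, K) = X_I M'
    UtM = np.matmul(C, GIIA)  # (T, n, K) = Xc M'
    sol = np.linalg.solve(Gw, UtM)

    XtM = np.matmul(GJI, A)  # (T, m, K)
    Csol = np.matmul(C.T, sol)  # (T, n, K); X_J Xc' sol = GJI (C' sol)
    inv_a = (np.float32(1.0) / a)[:, None, None]
    scores = (XtM - scale * np.matmul(GJI, Csol)) * inv_a
    MM = np.einsum("nk,tnk->tk", A, GIIA)  # diag of M M'
    Msol = np.einsum("tnk,tnk->tk", UtM, sol)
    bias = np.float32(-0.5) * (MM - scale * Msol) * inv_a[:, :, 0]

    pred = (scores + bias[:, None, :]).argmax(axis=2)
    return (pred == yte[None, :]).mean(axis=1)


#: trial counts up to which the Gram tensor (T x N x N) is precomputed
_GRAM_MAX_TRIALS = 256


def decode_timecourse(
    d: EpochedData,
    folds: list[FoldSpec],
    shrinkage: float = 0.01,
    scheme_name: str = "",
    method: str = "auto",
    gram: np.ndarray | None = None,
) -> AccuracyTimecourse:
    """Cross-validated decoding accuracy per timepoint, averaged over folds.

    A precomputed ``gram`` (from :func:`compute_gram`) may be passed to
    share channel-dimension work across schemes; it is derived
    automatically for small datasets.
    """
    if not folds:
        raise ValueError("need at least one fold")
    n_trials = d.n_trials
    for f in folds:
        if f.train_idx.max() >= n_trials or f.test_idx.max() >= n_trials:
            raise IndexError("fold references trials beyond the data")
    gamma = float(shrinkage)
    use_gram = method in ("auto", "gram") and gamma > 0
    if method == "auto" and gram is None and n_trials > _GRAM_MAX_TRIALS:
        use_gram = False
    acc = np.zeros(d.n_times)
    if use_gram:
        if gram is None:
            gram = compute_gram(d)
        for f in folds:
            acc += _fold_accuracy_gram(gram, f, gamma, d.n_channels)
    else:
        data_t = np.ascontiguousarray(d.data.transpose(2, 0, 1), dtype=np.float32)
        for f in folds:
            acc += _fold_accuracy_batched(data_t, f, gamma, method=method)
    acc /= len(folds)
    return AccuracyTimecourse(d.participant_id, scheme_name, d.times_ms, acc, len(folds))


def smooth_timecourse(tc: AccuracyTimecourse, window_points: int = 3) -> AccuracyTimecourse:
    """Centered moving average; the window shrinks at the series edges."""
    if window_points % 2 != 1:
        raise ValueError("window must be odd")
    n = len(tc.accuracy)
    if window_points > n:
        raise ValueError(f"window ({window_points}) exceeds series length ({n})")
    kernel = np.ones(window_points)
    sums = np.convolve(tc.accuracy, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return AccuracyTimecourse(tc.participant_id, tc.scheme, tc.times_ms, sums / counts, tc.n_folds)
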