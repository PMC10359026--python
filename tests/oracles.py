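"""Independent brute-force oracles used to validate the implementation.

These are deliberately written from first principles (explicit inverses,
definition-level step-up) and share no code with the package.
"""

import numpy as np


def brute_force_lda_scores(Xtr, ytr, Xte, gamma):
    """Gaussian equal-covariance discriminant with the shrinkage target
    (1-g) S + g (trace(S)/p) I, equal priors, via an explicit inverse."""
    classes = np.unique(ytr)
    n, p = Xtr.shape
    means = np.array([Xtr[ytr == c].mean(axis=0) for c in classes])
    resid = Xtr - np.array([means[list(classes).index(c)] for c in ytr])
    S = resid.T @ resid / (n - len(classes))
    if np.trace(S) == 0:
        Sigma = np.eye(p)
    else:
        Sigma = (1 - gamma) * S + gamma * (np.trace(S) / p) * np.eye(p)
    Si = np.linalg.inv(Sigma)
    scores = np.empty((len(Xte), len(classes)))
    for j, m in enumerate(means):
        scores[:, j] = Xte @ Si @ m - 0.5 * m @ Si @ m
    return classes, scores


def brute_force_bh(p, alpha=0.05):
    """Benjamini-Hochberg adjusted p values and step-up rejections, from
    the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = ranked * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    thresh = (np.arange(m) + 1) / m * alpha
    below = np.flatnonzero(ranked <= thresh)
    sig = np.zeros(m, dtype=bool)
    if below.size:
        sig[order[: below.max() + 1]] = True
    return out, sig
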