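"""Within-subject permutation oracles for the three-condition post-hoc tests.

Independent of the package implementation: condition labels are permuted
within each subject and the studentized-range / mean-rank-difference null
distributions are built by Monte Carlo.
"""

import itertools

import numpy as np
from scipy import stats


def _permute(X: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    n, k = X.shape
    orders = np.array(list(itertools.permutations(range(k))))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(orders), size=(n_perm, n))
    cols = orders[idx]
    return X[np.arange(n)[None, :, None], cols]  # (P, n, k)


def perm_tukey_pvalues(X: np.ndarray, n_perm: int = 100_000, seed: int = 123):
    """Permutation p per pair: P(studentized range >= observed pairwise q)."""
    n, k = X.shape
    perm = _permute(X, n_perm, seed)
    grand = perm.mean(axis=(1, 2), keepdims=True)
    subj = perm.mean(axis=2, keepdims=True)
    cond = perm.mean(axis=1, keepdims=True)
    resid = perm - subj - cond + grand
    mse = (resid**2).sum(axis=(1, 2)) / ((n - 1) * (k - 1))
    cmeans = perm.mean(axis=1)
    qrange = (cmeans.max(axis=1) - cmeans.min(axis=1)) / np.sqrt(mse / n)

    grand0 = X.mean()
    resid0 = X - X.mean(1, keepdims=True) - X.mean(0, keepdims=True) + grand0
    mse0 = (resid0**2).sum() / ((n - 1) * (k - 1))
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(X[:, j].mean() - X[:, i].mean()) / np.sqrt(mse0 / n)
            out[(i, j)] = float(np.mean(qrange >= q - 1e-12))
    return out


def perm_dunn_pvalues(X: np.ndarray, n_perm: int = 100_000, seed: int = 123):
    """Permutation p per pair: mid-p of |mean rank diff|, Bonferroni x3.

    The rank-permutation null is discrete with large atoms; the mid-p
    convention (count half of the ties with the observed statistic) is the
    standard way to compare it against a continuous approximation.
    """
    n, k = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    mr = ranks.mean(axis=0)
    perm = _permute(ranks, n_perm, seed)
    pmr = perm.mean(axis=1)
    n_pairs = k * (k - 1) // 2
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            obs = abs(mr[j] - mr[i])
            null = np.abs(pmr[:, j] - pmr[:, i])
            gt = float(np.mean(null > obs + 1e-9))
            eq = float(np.mean(np.abs(null - obs) <= 1e-9))
            out[(i, j)] = min(1.0, (gt + 0.5 * eq) * n_pairs)
    return out
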