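"""Maximum-likelihood admixture: ancestry proportions Q and ancestral allele
frequencies P for k clusters, fitted by EM, with cross-validation over k.

Model: genotype g_ij ~ Binomial(2, sum_l q_il p_lj), with Q rows on the
simplex and P in [0, 1].  The EM updates (frappe-style) ascend the observed
log-likelihood monotonically; missing genotypes are simply skipped.  Because
the likelihood is invariant to cluster relabelling, :func:`align_columns`
matches clusters between fits by Hungarian assignment on Q-column
correlations.

Model choice follows the usual practice: fit a range of k, mask a random
subset of genotype entries per cross-validation fold, and score each k by
the mean squared error of the masked dosages predicted as 2 * (Q P); the k
with the smallest CV error is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotypes import MISSING, GenotypeMatrix

_EPS = 1e-6


@dataclass
class AdmixtureFit:
    k: int
    Q: np.ndarray        # n x k, rows on the simplex
    P: np.ndarray        # k x m, in [eps, 1-eps]
    loglik: float
    n_iter: int
    converged: bool
    seed: int
    loglik_history: list[float] | None = None


@dataclass
class CVResult:
    k: int
    mean_cv_error: float
    fold_errors: list[float]


def _loglik(g: np.ndarray, obs: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    f = Q @ P
    ll = np.where(obs, g * np.log(f) + (2.0 - g) * np.log1p(-f), 0.0)
    return float(ll.sum())


def _em_once(g: np.ndarray, obs: np.ndarray, k: int, rng: np.random.Generator,
             max_iter: int, tol: float, history: list[float] | None = None):
    n, m = g.shape
    Q = rng.dirichlet(np.ones(k), size=n)
    freqs = np.where(obs, g, np.nan)
    base = np.nanmean(freqs, axis=0) / 2.0
    base = np.nan_to_num(base, nan=0.5)
    P = np.clip(base[None, :] + rng.uniform(-0.1, 0.1, size=(k, m)), _EPS, 1.0 - _EPS)
    Q = np.clip(Q, _EPS, None)
    Q /= Q.sum(axis=1, keepdims=True)

    g0 = np.where(obs, g, 0.0)
    two_minus_g = np.where(obs, 2.0 - g, 0.0)
    ll = _loglik(g0, obs, Q, P)
    if history is not None:
        history.append(ll)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        F = Q @ P
        U = g0 / F
        V = two_minus_g / (1.0 - F)
        # Q update: q_il <- q_il * [ (U P^T)_il + (V (1-P)^T)_il ], normalised
        Qn = Q * (U @ P.T + V @ (1.0 - P).T)
        Qn /= Qn.sum(axis=1, keepdims=True)
        # P update: p_lj <- p_lj (Q^T U)_lj / [ p_lj (Q^T U)_lj + (1-p_lj)(Q^T V)_lj ]
        A = Q.T @ U
        B = Q.T @ V
        num = P * A
        den = num + (1.0 - P) * B
        with np.errstate(invalid="ignore", divide="ignore"):
            Pn = np.where(den > 0, num / den, P)
        Q = np.clip(Qn, _EPS, None)
        Q /= Q.sum(axis=1, keepdims=True)
        P = np.clip(Pn, _EPS, 1.0 - _EPS)
        ll_new = _loglik(g0, obs, Q, P)
        if not np.isfinite(ll_new):
            raise FloatingPointError("non-finite log-likelihood")
        if history is not None:
            history.append(ll_new)
        if ll_new - ll < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return Q, P, ll, it, converged


def fit_admixture(gm: GenotypeMatrix | np.ndarray, k: int, seed: int = 0,
                  max_iter: int = 2000, tol: float = 1e-6,
                  n_restarts: int = 3, record_history: bool = False) -> AdmixtureFit:
    """Fit the k-cluster admixture model by EM with multiple restarts.

    Accepts a GenotypeMatrix or a raw dosage array (missing = -1).  The best
    of ``n_restarts`` seeded starts by final log-likelihood is returned.
    With k = 1 the fit reduces to the sample allele frequencies.
    """
    calls = gm.calls if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    n, m = calls.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    obs = calls != MISSING
    g = calls.astype(float)

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed + 1) * 100_003 + r)
        hist: list[float] | None = [] if record_history else None
        Q, P, ll, it, conv = _em_once(g, obs, k, rng, max_iter, tol, history=hist)
        if best is None or ll > best[2]:
            best = (Q, P, ll, it, conv, hist)
    Q, P, ll, it, conv, hist = best
    return AdmixtureFit(k=k, Q=Q, P=P, loglik=ll, n_iter=it, converged=conv,
                        seed=seed, loglik_history=hist)


def predict_dosage(fit: AdmixtureFit) -> np.ndarray:
    """Expected dosage matrix 2 * (Q P)."""
    return 2.0 * fit.Q @ fit.P


def cv_error(gm: GenotypeMatrix | np.ndarray, k: int, folds: int = 5, seed: int = 0,
             max_iter: int = 500, tol: float = 1e-4, n_restarts: int = 1) -> CVResult:
    """Masked-entry cross-validation error for one k.

    Non-missing genotype entries are partitioned at random into ``folds``
    folds; per fold those entries are masked, the model refitted, and the
    masked dosages predicted as 2 Q P; the fold error is their mean squared
    error.  Returns the mean across folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    calls = (gm.calls if isinstance(gm, GenotypeMatrix) else np.asarray(gm)).copy()
    obs_idx = np.argwhere(calls != MISSING)
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, folds, size=len(obs_idx))

    errors = []
    for f in range(folds):
        mask = obs_idx[assignment == f]
        if len(mask) == 0:
            raise ValueError(f"fold {f} has no masked entries")
        work = calls.copy()
        work[mask[:, 0], mask[:, 1]] = MISSING
        fit = fit_admixture(work, k, seed=seed * folds + f, max_iter=max_iter,
                            tol=tol, n_restarts=n_restarts)
        pred = predict_dosage(fit)
        truth = calls[mask[:, 0], mask[:, 1]].astype(float)
        errors.append(float(np.mean((truth - pred[mask[:, 0], mask[:, 1]]) ** 2)))
    return CVResult(k=k, mean_cv_error=float(np.mean(errors)), fold_errors=errors)


def choose_k(gm: GenotypeMatrix | np.ndarray, k_values, folds: int = 5,
             seed: int = 0, **kwargs) -> tuple[int, list[CVResult]]:
    """Cross-validate each k and return (best k, all CV results)."""
    results = [cv_error(gm, k, folds=folds, seed=seed, **kwargs) for k in k_values]
    best = min(results, key=lambda r: (r.mean_cv_error, r.k))
    return best.k, results


def align_columns(fit_a: AdmixtureFit, fit_b: AdmixtureFit) -> np.ndarray:
    """Permutation p of b's clusters best matching a's, by Hungarian
    assignment on Q-column Pearson correlation (constant columns score 0).

    ``fit_b.Q[:, p]`` lines up with ``fit_a.Q``.
    """
    if fit_a.k != fit_b.k:
        raise ValueError("fits have different k")
    k = fit_a.k
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            x, y = fit_a.Q[:, i], fit_b.Q[:, j]
            if np.std(x) < 1e-12 or np.std(y) < 1e-12:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(x, y)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm
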