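"""Classical (Torgerson) multidimensional scaling of trajectory
dissimilarities, with out-of-sample projection and stability checks.

Classical MDS double-centers the squared-distance matrix,
``B = -1/2 J D^2 J``, and takes the leading eigenvectors of ``B`` scaled
by the square roots of their eigenvalues as coordinates.  Optimal-
matching distances are metric but not guaranteed Euclidean, so negative
eigenvalues can appear; they are excluded from the scores and from the
variance-explained denominator, and their relative mass is reported.

Out-of-sample points (e.g. a replication cohort) are placed by Gower
interpolation from their distances to the training points, which is
exact for the training points themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes

__all__ = [
    "EmbeddingResult",
    "StabilityReport",
    "classical_mds",
    "project_new",
    "jackknife_stability",
    "permutation_stability",
    "interpret_dimensions",
]


@dataclass
class EmbeddingResult:
    """MDS eigenstructure plus the centering statistics needed to project
    new points later."""

    eigenvalues: np.ndarray  # full spectrum, descending
    scores: np.ndarray  # (n, k)
    variance_explained: np.ndarray  # per retained dimension
    cumulative_variance: np.ndarray
    row_means: np.ndarray  # row means of the squared-distance matrix
    grand_mean: float
    negative_mass: float  # |sum of negative eigenvalues| / sum |eigenvalues|

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return D


def classical_mds(D, k: int) -> EmbeddingResult:
    """Torgerson scaling of a dissimilarity matrix to ``k`` dimensions.

    Variance-explained fractions are taken over the positive eigenvalues
    only.  Raises if fewer than ``k`` positive eigenvalues exist.  Each
    dimension's sign is fixed by making its largest-magnitude loading
    positive (callers may re-orient against interpretable features).
    """
    values = getattr(D, "values", D)
    D = _check_dissimilarity(values)
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError("require 1 <= k < n")
    D2 = D ** 2
    row_means = D2.mean(axis=1)
    grand = float(D2.mean())
    B = -0.5 * (D2 - row_means[:, None] - row_means[None, :] + grand)
    lam, vec = eigh(B)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = max(abs(lam[0]), 1.0) * n * np.finfo(float).eps
    pos = lam > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalue: matrix carries no usable dimension")
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the {n_pos} positive eigenvalue(s)")
    scores = vec[:, :k] * np.sqrt(lam[:k])
    # deterministic sign: largest-|loading| element positive
    flip = np.sign(scores[np.argmax(np.abs(scores), axis=0),
                          np.arange(k)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    pos_sum = lam[pos].sum()
    ve = lam[:k] / pos_sum
    neg_mass = float(-lam[lam < -tol].sum() / np.abs(lam).sum()) if np.any(
        lam < -tol) else 0.0
    return EmbeddingResult(lam, scores, ve, np.cumsum(ve), row_means, grand,
                           neg_mass)


def project_new(d_new, emb: EmbeddingResult) -> np.ndarray:
    """Gower interpolation of a new point (or points) from its distances to
    all training points; exact for training points."""
    d = np.atleast_2d(np.asarray(d_new, dtype=float))
    if d.shape[1] != emb.row_means.shape[0]:
        raise ValueError("distance vector length does not match training size")
    b = -0.5 * (d ** 2 - emb.row_means[None, :])
    lam = emb.eigenvalues[:emb.k]
    out = (b @ emb.scores) / lam
    return out[0] if np.asarray(d_new).ndim == 1 else out


@dataclass
class StabilityReport:
    jackknife_coefficient: float
    n_deletions: int
    permutation_p: float | None = None


def _procrustes_align(X, Y):
    """Align Y to X by translation, rotation/reflection and scaling."""
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    R, s = orthogonal_procrustes(Yc, Xc)
    scale = s / (Yc ** 2).sum() if (Yc ** 2).sum() > 0 else 1.0
    return Yc @ R * scale + mx


def jackknife_stability(D, k: int, max_leave_out: int = 200,
                        seed: int | None = 0) -> StabilityReport:
    """Leave-one-out stability of the MDS configuration.

    Each deletion re-embeds the remaining points, Procrustes-aligns them
    to the full solution, and accumulates squared displacements; the
    coefficient is ``1 - mean squared displacement / total score
    variance``, clipped to [0, 1].  For large n, deletions are subsampled
    to ``max_leave_out``.
    """
    values = getattr(D, "values", D)
    D = _check_dissimilarity(values)
    n = D.shape[0]
    if n < 10:
        raise ValueError("jackknife requires at least 10 points")
    full = classical_mds(D, k)
    total_var = float(((full.scores - full.scores.mean(axis=0)) ** 2).mean())
    if total_var <= 0:
        raise ValueError("degenerate embedding: zero score variance")
    rng = np.random.default_rng(seed)
    deletions = (np.arange(n) if n <= max_leave_out else
                 rng.choice(n, size=max_leave_out, replace=False))
    sq = []
    for i in deletions:
        keep = np.delete(np.arange(n), i)
        sub = classical_mds(D[np.ix_(keep, keep)], k)
        aligned = _procrustes_align(full.scores[keep], sub.scores)
        sq.append(((aligned - full.scores[keep]) ** 2).mean())
    coef = float(np.clip(1.0 - np.mean(sq) / total_var, 0.0, 1.0))
    return StabilityReport(coef, len(deletions))


def permutation_stability(D, k: int, n_permutations: int = 99,
                          seed: int | None = 0) -> float:
    """Heuristic permutation test of the embedding's variance concentration.

    Compares the observed top-``k`` positive-eigenvalue variance fraction
    against matrices whose off-diagonal entries are symmetrically
    shuffled, destroying any low-dimensional structure while keeping the
    distance distribution.  Returns the permutation p-value.  This is a
    documented placeholder: the canonical form of this test is not
    standardized.
    """
    values = getattr(D, "values", D)
    D = _check_dissimilarity(values)
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    obs = classical_mds(D, k).cumulative_variance[-1]
    iu = np.triu_indices(n, 1)
    hits = 0
    for _ in range(n_permutations):
        vals = rng.permutation(D[iu])
        P = np.zeros_like(D)
        P[iu] = vals
        P = P + P.T
        try:
            stat = classical_mds(P, k).cumulative_variance[-1]
        except ValueError:
            stat = 0.0
        hits += stat >= obs
    return (hits + 1) / (n_permutations + 1)


def interpret_dimensions(scores, features) -> "pandas.DataFrame":
    """Post-hoc interpretation of each (standardized) MDS dimension.

    For every column of ``features`` (a DataFrame aligned with the score
    rows): binary columns are modeled by logistic regression of the
    indicator on the dimension (odds ratio per SD), continuous columns
    (e.g. total comorbidity count, age at first diagnosis) by ordinary
    least squares.  Returns a tidy table of effects with CIs, p-values
    and flags for separation or constant features.
    """
    import pandas as pd
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    if len(features) != scores.shape[0]:
        raise ValueError("features are not aligned with scores")
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
    rows = []
    for col in features.columns:
        y = np.asarray(features[col], dtype=float)
        uniq = np.unique(y[~np.isnan(y)])
        is_binary = uniq.size <= 2 and set(uniq).issubset({0.0, 1.0})
        for j in range(z.shape[1]):
            rec = {"dimension": j + 1, "feature": col,
                   "kind": "logistic" if is_binary else "linear",
                   "flag": ""}
            ok = ~np.isnan(y)
            if uniq.size < 2:
                rec.update(effect=np.nan, ci_low=np.nan, ci_high=np.nan,
                           p=np.nan, flag="constant_feature")
                rows.append(rec)
                continue
            X = sm.add_constant(z[ok, j])
            try:
                if is_binary:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = sm.Logit(y[ok], X).fit(disp=0, maxiter=200)
                    beta = fit.params[1]
                    ci = fit.conf_int()[1]
                    if abs(beta) > 15:  # quasi-separation
                        rec["flag"] = "separation"
                    rec.update(effect=float(np.exp(beta)),
                               ci_low=float(np.exp(ci[0])),
                               ci_high=float(np.exp(ci[1])),
                               p=float(fit.pvalues[1]))
                else:
                    fit = sm.OLS(y[ok], X).fit()
                    ci = fit.conf_int()[1]
                    rec.update(effect=float(fit.params[1]),
                               ci_low=float(ci[0]), ci_high=float(ci[1]),
                               p=float(fit.pvalues[1]))
            except Exception as exc:  # separation / non-convergence
                rec.update(effect=np.inf, ci_low=np.nan, ci_high=np.nan,
                           p=np.nan, flag=f"fit_failed:{type(exc).__name__}")
                warnings.warn(f"dimension {j+1} vs {col}: {exc}")
            rows.append(rec)
    return pd.DataFrame(rows)
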