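"""Association testing of trajectory dimensions and clusters against risk
factors and outcomes, and the replication-projection harness.

The joint test is a MANCOVA relating the retained MDS dimension scores
(dependent) to one predictor at a time plus covariates, summarized by
Pillai's trace with its standard F approximation.  Predictors passing a
Bonferroni threshold get post-hoc per-dimension ordinary least squares.
Cluster membership is analyzed analogously by multinomial logistic
regression against a reference cluster.  A replication cohort is scored
by projecting its trajectories onto the primary embedding and re-running
the associations, reporting sign concordance with the primary effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationResult",
    "ClusterAssociationResult",
    "mancova",
    "posthoc_regressions",
    "association_table",
    "cluster_association",
    "replication_harness",
]


@dataclass
class AssociationResult:
    variable: str
    n_nonmissing: int
    joint_F: float
    joint_p: float
    betas: np.ndarray | None = None  # filled only if joint test passes
    posthoc_p: np.ndarray | None = None


@dataclass
class ClusterAssociationResult:
    variable: str
    reference: int
    odds_ratios: dict  # cluster -> OR per unit predictor
    p_values: dict
    flagged: str = ""


def _design(predictor, covariates, name="predictor"):
    """Listwise-deleted design matrix [const, predictor, covariates]."""
    pred = np.asarray(predictor, dtype=float)
    cols = {name: pred}
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols[str(c)] = np.asarray(cov[c], dtype=float)
    X = pd.DataFrame(cols)
    ok = ~X.isna().any(axis=1).to_numpy()
    X = X.loc[ok]
    if np.nanstd(X[name].to_numpy()) == 0:
        raise ValueError("constant predictor")
    Xm = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in X.columns])
    names = ["const"] + list(X.columns)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify a collinear column via QR
        _, R = np.linalg.qr(Xm)
        bad = [names[i] for i in range(Xm.shape[1])
               if abs(R[i, i]) < 1e-10 * abs(R).max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return Xm, names, ok


def mancova(scores, predictor, covariates=None,
            variable: str = "predictor") -> AssociationResult:
    """Pillai's-trace MANCOVA of the score matrix on one predictor,
    adjusting for covariates; missing predictor/covariate values are
    deleted listwise.

    The trace and its standard F approximation are computed directly so
    that an exact linear dependence of the scores on the predictor
    (Pillai -> 1) yields F = inf, p = 0 rather than a numerical
    breakdown of the residual SSCP inverse.
    """
    from scipy import stats as _st

    scores = np.asarray(scores, dtype=float)
    Xm, names, ok = _design(predictor, covariates)
    Y = scores[ok]
    n, p = Y.shape
    r = Xm.shape[1]
    B, *_ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ B
    E = resid.T @ resid
    df_e = n - r
    L = np.zeros((1, r))
    L[0, 1] = 1.0  # test the predictor coefficient only
    XtX_inv = np.linalg.pinv(Xm.T @ Xm)
    LB = L @ B
    H = LB.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ LB
    V = float(np.trace(H @ np.linalg.pinv(H + E)))
    V = min(max(V, 0.0), 1.0)  # q = 1 degree of freedom
    df1, df2 = p, df_e - p + 1
    if df2 <= 0:
        raise ValueError("too few observations for the MANCOVA F test")
    if V >= 1.0 - 1e-12:
        F, pval = float("inf"), 0.0
    else:
        F = (V / (1.0 - V)) * df2 / df1
        pval = float(_st.f.sf(F, df1, df2))
    return AssociationResult(variable, int(ok.sum()), float(F), pval)


def posthoc_regressions(scores, predictor, covariates=None):
    """Per-dimension OLS of each score on the predictor plus covariates;
    returns (betas, p_values) for the predictor coefficient (1-df F)."""
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    Xm, names, ok = _design(predictor, covariates)
    betas, ps = [], []
    for j in range(scores.shape[1]):
        fit = sm.OLS(scores[ok, j], Xm).fit()
        betas.append(float(fit.params[1]))
        ps.append(float(fit.pvalues[1]))
    return np.array(betas), np.array(ps)


def association_table(scores, variables: pd.DataFrame, covariates=None,
                      threshold: float = 0.002) -> pd.DataFrame:
    """Run the MANCOVA per variable and post-hoc regressions for those
    passing ``threshold``; returns a table with one row per variable
    (N, joint F, joint p, per-dimension betas and p-values)."""
    k = np.asarray(scores).shape[1]
    rows = []
    for var in variables.columns:
        try:
            res = mancova(scores, variables[var], covariates, variable=var)
        except ValueError as exc:
            warnings.warn(f"{var}: {exc}")
            continue
        rec = {"variable": var, "n": res.n_nonmissing,
               "F": res.joint_F, "p": res.joint_p}
        if res.joint_p < threshold:
            betas, ps = posthoc_regressions(scores, variables[var], covariates)
            res.betas, res.posthoc_p = betas, ps
            for j in range(k):
                rec[f"beta{j+1}"] = betas[j]
                rec[f"p{j+1}"] = ps[j]
        else:
            for j in range(k):
                rec[f"beta{j+1}"] = np.nan
                rec[f"p{j+1}"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def cluster_association(labels, predictor, covariates=None, reference=None,
                        variable: str = "predictor") -> ClusterAssociationResult:
    """Multinomial logistic regression of cluster membership on one
    predictor (plus covariates), reporting per-cluster odds ratios
    against the reference cluster."""
    import statsmodels.api as sm

    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least two clusters")
    if reference is None:
        reference = clusters[0]
    if reference not in clusters:
        raise ValueError(f"reference cluster {reference} not present")
    Xm, names, ok = _design(predictor, covariates)
    lab = labels[ok]
    # recode so the reference is category 0
    others = [c for c in clusters if c != reference]
    recoded = np.zeros(len(lab), dtype=int)
    for i, c in enumerate(others, start=1):
        recoded[lab == c] = i
    flagged = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(recoded, Xm).fit(disp=0, maxiter=500)
        if not fit.mle_retvals.get("converged", True):
            flagged = "non-convergence"
    except Exception as exc:
        raise ValueError(f"multinomial fit failed ({exc}); possible "
                         "separation or empty cluster") from exc
    params = np.asarray(fit.params)  # (n_exog, k-1)
    pvals = np.asarray(fit.pvalues)
    ors = {c: float(np.exp(params[1, i])) for i, c in enumerate(others)}
    ps = {c: float(pvals[1, i]) for i, c in enumerate(others)}
    if any(abs(params[1, i]) > 15 for i in range(len(others))):
        flagged = (flagged + ";separation").strip(";")
    return ClusterAssociationResult(variable, reference, ors, ps, flagged)


def replication_harness(primary_scores, primary_embedding,
                        replication_sequences, primary_sequences,
                        cost_model, transition_model,
                        variables_primary: pd.DataFrame,
                        variables_replication: pd.DataFrame,
                        covariates_primary=None, covariates_replication=None,
                        threshold: float = 0.002) -> dict:
    """Project a replication cohort onto the primary embedding and re-test
    the primary associations.

    Returns the replication association table, the projected scores, and
    the sign concordance of post-hoc effects for variables significant in
    the primary cohort.
    """
    from .dissimilarity import cross_matrix
    from .embedding import project_new

    if len(replication_sequences) == 0:
        raise ValueError("empty replication set")
    d = cross_matrix(replication_sequences, primary_sequences, cost_model,
                     transition_model)
    rep_scores = project_new(d, primary_embedding)
    primary_tab = association_table(primary_scores, variables_primary,
                                    covariates_primary, threshold)
    rep_tab = association_table(
        rep_scores, variables_replication, covariates_replication,
        threshold=1.1)  # always fill post-hoc effects for comparison
    concord, total = 0, 0
    for _, prow in primary_tab.iterrows():
        if not prow["p"] < threshold:
            continue
        rrow = rep_tab[rep_tab.variable == prow["variable"]]
        if rrow.empty:
            continue
        rrow = rrow.iloc[0]
        for c in primary_tab.columns:
            if c.startswith("beta") and np.isfinite(prow[c]):
                total += 1
                concord += np.sign(prow[c]) == np.sign(rrow[c])
    return {
        "replication_scores": rep_scores,
        "primary_table": primary_tab,
        "replication_table": rep_tab,
        "sign_concordance": (concord / total) if total else float("nan"),
        "n_compared": total,
    }
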