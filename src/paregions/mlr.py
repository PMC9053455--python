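"""Baseline-category multinomial logistic regression with full diagnostics.

The model: with J response categories and baseline h, the probability of
category j for covariate row x is

    P(Y = j) = exp(x' b_j) / (1 + sum_g exp(x' b_g)),     b_h = 0,

so each non-baseline category contributes one logit contrast
ln(P_j / P_h) = x' b_j.  Estimation is by maximum likelihood with full
Newton-Raphson on the observed information (step-halving on any likelihood
decrease); the inverse observed information doubles as the Wald covariance.
Predictors enter on their raw scales; internally the optimizer works on
standardized copies for conditioning and maps coefficients and covariance
back exactly.

Diagnostics: Wald inference with odds ratios and confidence bounds, the
likelihood-ratio test against the intercept-only model, Cox-Snell and
Nagelkerke pseudo-R2, the classification hit ratio against the maximum
chance criterion, tolerance / variance-inflation collinearity screening, and
the Hausman-McFadden test of the independence-of-irrelevant-alternatives
assumption (one run per omitted non-baseline category, with an explicit
"inconclusive" flag when the covariance difference is not positive
definite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .synthetic import COVARIATE_NAMES
from .taxonomy import ClusterSolution

logger = logging.getLogger(__name__)

DEFAULT_BASELINE = "unhealthy"
DEFAULT_REFERENCE_DROPS = ("agriculture", "pop_gt64")


class RankDeficiencyError(ValueError):
    """Raised when the predictor matrix is not full rank."""


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class MLRDesign:
    """Response codes, design matrix and naming for one fit.

    ``y`` holds integer codes into ``categories``; the baseline category is
    the *last* entry of ``categories`` and carries no free coefficients.
    ``X`` includes the leading intercept column.
    """

    X: np.ndarray
    y: np.ndarray
    categories: List[str]
    predictor_names: List[str]
    baseline: str

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    @property
    def J(self) -> int:
        return len(self.categories)


def build_design(
    covariates: pd.DataFrame,
    solution: ClusterSolution,
    baseline: str = DEFAULT_BASELINE,
    drop_references: Sequence[str] = DEFAULT_REFERENCE_DROPS,
    predictors: Optional[Sequence[str]] = None,
) -> MLRDesign:
    """Assemble the regression design from covariates and cluster labels.

    One indicator from each compositional group is dropped (reference
    coding); by default agriculture for the sector shares and the over-64
    share for the population shares.
    """
    if solution.labels is None:
        raise ValueError("cluster solution must be labeled before regression")
    if predictors is None:
        predictors = [c for c in COVARIATE_NAMES if c not in set(drop_references)]
    else:
        predictors = [p for p in predictors if p not in set(drop_references)]
    cov = covariates.set_index("region_id")
    rids = sorted(solution.assignments)
    labels = [solution.label_of(r) for r in rids]
    cats = sorted(set(labels))
    if baseline not in cats:
        raise ValueError(f"baseline {baseline!r} not among response categories {cats}")
    categories = [c for c in cats if c != baseline] + [baseline]
    code = {c: i for i, c in enumerate(categories)}
    y = np.array([code[l] for l in labels])
    Xp = cov.loc[rids, list(predictors)].to_numpy(dtype=float)
    if np.any(Xp.std(axis=0) == 0):
        const = [p for p, s in zip(predictors, Xp.std(axis=0)) if s == 0]
        raise ValueError(f"constant predictor(s): {const}")
    X = np.column_stack([np.ones(len(rids)), Xp])
    return MLRDesign(
        X=X, y=y, categories=categories, predictor_names=list(predictors), baseline=baseline
    )


def design_from_labels(
    X_predictors: np.ndarray,
    labels: Sequence,
    baseline,
    predictor_names: Optional[Sequence[str]] = None,
) -> MLRDesign:
    """Design straight from arrays (simulation / testing convenience)."""
    labels = list(labels)
    cats = sorted({str(l) for l in labels})
    baseline = str(baseline)
    categories = [c for c in cats if c != baseline] + [baseline]
    code = {c: i for i, c in enumerate(categories)}
    y = np.array([code[str(l)] for l in labels])
    X_predictors = np.asarray(X_predictors, dtype=float)
    if predictor_names is None:
        predictor_names = [f"x{i + 1}" for i in range(X_predictors.shape[1])]
    X = np.column_stack([np.ones(len(y)), X_predictors])
    return MLRDesign(
        X=X, y=y, categories=categories, predictor_names=list(predictor_names),
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _log_probs(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(n, J) log-probabilities; columns follow the category order (baseline last)."""
    eta = X @ beta.T  # (n, J-1)
    full = np.column_stack([eta, np.zeros(len(X))])  # baseline linear predictor = 0
    return full - logsumexp(full, axis=1, keepdims=True)


def _loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    lp = _log_probs(beta, X)
    return float(lp[np.arange(len(y)), y].sum())


def _score_and_info(
    beta: np.ndarray, X: np.ndarray, Y: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Score vector and observed information for the flattened coefficients."""
    n, p1 = X.shape
    Jm1 = beta.shape[0]
    P = np.exp(_log_probs(beta, X))[:, :Jm1]  # (n, J-1)
    resid = Y[:, :Jm1] - P
    score = (resid.T @ X).reshape(-1)  # (J-1)*p1, contrast-major
    # W[i, j, k] = P_ij (delta_jk - P_ik)
    W = -P[:, :, None] * P[:, None, :]
    W[:, np.arange(Jm1), np.arange(Jm1)] += P
    info = np.einsum("ijk,ia,ib->jakb", W, X, X).reshape(Jm1 * p1, Jm1 * p1)
    return score, info


@dataclass
class MLRFit:
    """Fitted multinomial logit: coefficients, covariance and fit statistics."""

    design: MLRDesign
    coefficients: np.ndarray  # (J-1, p+1), raw scale, intercept first
    covariance: np.ndarray  # ((J-1)(p+1))^2, contrast-major flattening
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    iterations: int
    max_score: float
    separated: bool = False

    @property
    def n_free_parameters(self) -> int:
        return self.coefficients.size

    def predict_proba(self, X: Optional[np.ndarray] = None) -> np.ndarray:
        """(n, J) category probabilities, columns ordered as ``design.categories``."""
        if X is None:
            X = self.design.X
        return np.exp(_log_probs(self.coefficients, X))

    def predict(self, X: Optional[np.ndarray] = None) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def null_log_likelihood(y: np.ndarray, J: int) -> float:
    """Intercept-only maximized log-likelihood: category frequencies are the MLE."""
    counts = np.bincount(y, minlength=J).astype(float)
    n = counts.sum()
    nz = counts > 0
    return float(np.sum(counts[nz] * np.log(counts[nz] / n)))


def fit_mlr(
    design: MLRDesign,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> MLRFit:
    """Newton-Raphson maximum likelihood with step-halving.

    Convergence when the max absolute score component falls below
    ``score_tol`` or the relative log-likelihood change below ``ll_tol``.
    Non-convergence (e.g. separation, with coefficients drifting to
    infinity) is flagged on the result, never silent.
    """
    X, y = design.X, design.y
    J = design.J
    n, p1 = X.shape
    if n <= (J - 1) * p1:
        logger.warning(
            "sample size %d does not exceed the free parameter count %d", n, (J - 1) * p1
        )
    if np.linalg.matrix_rank(X) < p1:
        raise RankDeficiencyError(_collinear_message(X, design.predictor_names))

    # standardize (conditioning only; mapped back exactly below)
    mean = X[:, 1:].mean(axis=0)
    scale = X[:, 1:].std(axis=0)
    scale[scale == 0] = 1.0
    Xs = np.column_stack([np.ones(n), (X[:, 1:] - mean) / scale])
    Y = np.eye(J)[y]

    beta = np.zeros((J - 1, p1))
    ll = _loglik(beta, Xs, y)
    converged = False
    it = 0
    max_score = np.inf
    for it in range(1, max_iter + 1):
        score, info = _score_and_info(beta, Xs, Y)
        max_score = float(np.max(np.abs(score)))
        if max_score < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score).reshape(J - 1, p1)
        except np.linalg.LinAlgError:
            step = (np.linalg.pinv(info) @ score).reshape(J - 1, p1)
        factor = 1.0
        new_ll = _loglik(beta + factor * step, Xs, y)
        while new_ll < ll and factor > 1e-8:
            factor /= 2.0
            new_ll = _loglik(beta + factor * step, Xs, y)
        beta = beta + factor * step
        stalled = abs(new_ll - ll) < ll_tol * (abs(ll) + 1.0)
        ll = new_ll
        if stalled:
            score, _ = _score_and_info(beta, Xs, Y)
            max_score = float(np.max(np.abs(score)))
            if max_score < 1e-6 or factor < 1e-6:
                # likelihood flat; accept if the gradient is small too
                converged = max_score < 1e-6
                break
    if not converged:
        logger.warning(
            "multinomial logit did not converge after %d iterations "
            "(max score %.3g); possible separation", it, max_score
        )
    # (quasi-)separation: with separated classes the likelihood approaches
    # its supremum as coefficients diverge, so the score can vanish at
    # enormous estimates; flag standardized slopes beyond +/-15 (an odds
    # shift of e^15 per SD has no finite-data interpretation)
    separated = bool(beta[:, 1:].size and np.max(np.abs(beta[:, 1:])) > 15.0)
    if separated:
        logger.warning(
            "separation suspected: max standardized coefficient %.3g",
            float(np.max(np.abs(beta[:, 1:]))),
        )

    _, info = _score_and_info(beta, Xs, Y)
    # invert through an eigenvalue floor: near-zero (or round-off negative)
    # eigenvalues of the information arise under quasi-separation and must
    # not be inverted as-is; flooring yields a PSD covariance with large but
    # finite variances along the weakly identified directions
    w, V = np.linalg.eigh(info)
    tol = 1e-10 * max(float(w.max()), 1e-300)
    cov_s = (V / np.maximum(w, tol)) @ V.T
    # map standardized-scale estimates back to the raw scale
    A1 = np.zeros((p1, p1))
    A1[0, 0] = 1.0
    A1[0, 1:] = -mean / scale
    A1[np.arange(1, p1), np.arange(1, p1)] = 1.0 / scale
    A = np.kron(np.eye(J - 1), A1)
    beta_raw = (A1 @ beta.T).T
    cov_raw = A @ cov_s @ A.T
    cov_raw = (cov_raw + cov_raw.T) / 2.0

    return MLRFit(
        design=design,
        coefficients=beta_raw,
        covariance=cov_raw,
        log_likelihood=float(ll),
        null_log_likelihood=null_log_likelihood(y, J),
        converged=converged,
        iterations=it,
        max_score=max_score,
        separated=separated,
    )


def _collinear_message(X: np.ndarray, names: Sequence[str]) -> str:
    # identify a minimal-looking collinear set via the null space
    _, s, vt = np.linalg.svd(X[:, 1:] - X[:, 1:].mean(axis=0))
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)
    null = vt[s < tol] if len(s) else vt
    involved = set()
    for row in np.atleast_2d(null):
        involved.update(np.asarray(names)[np.abs(row) > 1e-8].tolist())
    return f"predictor matrix is rank deficient; collinear set: {sorted(involved)}"


# ---------------------------------------------------------------------------
# inference and diagnostics
# ---------------------------------------------------------------------------

Z_975 = 1.959964


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def wald_inference(fit: MLRFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient table: b, SE, z, p, odds ratio and CI, with stars.

    One block of rows per contrast (non-baseline category vs baseline).
    """
    if not np.all(np.isfinite(fit.covariance)):
        raise ValueError("covariance is not finite")
    eig = np.linalg.eigvalsh(fit.covariance)
    if eig.min() < -1e-6 * max(1.0, float(eig.max())):
        raise ValueError("covariance is not positive semi-definite")
    z_crit = float(stats.norm.ppf(0.5 + level / 2.0))
    p1 = fit.coefficients.shape[1]
    names = ["intercept"] + list(fit.design.predictor_names)
    rows = []
    se_all = np.sqrt(np.clip(np.diag(fit.covariance), 0.0, None))
    for j, cat in enumerate(fit.design.categories[:-1]):
        for a in range(p1):
            b = float(fit.coefficients[j, a])
            se = float(se_all[j * p1 + a])
            z = b / se if se > 0 else np.inf * np.sign(b) if b != 0 else 0.0
            p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
            with np.errstate(over="ignore"):
                rows.append(
                    {
                        "contrast": f"{cat} vs {fit.design.baseline}",
                        "predictor": names[a],
                        "b": b,
                        "se": se,
                        "z": z,
                        "p_value": p,
                        "odds_ratio": float(np.exp(b)),
                        "ci_lower": float(np.exp(b - z_crit * se)),
                        "ci_upper": float(np.exp(b + z_crit * se)),
                        "stars": _stars(p),
                    }
                )
    return pd.DataFrame(rows)


def likelihood_ratio_test(fit: MLRFit) -> Tuple[float, int, float]:
    """LR test of the fitted model against the intercept-only model."""
    chi2 = 2.0 * (fit.log_likelihood - fit.null_log_likelihood)
    if chi2 < -1e-6:
        raise ValueError(
            f"full-model log-likelihood below the null ({chi2:.3g}); optimization bug"
        )
    chi2 = max(chi2, 0.0)
    df = (fit.design.J - 1) * fit.design.n_predictors
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def pseudo_r2(fit: MLRFit) -> Tuple[float, float]:
    """Cox-Snell and Nagelkerke pseudo-R2."""
    n = fit.design.n
    cox_snell = 1.0 - np.exp((2.0 / n) * (fit.null_log_likelihood - fit.log_likelihood))
    ceiling = 1.0 - np.exp((2.0 / n) * fit.null_log_likelihood)
    nagelkerke = cox_snell / ceiling if ceiling > 0 else 0.0
    return float(cox_snell), float(nagelkerke)


def max_chance_criterion(counts: Sequence[int]) -> float:
    """1.25 x the largest observed category proportion (practical-significance bar)."""
    counts = np.asarray(counts, dtype=float)
    return float(1.25 * counts.max() / counts.sum())


def classification_accuracy(fit: MLRFit) -> Tuple[float, float, bool]:
    """Hit ratio of argmax-probability prediction vs the maximum chance criterion."""
    pred = fit.predict()
    hit_ratio = float(np.mean(pred == fit.design.y))
    counts = np.bincount(fit.design.y, minlength=fit.design.J)
    mc = max_chance_criterion(counts)
    return hit_ratio, mc, hit_ratio >= mc


def collinearity_screen(
    X_predictors: np.ndarray, names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Tolerance and VIF per predictor from auxiliary least-squares fits."""
    X = np.asarray(X_predictors, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two predictors")
    if n <= p:
        raise ValueError("need more observations than predictors")
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    rows = []
    for a in range(p):
        target = X[:, a]
        others = np.column_stack([np.ones(n), np.delete(X, a, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
        tol = max(0.0, 1.0 - r2)
        perfect = tol < 1e-12
        rows.append(
            {
                "predictor": names[a],
                "tolerance": tol,
                "vif": np.inf if perfect else 1.0 / tol,
                "perfectly_collinear": perfect,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hausman-McFadden IIA test
# ---------------------------------------------------------------------------

@dataclass
class IIATestResult:
    omitted_category: str
    statistic: float
    df: int
    p_value: float
    valid: bool
    note: str


def hausman_mcfadden_iia(fit: MLRFit, omit_category: str) -> IIATestResult:
    """Hausman-McFadden specification test of IIA.

    Refits the model on the sample with ``omit_category``'s observations
    removed and compares the common coefficients:
    H = d' (V_r - V_f)^- d with d = b_restricted - b_full.  When the
    covariance difference is not positive definite the test uses a
    generalized inverse over its non-negative eigenspace and is flagged
    inconclusive.
    """
    design = fit.design
    if omit_category == design.baseline:
        raise ValueError("cannot omit the baseline category")
    if omit_category not in design.categories:
        raise ValueError(f"unknown category {omit_category!r}")
    omit_idx = design.categories.index(omit_category)
    keep = design.y != omit_idx
    labels_kept = [design.categories[c] for c in design.y[keep]]
    if len(set(labels_kept)) < 2:
        raise ValueError("restricted model is not estimable: fewer than two categories remain")
    sub = design_from_labels(
        design.X[keep][:, 1:], labels_kept, design.baseline, design.predictor_names
    )
    fit_r = fit_mlr(sub)

    p1 = design.X.shape[1]
    common = [c for c in design.categories[:-1] if c != omit_category]
    idx_f = np.concatenate(
        [np.arange(design.categories.index(c) * p1, design.categories.index(c) * p1 + p1)
         for c in common]
    )
    idx_r = np.concatenate(
        [np.arange(sub.categories.index(c) * p1, sub.categories.index(c) * p1 + p1)
         for c in common]
    )
    b_f = fit.coefficients.reshape(-1)[idx_f]
    b_r = fit_r.coefficients.reshape(-1)[idx_r]
    V_f = fit.covariance[np.ix_(idx_f, idx_f)]
    V_r = fit_r.covariance[np.ix_(idx_r, idx_r)]
    H, df, p, valid, note = hausman_quadratic(b_r - b_f, V_r - V_f)
    return IIATestResult(omit_category, H, df, p, valid, note)


def hausman_quadratic(
    d: np.ndarray, M: np.ndarray
) -> Tuple[float, int, float, bool, str]:
    """H = d' M^- d with chi-square p-value; non-PD M flags the run invalid.

    When M is positive definite the full inverse is used (df = dim); otherwise
    a generalized inverse over the non-negative eigenspace (df = its rank) and
    the result is marked inconclusive.
    """
    d = np.asarray(d, dtype=float)
    M = np.asarray(M, dtype=float)
    eigvals, eigvecs = np.linalg.eigh((M + M.T) / 2.0)
    tol = 1e-10 * max(1.0, float(np.abs(eigvals).max()))
    if np.all(eigvals > tol):
        H = float(d @ np.linalg.solve(M, d))
        df = len(d)
        valid = True
        note = "covariance difference positive definite"
    else:
        pos = eigvals > tol
        if not np.any(pos):
            return 0.0, 0, 1.0, False, "covariance difference has no positive eigenvalues"
        Minv = (eigvecs[:, pos] / eigvals[pos]) @ eigvecs[:, pos].T
        H = float(d @ Minv @ d)
        df = int(pos.sum())
        valid = False
        note = "covariance difference not positive definite; generalized inverse used"
    H = max(H, 0.0)
    p = float(stats.chi2.sf(H, df)) if df > 0 else 1.0
    return H, df, p, valid, note


# ---------------------------------------------------------------------------
# simulation utility (parameter-recovery and calibration studies)
# ---------------------------------------------------------------------------

def simulate_mlr_data(
    beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
    X: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (X_predictors, y) from the multinomial logit with coefficients
    ``beta`` ((J-1) x (p+1), intercept first, baseline = last category)."""
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[1] - 1
    if X is None:
        X = rng.standard_normal((n, p))
    Xd = np.column_stack([np.ones(n), X])
    probs = np.exp(_log_probs(beta, Xd))
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    y = (u[:, None] > cum).sum(axis=1)
    return X, y


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

@dataclass
class MLRDiagnostics:
    lr_chi2: float
    lr_df: int
    lr_p: float
    cox_snell_r2: float
    nagelkerke_r2: float
    hit_ratio: float
    max_chance: float
    practical_significance: bool
    collinearity: pd.DataFrame
    iia_tests: List[IIATestResult]


@dataclass
class MLRAnalysis:
    fit: MLRFit
    wald_table: pd.DataFrame
    diagnostics: MLRDiagnostics


def mlr_analysis(
    covariates: pd.DataFrame,
    solution: ClusterSolution,
    baseline: str = DEFAULT_BASELINE,
    drop_references: Sequence[str] = DEFAULT_REFERENCE_DROPS,
    level: float = 0.95,
) -> MLRAnalysis:
    """Fit the cluster-membership model and assemble the full diagnostic battery."""
    design = build_design(covariates, solution, baseline, drop_references)
    fit = fit_mlr(design)
    wald = wald_inference(fit, level)
    chi2, df, p = likelihood_ratio_test(fit)
    cs, nk = pseudo_r2(fit)
    hit, mc, practical = classification_accuracy(fit)
    coll = collinearity_screen(design.X[:, 1:], design.predictor_names)
    iia = []
    for cat in design.categories[:-1]:
        try:
            iia.append(hausman_mcfadden_iia(fit, cat))
        except ValueError as exc:
            logger.warning("IIA test omitting %s failed: %s", cat, exc)
    return MLRAnalysis(
        fit=fit,
        wald_table=wald,
        diagnostics=MLRDiagnostics(
            lr_chi2=chi2, lr_df=df, lr_p=p,
            cox_snell_r2=cs, nagelkerke_r2=nk,
            hit_ratio=hit, max_chance=mc, practical_significance=practical,
            collinearity=coll, iia_tests=iia,
        ),
    )
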