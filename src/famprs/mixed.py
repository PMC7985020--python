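"""Kinship-aware association models.

* :func:`prune_ld` / :func:`compute_grm` — genomic relationship matrix on
  LD-pruned dosages (centred and standardised by sample allele frequency).
* :func:`fit_logistic_mixed` — logistic mixed model with a GRM random
  effect, estimated by penalised quasi-likelihood with the variance
  component optimised by a derivative-free simplex search; Wald tests,
  one-sided p-values for the hypothesis that the group coded 1 has the
  higher score.
* :func:`fit_lmm_quant` — linear mixed model (REML) with an optional
  second i.i.d. random intercept, cluster-bootstrap CIs and permutation
  p-values.
* :func:`fast_assoc_many` — many Wald tests under a variance structure
  estimated once on the null model (the fast path used for the simulated
  score ensembles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from ._rng import substream
from .panels import DosagePanel

__all__ = [
    "Grm",
    "AssociationResult",
    "QuantResult",
    "prune_ld",
    "compute_grm",
    "fit_logistic_mixed",
    "fit_lmm_quant",
    "permutation_p",
    "bootstrap_ci",
    "fast_assoc_many",
]


def prune_ld(
    panel: DosagePanel, window: int = 50, step: int = 5, r2_max: float = 0.5
) -> DosagePanel:
    """Greedy sliding-window LD pruning on dosage correlations.

    Within each window of ``window`` variants, the later-positioned variant
    of any pair with squared Pearson correlation above ``r2_max`` is
    dropped; the window then advances by ``step``.  Monomorphic variants are
    removed first (their correlation is undefined).
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    d = panel.dosages
    poly = d.std(axis=0) > 0
    keep = np.flatnonzero(poly)
    alive = {int(j): True for j in keep}
    order = list(keep)
    start = 0
    while start < len(order):
        win = [j for j in order[start : start + window] if alive[j]]
        for a_i in range(len(win)):
            if not alive[win[a_i]]:
                continue
            for b_i in range(a_i + 1, len(win)):
                j1, j2 = win[a_i], win[b_i]
                if not alive[j2]:
                    continue
                r = np.corrcoef(d[:, j1], d[:, j2])[0, 1]
                if r * r > r2_max:
                    alive[j2] = False
        start += step
    kept = np.array([j for j in order if alive[j]], dtype=int)
    return panel.subset_variants(kept)


@dataclass
class Grm:
    """Pairwise genomic relatedness over subjects."""

    matrix: np.ndarray
    subjects: list[str]
    m_variants: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.subjects), len(self.subjects)):
            raise ValueError("GRM shape does not match subject count")

    def aligned(self, subjects: list[str]) -> np.ndarray:
        idx = [self.subjects.index(s) for s in subjects]
        return self.matrix[np.ix_(idx, idx)]

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.subjects, columns=self.subjects).to_csv(
            path, sep="\t"
        )


def compute_grm(panel: DosagePanel, ridge: float = 1e-6) -> Grm:
    """Centred-standardised GRM: K = (1/m) sum_j x_j x_j' with
    x_ij = (d_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)), p_j the sample frequency.

    Monomorphic variants are skipped; a small ridge keeps K numerically
    positive semi-definite.
    """
    if panel.n_subjects < 2:
        raise ValueError("need at least two subjects")
    d = panel.dosages
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic variants")
    dp = d[:, poly]
    pp = p[poly]
    x = (dp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    m = x.shape[1]
    k = (x @ x.T) / m
    k[np.diag_indices_from(k)] += ridge
    return Grm(k, list(panel.subjects), m)


# --------------------------------------------------------------------------
# logistic mixed model (PQL + simplex search over the variance component)


@dataclass
class AssociationResult:
    score_type: str
    threshold: float
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_z: float
    p_one_sided: float
    p_two_sided: float
    sigma2: float
    converged: bool


def _pql_inner(
    y: np.ndarray,
    x: np.ndarray,
    k: np.ndarray,
    sigma2: float,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> dict:
    """PQL working-model iterations at a fixed variance component.

    With sigma2 = 0 this reduces exactly to IRLS for the logistic GLM.
    Returns the working-model quantities needed for the outer objective and
    Wald inference.
    """
    n, p = x.shape
    beta = np.zeros(p)
    eta = np.full(n, np.log((y.mean() + 1e-3) / (1 - y.mean() + 1e-3)))
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        v = sigma2 * k + np.diag(1.0 / w)
        cho = np.linalg.cholesky(v)
        vi_x = np.linalg.solve(v, x)
        vi_z = np.linalg.solve(v, z)
        xtvx = x.T @ vi_x
        beta_new = np.linalg.solve(xtvx, x.T @ vi_z)
        resid = z - x @ beta_new
        u = sigma2 * (k @ np.linalg.solve(v, resid))
        eta_new = x @ beta_new + u
        step = np.max(np.abs(eta_new - eta))
        beta, eta = beta_new, eta_new
        if np.max(np.abs(beta)) > 30:
            raise ValueError(
                "divergent coefficients: complete separation suspected"
            )
        if step < tol:
            break
    else:
        return {"converged": False, "beta": beta, "cov": np.linalg.inv(xtvx)}
    # working-model REML log-likelihood (the outer objective)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho)))
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    quad = float(resid @ np.linalg.solve(v, resid))
    reml = -0.5 * (logdet_v + logdet_xtvx + quad)
    return {
        "converged": True,
        "beta": beta,
        "cov": np.linalg.inv(xtvx),
        "reml": reml,
    }


def fit_logistic_mixed(
    y: np.ndarray,
    prs_z: np.ndarray,
    covariates: np.ndarray | None,
    grm: Grm | np.ndarray,
    sigma2: float | None = None,
    score_type: str = "PRS",
    threshold: float = np.nan,
) -> AssociationResult:
    """Logistic mixed model logit P(y=1) = a + b z + c'cov + u, u ~ N(0, s2 K).

    The variance component is profiled by Nelder-Mead simplex search on the
    PQL working-model REML objective (pass ``sigma2`` to fix it; 0 gives the
    plain logistic GLM).  Wald SE comes from the working model; the
    one-sided p tests H1: b > 0 (group coded 1 has the higher score).
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant")
    z = np.asarray(prs_z, dtype=float)
    cols = [np.ones_like(y), z]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.extend(cov.T)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("model matrix is rank deficient")
    k = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, dtype=float)
    if k.shape != (len(y), len(y)):
        raise ValueError("GRM does not match the analysis subjects")

    if sigma2 is not None:
        fit = _pql_inner(y, x, k, sigma2)
        s2 = sigma2
    else:

        def neg_obj(theta: np.ndarray) -> float:
            s = float(np.exp(theta[0]))
            if s > 1e4:
                return np.inf
            f = _pql_inner(y, x, k, s)
            if not f["converged"]:
                return np.inf
            return -f["reml"]

        best = None
        for start in (-2.0, 0.0):
            res = optimize.minimize(
                neg_obj, x0=[start], method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200},
            )
            if best is None or res.fun < best.fun:
                best = res
        s2 = float(np.exp(best.x[0]))
        # compare against the boundary (no family variance)
        f0 = _pql_inner(y, x, k, 0.0)
        if f0["converged"] and f0["reml"] >= -best.fun:
            s2 = 0.0
        fit = _pql_inner(y, x, k, s2)

    beta = float(fit["beta"][1])
    se = float(np.sqrt(fit["cov"][1, 1]))
    wald = beta / se
    return AssociationResult(
        score_type=score_type,
        threshold=threshold,
        beta=beta,
        se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        wald_z=wald,
        p_one_sided=float(sps.norm.sf(wald)),
        p_two_sided=float(2 * sps.norm.sf(abs(wald))),
        sigma2=float(s2),
        converged=bool(fit["converged"]),
    )


# --------------------------------------------------------------------------
# linear mixed model (REML)


@dataclass
class QuantResult:
    beta: float
    se: float
    p_one_sided: float
    p_two_sided: float
    sigma2_g: float
    sigma2_extra: float
    sigma2_e: float
    converged: bool
    ci_low: float = np.nan
    ci_high: float = np.nan
    perm_p: float = np.nan
    n_perm_extreme: int = -1
    n_perm: int = 0


def _reml_loglik(
    y: np.ndarray, x: np.ndarray, vlist: list[np.ndarray], variances: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    n = len(y)
    v = variances[-1] * np.eye(n)
    for s, mat in zip(variances[:-1], vlist):
        v += s * mat
    cho = np.linalg.cholesky(v)
    vi_x = np.linalg.solve(v, x)
    xtvx = x.T @ vi_x
    beta = np.linalg.solve(xtvx, vi_x.T @ y)
    resid = y - x @ beta
    quad = float(resid @ np.linalg.solve(v, resid))
    logdet_v = 2.0 * np.sum(np.log(np.diag(cho)))
    _, logdet_xtvx = np.linalg.slogdet(xtvx)
    ll = -0.5 * (logdet_v + logdet_xtvx + quad)
    return ll, beta, np.linalg.inv(xtvx)


def fit_lmm_quant(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None,
    grm: Grm | np.ndarray | None,
    extra_re: np.ndarray | None = None,
    fix_zero_variance: bool = False,
    direction: str = "greater",
) -> QuantResult:
    """REML linear mixed model y = a + b x + c'cov + u + v + e.

    ``u ~ N(0, s2_g K)``; ``v`` is an i.i.d. random intercept over the
    ``extra_re`` grouping (e.g. married-in status).  With
    ``fix_zero_variance`` both variance components are pinned at 0 and the
    fit equals ordinary least squares.  One-sided p tests H1: b > 0 by
    default (``direction='less'`` flips it).
    """
    y = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    cols = [np.ones_like(y), xv]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.extend(cov.T)
    xmat = np.column_stack(cols)
    if np.linalg.matrix_rank(xmat) < xmat.shape[1]:
        raise ValueError("model matrix is rank deficient")
    vlist: list[np.ndarray] = []
    if grm is not None:
        k = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, dtype=float)
        vlist.append(k)
    if extra_re is not None:
        groups = np.asarray(extra_re)
        zmat = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
        vlist.append(zmat @ zmat.T)
    n_comp = len(vlist)

    if fix_zero_variance or n_comp == 0:
        variances = np.array([0.0] * n_comp + [1.0])
        _, beta, cov_b = _reml_loglik(y, xmat, vlist, variances)
        resid = y - xmat @ beta
        dof = len(y) - xmat.shape[1]
        s2e = float(resid @ resid / dof) if dof > 0 else np.nan
        cov_b = cov_b * s2e
        converged = True
        var_out = [0.0] * n_comp + [s2e]
    else:
        var_y = y.var(ddof=1)

        def neg(theta: np.ndarray) -> float:
            v = np.exp(theta) * var_y
            try:
                ll, _, _ = _reml_loglik(y, xmat, vlist, v)
            except np.linalg.LinAlgError:
                return np.inf
            return -ll

        x0 = np.full(n_comp + 1, np.log(1.0 / (n_comp + 1)))
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400 * (n_comp + 1)},
        )
        variances = np.exp(res.x) * var_y
        ll, beta, cov_b = _reml_loglik(y, xmat, vlist, variances)
        converged = bool(res.success)
        var_out = list(variances)

    b = float(beta[1])
    se = float(np.sqrt(cov_b[1, 1]))
    z = b / se
    p_two = float(2 * sps.norm.sf(abs(z)))
    p_one = float(sps.norm.sf(z) if direction == "greater" else sps.norm.cdf(z))
    return QuantResult(
        beta=b,
        se=se,
        p_one_sided=p_one,
        p_two_sided=p_two,
        sigma2_g=float(var_out[0]) if grm is not None else 0.0,
        sigma2_extra=float(var_out[-2]) if extra_re is not None else 0.0,
        sigma2_e=float(var_out[-1]),
        converged=converged,
    )


def permutation_p(
    fit_fn,
    y: np.ndarray,
    p_observed: float,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, int]:
    """Empirical p from ``n_perm`` unrestricted phenotype permutations.

    ``fit_fn(y_perm)`` must return the permutation's p-value on the same
    convention as ``p_observed``.  Ties count as at-least-as-extreme; failed
    fits are redrawn with a cap of twice ``n_perm`` attempts.  Returns
    (empirical p, count of permutations with p <= observed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = substream(seed, "permutation")
    y = np.asarray(y)
    count = done = attempts = 0
    while done < n_perm:
        if attempts >= 2 * n_perm:
            raise RuntimeError("too many failed permutation fits")
        attempts += 1
        try:
            p = fit_fn(y[rng.permutation(len(y))])
        except (ValueError, np.linalg.LinAlgError):
            continue
        if p <= p_observed:
            count += 1
        done += 1
    return count / n_perm, count


def bootstrap_ci(
    fit_fn,
    families: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI for an effect by resampling whole families.

    ``fit_fn(row_index)`` must return the effect estimate for the subjects
    selected by ``row_index`` (with repeats).  Draws with a degenerate
    outcome (fit raising ValueError) are redrawn, capped at 3x ``n_boot``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = substream(seed, "bootstrap")
    families = np.asarray(families)
    unique = np.unique(families)
    members = {f: np.flatnonzero(families == f) for f in unique}
    est = []
    attempts = 0
    while len(est) < n_boot:
        if attempts >= 3 * n_boot:
            raise RuntimeError("too many degenerate bootstrap draws")
        attempts += 1
        draw = rng.choice(unique, size=len(unique), replace=True)
        idx = np.concatenate([members[f] for f in draw])
        try:
            est.append(fit_fn(idx))
        except (ValueError, np.linalg.LinAlgError):
            continue
    a = (1 - level) / 2
    lo, hi = np.quantile(est, [a, 1 - a])
    return float(lo), float(hi)


def fast_assoc_many(
    y: np.ndarray,
    covariates: np.ndarray | None,
    grm: Grm | np.ndarray,
    scores: np.ndarray,
) -> np.ndarray:
    """One-sided Wald p per column of ``scores`` under a fixed variance
    structure.

    The variance components are estimated once by REML on the null model
    (outcome on covariates only); each score is then tested by generalised
    least squares with that fixed covariance — the computational fast path
    for large simulated-score ensembles.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    x0 = np.column_stack(cols)
    k = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, dtype=float)
    var_y = y.var(ddof=1)

    def neg(theta: np.ndarray) -> float:
        v = np.exp(theta) * var_y
        try:
            ll, _, _ = _reml_loglik(y, x0, [k], v)
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    res = optimize.minimize(
        neg, [np.log(0.5), np.log(0.5)], method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 600},
    )
    variances = np.exp(res.x) * var_y
    v = variances[0] * k + variances[1] * np.eye(n)
    vinv = np.linalg.inv(v)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    pvals = np.empty(scores.shape[1])
    vi_x0 = vinv @ x0
    for j in range(scores.shape[1]):
        x = np.column_stack([x0, scores[:, j]])
        vi_x = np.column_stack([vi_x0, vinv @ scores[:, j]])
        xtvx = x.T @ vi_x
        beta = np.linalg.solve(xtvx, vi_x.T @ y)
        cov_b = np.linalg.inv(xtvx)
        z = beta[-1] / np.sqrt(cov_b[-1, -1])
        pvals[j] = sps.norm.sf(z)
    return pvals
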