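"""Cross-disorder weight construction.

Two routes from several disorder GWAS to scoring weights:

* a *shared* score — variants nominally associated (p < 0.05) with every
  disorder and sign-concordant on a common allele orientation, combined by
  DerSimonian-Laird random-effects meta-analysis;
* *disorder-specific* statistics — the target GWAS linearly corrected for a
  covariate GWAS using the covariate's SNP heritability and the
  coheritability of the pair, both estimated by LD score regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import SummaryStatistics

__all__ = [
    "MetaAnalysisResult",
    "LdscEstimate",
    "orient_to_reference",
    "select_shared",
    "random_effects_meta",
    "shared_meta",
    "ldsc_h2",
    "ldsc_coherit",
    "gwis_correct",
]


def orient_to_reference(
    reference: SummaryStatistics, other: SummaryStatistics
) -> pd.DataFrame:
    """Return ``other`` rows matched to ``reference`` ids, effects re-signed
    onto the reference allele orientation.

    Variants absent from either input or with a discordant allele pair are
    excluded.
    """
    ref = reference.df.set_index("SNP")
    oth = other.df.set_index("SNP")
    common = ref.index.intersection(oth.index)
    ref = ref.loc[common]
    oth = oth.loc[common]
    same = (oth["A1"] == ref["A1"]) & (oth["A2"] == ref["A2"])
    swapped = (oth["A1"] == ref["A2"]) & (oth["A2"] == ref["A1"])
    keep = same | swapped
    out = oth[keep].copy()
    sw = swapped[keep]
    out.loc[sw, "BETA"] = -out.loc[sw, "BETA"]
    if "FRQ" in out.columns:
        out.loc[sw, "FRQ"] = 1.0 - out.loc[sw, "FRQ"]
    out["A1"] = ref.loc[keep, "A1"]
    out["A2"] = ref.loc[keep, "A2"]
    return out.reset_index()


def select_shared(*stats: SummaryStatistics, p_max: float = 0.05) -> list[str]:
    """Variants with p < ``p_max`` in every study and concordant effect sign.

    Sign concordance is evaluated on a common allele orientation (the first
    study's), before any positive-flipping.  Variants missing from any study
    are excluded.  Order of the inputs does not affect the result.
    """
    if len(stats) < 2:
        raise ValueError("need at least two studies")
    ref = stats[0]
    oriented = [ref.df[["SNP", "BETA", "P"]].copy()]
    for s in stats[1:]:
        oriented.append(orient_to_reference(ref, s)[["SNP", "BETA", "P"]])
    merged = oriented[0]
    for i, o in enumerate(oriented[1:], start=1):
        merged = merged.merge(o, on="SNP", suffixes=("", f"_{i}"))
    beta_cols = [c for c in merged.columns if c.startswith("BETA")]
    p_cols = [c for c in merged.columns if c.startswith("P")]
    sig = (merged[p_cols] < p_max).all(axis=1)
    signs = np.sign(merged[beta_cols].to_numpy())
    concordant = (signs == signs[:, [0]]).all(axis=1) & (signs != 0).all(axis=1)
    return merged.loc[sig & concordant, "SNP"].tolist()


@dataclass
class MetaAnalysisResult:
    """Combined effects from a DerSimonian-Laird random-effects model."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    tau2: np.ndarray
    q: np.ndarray
    k: int


def random_effects_meta(betas: np.ndarray, ses: np.ndarray) -> MetaAnalysisResult:
    """DerSimonian-Laird meta-analysis, vectorised over variants.

    ``betas``/``ses`` have shape (n_variants, k) or (k,).  Fixed weights are
    1/SE^2; tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random
    weights 1/(SE^2 + tau^2); two-sided Wald p-values.
    """
    b = np.atleast_2d(np.asarray(betas, dtype=float))
    s = np.atleast_2d(np.asarray(ses, dtype=float))
    if b.shape != s.shape:
        raise ValueError("betas and ses must have the same shape")
    k = b.shape[1]
    if k < 2:
        raise ValueError("need at least two studies")
    if (s <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    wsum = w.sum(axis=1)
    beta_fe = (w * b).sum(axis=1) / wsum
    q = (w * (b - beta_fe[:, None]) ** 2).sum(axis=1)
    denom = wsum - (w**2).sum(axis=1) / wsum
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.maximum(0.0, (q - (k - 1)) / denom)
    wr = 1.0 / (s**2 + tau2[:, None])
    beta_re = (wr * b).sum(axis=1) / wr.sum(axis=1)
    se_re = 1.0 / np.sqrt(wr.sum(axis=1))
    z = beta_re / se_re
    p = 2.0 * sps.norm.sf(np.abs(z))
    return MetaAnalysisResult(beta_re, se_re, p, tau2, q, k)


def shared_meta(
    stats: list[SummaryStatistics], variant_ids: list[str]
) -> SummaryStatistics:
    """Random-effects meta-analysis of the selected shared variants.

    Effects are combined on the first study's allele orientation; the output
    is a standard summary-statistics table usable by the scoring engine.
    """
    ref = stats[0].df.set_index("SNP").loc[variant_ids]
    mats_b = [ref["BETA"].to_numpy()]
    mats_s = [ref["SE"].to_numpy()]
    for s in stats[1:]:
        o = orient_to_reference(stats[0], s).set_index("SNP").loc[variant_ids]
        mats_b.append(o["BETA"].to_numpy())
        mats_s.append(o["SE"].to_numpy())
    res = random_effects_meta(np.column_stack(mats_b), np.column_stack(mats_s))
    out = pd.DataFrame(
        {
            "SNP": variant_ids,
            "A1": ref["A1"].to_numpy(),
            "A2": ref["A2"].to_numpy(),
            "BETA": res.beta,
            "SE": res.se,
            "P": np.clip(res.p, np.nextafter(0, 1), 1.0),
        }
    )
    for c in ("CHR", "BP", "INFO", "FRQ"):
        if c in ref.columns:
            out[c] = ref[c].to_numpy()
    return SummaryStatistics(out)


@dataclass
class LdscEstimate:
    """LD-score-regression point estimates (no jackknife SEs)."""

    h2: float | None
    intercept: float
    rho_g: float | None = None
    r_g: float | None = None
    m: int = 0


def _ldsc_wls(y: np.ndarray, l: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on l with weights 1/max(l, 1)."""
    w = 1.0 / np.maximum(l, 1.0)
    x = np.column_stack([np.ones_like(l), l])
    xw = x * w[:, None]
    coef = np.linalg.solve(x.T @ xw, xw.T @ y)
    return float(coef[0]), float(coef[1])


def ldsc_h2(
    stats: SummaryStatistics, ld_scores: np.ndarray, n: float, m: int
) -> LdscEstimate:
    """SNP heritability from the regression chi2_j ~ intercept + (N h2 / M) l_j."""
    df = stats.df
    if len(df) < 10:
        raise ValueError("fewer than 10 variants: LDSC fit would be unstable")
    l = np.asarray(ld_scores, dtype=float)
    if l.shape[0] != len(df):
        raise ValueError("LD scores must align with the variants")
    chi2 = (df["BETA"].to_numpy() / df["SE"].to_numpy()) ** 2
    intercept, slope = _ldsc_wls(chi2, l)
    return LdscEstimate(h2=slope * m / n, intercept=intercept, m=m)


def ldsc_coherit(
    stats1: SummaryStatistics,
    stats2: SummaryStatistics,
    ld_scores: np.ndarray,
    n1: float,
    n2: float,
    m: int,
) -> LdscEstimate:
    """Coheritability from z1_j z2_j ~ intercept + (sqrt(N1 N2) rho_g / M) l_j.

    ``stats2`` is re-oriented onto ``stats1``'s alleles before forming the
    products; the genetic correlation is derived from univariate fits and
    clamped to [-1, 1].
    """
    df1 = stats1.df.set_index("SNP")
    o2 = orient_to_reference(stats1, stats2).set_index("SNP")
    l = pd.Series(np.asarray(ld_scores, dtype=float), index=stats1.df["SNP"])
    common = df1.index.intersection(o2.index)
    if len(common) < 10:
        raise ValueError("fewer than 10 shared variants: LDSC fit would be unstable")
    z1 = (df1.loc[common, "BETA"] / df1.loc[common, "SE"]).to_numpy()
    z2 = (o2.loc[common, "BETA"] / o2.loc[common, "SE"]).to_numpy()
    lc = l.loc[common].to_numpy()
    intercept, slope = _ldsc_wls(z1 * z2, lc)
    rho_g = slope * m / np.sqrt(n1 * n2)
    h2_1 = ldsc_h2(SummaryStatistics(df1.loc[common].reset_index()), lc, n1, m).h2
    h2_2 = ldsc_h2(
        SummaryStatistics(o2.loc[common].reset_index()), lc, n2, m
    ).h2
    if h2_1 > 0 and h2_2 > 0:
        r_g = float(np.clip(rho_g / np.sqrt(h2_1 * h2_2), -1.0, 1.0))
    else:
        r_g = np.nan
    return LdscEstimate(h2=h2_1, intercept=intercept, rho_g=rho_g, r_g=r_g, m=m)


def gwis_correct(
    target: SummaryStatistics,
    covariate: SummaryStatistics,
    h2_cov: float,
    rho_g: float,
) -> SummaryStatistics:
    """Disorder-specific statistics: target effects minus the genetically
    predictable covariate contribution.

    The correction coefficient is ``b = rho_g / h2_cov``; per shared variant
    (covariate re-oriented onto the target's alleles)
    ``beta* = beta_t - b beta_c`` with ``SE* = sqrt(SE_t^2 + b^2 SE_c^2)``
    (zero sampling covariance: non-overlapping training samples) and a
    two-sided Wald p-value.  With ``rho_g = 0`` the output equals the target
    restricted to the shared variants.
    """
    if h2_cov <= 0:
        raise ValueError(f"covariate heritability must be positive, got {h2_cov}")
    b = rho_g / h2_cov
    t = target.df.set_index("SNP")
    c = orient_to_reference(target, covariate).set_index("SNP")
    common = t.index.intersection(c.index)
    t = t.loc[common]
    c = c.loc[common]
    beta = t["BETA"].to_numpy() - b * c["BETA"].to_numpy()
    se = np.sqrt(t["SE"].to_numpy() ** 2 + b**2 * c["SE"].to_numpy() ** 2)
    z = beta / se
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    out = t.reset_index()[[col for col in t.reset_index().columns]]
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    res = SummaryStatistics(out)
    res.correction_b = b  # inspectable intermediate
    return res
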