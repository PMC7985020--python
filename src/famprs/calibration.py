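"""Simulated-score empirical null and the exact binomial success test.

An ensemble of simulated scores is built by drawing, per threshold, the
same number of variants as the disorder score uses at that threshold, with
weights sampled from the pooled harmonised effects of the training GWAS.
Each simulated score is tested with the same model as the disorder score;
the number of simulated scores at least as strongly associated as the
disorder score is the success count of an exact binomial test with a
Clopper-Pearson confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream
from .panels import DosagePanel
from .prs import zstandardize
from .sumstats import AlignedVariantSet

__all__ = [
    "NullPrsEnsemble",
    "CalibrationResult",
    "draw_null_prs",
    "choose_threshold",
    "binomial_success_test",
    "calibrate_contrast",
]


@dataclass
class NullPrsEnsemble:
    """Simulated standardised scores: {threshold: (n_sim, n_subjects)}."""

    scores: dict[float, np.ndarray] = field(repr=False)
    subjects: list[str] = field(default_factory=list)
    n_sim: int = 0
    skipped: list[float] = field(default_factory=list)
    seed: int = 0


def draw_null_prs(
    panel: DosagePanel,
    counts_per_threshold: dict[float, int],
    effect_pool: np.ndarray,
    n_sim: int,
    seed: int,
) -> NullPrsEnsemble:
    """Simulated scores matched in SNP count to the disorder score.

    Per simulation and threshold: variants sampled uniformly without
    replacement from the panel, weights with replacement from
    ``effect_pool`` (non-negative harmonised effects); scores computed as
    the weighted dosage sum and Z-standardised over the panel subjects.
    Thresholds with a zero count are skipped and recorded.
    """
    pool = np.asarray(effect_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("effect pool is empty")
    if (pool < 0).any():
        raise ValueError("effect pool must be positively harmonised")
    max_count = max(counts_per_threshold.values())
    if max_count > panel.n_variants:
        raise ValueError(
            f"requested {max_count} variants but panel has {panel.n_variants}"
        )
    rng = substream(seed, "null-prs")
    d = panel.dosages
    out: dict[float, np.ndarray] = {}
    skipped: list[float] = []
    for thr, cnt in counts_per_threshold.items():
        if cnt == 0:
            skipped.append(thr)
            continue
        sims = np.empty((n_sim, panel.n_subjects))
        for s in range(n_sim):
            idx = rng.choice(panel.n_variants, size=cnt, replace=False)
            w = rng.choice(pool, size=cnt, replace=True)
            sims[s] = zstandardize(d[:, idx] @ w)
        out[thr] = sims
    return NullPrsEnsemble(out, list(panel.subjects), n_sim, skipped, seed)


def choose_threshold(sim_assoc_p: dict[float, np.ndarray]) -> float:
    """Threshold with the lowest mean simulated association p-value.

    Ties are broken toward the more permissive (larger) threshold; all-NaN
    columns are excluded.
    """
    means: dict[float, float] = {}
    for thr, ps in sim_assoc_p.items():
        ps = np.asarray(ps, dtype=float)
        if np.isnan(ps).all():
            continue
        means[thr] = float(np.nanmean(ps))
    if not means:
        raise ValueError("no threshold has defined association p-values")
    best = min(means.values())
    candidates = [t for t, m in means.items() if m == best]
    return max(candidates)


@dataclass
class CalibrationResult:
    """Exact binomial estimate of the simulated-score success probability."""

    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    significant: bool
    alpha: float
    threshold: float = np.nan
    contrast: str = ""
    score_type: str = ""

    @property
    def estimate_str(self) -> str:
        """Printed-table convention: 4 decimals, '<1e-04' when k = 0."""
        if self.k == 0:
            return "<1e-04"
        return f"{self.estimate:.4f}"

    @property
    def ci_str(self) -> str:
        return f"{self.ci_low:.3f}-{self.ci_high:.3f}"


def binomial_success_test(
    k: int, n: int, alpha_threshold: float = 0.05 / 16
) -> CalibrationResult:
    """Exact binomial estimate k/n with a Clopper-Pearson 95% CI.

    Lower bound ``BetaQuantile(0.025; k, n-k+1)`` (0 when k = 0); upper
    bound ``BetaQuantile(0.975; k+1, n-k)`` (1 when k = n).  The
    significance flag tests the estimate against ``alpha_threshold``
    (default 0.05/16, the calibration family's Bonferroni level).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    est = k / n
    lo = 0.0 if k == 0 else float(sps.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(0.975, k + 1, n - k))
    return CalibrationResult(
        k=k,
        n=n,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        significant=est < alpha_threshold,
        alpha=alpha_threshold,
    )


def calibrate_contrast(
    p_disorder: float,
    sim_p: np.ndarray,
    threshold: float,
    contrast: str = "",
    score_type: str = "",
    alpha_threshold: float = 0.05 / 16,
) -> CalibrationResult:
    """Success count: simulations at least as strongly associated as the
    disorder score (ties count as successes)."""
    sim_p = np.asarray(sim_p, dtype=float)
    k = int(np.sum(sim_p <= p_disorder))
    res = binomial_success_test(k, sim_p.size, alpha_threshold)
    res.threshold = threshold
    res.contrast = contrast
    res.score_type = score_type
    return res


def calibration_table(results: list[CalibrationResult]) -> pd.DataFrame:
    """Report rows mirroring the calibration summary columns."""
    return pd.DataFrame(
        {
            "group": [r.contrast for r in results],
            "disorder_prs": [r.score_type for r in results],
            "min_pprs": [r.threshold for r in results],
            "n_success": [r.k for r in results],
            "prob": [r.estimate_str for r in results],
            "ci_low": [round(r.ci_low, 3) for r in results],
            "ci_high": [round(r.ci_high, 3) for r in results],
            "significant": [r.significant for r in results],
        }
    )
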