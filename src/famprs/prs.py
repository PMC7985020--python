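"""Polygenic risk scores: p-value thresholding, risk-load scaling and
Z-standardisation.

Raw scores are ``S_i = sum_j w_j d_ij`` with dosages oriented to the risk
allele; the scaled score divides by the maximum attainable load
``2 * sum_j w_j`` so that 0 and 1 are the minimum and maximum possible
cumulative risk loads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import DosagePanel
from .sumstats import AlignedVariantSet, SummaryStatistics

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PrsProfile",
    "select_by_threshold",
    "score",
    "zstandardize",
    "profile_thresholds",
]

#: the ten training-GWAS p-value cutoffs used throughout the pipeline
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    5e-8,
    1e-7,
    1e-6,
    1e-5,
    1e-4,
    1e-3,
    0.01,
    0.05,
    0.1,
    0.2,
)


def select_by_threshold(stats: SummaryStatistics, p_thr: float) -> SummaryStatistics:
    """Retain variants with p strictly below ``p_thr`` ("below" is strict)."""
    if not (0 < p_thr <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {p_thr}")
    p = pd.to_numeric(stats.df["P"], errors="coerce")
    return SummaryStatistics(stats.df[(p < p_thr).to_numpy()].copy())


def score(panel: DosagePanel, variants: AlignedVariantSet) -> pd.DataFrame:
    """Raw and scaled PRS for every panel subject.

    Returns a DataFrame indexed like ``panel.subjects`` with columns
    ``raw``, ``scaled`` and ``n_snps``.  Missing dosages are mean-imputed
    (2 x effect-allele frequency in the test sample).
    """
    if len(variants) == 0:
        raise ValueError("empty variant set: nothing to score")
    d = panel.dosages[:, variants.panel_index].copy()
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
    bad = (d < 0) | (d > 2)
    if bad.any():
        j = int(np.where(bad.any(axis=0))[0][0])
        raise ValueError(
            f"dosage outside [0, 2] for variant {variants.variant_ids[j]}"
        )
    d[:, variants.flip] = 2.0 - d[:, variants.flip]
    w = variants.weights
    raw = d @ w
    wsum = w.sum()
    scaled = raw / (2.0 * wsum) if wsum > 0 else np.zeros_like(raw)
    return pd.DataFrame(
        {"raw": raw, "scaled": scaled, "n_snps": len(variants)},
        index=pd.Index(panel.subjects, name="subject_id"),
    )


def zstandardize(x: np.ndarray | pd.Series) -> np.ndarray:
    """(x - mean) / sample SD (n-1 denominator) over exactly the given values."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two subjects to standardise")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or undefined variance: degenerate score")
    return (arr - arr.mean()) / sd


@dataclass
class PrsProfile:
    """Per-subject scores for one score type across the threshold grid.

    ``table`` is long-format: subject_id, score_type, threshold, raw,
    scaled, z, n_snps.  Thresholds with no selected variants are absent.
    """

    table: pd.DataFrame = field(repr=False)

    def at(self, threshold: float) -> pd.DataFrame:
        t = self.table[np.isclose(self.table["threshold"], threshold)]
        if t.empty:
            raise KeyError(f"no scores at threshold {threshold}")
        return t.set_index("subject_id")

    def thresholds(self) -> list[float]:
        return sorted(self.table["threshold"].unique().tolist())


def profile_thresholds(
    stats: SummaryStatistics,
    panel: DosagePanel,
    score_type: str,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> PrsProfile:
    """Score a panel at every threshold of the grid.

    Statistics are aligned to the panel once; thresholding then subsets the
    aligned weights, so the variant sets are nested across the grid.
    Standardisation here is over all panel subjects; analyses that model a
    subset must re-standardise over exactly that subset.
    """
    from .sumstats import align_to_panel

    aligned = align_to_panel(stats, panel)
    frames = []
    for thr in thresholds:
        sub = aligned.subset(aligned.pvalues < thr)
        if len(sub) == 0:
            continue
        sc = score(panel, sub)
        sc = sc.reset_index()
        sc.insert(1, "score_type", score_type)
        sc.insert(2, "threshold", thr)
        try:
            sc["z"] = zstandardize(sc["raw"].to_numpy())
        except ValueError:
            sc["z"] = np.nan
        frames.append(sc)
    if not frames:
        raise ValueError("no threshold selected any variants")
    return PrsProfile(pd.concat(frames, ignore_index=True))
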