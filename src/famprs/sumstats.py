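"""GWAS summary-statistics IO, harmonisation, filtering and panel alignment.

The on-disk format is a tab-delimited table with header
``SNP CHR BP A1 A2 BETA SE P INFO FRQ N`` (``CHR BP SE INFO FRQ N``
optional).  ``A1`` is the effect allele; ``BETA`` is on the log-odds or
liability scale.  An ``OR`` column is accepted in place of ``BETA`` and is
converted with ``beta = ln(OR)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import DosagePanel

__all__ = [
    "SummaryStatistics",
    "AlignedVariantSet",
    "read_sumstats",
    "write_sumstats",
    "harmonize_positive",
    "filter_info",
    "align_to_panel",
]

REQUIRED = ["SNP", "A1", "A2", "BETA", "P"]
OPTIONAL = ["CHR", "BP", "SE", "INFO", "FRQ", "N"]
CANONICAL_ORDER = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "INFO", "FRQ", "N"]


@dataclass
class SummaryStatistics:
    """Per-variant GWAS results as a validated DataFrame."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"summary statistics lack columns: {missing}")
        if df["SNP"].duplicated().any():
            dups = sorted(df.loc[df["SNP"].duplicated(), "SNP"].unique().tolist())
            raise ValueError(f"duplicated variant ids: {dups}")
        same = df["A1"].astype(str) == df["A2"].astype(str)
        if same.any():
            # records with identical alleles are uninterpretable; drop them
            df = df[~same]
        se = df.get("SE")
        if se is not None:
            bad = (pd.to_numeric(se, errors="coerce") <= 0).fillna(False)
            if bad.any():
                raise ValueError(
                    f"non-positive SE for variants: {df.loc[bad, 'SNP'].tolist()}"
                )
        p = pd.to_numeric(df["P"], errors="coerce")
        bad_p = ((p <= 0) | (p > 1)).fillna(False)
        if bad_p.any():
            raise ValueError(
                f"p-values outside (0,1] for variants: {df.loc[bad_p, 'SNP'].tolist()}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["SNP"].tolist()


def read_sumstats(path: str | Path) -> SummaryStatistics:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    if "BETA" not in df.columns:
        if "OR" in df.columns:
            df["BETA"] = np.log(pd.to_numeric(df["OR"]))
            df = df.drop(columns=["OR"])
        else:
            raise ValueError("summary statistics need a BETA or OR column")
    cols = [c for c in CANONICAL_ORDER if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    return SummaryStatistics(df[cols])


def write_sumstats(stats: SummaryStatistics, path: str | Path) -> None:
    stats.df.to_csv(path, sep="\t", index=False)


def harmonize_positive(stats: SummaryStatistics) -> SummaryStatistics:
    """Flip alleles so every effect size is non-negative.

    Variants with a negative effect have A1/A2 swapped, the effect negated
    and the effect-allele frequency complemented; p-values are untouched.
    Idempotent.
    """
    df = stats.df.copy()
    flip = df["BETA"].to_numpy() < 0
    if flip.any():
        # note: to_numpy() can alias the column storage, hence the copies
        a1 = df["A1"].to_numpy(dtype=object).copy()
        a2 = df["A2"].to_numpy(dtype=object).copy()
        df["A1"] = np.where(flip, a2, a1)
        df["A2"] = np.where(flip, a1, a2)
        df.loc[flip, "BETA"] = -df.loc[flip, "BETA"]
        if "FRQ" in df.columns:
            df.loc[flip, "FRQ"] = 1.0 - df.loc[flip, "FRQ"]
    return SummaryStatistics(df)


def filter_info(
    stats: SummaryStatistics,
    lo: float,
    hi: float = np.inf,
    keep_missing: bool = False,
) -> SummaryStatistics:
    """Retain variants with ``lo <= INFO <= hi`` (bounds inclusive).

    Variants without an INFO value are kept only when ``keep_missing`` is
    set.  ``lo > hi`` is rejected.
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    df = stats.df
    if "INFO" not in df.columns:
        if keep_missing:
            return SummaryStatistics(df.copy())
        raise ValueError("no INFO column and keep_missing is False")
    info = pd.to_numeric(df["INFO"], errors="coerce")
    keep = (info >= lo) & (info <= hi)
    if keep_missing:
        keep = keep | info.isna()
    return SummaryStatistics(df[keep.to_numpy()].copy())


@dataclass
class AlignedVariantSet:
    """Variants matched between summary statistics and a dosage panel.

    ``weights`` are the (non-negative, harmonised) effect sizes; ``flip``
    marks variants whose panel dosage counts the non-effect allele and must
    be complemented (d -> 2 - d) before scoring.  ``panel_index`` gives each
    variant's column in the panel.  ``dropped`` records unmatched or
    allele-discordant variants with a reason.
    """

    variant_ids: list[str]
    weights: np.ndarray
    flip: np.ndarray
    panel_index: np.ndarray
    pvalues: np.ndarray
    dropped: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("aligned weights must be non-negative")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, mask: np.ndarray) -> "AlignedVariantSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AlignedVariantSet(
            [self.variant_ids[i] for i in idx],
            self.weights[idx],
            self.flip[idx],
            self.panel_index[idx],
            self.pvalues[idx],
            self.dropped,
        )


def align_to_panel(stats: SummaryStatistics, panel: DosagePanel) -> AlignedVariantSet:
    """Match harmonised statistics to panel variants by id and allele pair.

    A variant matches when its (A1, A2) pair equals the panel's pair in
    either orientation; when the panel counts the other allele the flip flag
    is set so scoring complements the dosage.  Strand flipping is never
    attempted; discordant allele pairs are dropped and logged.
    """
    if (stats.df["BETA"].to_numpy() < 0).any():
        raise ValueError("statistics must be positively harmonised before alignment")
    pv = panel.variants
    panel_lookup = {
        s: (i, a1, a2)
        for i, (s, a1, a2) in enumerate(
            zip(pv["SNP"].astype(str), pv["A1"].astype(str), pv["A2"].astype(str))
        )
    }
    ids: list[str] = []
    weights: list[float] = []
    flips: list[bool] = []
    pidx: list[int] = []
    pvals: list[float] = []
    dropped: list[tuple[str, str]] = []
    for row in stats.df.itertuples(index=False):
        snp = str(row.SNP)
        hit = panel_lookup.get(snp)
        if hit is None:
            dropped.append((snp, "absent_from_panel"))
            continue
        i, pa1, pa2 = hit
        sa1, sa2 = str(row.A1), str(row.A2)
        if (sa1, sa2) == (pa1, pa2):
            flip = False
        elif (sa1, sa2) == (pa2, pa1):
            flip = True
        else:
            dropped.append((snp, "allele_mismatch"))
            continue
        ids.append(snp)
        weights.append(float(row.BETA))
        flips.append(flip)
        pidx.append(i)
        pvals.append(float(row.P))
    if not ids:
        raise ValueError("no variants shared between statistics and panel")
    drop_log = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    return AlignedVariantSet(
        ids,
        np.array(weights),
        np.array(flips, dtype=bool),
        np.array(pidx, dtype=int),
        np.array(pvals),
        drop_log,
    )
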