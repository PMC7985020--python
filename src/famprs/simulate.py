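"""Synthetic multiplex-family and case/control cohort generator.

Produces, with no external data: (a) multi-generation pedigrees with
BD/MDD/unaffected members under a correlated liability-threshold model and
optional spouse assortment on genetic BD score, (b) an unrelated
case/control cohort from the same effect panel, and (c) training GWAS
summary statistics for three genetically correlated disorders plus an
uncorrelated negative-control disorder.

Variants are simulated in linkage equilibrium (the scoring pipeline does no
clumping); :func:`simulate_ld_sumstats` provides a separate block-correlated
mode for LD-score-regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream
from .panels import DosagePanel, PedigreeCohort, PHENO_COLUMNS
from .sumstats import SummaryStatistics

__all__ = [
    "DISORDERS",
    "SimulationConfig",
    "TrueEffectPanel",
    "make_effect_panel",
    "simulate_founders",
    "gene_drop",
    "assign_phenotypes",
    "ascertain_multiplex",
    "simulate_sumstats",
    "simulate_family_cohort",
    "simulate_case_control",
    "simulate_ld_sumstats",
]

DISORDERS = ("BD", "SCZ", "MDD", "NEG")

_DEFAULT_RG = np.array(
    [
        # BD    SCZ   MDD   NEG
        [1.00, 0.60, 0.40, 0.00],
        [0.60, 1.00, 0.40, 0.00],
        [0.40, 0.40, 1.00, 0.00],
        [0.00, 0.00, 0.00, 1.00],
    ]
)


def _check_corr(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(DISORDERS), len(DISORDERS)):
        raise ValueError(f"{name} must be {len(DISORDERS)}x{len(DISORDERS)}")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(mat).min() < -1e-9:
        raise ValueError(f"{name} must be positive semi-definite")
    return mat


@dataclass
class SimulationConfig:
    """Design quantities for the synthetic cohorts.

    ``h2``/``prevalence``/``gwas_n`` are per-disorder mappings over
    ``DISORDERS``.  ``genetic_correlation`` is the cross-disorder
    correlation of true effects; by default the total liability correlation
    targets the same matrix, with the residual (environmental) correlation
    derived accordingly — pass ``liability_correlation`` to override.
    """

    n_variants: int = 400
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_families: int = 30
    generations_per_family: int = 3
    children_per_couple: float = 3.0  # Poisson mean, truncated to >= 1
    n_cc_cases: int = 100
    n_cc_controls: int = 150
    h2: dict[str, float] = field(
        default_factory=lambda: {"BD": 0.5, "SCZ": 0.5, "MDD": 0.3, "NEG": 0.3}
    )
    genetic_correlation: np.ndarray = field(default_factory=lambda: _DEFAULT_RG.copy())
    liability_correlation: np.ndarray | None = None
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"BD": 0.1, "SCZ": 0.05, "MDD": 0.2, "NEG": 0.05}
    )
    gwas_n: dict[str, int] = field(
        default_factory=lambda: {d: 50_000 for d in DISORDERS}
    )
    min_affected_for_multiplex: int = 2
    assortative_mating_strength: float = 0.0
    causal_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"maf_range must lie in (0, 1), got {self.maf_range}")
        for d in DISORDERS:
            if not 0 <= self.h2[d] <= 1:
                raise ValueError(f"h2[{d}] outside [0, 1]")
            if not 0 < self.prevalence[d] < 1:
                raise ValueError(f"prevalence[{d}] outside (0, 1)")
        if not 0 <= self.assortative_mating_strength < 1:
            raise ValueError("assortative_mating_strength must be in [0, 1)")
        self.genetic_correlation = _check_corr(
            self.genetic_correlation, "genetic_correlation"
        )
        if self.liability_correlation is not None:
            self.liability_correlation = _check_corr(
                self.liability_correlation, "liability_correlation"
            )

    def residual_correlation(self) -> np.ndarray:
        """Environmental correlation matrix implied by the liability target.

        With target total liability correlation R_L, genetic correlation R_g
        and heritabilities h, the residual correlation satisfies
        ``R_L = sqrt(h h') R_g + sqrt((1-h)(1-h')) R_e`` elementwise.
        """
        target = (
            self.liability_correlation
            if self.liability_correlation is not None
            else self.genetic_correlation
        )
        h = np.array([self.h2[d] for d in DISORDERS])
        gh = np.sqrt(np.outer(h, h))
        eh = np.sqrt(np.outer(1 - h, 1 - h))
        re = np.ones_like(target)
        off = eh > 0
        re[off] = (target[off] - gh[off] * self.genetic_correlation[off]) / eh[off]
        np.fill_diagonal(re, 1.0)
        if np.abs(re).max() > 1 + 1e-9:
            raise ValueError("implied residual correlation exceeds [-1, 1]")
        if np.linalg.eigvalsh(re).min() < -1e-9:
            raise ValueError("implied residual correlation is not positive semi-definite")
        return np.clip(re, -1.0, 1.0)


@dataclass
class TrueEffectPanel:
    """Ground-truth per-variant liability effects for every disorder.

    ``betas[:, d]`` are per-allele effects scaled so the aggregate genetic
    liability has (theoretical) unit variance per disorder before the h2
    scaling applied at phenotype assignment.
    """

    variants: pd.DataFrame = field(repr=False)  # SNP CHR BP A1 A2 + MAF
    betas: np.ndarray = field(repr=False)  # (n_variants, n_disorders)
    causal: np.ndarray = field(repr=False)  # bool, same shape

    @property
    def mafs(self) -> np.ndarray:
        return self.variants["MAF"].to_numpy()

    def disorder_index(self, disorder: str) -> int:
        return DISORDERS.index(disorder)

    def genetic_score(self, dosages: np.ndarray, disorder: str) -> np.ndarray:
        """Standardised aggregate genetic liability G_d for given dosages.

        Centred by the theoretical mean ``sum_j 2 p_j beta_j`` and scaled by
        the theoretical SD (unity by construction of the panel).
        """
        d = self.disorder_index(disorder)
        b = self.betas[:, d]
        mu = float(2.0 * self.mafs @ b)
        var = float((2.0 * self.mafs * (1.0 - self.mafs)) @ b**2)
        sd = np.sqrt(var) if var > 0 else 1.0
        return (dosages @ b - mu) / sd


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "T"), ("G", "A")]


def make_effect_panel(config: SimulationConfig, seed: int) -> TrueEffectPanel:
    """Draw MAFs, alleles and cross-correlated true effects."""
    rng = substream(seed, "effects")
    m = config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "CHR": (np.arange(m) % 22) + 1,
            "BP": (np.arange(m) // 22 + 1) * 10_000,
            "A1": [p[0] for p in pairs],
            "A2": [p[1] for p in pairs],
            "MAF": mafs,
        }
    )
    chol = np.linalg.cholesky(
        config.genetic_correlation + 1e-10 * np.eye(len(DISORDERS))
    )
    u = rng.standard_normal((m, len(DISORDERS))) @ chol.T
    causal = rng.random((m, len(DISORDERS))) < config.causal_fraction
    u = u * causal
    # per-variant scaling so each causal variant contributes equally and the
    # aggregate genetic variance is 1 per disorder
    het = 2.0 * mafs * (1.0 - mafs)
    n_causal = np.maximum(causal.sum(axis=0), 1)
    betas = u / np.sqrt(het[:, None] * n_causal[None, :])
    return TrueEffectPanel(variants, betas, causal)


def simulate_founders(
    n_subjects: int,
    effect_panel: TrueEffectPanel,
    seed: int,
    id_prefix: str = "F",
) -> DosagePanel:
    """Draw founder genotypes as two Bernoulli(p_j) allele draws per variant.

    Haplotypes are retained so gene dropping can transmit single alleles.
    """
    mafs = effect_panel.mafs
    if not np.all(np.isfinite(mafs)):
        raise ValueError("non-finite MAF in effect panel")
    rng = substream(seed, "founders")
    haps = (
        rng.random((n_subjects, len(mafs), 2)) < mafs[None, :, None]
    ).astype(np.int8)
    subjects = [f"{id_prefix}{i + 1}" for i in range(n_subjects)]
    return DosagePanel(
        subjects,
        effect_panel.variants[["SNP", "CHR", "BP", "A1", "A2"]].copy(),
        haps.sum(axis=2).astype(float),
        haplotypes=haps,
    )


def _meiosis(parent_haps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete: a uniformly chosen allele per variant (no linkage)."""
    m = parent_haps.shape[0]
    pick = rng.integers(0, 2, size=m)
    return parent_haps[np.arange(m), pick]


def gene_drop(
    pedigree: PedigreeCohort, founder_alleles: DosagePanel, seed: int
) -> DosagePanel:
    """Transmit founder alleles down a pedigree, one random allele per parent.

    Every non-founder must have both parents in the pedigree; founders must
    carry allele-resolved genotypes in ``founder_alleles``.
    """
    if founder_alleles.haplotypes is None:
        raise ValueError("founder panel must carry allele-resolved haplotypes")
    rng = substream(seed, "transmission")
    t = pedigree.table
    ids = t["iid"].tolist()
    present = set(ids)
    founder_idx = {s: i for i, s in enumerate(founder_alleles.subjects)}
    m = founder_alleles.n_variants
    haps: dict[str, np.ndarray] = {}
    pending = list(t.itertuples(index=False))
    # iterate until all members resolved (handles arbitrary row order)
    progress = True
    while pending and progress:
        progress = False
        remaining = []
        for row in pending:
            iid, fa, mo = row.iid, row.father, row.mother
            if fa == "0" and mo == "0":
                if iid not in founder_idx:
                    raise ValueError(f"founder {iid} has no genotype in founder panel")
                haps[iid] = founder_alleles.haplotypes[founder_idx[iid]]
                progress = True
                continue
            if fa == "0" or mo == "0" or fa not in present or mo not in present:
                raise ValueError(f"non-founder {iid} is missing a parent")
            if fa in haps and mo in haps:
                child = np.empty((m, 2), dtype=np.int8)
                child[:, 0] = _meiosis(haps[fa], rng)
                child[:, 1] = _meiosis(haps[mo], rng)
                haps[iid] = child
                progress = True
            else:
                remaining.append(row)
        pending = remaining
    if pending:
        raise ValueError(
            f"unresolvable pedigree (cycle or missing parents) at: "
            f"{[r.iid for r in pending]}"
        )
    hap_arr = np.stack([haps[i] for i in ids])
    return DosagePanel(
        ids,
        founder_alleles.variants.copy(),
        hap_arr.sum(axis=2).astype(float),
        haplotypes=hap_arr,
    )


def assign_phenotypes(
    dosages: DosagePanel,
    effect_panel: TrueEffectPanel,
    config: SimulationConfig,
    seed: int,
    structure: pd.DataFrame | None = None,
    cohort_label: str = "FAM",
) -> PedigreeCohort:
    """Assign diagnoses under the correlated liability-threshold model.

    Per subject, ``L_d = sqrt(h2_d) G_d + sqrt(1 - h2_d) E_d`` with G_d the
    standardised genetic score and E residual-correlated per
    :meth:`SimulationConfig.residual_correlation`.  Diagnosis is BD if
    ``L_BD > T_BD``, else MDD if ``L_MDD > T_MDD``, else unaffected, with
    ``T_d`` the upper prevalence quantile of the standard normal.
    """
    rng = substream(seed, "environment")
    n = dosages.n_subjects
    re_chol = np.linalg.cholesky(
        config.residual_correlation() + 1e-10 * np.eye(len(DISORDERS))
    )
    env = rng.standard_normal((n, len(DISORDERS))) @ re_chol.T
    liab = np.empty((n, len(DISORDERS)))
    gsc = np.empty((n, len(DISORDERS)))
    for d, name in enumerate(DISORDERS):
        g = effect_panel.genetic_score(dosages.dosages, name)
        gsc[:, d] = g
        h2 = config.h2[name]
        liab[:, d] = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * env[:, d]
    thresholds = {
        d: sps.norm.isf(config.prevalence[d]) for d in DISORDERS
    }
    diag = np.where(
        liab[:, DISORDERS.index("BD")] > thresholds["BD"],
        "BD",
        np.where(
            liab[:, DISORDERS.index("MDD")] > thresholds["MDD"], "MDD", "unaffected"
        ),
    )
    if structure is None:
        structure = pd.DataFrame(
            {
                "fid": [f"S{i + 1}" for i in range(n)],
                "iid": dosages.subjects,
                "father": "0",
                "mother": "0",
                "sex": (rng.integers(0, 2, size=n) + 1),
                "generation": 0,
                "married_in": False,
            }
        )
    else:
        structure = structure.set_index("iid").loc[dosages.subjects].reset_index()
    tbl = structure.copy()
    tbl["diagnosis"] = diag
    tbl["cohort"] = cohort_label
    age = rng.normal(45, 12, size=n).clip(16, 90).round(1)
    tbl["age_interview"] = age
    onset = rng.normal(25, 6, size=n).clip(10, None).round(1)
    tbl["age_onset"] = np.where(diag == "unaffected", np.nan, np.minimum(onset, age))
    for d, name in enumerate(DISORDERS):
        tbl[f"liab_{name}"] = liab[:, d]
        tbl[f"gscore_{name}"] = gsc[:, d]
    cols = PHENO_COLUMNS + [c for c in tbl.columns if c not in PHENO_COLUMNS]
    return PedigreeCohort(tbl[cols])


def ascertain_multiplex(cohort: PedigreeCohort, min_affected: int) -> PedigreeCohort:
    """Keep only families with at least ``min_affected`` BD cases.

    ``min_affected = 0`` is the identity; negative values are rejected.
    """
    if min_affected < 0:
        raise ValueError("min_affected must be non-negative")
    if min_affected == 0:
        return PedigreeCohort(cohort.table.copy())
    t = cohort.table
    counts = t.groupby("fid")["diagnosis"].apply(lambda s: (s == "BD").sum())
    keep = counts[counts >= min_affected].index
    return PedigreeCohort(t[t["fid"].isin(keep)].copy())


def simulate_sumstats(
    effect_panel: TrueEffectPanel,
    disorder: str,
    gwas_n: int,
    seed: int,
    info_dist: tuple[float, float] = (0.4, 1.1),
) -> SummaryStatistics:
    """Emulated training-GWAS results for one disorder.

    ``beta_hat_j = beta_true_j + eps_j`` with
    ``SE_j = 1 / sqrt(2 p_j (1 - p_j) gwas_n)``, two-sided Wald p-values and
    INFO drawn uniformly on ``info_dist`` to exercise quality filters.
    Monomorphic variants are emitted with missing statistics.
    """
    if gwas_n <= 0:
        raise ValueError("gwas_n must be positive")
    rng = substream(seed, f"sumstats:{disorder}")
    d = effect_panel.disorder_index(disorder)
    p = effect_panel.mafs
    beta_true = effect_panel.betas[:, d]
    het = 2.0 * p * (1.0 - p)
    mono = het <= 0
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(het * gwas_n)
    se[mono] = np.nan
    beta_hat = beta_true + rng.standard_normal(len(p)) * np.where(mono, 0.0, se)
    with np.errstate(invalid="ignore"):
        z = beta_hat / se
    pval = 2.0 * sps.norm.sf(np.abs(z))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    beta_hat[mono] = np.nan
    pval[mono] = np.nan
    info = rng.uniform(*info_dist, size=len(p))
    df = effect_panel.variants[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    df["BETA"] = beta_hat
    df["SE"] = se
    df["P"] = pval
    df["INFO"] = info
    df["FRQ"] = p
    df["N"] = gwas_n
    df["FLAGGED"] = mono
    return SummaryStatistics(df)


# --------------------------------------------------------------------------
# pedigree construction


def _match_spouses(
    child_scores: np.ndarray,
    spouse_scores: np.ndarray,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pair each child with a spouse index, rank-matching on genetic score.

    With strength r each child's matching key is ``r z(rank) +
    sqrt(1-r^2) noise``; children sorted by key are paired with spouses
    sorted by score, which induces approximately Spearman correlation r
    between spouse genetic scores.  r = 0 is random mating.
    """
    n = len(child_scores)
    if strength <= 0:
        return rng.permutation(n)
    ranks = sps.rankdata(child_scores)
    z = sps.norm.ppf(ranks / (n + 1))
    key = strength * z + np.sqrt(1 - strength**2) * rng.standard_normal(n)
    child_order = np.argsort(key)
    spouse_order = np.argsort(spouse_scores)
    out = np.empty(n, dtype=int)
    out[child_order] = spouse_order
    return out


def simulate_family_cohort(
    config: SimulationConfig,
    effect_panel: TrueEffectPanel,
    seed: int,
) -> tuple[PedigreeCohort, DosagePanel]:
    """Build multi-generation pedigrees with genotypes (no diagnoses yet).

    Generation 0 of each family is a founder couple; each couple has a
    truncated-Poisson number of children; children of non-terminal
    generations marry spouses drawn from a fresh founder pool, matched
    across families on true BD genetic score when assortative mating is
    configured.  Returns the structure table (inside a cohort with
    placeholder phenotype columns) and the genotype panel.
    """
    rng = substream(seed, "pedigree")
    n_fam = config.n_families
    m = config.n_variants
    variants = effect_panel.variants[["SNP", "CHR", "BP", "A1", "A2"]].copy()

    rows: list[dict] = []
    haps: dict[str, np.ndarray] = {}

    def add_founder(iid: str, fid: str, gen: int, sex: int, married_in: bool,
                    hap: np.ndarray) -> None:
        haps[iid] = hap
        rows.append(
            dict(fid=fid, iid=iid, father="0", mother="0", sex=sex,
                 generation=gen, married_in=married_in)
        )

    def draw_haps(k: int) -> np.ndarray:
        return (
            rng.random((k, m, 2)) < effect_panel.mafs[None, :, None]
        ).astype(np.int8)

    # generation 0: founder couples
    couples: list[tuple[str, str, str]] = []  # (fid, father, mother)
    g0 = draw_haps(2 * n_fam)
    for f in range(n_fam):
        fid = f"FAM{f + 1}"
        pa, ma = f"{fid}_G0_P", f"{fid}_G0_M"
        add_founder(pa, fid, 0, 1, False, g0[2 * f])
        add_founder(ma, fid, 0, 2, False, g0[2 * f + 1])
        couples.append((fid, pa, ma))

    for gen in range(1, config.generations_per_family):
        children: list[tuple[str, str, int]] = []  # (fid, iid, sex)
        born: dict[str, int] = {}
        for fid, pa, ma in couples:
            n_child = max(1, rng.poisson(config.children_per_couple))
            for _ in range(n_child):
                born[fid] = born.get(fid, 0) + 1
                iid = f"{fid}_G{gen}_C{born[fid]}"
                sex = int(rng.integers(0, 2)) + 1
                child = np.empty((m, 2), dtype=np.int8)
                child[:, 0] = _meiosis(haps[pa], rng)
                child[:, 1] = _meiosis(haps[ma], rng)
                haps[iid] = child
                rows.append(
                    dict(fid=fid, iid=iid, father=pa, mother=ma, sex=sex,
                         generation=gen, married_in=False)
                )
                children.append((fid, iid, sex))
        if gen == config.generations_per_family - 1:
            break
        # children marry founders drawn from a fresh pool, matched on the
        # true BD genetic score across all families of this generation
        spouse_haps = draw_haps(len(children))
        child_dos = np.stack([haps[iid].sum(axis=1) for _, iid, _ in children])
        child_scores = effect_panel.genetic_score(child_dos.astype(float), "BD")
        spouse_scores = effect_panel.genetic_score(
            spouse_haps.sum(axis=2).astype(float), "BD"
        )
        pairing = _match_spouses(
            child_scores, spouse_scores, config.assortative_mating_strength, rng
        )
        couples = []
        for (fid, iid, sex), sp_idx in zip(children, pairing):
            sp_id = f"{iid}_sp"
            sp_sex = 2 if sex == 1 else 1
            add_founder(sp_id, fid, gen, sp_sex, True, spouse_haps[sp_idx])
            father, mother = (iid, sp_id) if sex == 1 else (sp_id, iid)
            couples.append((fid, father, mother))

    structure = pd.DataFrame(rows)
    ids = structure["iid"].tolist()
    hap_arr = np.stack([haps[i] for i in ids])
    panel = DosagePanel(ids, variants, hap_arr.sum(axis=2).astype(float), hap_arr)
    cohort = assign_phenotypes(
        panel, effect_panel, config, seed, structure=structure, cohort_label="FAM"
    )
    return cohort, panel


def simulate_case_control(
    config: SimulationConfig,
    effect_panel: TrueEffectPanel,
    seed: int,
    max_batches: int = 200,
) -> tuple[PedigreeCohort, DosagePanel]:
    """Unrelated BD cases and screened controls from the population model.

    Batches of unrelated subjects are simulated and classified until the
    configured case and control counts are reached.
    """
    need_cases, need_controls = config.n_cc_cases, config.n_cc_controls
    batch = max(200, need_cases + need_controls)
    got_rows: list[pd.DataFrame] = []
    got_dos: list[np.ndarray] = []
    n_cases = n_controls = 0
    for b in range(max_batches):
        panel = simulate_founders(
            batch, effect_panel, seed + 7919 * b, id_prefix=f"CC{b}_"
        )
        coh = assign_phenotypes(
            panel, effect_panel, config, seed + 7919 * b, cohort_label="CC"
        )
        t = coh.table
        take_case = t.index[t["diagnosis"] == "BD"][: need_cases - n_cases]
        take_ctrl = t.index[t["diagnosis"] == "unaffected"][
            : need_controls - n_controls
        ]
        idx = take_case.union(take_ctrl)
        if len(idx):
            got_rows.append(t.loc[idx])
            got_dos.append(panel.dosages[idx.to_numpy()])
            n_cases += len(take_case)
            n_controls += len(take_ctrl)
        if n_cases >= need_cases and n_controls >= need_controls:
            break
    else:
        raise RuntimeError(
            "could not collect the requested case/control counts; "
            "check prevalence and batch limits"
        )
    table = pd.concat(got_rows, ignore_index=True)
    dosages = np.vstack(got_dos)
    panel = DosagePanel(
        table["iid"].tolist(),
        effect_panel.variants[["SNP", "CHR", "BP", "A1", "A2"]].copy(),
        dosages,
    )
    return PedigreeCohort(table), panel


# --------------------------------------------------------------------------
# block-LD summary-statistic simulator (for LD score regression tests)


def simulate_ld_sumstats(
    n_blocks: int,
    block_size: int,
    block_r: float,
    h2: dict[str, float],
    genetic_correlation: np.ndarray,
    gwas_n: dict[str, float],
    seed: int,
) -> tuple[dict[str, SummaryStatistics], np.ndarray]:
    """Z-score summary statistics under exchangeable within-block LD.

    Block ``b`` (of ``n_blocks``) has pairwise genotype correlation
    ``r_b = block_r * (b + 1) / n_blocks``, so LD scores
    ``1 + (block_size - 1) r_b^2`` vary across blocks (the regression needs
    that leverage).  Per block, standardised joint effects are drawn with
    the configured cross-disorder correlation and per-variant variance
    ``h2 / M``; z-scores follow ``z = sqrt(N) R beta + MVN(0, R)`` with
    independent noise across disorders (non-overlapping samples).  Returns
    statistics on the standardised-genotype scale (SE = 1/sqrt(N)) plus the
    LD scores.
    """
    rng = substream(seed, "ld-sumstats")
    disorders = list(h2)
    k = len(disorders)
    corr = np.asarray(genetic_correlation, dtype=float)
    if corr.shape != (k, k) or not np.allclose(corr, corr.T):
        raise ValueError("genetic_correlation must be a symmetric k x k matrix")
    m_total = n_blocks * block_size
    chol_g = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
    sd = np.array([np.sqrt(h2[d] / m_total) for d in disorders])
    zs = {d: np.empty(m_total) for d in disorders}
    ld = np.empty(m_total)
    for blk in range(n_blocks):
        r_b = block_r * (blk + 1) / n_blocks
        r_block = np.full((block_size, block_size), r_b)
        np.fill_diagonal(r_block, 1.0)
        chol_r = np.linalg.cholesky(r_block + 1e-10 * np.eye(block_size))
        sl = slice(blk * block_size, (blk + 1) * block_size)
        ld[sl] = 1.0 + (block_size - 1) * r_b**2
        beta = (rng.standard_normal((block_size, k)) @ chol_g.T) * sd[None, :]
        noise = chol_r @ rng.standard_normal((block_size, k))
        for j, d in enumerate(disorders):
            n = gwas_n[d]
            zs[d][sl] = np.sqrt(n) * (r_block @ beta[:, j]) + noise[:, j]
    out = {}
    for d in disorders:
        n = gwas_n[d]
        se = np.full(m_total, 1.0 / np.sqrt(n))
        beta_hat = zs[d] * se
        p = np.clip(2.0 * sps.norm.sf(np.abs(zs[d])), np.nextafter(0, 1), 1.0)
        df = pd.DataFrame(
            {
                "SNP": [f"rs{i + 1}" for i in range(m_total)],
                "A1": "A",
                "A2": "G",
                "BETA": beta_hat,
                "SE": se,
                "P": p,
                "N": n,
            }
        )
        out[d] = SummaryStatistics(df)
    return out, ld
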