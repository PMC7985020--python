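"""End-to-end orchestration on a synthetic cohort.

``run_pipeline`` executes: simulation -> summary-statistic harmonisation and
filtering -> shared meta-analysis and disorder-specific (GWIS) weights ->
PRS profiles -> GRM on pruned genotypes -> the configured group contrasts ->
null calibration -> descriptive and calibration reports.  Every stage
failure aborts with the stage name; outputs are stamped with a config hash
and the master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as calib
from . import cross_disorder as xd
from . import mixed, prs, simulate, stats
from .panels import DosagePanel, PedigreeCohort
from .sumstats import SummaryStatistics, filter_info, harmonize_positive

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

DEFAULT_CONTRASTS = [
    ("FAM_BD", "CC_controls"),
    ("FAM_BD", "CC_BD"),
    ("FAM_unaffected", "CC_controls"),
    ("FAM_MDD", "CC_controls"),
    ("FAM_BD", "FAM_unaffected"),
    ("married_in", "CC_controls"),
]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable record."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")

    def record(self) -> dict:
        return {"stage": self.stage, "error": str(self.cause)}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    ``score_types`` picks the score families; GWIS types are written
    ``TARGET-COVARIATE``.  ``n_calibration`` is the simulated-score ensemble
    size (the full-scale analysis uses 10,000; desk-scale runs shrink it).
    """

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    thresholds: tuple[float, ...] = prs.DEFAULT_THRESHOLDS
    score_types: tuple[str, ...] = ("BD", "SCZ", "MDD", "Shared", "BD-MDD", "NEG")
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_CONTRASTS)
    )
    calibration_contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("FAM_BD", "CC_controls")]
    )
    exclude_married_in: bool = True
    info_min: float = 0.6
    gwis_info_range: tuple[float, float] = (0.9, 1.1)
    alpha: float = 0.05
    n_tests: int | None = None  # default: len(thresholds) * len(score_types)
    calibration_alpha_tests: int = 16
    n_calibration: int = 200
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["simulation"]["genetic_correlation"] = np.asarray(
            self.simulation.genetic_correlation
        ).tolist()
        if self.simulation.liability_correlation is not None:
            payload["simulation"]["liability_correlation"] = np.asarray(
                self.simulation.liability_correlation
            ).tolist()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _group_mask(table: pd.DataFrame, group: str) -> pd.Series:
    if group == "married_in":
        return (table["cohort"] == "FAM") & table["married_in"].astype(bool)
    cohort, _, diag = group.partition("_")
    diag = {"controls": "unaffected", "BD": "BD", "MDD": "MDD",
            "unaffected": "unaffected"}[diag]
    mask = (table["cohort"] == cohort) & (table["diagnosis"] == diag)
    return mask


def _contrast_frame(
    table: pd.DataFrame,
    group1: str,
    group0: str,
    exclude_married_in: bool,
) -> pd.DataFrame:
    m1 = _group_mask(table, group1)
    m0 = _group_mask(table, group0)
    if exclude_married_in and group1 != "married_in" and group0 != "married_in":
        mi = table["married_in"].astype(bool) & (table["cohort"] == "FAM")
        m1, m0 = m1 & ~mi, m0 & ~mi
    if (m1 & m0).any():
        raise ValueError(f"groups {group1} and {group0} overlap")
    if not m1.any() or not m0.any():
        raise ValueError(f"empty group in contrast {group1} vs {group0}")
    sub = table[m1 | m0].copy()
    sub["y"] = m1[m1 | m0].astype(int)
    return sub


def _merge_cohorts(
    fam: PedigreeCohort, fam_panel: DosagePanel, cc: PedigreeCohort, cc_panel: DosagePanel
) -> tuple[pd.DataFrame, DosagePanel]:
    table = pd.concat([fam.table, cc.table], ignore_index=True)
    dosages = np.vstack([fam_panel.dosages, cc_panel.dosages])
    panel = DosagePanel(
        fam_panel.subjects + cc_panel.subjects, fam_panel.variants.copy(), dosages
    )
    return table, panel


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    When ``config.out_dir`` is set, reports are also written there as TSV
    plus a JSON summary.
    """
    bundle: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    seed = config.seed
    sim = config.simulation

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return deco

    # ---- simulation ------------------------------------------------------
    @stage("simulate")
    def _sim():
        panel_fx = simulate.make_effect_panel(sim, seed)
        fam, fam_panel = simulate.simulate_family_cohort(sim, panel_fx, seed)
        fam = simulate.ascertain_multiplex(fam, sim.min_affected_for_multiplex)
        fam_panel = fam_panel.subset_subjects(fam.subjects)
        cc, cc_panel = simulate.simulate_case_control(sim, panel_fx, seed + 1)
        raw_stats = {
            d: simulate.simulate_sumstats(panel_fx, d, sim.gwas_n[d], seed)
            for d in simulate.DISORDERS
        }
        return panel_fx, fam, fam_panel, cc, cc_panel, raw_stats

    panel_fx, fam, fam_panel, cc, cc_panel, raw_stats = _sim
    table, panel = _merge_cohorts(fam, fam_panel, cc, cc_panel)

    # ---- summary-statistic processing -----------------------------------
    @stage("harmonize")
    def _harm():
        filtered = {
            d: filter_info(raw_stats[d], config.info_min) for d in simulate.DISORDERS
        }
        return filtered

    filtered = _harm

    @stage("shared_meta")
    def _shared():
        trio = [filtered["BD"], filtered["SCZ"], filtered["MDD"]]
        ids = xd.select_shared(*trio)
        if not ids:
            return None
        return harmonize_positive(xd.shared_meta(trio, ids))

    shared_stats = _shared

    @stage("gwis")
    def _gwis():
        out = {}
        lo, hi = config.gwis_info_range
        for st in config.score_types:
            if "-" not in st:
                continue
            target, cov = st.split("-")
            t = filter_info(raw_stats[target], lo, hi)
            c = filter_info(raw_stats[cov], lo, hi)
            # LD scores are constant without LD, so the regression cannot
            # separate slope from intercept here; the generator's configured
            # heritability and coheritability are used instead.
            i_t = simulate.DISORDERS.index(target)
            i_c = simulate.DISORDERS.index(cov)
            h2_c = sim.h2[cov]
            rho = sim.genetic_correlation[i_t, i_c] * np.sqrt(
                sim.h2[target] * h2_c
            )
            out[st] = xd.gwis_correct(t, c, h2_c, rho)
        return out

    gwis_stats = _gwis

    # ---- PRS profiles ----------------------------------------------------
    @stage("score")
    def _score():
        profiles: dict[str, prs.PrsProfile] = {}
        for st in config.score_types:
            if st == "Shared":
                if shared_stats is None:
                    continue
                ss = shared_stats
            elif "-" in st:
                ss = harmonize_positive(gwis_stats[st])
            else:
                ss = harmonize_positive(filtered[st])
            try:
                profiles[st] = prs.profile_thresholds(
                    ss, panel, st, config.thresholds
                )
            except ValueError:
                continue
        if not profiles:
            raise ValueError("no score type produced any profile")
        return profiles

    profiles = _score

    # ---- GRM -------------------------------------------------------------
    @stage("grm")
    def _grm():
        pruned = mixed.prune_ld(panel)
        return mixed.compute_grm(pruned)

    grm = _grm

    # ---- contrasts -------------------------------------------------------
    @stage("associate")
    def _assoc():
        rows = []
        subj_pos = {s: i for i, s in enumerate(panel.subjects)}
        for g1, g0 in config.contrasts:
            sub = _contrast_frame(table, g1, g0, config.exclude_married_in)
            idx = [subj_pos[s] for s in sub["iid"]]
            kk = grm.matrix[np.ix_(idx, idx)]
            sex = (sub["sex"].to_numpy() == 2).astype(float)
            for st, profile in profiles.items():
                for thr in profile.thresholds():
                    sc = profile.at(thr).loc[sub["iid"], "raw"].to_numpy()
                    try:
                        z = prs.zstandardize(sc)
                        res = mixed.fit_logistic_mixed(
                            sub["y"].to_numpy(), z, sex, kk,
                            score_type=st, threshold=thr,
                        )
                    except ValueError:
                        continue
                    rows.append(
                        {
                            "contrast": f"{g1}_vs_{g0}",
                            "score_type": st,
                            "threshold": thr,
                            "OR": res.odds_ratio,
                            "CI_low": res.ci_low,
                            "CI_high": res.ci_high,
                            "p_one_sided": res.p_one_sided,
                            "sigma2": res.sigma2,
                            "converged": res.converged,
                        }
                    )
        return pd.DataFrame(rows)

    assoc = _assoc
    n_tests = config.n_tests or len(config.thresholds) * len(config.score_types)
    if not assoc.empty:
        assoc["bonferroni_alpha"] = stats.bonferroni(config.alpha, n_tests)
        assoc["significant"] = assoc["p_one_sided"] < assoc["bonferroni_alpha"]

    # ---- anticipation (generation trend) ---------------------------------
    @stage("anticipation")
    def _anticipation():
        if "BD" not in profiles:
            return None
        t = table[(table["cohort"] == "FAM") & ~table["married_in"].astype(bool)]
        if t["generation"].nunique() < 2 or len(t) < 10:
            return None
        prof = profiles["BD"]
        thr = prof.thresholds()[-1]
        z = prs.zstandardize(prof.at(thr).loc[t["iid"], "raw"].to_numpy())
        sex = (t["sex"].to_numpy() == 2).astype(float)
        age = t["age_interview"].to_numpy(dtype=float)
        covs = np.column_stack([sex, age])
        subj_pos = {s: i for i, s in enumerate(panel.subjects)}
        idx = [subj_pos[s] for s in t["iid"]]
        kk = grm.matrix[np.ix_(idx, idx)]
        res = mixed.fit_lmm_quant(
            z, t["generation"].to_numpy(dtype=float), covs, kk
        )
        return {
            "threshold": thr,
            "beta": res.beta,
            "p_one_sided": res.p_one_sided,
        }

    anticipation = _anticipation

    # ---- null calibration ------------------------------------------------
    @stage("calibrate")
    def _calibrate():
        if "BD" not in profiles or config.n_calibration <= 0:
            return []
        bd = profiles["BD"]
        counts = {
            thr: int(bd.at(thr)["n_snps"].iloc[0]) for thr in bd.thresholds()
        }
        pool = np.concatenate(
            [
                np.abs(filtered[d].df["BETA"].dropna().to_numpy())
                for d in ("BD", "SCZ", "MDD")
            ]
        )
        ensemble = calib.draw_null_prs(
            panel, counts, pool, config.n_calibration, seed
        )
        results = []
        subj_pos = {s: i for i, s in enumerate(panel.subjects)}
        for g1, g0 in config.calibration_contrasts:
            sub = _contrast_frame(table, g1, g0, config.exclude_married_in)
            idx = [subj_pos[s] for s in sub["iid"]]
            kk = grm.matrix[np.ix_(idx, idx)]
            sex = (sub["sex"].to_numpy() == 2).astype(float)
            y = sub["y"].to_numpy(dtype=float)
            sim_p = {}
            for thr, sims in ensemble.scores.items():
                sub_scores = sims[:, idx].T
                sim_p[thr] = mixed.fast_assoc_many(y, sex, kk, sub_scores)
            thr = calib.choose_threshold(sim_p)
            for st, profile in profiles.items():
                try:
                    sc = profile.at(thr).loc[sub["iid"], "raw"].to_numpy()
                except KeyError:
                    continue
                p_dis = float(
                    mixed.fast_assoc_many(y, sex, kk, prs.zstandardize(sc))[0]
                )
                res = calib.calibrate_contrast(
                    p_dis,
                    sim_p[thr],
                    thr,
                    contrast=f"{g1}_vs_{g0}",
                    score_type=st,
                    alpha_threshold=stats.bonferroni(
                        config.alpha, config.calibration_alpha_tests
                    ),
                )
                results.append(res)
        return results

    calib_results = _calibrate

    # ---- descriptive table ----------------------------------------------
    @stage("describe")
    def _describe():
        rows = []
        groups = ["FAM_BD", "FAM_MDD", "FAM_unaffected", "CC_BD", "CC_controls"]
        for g in groups:
            m = _group_mask(table, g)
            sub = table[m]
            if sub.empty:
                continue
            n = len(sub)
            med_age, mad_age = stats.median_mad(sub["age_interview"])
            n_f = int((sub["sex"] == 2).sum())
            row = {
                "group": g,
                "n": n,
                "median_age": med_age,
                "mad_age": mad_age,
                "female_n": n_f,
                "female_pct": stats.percent_summary(n_f, n),
                "missing_age": int(sub["age_interview"].isna().sum()),
            }
            onset = sub["age_onset"]
            if onset.notna().any():
                mo, mado = stats.median_mad(onset)
                row.update(median_onset=mo, mad_onset=mado)
            rows.append(row)
        return pd.DataFrame(rows)

    table1 = _describe

    bundle.update(
        {
            "associations": assoc,
            "anticipation": anticipation,
            "calibration": calib.calibration_table(calib_results)
            if calib_results
            else pd.DataFrame(),
            "descriptives": table1,
            "n_fam": int((table["cohort"] == "FAM").sum()),
            "n_cc": int((table["cohort"] == "CC").sum()),
            "bonferroni_alpha": stats.bonferroni(config.alpha, n_tests),
        }
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        bundle["calibration"].to_csv(out / "calibration.tsv", sep="\t", index=False)
        table1.to_csv(out / "descriptives.tsv", sep="\t", index=False)
        fam.write_fam(out / "families.fam")
        fam.write_phenotypes(out / "phenotypes.tsv")
        summary = {
            "config_hash": bundle["config_hash"],
            "seed": seed,
            "n_fam": bundle["n_fam"],
            "n_cc": bundle["n_cc"],
            "bonferroni_alpha": bundle["bonferroni_alpha"],
            "anticipation": anticipation,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return bundle
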