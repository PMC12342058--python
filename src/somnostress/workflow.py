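"""End-to-end study pipeline on a synthetic cohort.

``run_study`` chains the stages — generate, stage, spectral, architecture,
behavior, statistics — and emits one table per analysis the study design
calls for: interaction scores pre/post defeat, baseline sleep architecture
and SWA time courses by sex and phenotype, bout statistics, relative SWA
by EEG lead, sleep lost / recovery / slow-wave energy around the
restriction day, pre/post-defeat sleep change, and the accompanying
ANOVA + Holm–Šídák blocks.

Exclusion rules applied throughout: recordings with more than 5% artifact
epochs are dropped from all sleep analyses; subjects with a post-defeat
social-interaction ratio inside the closed band [0.9, 1.1] are dropped
from sleep analyses but kept in behavioral tables.

With ``synthesize_signals=False`` the pipeline runs signal-free: it uses
the generator's ground-truth hypnograms and analytic band powers instead
of staging rendered EEG. This keeps replicate-level Monte-Carlo studies
cheap while exercising the identical downstream analysis code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import architecture as arch
from . import behavior as beh
from . import spectral as spec
from . import staging
from . import stats as st
from . import synth
from .core import NREM, Hypnogram


@dataclass
class StudyConfig:
    """Configuration of one synthetic study run; seeds are explicit."""

    n_pairs: int = 4
    seed: int = 0
    synthesize_signals: bool = True
    artifact_fraction: float = 0.01
    presets: dict | None = None
    emg_wake_quantile: float = 0.60
    delta_nrem_quantile: float = 0.55
    theta_delta_rem_ratio: float = 1.5
    swa_bin_h: float = 1.0
    zone_mode: str = "boundary"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All analysis tables plus provenance (config hash, seed)."""

    tables: dict[str, pd.DataFrame]
    manifest: dict

    def report_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].round(9).to_csv(index=False).encode())
        return h.hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def apply_exclusions(design: pd.DataFrame, post_scores: pd.DataFrame,
                     artifact_fractions: dict[str, float]) -> tuple[list[str], pd.DataFrame]:
    """Decide which subjects enter the sleep analyses.

    Parameters
    ----------
    design : cohort design table with ``subject_id``.
    post_scores : per-subject post-defeat interaction results with
        ``subject_id`` and ``sir``.
    artifact_fractions : worst-case artifact fraction per subject across
        its analysed recordings.

    Returns
    -------
    (included subject ids for sleep analyses, audit table). Behavioral
    analyses always keep every subject.
    """
    audit_rows = []
    sirs = post_scores.set_index("subject_id")["sir"] if len(post_scores) else pd.Series(dtype=float)
    included = []
    for sid in design["subject_id"]:
        reasons = []
        frac = artifact_fractions.get(sid, 0.0)
        if frac > staging.ARTIFACT_EXCLUSION_FRACTION:
            reasons.append(f"artifact>{staging.ARTIFACT_EXCLUSION_FRACTION:.0%}")
        if sid in sirs.index:
            if beh.classify_phenotype(float(sirs[sid])) == "excluded":
                reasons.append("SIR in [0.9, 1.1]")
        else:
            reasons.append("missing post-defeat interaction data")
        if reasons:
            audit_rows.append({"subject_id": sid, "reason": "; ".join(reasons),
                               "artifact_fraction": frac,
                               "sir": float(sirs.get(sid, np.nan))})
        else:
            included.append(sid)
    audit = pd.DataFrame(audit_rows,
                         columns=["subject_id", "reason", "artifact_fraction", "sir"])
    return included, audit


def _analysis_hypnograms(cohort: synth.CohortBundle, cfg: StudyConfig,
                         day_kinds: tuple[str, ...]):
    """Per subject and analysis day: hypnogram + band-power tables.

    Signal mode stages the rendered EEG; signal-free mode uses generator
    truth. Returns (hyps, powers, artifact_fracs) keyed by
    (subject, day_kind).
    """
    hyps: dict[tuple[str, str], Hypnogram] = {}
    powers: dict[tuple[str, str], pd.DataFrame] = {}
    worst_artifact: dict[str, float] = {}
    for sid in cohort.design["subject_id"]:
        for kind in day_kinds:
            day = cohort.schedule.day_of_kind(kind)
            truth = cohort.day_hypnogram(sid, day.day_index)
            s_day = cohort.day_s(sid, day.day_index)
            params = cohort.params[sid]
            if cfg.synthesize_signals:
                rec = cohort.recordings[(sid, day.day_index)]
                hyp, thr = staging.stage_recording(
                    rec,
                    emg_wake_quantile=cfg.emg_wake_quantile,
                    delta_nrem_quantile=cfg.delta_nrem_quantile,
                    theta_delta_rem_ratio=cfg.theta_delta_rem_ratio,
                )
                pw = staging.extract_features(rec)
            else:
                hyp = truth
                pw = synth.truth_band_powers(truth, s_day, params)
                par = synth.truth_band_powers(truth, s_day, params,
                                              channel="eeg_parietal")
                pw = pw.assign(delta_parietal=par["delta"],
                               total_parietal=par["total"])
            hyps[(sid, kind)] = hyp
            powers[(sid, kind)] = pw
            frac = hyp.artifact_fraction
            worst_artifact[sid] = max(worst_artifact.get(sid, 0.0), frac)
    return hyps, powers, worst_artifact


def _swa_tables(sid_rows, hyps, powers, cfg) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Baseline-normalized SWA time courses, relative SWA by lead, SWE."""
    tc_rows, lead_rows, swe_rows = [], [], []
    for row in sid_rows:
        sid = row["subject_id"]
        base_hyp, base_pw = hyps[(sid, "baseline")], powers[(sid, "baseline")]
        base_nrem = base_hyp.mask(NREM)
        base_delta = base_pw["delta"].to_numpy()[base_nrem]
        base_delta = base_delta[np.isfinite(base_delta)]
        for kind in ("baseline", "recovery", "post_defeat"):
            if (sid, kind) not in hyps:
                continue
            hyp, pw = hyps[(sid, kind)], powers[(sid, kind)]
            nrem = hyp.mask(NREM)
            delta = pw["delta"].to_numpy()
            ok = nrem & np.isfinite(delta)
            norm = spec.normalized_swa(delta[ok], base_delta)
            tc = spec.swa_timecourse(norm, hyp.epoch_zt_s()[ok], cfg.swa_bin_h)
            tc.insert(0, "subject_id", sid)
            tc.insert(1, "day", kind)
            tc_rows.append(tc)
            swe = spec.slow_wave_energy(np.nan_to_num(delta), nrem & np.isfinite(delta))
            swe_rows.append({"subject_id": sid, "day": kind,
                             "swe_uv2s": float(swe[-1]),
                             "swe_rel_baseline": np.nan})
        if "delta_parietal" in base_pw:
            ok = base_nrem & np.isfinite(base_pw["delta"].to_numpy())
            for lead, dcol, tcol in (("frontal", "delta", "total"),
                                     ("parietal", "delta_parietal", "total_parietal")):
                rel = spec.relative_swa(base_pw[dcol].to_numpy()[ok],
                                        base_pw[tcol].to_numpy()[ok])
                lead_rows.append({"subject_id": sid, "lead": lead,
                                  "rel_swa_pct": float(np.mean(rel))})
    swe_df = pd.DataFrame(swe_rows)
    base_swe = swe_df[swe_df["day"] == "baseline"].set_index("subject_id")["swe_uv2s"]
    swe_df["swe_rel_baseline"] = [
        100.0 * r.swe_uv2s / base_swe[r.subject_id] if base_swe.get(r.subject_id, 0) else np.nan
        for r in swe_df.itertuples()
    ]
    tc = pd.concat(tc_rows, ignore_index=True) if tc_rows else pd.DataFrame()
    return tc, pd.DataFrame(lead_rows), swe_df


def _anova_block(table: pd.DataFrame, dv: str, meta: pd.DataFrame) -> pd.DataFrame:
    """Mixed ANOVA on a per-subject pre/post table, degrading the
    between-factor set when cells are too small; Holm–Šídák over the
    within-level post-hoc t-tests."""
    long = table.melt(id_vars="subject_id", value_vars=["pre", "post"],
                      var_name="time_bin", value_name="value")
    long = long.merge(meta, on="subject_id")
    for between in (("sex", "phenotype"), ("sex",), ()):
        try:
            res = st.mixed_anova(long, dv="value", between=between)
            res.insert(0, "dv", dv)
            res.attrs["between_factors"] = between
            return res
        except ValueError:
            continue
    return pd.DataFrame([{"dv": dv, "effect": "unavailable", "SS": np.nan,
                          "df_num": np.nan, "df_den": np.nan, "MS": np.nan,
                          "F": np.nan, "p": np.nan, "stratum": "n/a"}])


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full synthetic study; pure function of the config."""
    cfg = config
    try:
        cohort = synth.simulate_cohort(
            cfg.n_pairs, seed=cfg.seed, presets=cfg.presets,
            artifact_fraction=cfg.artifact_fraction,
            synthesize=cfg.synthesize_signals,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(f"generate: {e}") from e

    # --- behavior ---------------------------------------------------------
    try:
        beh_rows = []
        for sid in cohort.design["subject_id"]:
            for when in ("pre", "post"):
                res = beh.score_interaction_test(
                    cohort.trajectories[(sid, when, "empty")],
                    cohort.trajectories[(sid, when, "target")],
                    mode=cfg.zone_mode,
                )
                beh_rows.append({"subject_id": sid, "when": when, **res})
        interaction = pd.DataFrame(beh_rows)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"behavior: {e}") from e

    # --- staging / spectral ----------------------------------------------
    day_kinds = ("baseline", "sleep_restriction", "recovery", "post_defeat")
    try:
        hyps, powers, worst_artifact = _analysis_hypnograms(cohort, cfg, day_kinds)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"staging: {e}") from e

    post_scores = interaction[interaction["when"] == "post"][["subject_id", "sir"]]
    included, audit = apply_exclusions(cohort.design, post_scores, worst_artifact)
    meta = cohort.design.copy()
    measured = post_scores.set_index("subject_id")["sir"].map(beh.classify_phenotype)
    meta["phenotype"] = meta["subject_id"].map(measured)
    sleep_meta = meta[meta["subject_id"].isin(included)]
    sid_rows = sleep_meta.to_dict("records")

    # --- architecture -----------------------------------------------------
    try:
        arch_rows, bout_rows, lost_rows, recov_rows = [], [], [], []
        for row in sid_rows:
            sid = row["subject_id"]
            base = hyps[(sid, "baseline")]
            for window, label in (((0.0, 12.0), "light"), ((12.0, 24.0), "dark")):
                mins = arch.state_minutes(base, window)
                arch_rows.append({"subject_id": sid, "phase": label,
                                  **mins.to_dict()})
            bouts = arch.bout_stats(arch.segment_bouts(base))
            bouts.insert(0, "subject_id", sid)
            bout_rows.append(bouts)
            lost = arch.sleep_lost(base, hyps[(sid, "sleep_restriction")])
            lost_rows.append({"subject_id": sid, **lost.to_dict()})
            # the 18 h recovery window follows forced wake on the same day
            rec_curve = arch.recovery_sleep(base, hyps[(sid, "sleep_restriction")])
            recov_rows.append({"subject_id": sid,
                               "nrem_recovered_min": rec_curve["cum_nrem_gain_min"].iloc[-1],
                               "rem_recovered_min": rec_curve["cum_rem_gain_min"].iloc[-1]})
        pre = {r["subject_id"]: hyps[(r["subject_id"], "baseline")] for r in sid_rows}
        post = {r["subject_id"]: hyps[(r["subject_id"], "post_defeat")] for r in sid_rows}
        prepost = arch.pre_post_change(pre, post, "nrem_minutes")
    except Exception as e:  # noqa: BLE001
        raise StageError(f"architecture: {e}") from e

    # --- spectral ---------------------------------------------------------
    try:
        swa_tc, rel_lead, swe = _swa_tables(sid_rows, hyps, powers, cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"spectral: {e}") from e

    # --- statistics -------------------------------------------------------
    try:
        anova = _anova_block(prepost, "nrem_minutes_pre_post",
                             sleep_meta[["subject_id", "sex", "phenotype"]])
        pvals = anova.loc[anova["p"].notna(), "p"].tolist()
        posthoc = st.holm_sidak(pvals) if pvals else pd.DataFrame()
        if len(posthoc):
            posthoc.insert(0, "effect", anova.loc[anova["p"].notna(), "effect"].values)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stats: {e}") from e

    tables = {
        "interaction": interaction,
        "exclusions": audit,
        "baseline_architecture": pd.DataFrame(arch_rows),
        "bout_stats": pd.concat(bout_rows, ignore_index=True) if bout_rows else pd.DataFrame(),
        "baseline_swa_timecourse": swa_tc,
        "relative_swa_by_lead": rel_lead,
        "sleep_lost": pd.DataFrame(lost_rows),
        "recovery": pd.DataFrame(recov_rows),
        "swe": swe,
        "pre_post_change": prepost,
        "anova_pre_post_nrem": anova,
        "posthoc_holm_sidak": posthoc,
    }
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": int(len(cohort.design)),
        "sleep_analysis_subjects": included,
    }
    return StudyReport(tables=tables, manifest=manifest)


def exclusion_audit(report: StudyReport) -> pd.DataFrame:
    """Excluded subjects with the rule that removed them."""
    return report.tables["exclusions"].copy()
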