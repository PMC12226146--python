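"""End-to-end study orchestration.

``run_pipeline`` executes the full analysis on a synthetic cohort:
simulate -> per-subject connectome construction (scrub, partial
correlations, absolute values, lesion mask) -> graph metrics -> random-
graph normalization -> hubscores and cohort hub partition -> normative
w-scores and domains -> group statistics.  Every stage writes its tabular
artifacts to the output directory and the run ends with a JSON report
carrying seeds, counts and content hashes, so a rerun with the same config
and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cognition as cg
from . import stats as st
from .connectome import Connectome, apply_lesion_mask, build_connectome, write_connectome
from .hubs import classify_cohort, hub_frequency_table, hubscore_subject
from .metrics import WHOLEBRAIN_METRICS
from .nulls import normalize_metrics
from .synthetic import Cohort, CohortSpec, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending subject."""


@dataclass
class RunConfig:
    """All knobs of a simulated study run.

    Thresholds carry the pipeline's standard defaults (FD < 0.5 mm,
    translation < 1.5 mm, DVARS mean + 3 SD, lesion fraction > 0.5,
    hubscore quantile 0.2, 1000 null graphs); ``cohort`` holds the
    generator's study conditions.  ``master_seed`` is mandatory.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    fd_limit: float = 0.5
    translation_limit: float = 1.5
    dvars_k: float = 3.0
    max_scrub_fraction: float = 0.2
    lesion_threshold: float = 0.5
    hub_quantile: float = 0.2
    hubscore_on_normalized: bool = True
    n_random: int = 1000
    wholebrain_family: int = 4
    correlation_family: int = 24
    master_seed: int = 0
    write_connectomes: bool = False

    def validate(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        for name in ("fd_limit", "translation_limit", "dvars_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_scrub_fraction", "lesion_threshold", "hub_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subject_connectome(subj, cohort: Cohort, cfg: RunConfig) -> Connectome:
    if cohort.spec.noiseless:
        conn = Connectome(weights=np.abs(cohort.network.partial_corr), atlas=cohort.atlas)
        if subj.lesion is not None and subj.lesion.max() > 0:
            conn = apply_lesion_mask(conn, subj.lesion, cfg.lesion_threshold)
        return conn
    return build_connectome(
        subj.timeseries,
        motion=subj.motion,
        lesion=subj.lesion,
        atlas=cohort.atlas,
        fd_limit=cfg.fd_limit,
        translation_limit=cfg.translation_limit,
        dvars_k=cfg.dvars_k,
        lesion_threshold=cfg.lesion_threshold,
        max_scrub_fraction=cfg.max_scrub_fraction,
    )


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": {"master_seed": cfg.master_seed}}
    t_start = time.time()

    def stage(name):
        report["stages"][name] = {"t_start": round(time.time() - t_start, 3)}
        return time.time()

    def stage_done(name, t0, **info):
        report["stages"][name].update(seconds=round(time.time() - t0, 3), **info)

    # -- simulate ----------------------------------------------------------
    t0 = stage("simulate")
    cohort = generate_cohort(cfg.cohort, master_seed=cfg.master_seed)
    write_cohort(cohort, outdir / "cohort")
    stage_done("simulate", t0, n_subjects=len(cohort.subjects), n_regions=len(cohort.atlas))

    # -- connectomes + metrics + normalization -----------------------------
    t0 = stage("connectomes")
    norm_root = np.random.SeedSequence(cfg.master_seed + 1)
    norm_seeds = [int(s.generate_state(1)[0] % 2**31) for s in norm_root.spawn(len(cohort.subjects))]

    nodal_norm: dict[str, pd.DataFrame] = {}
    nodal_raw: dict[str, pd.DataFrame] = {}
    whole_rows = []
    n_floating = {}
    failed_qc: list[str] = []
    kept_subjects = []
    for subj, nseed in zip(cohort.subjects, norm_seeds):
        try:
            conn = _subject_connectome(subj, cohort, cfg)
        except ValueError as exc:
            if "quality gate" in str(exc):
                failed_qc.append(subj.subject_id)
                continue
            raise PipelineError(f"connectome stage failed for {subj.subject_id}: {exc}") from exc
        if cfg.write_connectomes:
            (outdir / "connectomes").mkdir(exist_ok=True)
            write_connectome(conn, outdir / "connectomes" / f"{subj.subject_id}_connectome.tsv")
        norm = normalize_metrics(conn, n_random=cfg.n_random, seed=nseed)
        nodal_norm[subj.subject_id] = norm.nodal_normalized
        nodal_raw[subj.subject_id] = norm.nodal_observed
        row = {"subject_id": subj.subject_id, "group": subj.group}
        for m in WHOLEBRAIN_METRICS:
            row[m] = norm.wholebrain_normalized[m]
            row[m + "_raw"] = norm.wholebrain_observed[m]
        whole_rows.append(row)
        n_floating[subj.subject_id] = len(conn.floating_nodes)
        kept_subjects.append(subj)
    whole = pd.DataFrame(whole_rows).set_index("subject_id")
    whole.to_csv(outdir / "metrics_wholebrain.tsv", sep="\t")
    stage_done(
        "connectomes", t0,
        n_passed_qc=len(kept_subjects), failed_qc=failed_qc,
        floating_nodes={k: v for k, v in n_floating.items() if v},
    )

    # -- hub classification ------------------------------------------------
    t0 = stage("hubs")
    region_names = cohort.atlas.names
    score_rows = {}
    for subj in kept_subjects:
        table = nodal_norm[subj.subject_id] if cfg.hubscore_on_normalized else nodal_raw[subj.subject_id]
        score_rows[subj.subject_id] = hubscore_subject(table, quantile=cfg.hub_quantile)
    scores = pd.DataFrame(score_rows).T
    scores.columns = region_names
    scores.to_csv(outdir / "hubscores.tsv", sep="\t")

    groups = pd.Series({s.subject_id: s.group for s in kept_subjects})
    controls = [s.subject_id for s in kept_subjects if s.group == "control"]
    partition = classify_cohort(scores, controls)
    pd.DataFrame(
        {
            "label": partition.labels,
            "fraction_hubscore_ge2": partition.fraction_hubscore_ge2,
            "fraction_hubscore_0": partition.fraction_hubscore_0,
        }
    ).to_csv(outdir / "hub_partition.tsv", sep="\t", index_label="region")
    stage_done("hubs", t0, n_hubs=len(partition.hubs), n_nonhubs=len(partition.nonhubs))

    # -- cognition ---------------------------------------------------------
    t0 = stage("cognition")
    participants = cohort.participants.set_index("subject_id").loc[[s.subject_id for s in kept_subjects]]
    controls_df = participants[participants["group"] == "control"]
    model = cg.fit_normative_model(controls_df)
    wsc = cg.w_score(model, participants)
    wsc.to_csv(outdir / "wscores.tsv", sep="\t")
    domains = cg.domain_scores(wsc)
    domains.to_csv(outdir / "domains.tsv", sep="\t")
    impairment_rate = {
        g: float(domains.loc[participants["group"] == g, "impaired"].mean())
        for g in ("patient", "control")
    }
    stage_done("cognition", t0, impairment_rate=impairment_rate)

    # -- statistics --------------------------------------------------------
    t0 = stage("stats")
    patients = [s.subject_id for s in kept_subjects if s.group == "patient"]
    wb_results = []
    for m in WHOLEBRAIN_METRICS[:4]:
        vals, flags = st.log_transform_if_nonnormal(whole[m].to_numpy())
        series = pd.Series(vals, index=whole.index)
        res = st.mann_whitney(series.loc[patients], series.loc[controls],
                              family_size=cfg.wholebrain_family)
        wb_results.append(
            {"metric": m, "U": res.statistic, "p": res.p, "p_bonf": res.p_bonf,
             "log_transformed": flags["transformed"]}
        )
    wb_df = pd.DataFrame(wb_results)
    wb_df.to_csv(outdir / "stats_wholebrain.tsv", sep="\t", index=False)

    # hub-frequency chi-square per node
    freq = hub_frequency_table(scores, groups)
    chi_rows = []
    for node, table in freq.items():
        res = st.chi_square_2x2(table, family_size=len(freq))
        chi_rows.append({"region": node, "chi2": res.statistic, "p": res.p, "p_bonf": res.p_bonf})
    pd.DataFrame(chi_rows).to_csv(outdir / "stats_hub_frequency.tsv", sep="\t", index=False)

    # mixed ANOVA per nodal metric, hubs and nonhubs separately
    anova_rows = []
    for metric in ("clustering", "betweenness", "assortativity", "strength",
                   "path_length", "local_efficiency"):
        for label, node_set in (("hubs", partition.hubs), ("nonhubs", partition.nonhubs)):
            if len(node_set) < 2:
                continue
            long_rows = []
            for subj in kept_subjects:
                tab = nodal_norm[subj.subject_id]
                tab.index = region_names
                for node in node_set:
                    v = tab.loc[node, metric]
                    long_rows.append(
                        {"subject": subj.subject_id, "group": subj.group,
                         "node": node, "value": v}
                    )
            long = pd.DataFrame(long_rows).dropna(subset=["value"])
            complete = long.groupby("subject")["node"].nunique() == len(node_set)
            long = long[long["subject"].map(complete)]
            if long["subject"].nunique() < 4:
                continue
            positive = long["value"].min() >= 0
            if positive:
                vals, _ = st.log_transform_if_nonnormal(long["value"].to_numpy())
                long = long.assign(value=vals)
            try:
                res = st.mixed_anova(long, dv="value", within="node",
                                     subject="subject", between="group")
            except ValueError:
                continue
            b = res["between"]
            anova_rows.append(
                {"metric": metric, "node_set": label, "F": b.statistic,
                 "df1": b.df[0], "df2": b.df[1], "p": b.p,
                 "eta_p2": b.effect_size, "grade": b.effect_grade}
            )
    anova_df = pd.DataFrame(anova_rows)
    anova_df.to_csv(outdir / "stats_anova.tsv", sep="\t", index=False)

    # whole-brain metric x cognitive domain correlation grid
    domain_cols = [c for c in domains.columns if c != "impaired"]
    grid = st.correlation_matrix(
        domains[domain_cols], whole[WHOLEBRAIN_METRICS[:4]],
        family_size=cfg.correlation_family,
    )
    grid.to_csv(outdir / "stats_correlations.tsv", sep="\t", index=False)

    n_sig = int((grid["p_bonf"] < 0.05).sum())
    summary = {
        "wholebrain_significant": wb_df.loc[wb_df["p_bonf"] < 0.05, "metric"].tolist(),
        "anova_significant": anova_df.loc[anova_df["p"] < 0.05, ["metric", "node_set"]].to_dict("records") if len(anova_df) else [],
        "n_significant_correlations": n_sig,
    }
    (outdir / "stats_summary.json").write_text(json.dumps(summary, indent=2))
    stage_done("stats", t0, **summary)

    # -- report ------------------------------------------------------------
    report["counts"] = {
        "subjects": len(cohort.subjects),
        "subjects_passing_qc": len(kept_subjects),
        "regions": len(cohort.atlas),
        "hubs": len(partition.hubs),
        "nonhubs": len(partition.nonhubs),
        "planted_hubs": sorted(cohort.network.planted_hubs),
        "hub_regions": partition.hubs,
        "significant_correlation_cells": n_sig,
    }
    report["artifacts"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json"))
        if p.name != "run_report.json"
    }
    report["total_seconds"] = round(time.time() - t_start, 3)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
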