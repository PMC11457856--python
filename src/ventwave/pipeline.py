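"""End-to-end analysis pipeline on a synthetic cohort.

Mirrors the study shape: simulate flow-rate groups -> per-breath motion
metrics -> mechanics/energetics -> synthetic EIT regional metrics -> cohort
statistics -> CSV + markdown report. Fully deterministic for a given
configuration and seed; every artifact embeds the config hash, seed, and
package version for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breaths import CHANNELS, motion_metrics, segment_breaths
from .cohort import Scenario, make_cohort
from .eit import regional_summary, tidal_image
from .eit_synth import make_regional_map, synthesize_eit
from .io import dump_json, write_waveform_csv
from .mechanics import mechanics_table, vei
from .stats import summarize_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    scenario: Scenario = field(default_factory=Scenario)
    seed: int = 0
    out_dir: str = "ventwave_report"
    n_per_group: int | None = None
    smoothing_window: int = 7
    flow_tolerance: float = 0.3  # L/min; above the 0.1 L/min sensor-noise SD
    unventilated_threshold: float = 0.10
    vei_K: float = 3800.0
    me_formula: str = "elastic-peep"
    mp_reference: str = "peep"  # or "atmosphere"
    discard_breaths: int = 2  # settle-in breaths dropped per subject
    eit_shape: tuple = (32, 32)
    eit_frame_rate: float = 48.0
    eit_right_share: float = 0.55
    eit_vd_bias: float = 0.3
    eit_heterogeneity_cv: float = 0.3
    write_waveforms: bool = True


def _config_hash(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("out_dir")
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _subject_metrics(subject, config: PipelineConfig, eit_seed: int) -> dict:
    rec = subject.recording
    segs = segment_breaths(rec, flow_tolerance=config.flow_tolerance)
    if len(segs) > config.discard_breaths + 2:
        segs = segs[config.discard_breaths:]
    if not segs:
        raise ValueError(f"{subject.subject_id}: no complete breaths")

    out: dict[str, float] = {}
    motion = motion_metrics(rec, flow_tolerance=config.flow_tolerance,
                            smoothing_window=config.smoothing_window)
    motion = motion[motion["breath_index"] >= config.discard_breaths]
    for channel in CHANNELS:
        insp = motion[(motion["channel"] == channel) & (motion["phase"] == "insp")]
        expp = motion[(motion["channel"] == channel) & (motion["phase"] == "exp")]
        out[f"T_peak_{channel}_s"] = float(insp["T_peak_s"].mean())
        out[f"slope_max_insp_{channel}"] = float(insp["slope_max"].mean())
        out[f"slope_max_exp_{channel}"] = float(expp["slope_max"].mean())

    mech = mechanics_table(rec, segs, me_formula=config.me_formula,
                           mp_reference=config.mp_reference)
    for col, name in (("dP", "dP_cmH2O"), ("V_T_mlkg", "V_T_mlkg"),
                      ("C_dyn_mlkg", "C_dyn_mlkg_cmH2O"),
                      ("Flow_peak_lpm", "Flow_peak_lpm"),
                      ("MP_tidal_J_min_kg", "MP_tidal_J_min_kg"),
                      ("ME_RS_J_kg", "ME_RS_J_kg"),
                      ("C_fit", "C_fit_ml_cmH2O"), ("R_fit", "R_fit_cmH2O_s_ml")):
        out[name] = float(mech[col].mean())

    # steady-state gas exchange at the delivered V_T and set rate
    lung, settings = subject.lung, subject.settings
    v_a = settings.rate * max(mech["V_T_ml"].mean() - lung.dead_space, 0.0)
    paco2 = (lung.CO2_production_constant / v_a) if v_a > 0 else 130.0
    out["PaCO2_mmHg"] = paco2
    out["VEI"] = vei(out["dP_cmH2O"], settings.rate, paco2, config.vei_K).VEI
    out["rate_bpm"] = settings.rate

    rmap = make_regional_map(config.eit_shape,
                             right_share=config.eit_right_share,
                             ventral_dorsal_bias=config.eit_vd_bias,
                             heterogeneity_cv=config.eit_heterogeneity_cv,
                             seed=eit_seed)
    frames = synthesize_eit(rec, rmap, frame_rate=config.eit_frame_rate)
    image = tidal_image(frames)
    reg = regional_summary(image, config.unventilated_threshold)
    for key in ("CoV_VD", "CoV_RL", "uniform_CoV_VD", "uniform_CoV_RL",
                "unventilated_pct", "rel_aeration_ventral",
                "rel_aeration_central", "rel_aeration_dorsal",
                "rel_aeration_right", "rel_aeration_left"):
        out[key] = float(reg[key])
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns result tables and paths.

    Writes per-subject waveform CSVs, the per-subject metric table, the
    group summary, the comparison battery (JSON), a markdown report, and a
    metadata file with the config hash, seed, and package version. Byte-
    identical outputs for identical (config, seed).
    """
    scenario = config.scenario
    n = config.n_per_group if config.n_per_group is not None else scenario.n_per_group
    if not scenario.groups:
        raise ValueError("scenario has no groups")
    if n < 2:
        raise ValueError("n_per_group must be >= 2 (validation before simulation)")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    cohort_seed, eit_root = (int(c.generate_state(1)[0] % 2 ** 31)
                             for c in ss.spawn(2))
    cohort = make_cohort(scenario, n, seed=cohort_seed)
    eit_rng = np.random.default_rng(eit_root)

    rows = []
    for subject in cohort:
        eit_seed = int(eit_rng.integers(2 ** 31))
        metrics = _subject_metrics(subject, config, eit_seed)
        row = {"subject_id": subject.subject_id, "group": subject.group,
               "time_s": scenario.duration}
        row.update(metrics)
        rows.append(row)
        if config.write_waveforms:
            wdir = out_dir / "waveforms"
            wdir.mkdir(exist_ok=True)
            write_waveform_csv(subject.recording,
                               wdir / f"{subject.subject_id}.csv")
    per_subject = pd.DataFrame(rows)

    long = per_subject.melt(
        id_vars=["subject_id", "group", "time_s"],
        var_name="metric", value_name="value")
    results = summarize_cohort(long)
    summary: pd.DataFrame = results["summary"]

    ground_truth = pd.DataFrame([s.ground_truth() for s in cohort])
    per_subject.to_csv(out_dir / "per_subject_metrics.csv", index=False,
                       float_format="%.10g")
    summary.to_csv(out_dir / "group_summary.csv", index=False,
                   float_format="%.10g")
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False,
                        float_format="%.10g")

    comparisons_json = {
        metric: {"test": r.test, "statistic": r.statistic, "df": list(r.df),
                 "p": r.p,
                 "pairwise": (r.pairwise.to_dict("records")
                              if r.pairwise is not None else None)}
        for metric, r in sorted(results["comparisons"].items())
    }
    dump_json(comparisons_json, out_dir / "comparisons.json")

    meta = {"config_hash": _config_hash(config), "seed": config.seed,
            "version": __version__,
            "config": {k: v for k, v in dataclasses.asdict(config).items()
                       if k != "out_dir"}}
    dump_json(meta, out_dir / "metadata.json")

    report = _render_report(summary, results["comparisons"], meta)
    (out_dir / "report.md").write_text(report, encoding="utf-8")

    return {"out_dir": out_dir, "per_subject": per_subject,
            "summary": summary, "comparisons": results["comparisons"],
            "cohort": cohort, "metadata": meta,
            "report_path": out_dir / "report.md"}


_REPORT_METRICS = (
    "T_peak_pressure_s", "T_peak_volume_s", "T_peak_flow_s",
    "slope_max_insp_pressure", "slope_max_insp_volume", "slope_max_insp_flow",
    "Flow_peak_lpm", "dP_cmH2O", "V_T_mlkg", "C_dyn_mlkg_cmH2O",
    "MP_tidal_J_min_kg", "ME_RS_J_kg", "VEI", "PaCO2_mmHg",
    "CoV_VD", "CoV_RL", "unventilated_pct",
)


def _render_report(summary: pd.DataFrame, comparisons: dict, meta: dict) -> str:
    lines = ["# Synthetic cohort ventilation report", "",
             f"- config hash: `{meta['config_hash']}`",
             f"- seed: {meta['seed']}",
             f"- ventwave version: {meta['version']}", "",
             "Group values are mean ± SD of per-subject means; the test is "
             "Welch t (2 groups) or one-way ANOVA with Tukey HSD (3+).", ""]
    for metric in _REPORT_METRICS:
        sub = summary[summary["metric"] == metric]
        if sub.empty:
            continue
        comp = comparisons.get(metric)
        ptxt = f"p = {comp.p:.4g} ({comp.test})" if comp is not None else "n/a"
        lines.append(f"## {metric}")
        lines.append("")
        lines.append("| group | mean | SD | n |")
        lines.append("|---|---|---|---|")
        for _, r in sub.iterrows():
            lines.append(f"| {r['group']} | {r['mean']:.6g} | {r['sd']:.4g} "
                         f"| {int(r['n'])} |")
        lines.append("")
        lines.append(ptxt)
        lines.append("")
    return "\n".join(lines)
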