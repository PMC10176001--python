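"""End-to-end pipeline: simulate → extract MEPs → map → classify → stats.

Each stage is a plain function over files so it can run standalone (and is
what the CLI subcommands call); :func:`run_pipeline` chains them and writes a
run manifest with per-stage row counts and exclusions.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    classify_cohort,
    control_reference,
    summarize_labels,
)
from .emg import extract_mep, flag_inconsistent_background
from .io import PipelineConfig, read_emg_dir, write_csv, write_emg_dir, write_json
from .mapping import StimulationEvent, build_map, cog_displacement, percent_change
from .stats import (
    mixed_anova,
    pearson_with_band,
    pooled_t_from_samples,
    responder_stratified_anova,
)
from .synthetic import FrameSpec, generate_cohort, make_scenarios

logger = logging.getLogger("mapresponder")

PAIN_OUTCOMES = ("nrs_rest", "nrs_reach", "nrs_drag", "soreness", "pain_area")
ANOVA_OUTCOMES = ("ppt_kpa", "lefs", "mvic_nm", "hop_cm")
CORR_OUTCOMES = (
    "ppt_kpa", "nrs_rest", "nrs_reach", "nrs_drag", "pain_area",
    "soreness", "lefs", "mvic_nm", "hop_cm",
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts
        logger.info("stage %s: %s", stage, counts)

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }


# ---------------------------------------------------------------- simulate

def simulate_stage(config: PipelineConfig, out_dir) -> dict:
    """Generate a synthetic cohort and write its raw-data files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = make_scenarios(
        n_experimental=config.n_experimental, n_control=config.n_control,
        seed=np.random.SeedSequence(config.seed).spawn(1)[0], grid=config.grid,
    )
    cohort = generate_cohort(
        scenarios, grid=config.grid, n_stimuli=config.n_stimuli,
        seed=np.random.SeedSequence(config.seed).spawn(2)[1],
        with_emg=config.with_emg,
    )

    coord_rows = []
    for (pid, tp), events in sorted(cohort["events"].items()):
        for ev in events:
            coord_rows.append(
                {"participant": pid, "timepoint": tp, "trial": ev.trial,
                 "x_cm": ev.x, "y_cm": ev.y, "amplitude_mv": ev.amplitude}
            )
    coords = pd.DataFrame(coord_rows)
    write_csv(coords, out / "coords.csv")

    groups = {s.participant_id: s.group for s in scenarios}
    outcome_rows = []
    for pid, panel in sorted(cohort["outcomes"].items()):
        for tp, values in panel.items():
            for name, value in values.items():
                outcome_rows.append(
                    {"participant": pid, "group": groups[pid], "time": tp,
                     "outcome": name, "value": value}
                )
    write_csv(pd.DataFrame(outcome_rows), out / "outcomes.csv")

    truth = pd.DataFrame(
        [{"participant": pid, **info} for pid, info in sorted(cohort["truth"].items())]
    )
    write_csv(truth, out / "truth.csv")

    if config.with_emg:
        write_emg_dir(cohort["frames"], out / "emg")
    else:
        # no waveform synthesis requested: event amplitudes are the MEP table
        meps = coords.rename(columns={"amplitude_mv": "amplitude_mv"}).assign(
            pre_stim_rms_mv=0.0, rejected=False, reason=""
        )
        write_csv(meps, out / "meps.csv")

    return {"participants": len(scenarios), "stimuli": len(coords)}


# ------------------------------------------------------------ extract MEPs

def extract_stage(
    emg_dir, coords_csv, out_csv, window_ms=(10.0, 60.0)
) -> dict:
    """Extract peak-to-peak MEPs from EMG files and join scalp coordinates."""
    frames_by_session = read_emg_dir(emg_dir)
    coords = pd.read_csv(coords_csv)
    coord_idx = coords.set_index(["participant", "timepoint", "trial"])

    rows = []
    n_rejected = 0
    for (pid, tp), frames in sorted(frames_by_session.items()):
        measurements = [extract_mep(f, window_ms) for f in frames]
        measurements = flag_inconsistent_background(measurements)
        for meas in measurements:
            try:
                crow = coord_idx.loc[(pid, tp, meas.trial)]
            except KeyError:
                n_rejected += 1
                rows.append(
                    {"participant": pid, "timepoint": tp, "trial": meas.trial,
                     "x_cm": np.nan, "y_cm": np.nan, "amplitude_mv": meas.amplitude,
                     "pre_stim_rms_mv": meas.pre_stim_rms, "rejected": True,
                     "reason": "no matching coordinate"}
                )
                continue
            n_rejected += int(meas.rejected)
            rows.append(
                {"participant": pid, "timepoint": tp, "trial": meas.trial,
                 "x_cm": float(crow["x_cm"]), "y_cm": float(crow["y_cm"]),
                 "amplitude_mv": meas.amplitude,
                 "pre_stim_rms_mv": meas.pre_stim_rms,
                 "rejected": meas.rejected, "reason": meas.reason}
            )
    meps = pd.DataFrame(rows)
    write_csv(meps, out_csv)
    return {"frames": len(meps), "rejected": n_rejected}


# -------------------------------------------------------------------- map

def map_stage(meps_csv, out_dir, config: PipelineConfig) -> dict:
    """Build per-session motor maps and the baseline→Day-2 change table."""
    out = Path(out_dir)
    meps = pd.read_csv(meps_csv)
    usable = meps[~meps["rejected"].astype(bool)]

    map_rows = []
    per_session: dict[tuple[str, str], dict] = {}
    for (pid, tp), grp in usable.groupby(["participant", "timepoint"]):
        events = [
            StimulationEvent(x=r.x_cm, y=r.y_cm, amplitude=r.amplitude_mv, trial=int(r.trial))
            for r in grp.itertuples()
        ]
        mm = build_map(events, config.grid, threshold_fraction=config.threshold_fraction)
        summary = mm.summary()
        per_session[(str(pid), str(tp))] = summary
        map_rows.append({"participant": pid, "timepoint": tp, **summary})
    maps = pd.DataFrame(map_rows)
    write_csv(maps, out / "maps.csv")

    change_rows = []
    n_incomplete = 0
    for pid in sorted({p for p, _ in per_session}):
        base = per_session.get((pid, "baseline"))
        day2 = per_session.get((pid, "day2"))
        if base is None or day2 is None:
            n_incomplete += 1
            logger.warning("participant %s lacks a complete map pair; excluded", pid)
            continue
        ed = cog_displacement(
            (base["cog_x_cm"], base["cog_y_cm"]), (day2["cog_x_cm"], day2["cog_y_cm"])
        ).ed
        change_rows.append(
            {"participant": pid,
             "delta_area_pct": percent_change(base["area_cm2"], day2["area_cm2"]),
             "delta_volume_pct": percent_change(base["volume_mv"], day2["volume_mv"]),
             "ed_cm": ed}
        )
    changes = pd.DataFrame(change_rows)
    write_csv(changes, out / "map_changes.csv")
    return {"maps": len(maps), "participants": len(changes), "incomplete": n_incomplete}


# ----------------------------------------------------------------- classify

def classify_stage(
    map_changes_csv, groups: pd.Series | dict, out_dir, config: PipelineConfig
) -> dict:
    """Build control reference bands and label experimental participants."""
    out = Path(out_dir)
    changes = pd.read_csv(map_changes_csv)
    group_map = dict(groups)
    changes["group"] = changes["participant"].astype(str).map(group_map)

    controls = changes[changes["group"] == "control"]
    experimental = changes[changes["group"] == "experimental"]
    refs = {
        "volume": control_reference(
            controls["delta_volume_pct"], "volume", config.band_multiplier
        ),
        "area": control_reference(
            controls["delta_area_pct"], "area", config.band_multiplier
        ),
    }
    labels = classify_cohort(experimental, refs)
    write_csv(labels, out / "labels.csv")
    summary = summarize_labels(labels, refs)
    summary["control"] = {"n": int(len(controls)), "label": "nonresponder"}
    write_json(summary, out / "classification_summary.json")
    return {
        "experimental": len(experimental), "control": len(controls),
        "volume_band_pct": refs["volume"].band, "area_band_pct": refs["area"].band,
    }


# -------------------------------------------------------------------- stats

def _map_metric_long(maps: pd.DataFrame, groups: dict) -> pd.DataFrame:
    rows = []
    for r in maps.itertuples():
        for outcome, value in (("map_area", r.area_cm2), ("map_volume", r.volume_mv)):
            rows.append(
                {"participant": str(r.participant), "group": groups[str(r.participant)],
                 "time": r.timepoint, "outcome": outcome, "value": value}
            )
    return pd.DataFrame(rows)


def stats_stage(
    outcomes_csv, maps_csv, map_changes_csv, labels_csv, out_dir, config: PipelineConfig
) -> dict:
    """ANOVAs, Day-2 between-group t-tests, and correlation table."""
    out = Path(out_dir)
    outcomes = pd.read_csv(outcomes_csv)
    maps = pd.read_csv(maps_csv)
    changes = pd.read_csv(map_changes_csv)
    labels = pd.read_csv(labels_csv)
    outcomes["participant"] = outcomes["participant"].astype(str)
    groups = dict(outcomes[["participant", "group"]].drop_duplicates().itertuples(index=False))

    long = outcomes.rename(columns={"time": "time"})
    anova_rows = []
    metric_long = _map_metric_long(maps, groups)
    for outcome in list(ANOVA_OUTCOMES) + ["map_area", "map_volume"]:
        table = metric_long if outcome.startswith("map_") else long
        try:
            res = mixed_anova(table, outcome)
        except ValueError as exc:
            logger.warning("mixed ANOVA skipped for %s: %s", outcome, exc)
            continue
        for effect, e in res.effects.items():
            anova_rows.append(
                {"outcome": outcome, "analysis": "group_x_time", "effect": effect,
                 "F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
                 "epsilon_gg": res.epsilon_gg, "n": res.n_used}
            )

    # responder-stratified ANOVA (facilitators vs depressors on map volume)
    strat_ok = False
    try:
        strat = responder_stratified_anova(long, labels, "ppt_kpa", metric="volume")
        for effect, e in strat.effects.items():
            anova_rows.append(
                {"outcome": "ppt_kpa", "analysis": "response_x_time", "effect": effect,
                 "F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
                 "epsilon_gg": strat.epsilon_gg, "n": strat.n_used}
            )
        strat_ok = True
    except ValueError as exc:
        logger.warning("responder-stratified ANOVA skipped: %s", exc)
    write_csv(pd.DataFrame(anova_rows), out / "anova_results.csv")

    # Day-2 between-group pain comparisons (pooled t from raw samples)
    day2 = outcomes[outcomes["time"] == "day2"]
    t_rows = []
    for outcome in PAIN_OUTCOMES:
        sub = day2[day2["outcome"] == outcome]
        x = sub[sub["group"] == "experimental"]["value"].to_numpy(float)
        y = sub[sub["group"] == "control"]["value"].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            continue
        res = pooled_t_from_samples(x, y)
        t_rows.append(
            {"outcome": outcome,
             "mean_experimental": x.mean(), "sd_experimental": x.std(ddof=1),
             "mean_control": y.mean(), "sd_control": y.std(ddof=1),
             "t": res.t, "df": res.df, "mean_difference": res.mean_difference,
             "ci95_low": res.ci95[0], "ci95_high": res.ci95[1], "p": res.p}
        )
    # CoG displacement between groups uses the same pooled-t comparison
    ed = changes.assign(group=changes["participant"].astype(str).map(groups))
    ex_ed = ed[ed["group"] == "experimental"]["ed_cm"].to_numpy(float)
    co_ed = ed[ed["group"] == "control"]["ed_cm"].to_numpy(float)
    if len(ex_ed) >= 2 and len(co_ed) >= 2:
        res = pooled_t_from_samples(ex_ed, co_ed)
        t_rows.append(
            {"outcome": "cog_displacement_cm",
             "mean_experimental": ex_ed.mean(), "sd_experimental": ex_ed.std(ddof=1),
             "mean_control": co_ed.mean(), "sd_control": co_ed.std(ddof=1),
             "t": res.t, "df": res.df, "mean_difference": res.mean_difference,
             "ci95_low": res.ci95[0], "ci95_high": res.ci95[1], "p": res.p}
        )
    table2 = pd.DataFrame(t_rows)
    write_csv(table2, out / "table2_replica.csv")

    # correlations: corticomotor changes vs outcome changes (experimental group)
    wide = outcomes.pivot_table(
        index=["participant", "group"], columns=["outcome", "time"], values="value"
    )
    corr_rows = []
    ex = changes.assign(group=changes["participant"].astype(str).map(groups))
    ex = ex[ex["group"] == "experimental"].set_index("participant")
    for map_metric in ("delta_volume_pct", "delta_area_pct", "ed_cm"):
        for outcome in CORR_OUTCOMES:
            xs, ys = [], []
            for pid in ex.index:
                try:
                    base = wide.loc[(pid, "experimental"), (outcome, "baseline")]
                    post = wide.loc[(pid, "experimental"), (outcome, "day2")]
                except KeyError:
                    continue
                if np.isnan(base) or np.isnan(post):
                    continue
                val = post - base if config.correlate_on == "change" else post
                xs.append(ex.loc[pid, map_metric])
                ys.append(val)
            try:
                res = pearson_with_band(xs, ys)
            except ValueError as exc:
                logger.warning("correlation skipped (%s vs %s): %s", map_metric, outcome, exc)
                continue
            corr_rows.append(
                {"map_metric": map_metric, "outcome": outcome,
                 "r": res.r, "p": res.p, "band": res.band, "n": res.n}
            )
    correlations = pd.DataFrame(corr_rows)
    write_csv(correlations, out / "correlations.csv")

    return {
        "anova_rows": len(anova_rows), "t_tests": len(t_rows),
        "correlations": len(correlations), "stratified_anova": strat_ok,
    }


# ----------------------------------------------------------------- validate

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


_OUTCOME_RANGES = {
    "nrs_rest": (0, 10), "nrs_reach": (0, 10), "nrs_drag": (0, 10),
    "soreness": (0, 6), "lefs": (0, 80),
}


def validate_inputs(
    coords_csv=None, outcomes_csv=None, grid=None, jitter_tol_cm: float = 0.5
) -> ValidationReport:
    """Schema and range checks on pipeline input tables.

    Coordinates up to ``jitter_tol_cm`` outside the grid raise a warning
    (hand-held-coil jitter); farther out is a violation.
    """
    report = ValidationReport()
    if coords_csv is not None:
        coords = pd.read_csv(coords_csv)
        required = {"participant", "timepoint", "trial", "x_cm", "y_cm"}
        missing = required - set(coords.columns)
        if missing:
            report.violations.append(f"coords: missing columns {sorted(missing)}")
        else:
            g = grid or PipelineConfig().grid
            ox, oy = g.origin
            for r in coords.itertuples():
                dx = max(ox - r.x_cm, r.x_cm - (ox + g.width_cm), 0)
                dy = max(oy - r.y_cm, r.y_cm - (oy + g.height_cm), 0)
                excess = max(dx, dy)
                if excess > jitter_tol_cm:
                    report.violations.append(
                        f"coords row {r.Index}: ({r.x_cm:.2f}, {r.y_cm:.2f}) cm "
                        f"outside grid by {excess:.2f} cm"
                    )
                elif excess > 0:
                    report.warnings.append(
                        f"coords row {r.Index}: {excess:.2f} cm outside grid (within jitter tolerance)"
                    )
        report.counts["coords_rows"] = len(coords)
    if outcomes_csv is not None:
        outcomes = pd.read_csv(outcomes_csv)
        required = {"participant", "group", "time", "outcome", "value"}
        missing = required - set(outcomes.columns)
        if missing:
            report.violations.append(f"outcomes: missing columns {sorted(missing)}")
        else:
            for r in outcomes.itertuples():
                rng = _OUTCOME_RANGES.get(r.outcome)
                if rng and not (rng[0] <= r.value <= rng[1]):
                    report.violations.append(
                        f"outcomes row {r.Index}: {r.outcome}={r.value} outside {rng}"
                    )
        report.counts["outcomes_rows"] = len(outcomes)
    return report


# ---------------------------------------------------------------- full run

def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full chain into ``config.out_dir`` and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.content_hash(), seed=config.seed)

    manifest.record("simulate", **simulate_stage(config, out))

    report = validate_inputs(out / "coords.csv", out / "outcomes.csv", config.grid)
    if not report.ok:
        raise RuntimeError(f"input validation failed: {report.violations[:5]}")
    manifest.record("validate", warnings=len(report.warnings), **report.counts)

    if config.with_emg:
        manifest.record(
            "extract_meps",
            **extract_stage(out / "emg", out / "coords.csv", out / "meps.csv",
                            config.mep_window_ms),
        )
    manifest.record("map", **map_stage(out / "meps.csv", out, config))

    outcomes = pd.read_csv(out / "outcomes.csv")
    outcomes["participant"] = outcomes["participant"].astype(str)
    groups = dict(outcomes[["participant", "group"]].drop_duplicates().itertuples(index=False))
    manifest.record(
        "classify", **classify_stage(out / "map_changes.csv", groups, out, config)
    )
    manifest.record(
        "stats",
        **stats_stage(out / "outcomes.csv", out / "maps.csv", out / "map_changes.csv",
                      out / "labels.csv", out, config),
    )

    config.to_yaml(out / "config.yaml")
    write_json(manifest.as_dict(), out / "manifest.json")
    _write_report(out)
    return manifest


def _write_report(out: Path) -> None:
    """Render a short markdown report of the run's headline tables."""
    import json as _json

    lines = ["# Pipeline report", ""]
    summary = _json.loads((out / "classification_summary.json").read_text())
    lines.append("## Responder classification")
    for metric in ("volume", "area"):
        if metric not in summary:
            continue
        s = summary[metric]
        parts = [
            f"{s['counts'][lab]} ({s['percent'][lab]}%) {lab}s"
            for lab in ("facilitator", "depressor", "nonresponder")
        ]
        band = s.get("reference", {}).get("band_pct")
        lines.append(
            f"- map {metric}: " + ", ".join(parts)
            + (f" — control band ±{band:.1f}%" if band is not None else "")
        )
    lines.append("")
    for name, title in [
        ("table2_replica.csv", "Day-2 between-group comparisons"),
        ("anova_results.csv", "Mixed ANOVAs"),
        ("correlations.csv", "Correlations (corticomotor vs outcome changes)"),
    ]:
        path = out / name
        if path.exists():
            df = pd.read_csv(path)
            lines += [f"## {title}", "", "```", df.to_string(index=False), "```", ""]
    (out / "report.md").write_text("\n".join(lines))
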