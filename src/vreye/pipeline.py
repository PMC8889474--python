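"""End-to-end orchestration: simulate -> extract metrics -> analyze -> report.

Runs the full analysis as a sequence of file-based stages, each re-runnable
from its predecessor's outputs alone:

1. ``simulate``  — write per-participant session logs (plus the simulator's
   ground-truth record and the use-episodes covariate table).
2. ``blinks``    — per participant x scene blink counts and EBR.
3. ``fixations`` — per participant x scene x category fixation totals.
4. ``pupils``    — per participant x scene x category mean pupil diameter.
5. ``surveys``   — per participant x scene VAS ratings.
6. ``analyze``   — assemble the cohort metrics table from the stage TSVs and
   run the paired-contrast / correlation battery.

All tables are TSV with a single header line.  Outputs are written to a
``.partial`` file and renamed on stage success, so an aborted run leaves its
partial output identifiable.  A :class:`RunManifest` (JSON) records the
config snapshot, seed, output paths, and per-stage row counts and warnings;
the config and seed fully determine every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blinks import EyeMode, detect_blinks, summarize_blinks
from .cohort import cohort_table
from .fixations import accumulate_fixations, fixation_indices
from .pupils import pupil_by_category
from .scenes import ACTIVE, ACTIVE_SCENES, CATEGORIES, NEUTRAL, scene_type
from .session import ParticipantLog, read_session_log, write_session_log
from .simulate import SimConfig, scene_catalogs, simulate_participant
from .stats import run_contrast_table


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, outputs, and per-stage accounting."""

    seed: int
    config: dict
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _atomic_write_tsv(df: pd.DataFrame, path: Path) -> None:
    partial = path.with_suffix(path.suffix + ".partial")
    df.to_csv(partial, sep="\t", index=False)
    os.replace(partial, path)


def read_logs(log_dir: str | Path) -> list[ParticipantLog]:
    """Read every participant log directory under ``log_dir`` (sorted)."""
    root = Path(log_dir)
    logs = []
    for sub in sorted(p for p in root.iterdir() if (p / "manifest.json").exists()):
        logs.append(read_session_log(sub))
    if not logs:
        raise FileNotFoundError(f"no participant logs under {root}")
    return logs


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: SimConfig, out_dir: Path) -> tuple[Path, int]:
    log_dir = out_dir / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)
    covariates = []
    truths = []
    for i in range(config.n_participants):
        log, truth = simulate_participant(config, i)
        write_session_log(log, log_dir / log.participant_id)
        covariates.append({"participant": log.participant_id,
                           "use_episodes": truth.use_episodes})
        truths.append(truth)
    _atomic_write_tsv(pd.DataFrame(covariates), out_dir / "covariates.tsv")
    with open(out_dir / "ground_truth.json.partial", "w") as fh:
        json.dump([dataclasses.asdict(t) for t in truths], fh, sort_keys=True)
    os.replace(out_dir / "ground_truth.json.partial", out_dir / "ground_truth.json")
    return log_dir, len(covariates)


def blinks_table(logs: list[ParticipantLog],
                 mode: EyeMode = EyeMode.BOTH_EYES) -> pd.DataFrame:
    rows = []
    for log in logs:
        for scene_name, session in log.sessions.items():
            events = detect_blinks(session.samples, mode)
            s = summarize_blinks(events, session, mode)
            rows.append({
                "participant": log.participant_id, "scene": scene_name,
                "blink_count": s.blink_count, "ebr_per_min": s.ebr_per_min,
                "discarded_short": s.discarded_short,
                "discarded_long": s.discarded_long,
            })
    return pd.DataFrame(rows)


def fixations_table(logs: list[ParticipantLog], catalogs) -> pd.DataFrame:
    rows = []
    for log in logs:
        for scene_name, session in log.sessions.items():
            ledger = accumulate_fixations(session.events, catalogs[scene_name],
                                          session.duration_ms)
            indices = fixation_indices(ledger, session.duration_ms)
            for cat in CATEGORIES:
                rows.append({
                    "participant": log.participant_id, "scene": scene_name,
                    "category": cat,
                    "total_ms": indices.total_ms[cat],
                    "mean_ms": indices.mean_ms.get(cat, np.nan),
                    "n_objects": indices.n_objects[cat],
                })
    return pd.DataFrame(rows)


def pupils_table(logs: list[ParticipantLog], catalogs,
                 mode: EyeMode = EyeMode.BOTH_EYES,
                 margin_ms: int = 0) -> pd.DataFrame:
    rows = []
    for log in logs:
        for scene_name, session in log.sessions.items():
            events = detect_blinks(session.samples, mode)
            summary = pupil_by_category(session.samples, events,
                                        catalogs[scene_name],
                                        margin_ms=margin_ms, mode=mode,
                                        scene_name=scene_name)
            for cat in CATEGORIES:
                if cat in summary.mean_mm:
                    rows.append({
                        "participant": log.participant_id, "scene": scene_name,
                        "category": cat, "mean_mm": summary.mean_mm[cat],
                        "n_samples": summary.n_samples[cat],
                        "n_excluded": summary.n_excluded,
                    })
    return pd.DataFrame(rows)


def surveys_table(logs: list[ParticipantLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for scene_name, session in log.sessions.items():
            ratings = {ev.payload.get("scale"): ev.payload.get("value")
                       for ev in session.events if ev.kind == "survey"}
            rows.append({
                "participant": log.participant_id, "scene": scene_name,
                "scene_type": scene_type(scene_name),
                "craving": ratings.get("craving", np.nan),
                "relevance": ratings.get("relevance", np.nan),
            })
    return pd.DataFrame(rows)


def assemble_cohort(blinks: pd.DataFrame, fixations: pd.DataFrame,
                    pupils: pd.DataFrame, surveys: pd.DataFrame,
                    covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rebuild the per-participant cohort metrics table from the stage TSVs."""
    participants = sorted(surveys["participant"].unique())
    out = pd.DataFrame({"participant": participants}).set_index("participant")

    for stype, col in ((ACTIVE, "craving_active"), (NEUTRAL, "craving_neutral")):
        sub = surveys[surveys["scene_type"] == stype]
        out[col] = sub.groupby("participant")["craving"].mean()

    for scene in ACTIVE_SCENES:
        fsub = fixations[fixations["scene"] == scene]
        for cat, col in ((ACTIVE, f"fix_active_{scene}"),
                         (NEUTRAL, f"fix_neutral_{scene}")):
            csub = fsub[fsub["category"] == cat].set_index("participant")
            out[col] = csub["total_ms"]
        psub = pupils[pupils["scene"] == scene]
        for cat, col in ((ACTIVE, f"pupil_active_{scene}"),
                         (NEUTRAL, f"pupil_neutral_{scene}")):
            csub = psub[psub["category"] == cat].set_index("participant")
            out[col] = csub["mean_mm"]

    for scene in blinks["scene"].unique():
        bsub = blinks[blinks["scene"] == scene].set_index("participant")
        out[f"blink_count_{scene}"] = bsub["blink_count"]
        out[f"ebr_per_min_{scene}"] = bsub["ebr_per_min"]

    bias_cols = [f"fix_active_{s}" for s in ACTIVE_SCENES if f"fix_active_{s}" in out]
    if bias_cols:
        diffs = pd.DataFrame({
            s: out[f"fix_active_{s}"] - out[f"fix_neutral_{s}"]
            for s in ACTIVE_SCENES if f"fix_active_{s}" in out
        })
        out["bias_ms"] = diffs.mean(axis=1)

    if covariates is not None and len(covariates):
        out = out.join(covariates.set_index("participant"))
    return out.reset_index()


def run_pipeline(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    mode: EyeMode = EyeMode.BOTH_EYES,
    margin_ms: int = 0,
) -> RunManifest:
    """Execute the full pipeline into ``out_dir`` and return the manifest.

    ``config`` is a :class:`SimConfig` or a path to a YAML/JSON config file;
    ``seed`` overrides the config's seed.  Idempotent given (config, seed).
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_file(config)
    config = dataclasses.replace(config)
    if seed is not None:
        config.seed = int(seed)
    config.validate()
    if config.n_participants <= 0:
        raise ValueError("n_participants must be positive for a pipeline run")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=config.to_dict())
    catalogs = scene_catalogs(config)

    def run_stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    log_dir, n = run_stage("simulate", lambda: stage_simulate(config, out))
    manifest.stages.append({"stage": "simulate", "participants": n})
    manifest.outputs["logs"] = str(log_dir)
    manifest.outputs["covariates"] = str(out / "covariates.tsv")

    logs = run_stage("read", lambda: read_logs(log_dir))

    for name, fn in (
        ("blinks", lambda: blinks_table(logs, mode)),
        ("fixations", lambda: fixations_table(logs, catalogs)),
        ("pupils", lambda: pupils_table(logs, catalogs, mode, margin_ms)),
        ("surveys", lambda: surveys_table(logs)),
    ):
        table = run_stage(name, fn)
        path = out / f"{name}.tsv"
        run_stage(name, lambda t=table, p=path: _atomic_write_tsv(t, p))
        manifest.stages.append({"stage": name, "rows": len(table)})
        manifest.outputs[name] = str(path)

    def analyze():
        tables = {n: pd.read_csv(out / f"{n}.tsv", sep="\t")
                  for n in ("blinks", "fixations", "pupils", "surveys")}
        covariates = pd.read_csv(out / "covariates.tsv", sep="\t")
        cohort = assemble_cohort(tables["blinks"], tables["fixations"],
                                 tables["pupils"], tables["surveys"], covariates)
        _atomic_write_tsv(cohort, out / "cohort.tsv")
        contrasts = run_contrast_table(cohort)
        _atomic_write_tsv(contrasts, out / "analysis.tsv")
        return cohort, contrasts

    cohort, contrasts = run_stage("analyze", analyze)
    manifest.stages.append({"stage": "analyze", "rows": len(contrasts)})
    manifest.outputs["cohort"] = str(out / "cohort.tsv")
    manifest.outputs["analysis"] = str(out / "analysis.tsv")

    for key, path in manifest.outputs.items():
        p = Path(path)
        if not p.exists() or (p.is_file() and p.stat().st_size == 0):
            raise PipelineError("manifest", RuntimeError(f"output {key} missing/empty"))
    with open(out / "manifest.json", "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest


def report(out_dir: str | Path) -> str:
    """Markdown summary of a completed run: condition means and contrasts."""
    out = Path(out_dir)
    cohort = pd.read_csv(out / "cohort.tsv", sep="\t")
    analysis = pd.read_csv(out / "analysis.tsv", sep="\t")

    lines = ["# VR cue-exposure session report", ""]
    lines += ["## Subjective craving (VAS 0-100)", "",
              "| condition | mean | sd |", "|---|---|---|"]
    for col, label in (("craving_active", "Active scenes"),
                       ("craving_neutral", "Neutral scenes")):
        if col in cohort:
            lines.append(f"| {label} | {cohort[col].mean():.2f} "
                         f"| {cohort[col].std(ddof=1):.2f} |")

    lines += ["", "## Cue fixation time by Active scene (ms)", "",
              "| scene | Active cues | Neutral cues |", "|---|---|---|"]
    for scene in ACTIVE_SCENES:
        a, nn = f"fix_active_{scene}", f"fix_neutral_{scene}"
        if a in cohort:
            lines.append(f"| {scene} | {cohort[a].mean():.0f} | {cohort[nn].mean():.0f} |")

    lines += ["", "## Mean pupil diameter by Active scene (mm)", "",
              "| scene | Active cues | Neutral cues |", "|---|---|---|"]
    for scene in ACTIVE_SCENES:
        a, nn = f"pupil_active_{scene}", f"pupil_neutral_{scene}"
        if a in cohort:
            lines.append(f"| {scene} | {cohort[a].mean():.3f} | {cohort[nn].mean():.3f} |")

    ebr_cols = [c for c in cohort.columns if c.startswith("ebr_per_min_")]
    if ebr_cols:
        lines += ["", "## Spontaneous eye-blink rate (blinks/min)", "",
                  "| scene | mean | sd |", "|---|---|---|"]
        for c in sorted(ebr_cols):
            scene = c.removeprefix("ebr_per_min_")
            lines.append(f"| {scene} | {cohort[c].mean():.2f} "
                         f"| {cohort[c].std(ddof=1):.2f} |")

    lines += ["", "## Contrast battery", "",
              "| contrast | n | t | df | p | d | 95% CI | r |",
              "|---|---|---|---|---|---|---|---|"]
    for _, row in analysis.iterrows():
        if row.get("kind") == "paired" and pd.notna(row.get("t")):
            ci = f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
            lines.append(f"| {row['contrast']} | {int(row['n'])} | {row['t']:.2f} "
                         f"| {int(row['df'])} | {row['p']:.3g} | {row['d']:.2f} "
                         f"| {ci} | |")
        elif row.get("kind") == "pearson" and pd.notna(row.get("r")):
            lines.append(f"| {row['contrast']} | {int(row['n'])} | | "
                         f"| {row['p']:.3g} | | | {row['r']:.2f} |")
    return "\n".join(lines) + "\n"
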