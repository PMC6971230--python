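"""File I/O: tally CSVs, plan/posterior serialisation, configs, reports.

All files are UTF-8 CSV with a header row (decimal point, no thousands
separators); configs are flat YAML key/value files. Every run can write a
JSON manifest recording the config snapshot, seed and SHA-256 digests of the
files it read and wrote, so reruns are traceable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .bandit_engine import AllocationPlan, ArmPrior, ArmPosterior
from .errors import ValidationError
from .inference import TestResult
from .staged_design import PosteriorSnapshot, StageConfig
from .synthetic_cohort import ScenarioSpec
from .trial_core import ConsultationTally, Stage

TALLY_COLUMNS = [
    "clinic_id",
    "gp_id",
    "week_index",
    "stage",
    "strategy_id",
    "discussed_count",
    "relevant_count",
    "inappropriate_count",
]


def read_tally_file(path: str | Path) -> list[ConsultationTally]:
    """Read and validate a tally CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TALLY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    tallies: list[ConsultationTally] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            tallies.append(
                ConsultationTally(
                    clinic_id=row.clinic_id,
                    gp_id=row.gp_id,
                    week_index=int(row.week_index),
                    stage=Stage(row.stage),
                    strategy_id=row.strategy_id,
                    discussed_count=int(row.discussed_count),
                    relevant_count=int(row.relevant_count),
                    inappropriate_count=int(row.inappropriate_count),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return tallies


def write_tally_file(path: str | Path, tallies: Iterable[ConsultationTally]) -> None:
    df = pd.DataFrame(
        [
            {
                "clinic_id": t.clinic_id,
                "gp_id": t.gp_id,
                "week_index": t.week_index,
                "stage": t.stage.value,
                "strategy_id": t.strategy_id,
                "discussed_count": t.discussed_count,
                "relevant_count": t.relevant_count,
                "inappropriate_count": t.inappropriate_count,
            }
            for t in tallies
        ],
        columns=TALLY_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_allocation_plans(path: str | Path, plans: Sequence[AllocationPlan]) -> None:
    """Serialise plans as week_index,clinic_id,strategy_id,sampled_mean rows."""
    rows = []
    for plan in plans:
        for clinic_id, sid in sorted(plan.assignments.items()):
            draw = plan.sampled_means.get(clinic_id, {}).get(sid, float("nan"))
            rows.append(
                {
                    "week_index": plan.week_index,
                    "clinic_id": clinic_id,
                    "strategy_id": sid,
                    "sampled_mean": draw,
                }
            )
    pd.DataFrame(rows, columns=["week_index", "clinic_id", "strategy_id", "sampled_mean"]).to_csv(
        path, index=False
    )


def read_allocation_plans(path: str | Path) -> dict[tuple[str, int], str]:
    """Read a plan CSV back as an allocation map (clinic, week) -> strategy."""
    df = pd.read_csv(path, dtype={"clinic_id": str, "strategy_id": str})
    return {
        (str(r.clinic_id), int(r.week_index)): str(r.strategy_id)
        for r in df.itertuples(index=False)
    }


def write_posterior_snapshots(
    path: str | Path, snapshots: Sequence[PosteriorSnapshot]
) -> None:
    pd.DataFrame(
        [
            {
                "week_index": s.week_index,
                "strategy_id": s.strategy_id,
                "post_mean": s.post_mean,
                "post_sd": s.post_sd,
                "n_obs": s.n_obs,
                "cumulative_pulls": s.cumulative_pulls,
            }
            for s in snapshots
        ]
    ).to_csv(path, index=False)


def write_final_statistics(path: str | Path, table: Sequence[TestResult]) -> None:
    """Final statistics CSV: strategy_id,mean_difference,standard_error,p_value,trial_count."""
    pd.DataFrame(
        [
            {
                "strategy_id": r.strategy_id,
                "mean_difference": r.mean_difference,
                "standard_error": r.standard_error,
                "p_value": r.p_value,
                "trial_count": r.trial_count,
            }
            for r in table
        ]
    ).to_csv(path, index=False)


def report_trajectories(
    snapshots: Sequence[PosteriorSnapshot], plot_path: str | Path | None = None
) -> pd.DataFrame:
    """Tabular twin of the trajectory figures: per week per arm belief and pulls.

    When ``plot_path`` is given and matplotlib is available, also writes a
    two-panel figure (posterior means with +/-1 sd bands for the top two arms;
    cumulative pulls).
    """
    if not snapshots:
        raise ValidationError("no posterior snapshots to report")
    df = pd.DataFrame(
        [
            {
                "week_index": s.week_index,
                "strategy_id": s.strategy_id,
                "post_mean": s.post_mean,
                "post_sd": s.post_sd,
                "cumulative_pulls": s.cumulative_pulls,
            }
            for s in snapshots
        ]
    )
    if plot_path is not None:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # plots are optional artefacts
            return df
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
        final = df[df.week_index == df.week_index.max()]
        top2 = set(final.sort_values("post_mean", ascending=False).strategy_id.head(2))
        for sid, grp in df.groupby("strategy_id"):
            ax1.plot(grp.week_index, grp.post_mean, label=str(sid))
            if sid in top2:
                ax1.fill_between(
                    grp.week_index,
                    grp.post_mean - grp.post_sd,
                    grp.post_mean + grp.post_sd,
                    alpha=0.15,
                )
            ax2.plot(grp.week_index, grp.cumulative_pulls, label=str(sid))
        ax1.set_xlabel("week")
        ax1.set_ylabel("posterior mean reward")
        ax2.set_xlabel("week")
        ax2.set_ylabel("cumulative clinic-weeks")
        ax1.legend(title="strategy", fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df


# --------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config into StageConfig / ArmPrior / ScenarioSpec / seed.

    Unknown keys raise a validation error so typos cannot silently fall back
    to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a flat key/value mapping")
    stage_fields = {f.name for f in dataclasses.fields(StageConfig)}
    prior_fields = {f.name for f in dataclasses.fields(ArmPrior)}
    scen_fields = {f.name for f in dataclasses.fields(ScenarioSpec)}
    stage_kw, prior_kw, scen_kw = {}, {}, {}
    seed = None
    for key, value in raw.items():
        if key == "seed":
            seed = int(value)
            scen_kw["seed"] = int(value)
        elif key in stage_fields:
            stage_kw[key] = value
            if key == "n_strategies":
                scen_kw[key] = value
        elif key in prior_fields:
            prior_kw[key] = value
        elif key in scen_fields:
            if key == "true_effects":
                value = {str(k): float(v) for k, v in value.items()}
            scen_kw[key] = value
        else:
            raise ValidationError(f"{path}: unknown config key {key!r}")
    return {
        "stage": StageConfig(**stage_kw),
        "prior": ArmPrior(**prior_kw),
        "scenario": ScenarioSpec(**scen_kw),
        "seed": seed,
    }


# --------------------------------------------------------------------------
# run manifests


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one CLI run."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> None:
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
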