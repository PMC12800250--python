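"""Configuration, table validation and the end-to-end replicate bundle.

Datasets travel as UTF-8 comma-separated CSV with a header row and '.'
decimals; reports are JSON; run configuration is YAML. ``replicate`` ties
the stages together: equilibrium enumeration, synthetic-data generation,
the pre-registered analysis suite, and figure-shaped summary tables
(per-group proportions; per-round means with binomial confidence intervals;
per-wave identity means with standard errors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .analysis import group_summaries, run_preregistered_suite
from .equilibrium import enumerate_pure_nash
from .game import CONDITIONS, ConditionSpec, N_PLAYERS
from .simulate import (
    ACTIONS_CSV_COLUMNS,
    IDENTITY_CSV_COLUMNS,
    SimConfig,
    TidyDatasets,
    generate_dataset,
)


class ValidationError(ValueError):
    """Raised when a table fails schema or consistency checks."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs: simulation shape and seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    conditions: tuple[str, ...] = ("global_only", "balanced", "global_boost")

    def to_dict(self) -> dict:
        return {"sim": self.sim.to_dict(), "conditions": list(self.conditions)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            sim=SimConfig.from_dict(d.get("sim", {})),
            conditions=tuple(d.get("conditions", ("global_only", "balanced", "global_boost"))),
        )

    def save(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# Validation


def _check(violations: list[str], ok: bool, message: str) -> None:
    if not ok:
        violations.append(message)


def validate_tables(actions: pd.DataFrame, identity: pd.DataFrame) -> list[str]:
    """Schema, key-uniqueness, referential-integrity and conservation checks.

    Returns a list of human-readable violation messages (empty = valid).
    """
    violations: list[str] = []

    missing = set(ACTIONS_CSV_COLUMNS) - set(actions.columns)
    _check(violations, not missing, f"actions: missing columns {sorted(missing)}")
    missing_i = set(IDENTITY_CSV_COLUMNS) - set(identity.columns)
    _check(violations, not missing_i, f"identity: missing columns {sorted(missing_i)}")
    if violations:
        return violations

    dup = actions.duplicated(subset=["group_id", "player_id", "round"])
    for idx in actions.index[dup][:20]:
        violations.append(f"actions row {idx}: duplicate (group, player, round) key")
    dup_i = identity.duplicated(subset=["player_id", "wave"])
    for idx in identity.index[dup_i][:20]:
        violations.append(f"identity row {idx}: duplicate (player, wave) key")

    pot_sum = (
        actions[["global_pot", "local_pot_1", "local_pot_2", "kept"]].sum(axis=1)
    )
    for idx in actions.index[pot_sum != N_PLAYERS][:20]:
        violations.append(
            f"actions row {idx}: pots sum to {pot_sum[idx]}, expected {N_PLAYERS}"
        )

    for col in ("score_global", "score_own_local", "score_other_local"):
        bad = (identity[col] < 0) | (identity[col] > 100)
        for idx in identity.index[bad][:20]:
            violations.append(
                f"identity row {idx}: {col}={identity.loc[idx, col]} outside [0, 100]"
            )

    action_players = set(actions["player_id"])
    identity_players = set(identity["player_id"])
    for pid in sorted(identity_players - action_players)[:20]:
        violations.append(f"identity: player {pid!r} has no action rows")
    for pid in sorted(action_players - identity_players)[:20]:
        violations.append(f"actions: player {pid!r} has no identity rows")

    unknown = set(actions["condition"].unique()) - set(CONDITIONS)
    _check(violations, not unknown, f"actions: unknown conditions {sorted(unknown)}")

    # Threshold flags must be consistent with the stored pots.
    if not unknown:
        for cname, g in actions.groupby("condition"):
            cond = CONDITIONS[cname]
            bad_global = g["global_met"].astype(bool) != (
                g["global_pot"] >= cond.global_threshold
            )
            for idx in g.index[bad_global][:10]:
                violations.append(f"actions row {idx}: global_met inconsistent with pot")
            if cond.has_local:
                for flag, pot in (("local1_met", "local_pot_1"), ("local2_met", "local_pot_2")):
                    bad = g[flag].astype(bool) != (g[pot] >= cond.local_threshold)
                    for idx in g.index[bad][:10]:
                        violations.append(f"actions row {idx}: {flag} inconsistent with pot")
    return violations


def validate_files(actions_path: Path | str, identity_path: Path | str) -> list[str]:
    """Load the two CSVs and validate them."""
    try:
        actions = pd.read_csv(actions_path)
    except OSError as exc:
        return [f"cannot read actions table {actions_path}: {exc}"]
    try:
        identity = pd.read_csv(identity_path)
    except OSError as exc:
        return [f"cannot read identity table {identity_path}: {exc}"]
    return validate_tables(actions, identity)


# ---------------------------------------------------------------------------
# Figure-shaped tables


def fig2_table(actions: pd.DataFrame) -> pd.DataFrame:
    """Per-group action proportions and success rates (boxplot-shaped data)."""
    return group_summaries(actions)


def _binomial_ci(successes: int, n: int) -> tuple[float, float]:
    lo, hi = stats.binomtest(successes, n).proportion_ci(confidence_level=0.95)
    return float(lo), float(hi)


def fig3_table(actions: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-round action shares and threshold success rates
    with 95% binomial confidence intervals on the action shares."""
    rows = []
    for (cond, rnd), g in actions.groupby(["condition", "round"]):
        n = len(g)
        measures = {
            f"action:{a}": int((g["action"] == a).sum())
            for a in ("invest_global", "invest_own_local", "invest_other_local", "keep")
        }
        per_group = g.groupby("group_id")[["global_met", "local1_met", "local2_met"]].first()
        n_groups = len(per_group)
        for metric, k, denom in (
            [(m, k, n) for m, k in measures.items()]
            + [("threshold:global", int(per_group["global_met"].sum()), n_groups)]
            + [
                (
                    "threshold:local",
                    int(per_group[["local1_met", "local2_met"]].to_numpy().sum()),
                    2 * n_groups,
                )
            ]
        ):
            lo, hi = _binomial_ci(k, denom)
            rows.append(
                {
                    "condition": cond,
                    "round": rnd,
                    "metric": metric,
                    "share": k / denom,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n": denom,
                }
            )
    return pd.DataFrame(rows)


def fig4_table(identity: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-wave identity means with standard errors."""
    rows = []
    for (cond, wave), g in identity.groupby(["condition", "wave"]):
        for col, label in (
            ("score_global", "global"),
            ("score_own_local", "own_local"),
            ("score_other_local", "other_local"),
        ):
            vals = g[col].to_numpy(float)
            rows.append(
                {
                    "condition": cond,
                    "wave": wave,
                    "target": label,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end bundle


def write_datasets(datasets: TidyDatasets, out_dir: Path | str) -> dict[str, Path]:
    """Write actions.csv, identity.csv and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "actions": out / "actions.csv",
        "identity": out / "identity.csv",
        "manifest": out / "manifest.json",
    }
    try:
        datasets.actions.to_csv(paths["actions"], index=False)
        datasets.identity.to_csv(paths["identity"], index=False)
        paths["manifest"].write_text(json.dumps(datasets.manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing dataset to {out}: {exc}") from exc
    return paths


def replicate(config: RunConfig, out_dir: Path | str) -> dict[str, Path]:
    """Run the whole pipeline and write the artifact bundle.

    Produces equilibria.json, actions.csv, identity.csv, manifest.json,
    report.json and the three figure-shaped tables. Deterministic given the
    config's seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    equilibria = {
        name: enumerate_pure_nash(CONDITIONS[name]).to_dict()
        for name in config.conditions
    }
    (out / "equilibria.json").write_text(json.dumps(equilibria, indent=2))

    datasets = generate_dataset(config.sim)
    paths = write_datasets(datasets, out)

    violations = validate_tables(datasets.actions, datasets.identity)
    if violations:
        raise ValidationError(
            "generated datasets failed validation: " + "; ".join(violations[:5])
        )

    report = run_preregistered_suite(datasets.actions, datasets.identity)
    report["seed"] = config.sim.seed
    (out / "report.json").write_text(json.dumps(report, indent=2))

    fig2_table(datasets.actions).to_csv(out / "fig2_table.csv", index=False)
    fig3_table(datasets.actions).to_csv(out / "fig3_table.csv", index=False)
    fig4_table(datasets.identity).to_csv(out / "fig4_table.csv", index=False)

    paths.update(
        {
            "equilibria": out / "equilibria.json",
            "report": out / "report.json",
            "fig2": out / "fig2_table.csv",
            "fig3": out / "fig3_table.csv",
            "fig4": out / "fig4_table.csv",
        }
    )
    return paths
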