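"""One-shot orchestration: simulate → profile → fit → associate → report.

``run_all`` executes the full process-evaluation sequence — engagement
profiling, the engagement-pattern LCA, the demographic/BMI subgroup
LCA, and the chi-square association stage — over either a synthetic
cohort or user-supplied roster/events files, writing every stage
artifact plus a manifest into one output directory. ``render_report``
rebuilds the human-readable report purely from those saved artifacts,
so every number in it traces to a machine-readable file.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from engage import __version__, defaults
from engage.association import crosstab_classes, pearson_chisq, ContingencyTable
from engage.engagement import build_profiles
from engage.lca import (
    FitConfig,
    LcaModel,
    engagement_spec,
    posterior_classify,
    select_model,
    subgroup_spec,
    align_classes,
)
from engage.synthetic import GeneratorConfig, gen_dataset


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    engagement_k_range: tuple[int, int] = (1, 8)
    subgroup_k_range: tuple[int, int] = (1, 6)
    roster_path: str | None = None
    events_path: str | None = None
    keep_truth: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        if "fit" in raw:
            kwargs["fit"] = FitConfig(**raw["fit"])
        for key in ("engagement_k_range", "subgroup_k_range"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("roster_path", "events_path", "keep_truth"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            "generator": {
                "n": self.generator.n,
                "seed": self.generator.seed,
                "subgroup_gamma": np.asarray(self.generator.subgroup_gamma).tolist(),
                "engagement_gamma": np.asarray(self.generator.engagement_gamma).tolist(),
                "exposure_days": list(self.generator.exposure_days),
                "reference_medians": dict(self.generator.reference_medians),
                "window_days": self.generator.window_days,
            },
            "fit": asdict(self.fit),
            "engagement_k_range": list(self.engagement_k_range),
            "subgroup_k_range": list(self.subgroup_k_range),
            "roster_path": self.roster_path,
            "events_path": self.events_path,
            "keep_truth": self.keep_truth,
        }
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(payload, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(config: PipelineConfig, out_dir) -> Path:
    """Run every stage and populate ``out_dir``; returns the directory.

    Stages run in a staging directory that replaces ``out_dir`` only on
    success, so a failed run leaves no partial outputs. Any stage
    failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(out_dir)
    staging = out_dir.parent / (out_dir.name + ".staging")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    timings: dict[str, float] = {}
    try:
        _run_stages(config, staging, timings)
    except StageError:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        shutil.rmtree(staging, ignore_errors=True)
        raise StageError("unknown", str(exc)) from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "digests": {
            p.name: _sha256(p) for p in sorted(staging.iterdir()) if p.is_file()
        },
    }
    _json_dump(manifest, staging / "manifest.json")

    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
    return out_dir


def _timed(timings: dict, stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()

        def __exit__(self, exc_type, exc, tb):
            timings[stage] = time.perf_counter() - self.t0
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(stage, str(exc)) from exc

    return _T()


def _run_stages(config: PipelineConfig, out: Path, timings: dict) -> None:
    # --- stage: data ------------------------------------------------------
    truth = None
    with _timed(timings, "data"):
        if config.roster_path is not None or config.events_path is not None:
            if config.roster_path is None or config.events_path is None:
                raise StageError("data", "roster_path and events_path go together")
            if not Path(config.roster_path).exists():
                raise StageError("data", f"missing roster file {config.roster_path}")
            if not Path(config.events_path).exists():
                raise StageError("data", f"missing events file {config.events_path}")
            roster = pd.read_csv(config.roster_path)
            events = pd.read_csv(config.events_path)
            medians_override = None
        else:
            bundle = gen_dataset(config.generator)
            roster, events = bundle.roster, bundle.events
            if config.keep_truth:
                truth = bundle.truth
                truth.to_csv(out / "truth.csv", index=False)
            medians_override = bundle.reference_medians
        roster.to_csv(out / "roster.csv", index=False)
        events.to_csv(out / "events.csv", index=False)

    # --- stage: profile ---------------------------------------------------
    with _timed(timings, "profile"):
        profiles, medians_used = build_profiles(
            roster, events,
            window_days=config.generator.window_days,
            medians=medians_override,
        )
        profiles.to_csv(out / "profiles.csv", index=False)
        _json_dump(medians_used, out / "medians.json")

    # --- stage: engagement LCA -------------------------------------------
    with _timed(timings, "lca_engagement"):
        e_spec = engagement_spec()
        lo, hi = config.engagement_k_range
        sweep = select_model(profiles, e_spec, range(lo, hi + 1), config.fit)
        sweep.table.to_csv(out / "sweep_engagement.csv", index=False)
        model_e = sweep.models[sweep.selected_k]
        model_e.to_json(out / "model_engagement.json")
        assign_e = posterior_classify(model_e, profiles, e_spec)
        classes = pd.DataFrame(
            {
                "participant_id": profiles["participant_id"],
                "engagement_class": [
                    f"class_{c + 1}" for c in assign_e.modal_class
                ],
            }
        )
        classes.to_csv(out / "classes.csv", index=False)

    # --- stage: subgroup LCA ---------------------------------------------
    with _timed(timings, "lca_subgroups"):
        s_spec = subgroup_spec()
        lo, hi = config.subgroup_k_range
        s_sweep = select_model(roster, s_spec, range(lo, hi + 1), config.fit)
        s_sweep.table.to_csv(out / "sweep_subgroups.csv", index=False)
        model_s = s_sweep.models[s_sweep.selected_k]
        model_s.to_json(out / "model_subgroups.json")
        assign_s = posterior_classify(model_s, roster, s_spec)
        subgroups = pd.DataFrame(
            {
                "participant_id": roster["participant_id"],
                "subgroup": [f"subgroup_{c + 1}" for c in assign_s.modal_class],
            }
        )
        subgroups.to_csv(out / "subgroups.csv", index=False)

    # --- stage: association ----------------------------------------------
    with _timed(timings, "association"):
        report: dict = {"feature_by_subgroup": {}, "class_by_subgroup": None}
        level_map = {f: defaults.CONSISTENCY_LEVELS for f in defaults.CONSISTENCY_FEATURES}
        level_map.update({f: defaults.QUANTITY_LEVELS for f in defaults.QUANTITY_FEATURES})
        sg_labels = sorted(subgroups["subgroup"].unique())
        feature_tables = []
        for feature in defaults.FEATURES:
            ct = pd.crosstab(profiles[feature], subgroups["subgroup"])
            ct = ct.reindex(
                index=[l for l in level_map[feature] if l in ct.index],
                columns=sg_labels, fill_value=0,
            )
            table = ContingencyTable(
                row_labels=tuple(ct.index), col_labels=tuple(ct.columns),
                counts=ct.to_numpy(),
            )
            entry = {"counts": ct.to_numpy().tolist(),
                     "levels": list(ct.index), "subgroups": sg_labels}
            try:
                res = pearson_chisq(table)
                entry.update(
                    statistic=res.statistic, df=res.df, p_value=res.p_value,
                    min_expected=res.min_expected,
                )
            except ValueError as exc:
                entry.update(error=str(exc))
            report["feature_by_subgroup"][feature] = entry
            long = ct.reset_index(names="level")
            long.insert(0, "feature", feature)
            feature_tables.append(long)
        pd.concat(feature_tables, ignore_index=True).to_csv(
            out / "feature_by_subgroup.csv", index=False
        )

        try:
            table, res, shares = crosstab_classes(
                classes["engagement_class"], subgroups["subgroup"]
            )
            report["class_by_subgroup"] = {
                "counts": table.counts.tolist(),
                "classes": list(table.row_labels),
                "subgroups": list(table.col_labels),
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
            shares.to_csv(out / "class_by_subgroup_shares.csv")
        except ValueError as exc:
            report["class_by_subgroup"] = {"error": str(exc)}
        _json_dump(report, out / "assoc_report.json")

    # --- stage: recovery diagnostics (synthetic runs only) ----------------
    if truth is not None:
        with _timed(timings, "recovery"):
            diag = {}
            gen = config.generator
            if model_e.n_classes == len(defaults.ENGAGEMENT_CLASSES):
                ref = LcaModel(gamma=gen.engagement_gamma, rho=gen.engagement_rho)
                diag["engagement"] = _recovery_errors(ref, model_e)
            if model_s.n_classes == len(defaults.SUBGROUP_CLASSES):
                ref = LcaModel(gamma=gen.subgroup_gamma, rho=gen.subgroup_rho)
                diag["subgroups"] = _recovery_errors(ref, model_s)
            diag["selected_k"] = {
                "engagement": sweep.selected_k,
                "subgroups": s_sweep.selected_k,
            }
            _json_dump(diag, out / "recovery.json")

    # --- stage: report ----------------------------------------------------
    with _timed(timings, "report"):
        (out / "report.md").write_text(render_report(out))


def _recovery_errors(reference: LcaModel, fitted: LcaModel) -> dict:
    perm = align_classes(reference, fitted)
    aligned = fitted.permute(perm)
    max_rho = max(
        float(np.abs(aligned.rho[item] - reference.rho[item]).max())
        for item in reference.rho
    )
    return {
        "max_abs_gamma_error": float(np.abs(aligned.gamma - reference.gamma).max()),
        "max_abs_rho_error": max_rho,
    }


# ---------------------------------------------------------------------------
# report rendering


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4f}") -> str:
    """Minimal GitHub-markdown table from a DataFrame (index included)."""

    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return floatfmt.format(v)
        return str(v)

    header = [str(df.index.name or "")] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [fmt(v) for v in row]) + " |")
    return "\n".join(lines)


def render_report(out_dir) -> str:
    """Render the markdown report from the saved stage artifacts only."""
    out = Path(out_dir)
    profiles = pd.read_csv(out / "profiles.csv")
    n = len(profiles)
    parts = [f"# Engagement process-evaluation report\n\nParticipants: {n}\n"]

    parts.append("## Feature use (share of sample per category)\n")
    level_map = {f: defaults.CONSISTENCY_LEVELS for f in defaults.CONSISTENCY_FEATURES}
    level_map.update({f: defaults.QUANTITY_LEVELS for f in defaults.QUANTITY_FEATURES})
    rows = {}
    for feature in defaults.FEATURES:
        freq = profiles[feature].value_counts()
        rows[feature] = {
            lvl: f"{freq.get(lvl, 0)} ({100.0 * freq.get(lvl, 0) / n:.2f}%)"
            for lvl in level_map[feature]
        }
    freq_df = pd.DataFrame(rows).T.fillna("—")
    freq_df.index.name = "feature"
    parts.append(_md_table(freq_df))

    for name, title in (
        ("model_engagement.json", "Engagement-pattern classes"),
        ("model_subgroups.json", "Demographic/BMI subgroup classes"),
    ):
        model = LcaModel.from_json(out / name)
        parts.append(f"\n## {title} (K={model.n_classes})\n")
        gamma = pd.DataFrame(
            {"prevalence": model.gamma},
            index=[f"class_{i + 1}" for i in range(model.n_classes)],
        )
        gamma.index.name = "class"
        parts.append(_md_table(gamma))
        for item, table in model.rho.items():
            df = pd.DataFrame(
                table.T,
                columns=[f"class_{i + 1}" for i in range(model.n_classes)],
            )
            df.index = list(_levels_for(item))
            df.index.name = item
            parts.append("\n" + _md_table(df))

    assoc = json.loads((out / "assoc_report.json").read_text())
    parts.append("\n## Feature use by fitted subgroup (chi-square)\n")
    assoc_rows = []
    for feature, entry in assoc["feature_by_subgroup"].items():
        if "p_value" in entry:
            assoc_rows.append(
                {"feature": feature, "statistic": entry["statistic"],
                 "df": entry["df"], "p": entry["p_value"]}
            )
        else:
            assoc_rows.append({"feature": feature, "statistic": float("nan"),
                               "df": 0, "p": float("nan")})
    adf = pd.DataFrame(assoc_rows).set_index("feature")
    parts.append(_md_table(adf, floatfmt="{:.4g}"))

    cbs = assoc.get("class_by_subgroup")
    if cbs and "counts" in cbs:
        parts.append("\n## Engagement class by subgroup\n")
        cdf = pd.DataFrame(cbs["counts"], index=cbs["classes"], columns=cbs["subgroups"])
        cdf.index.name = "class"
        parts.append(_md_table(cdf))
        parts.append(
            f"\nchi-square = {cbs['statistic']:.3f}, df = {cbs['df']}, "
            f"p = {cbs['p_value']:.4g}\n"
        )

    recovery = out / "recovery.json"
    if recovery.exists():
        diag = json.loads(recovery.read_text())
        parts.append("\n## Recovery diagnostics (synthetic truth retained)\n")
        parts.append("```json\n" + json.dumps(diag, indent=2, sort_keys=True) + "\n```")

    return "\n".join(parts) + "\n"


def _levels_for(item: str):
    if item in defaults.CONSISTENCY_FEATURES:
        return defaults.CONSISTENCY_LEVELS
    if item in defaults.QUANTITY_FEATURES:
        return defaults.QUANTITY_LEVELS
    return defaults.SUBGROUP_LEVELS[item]
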