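"""End-to-end orchestration: generate -> preprocess -> fit -> report.

A single config (YAML or JSON) drives the pipeline.  Stages write their
outputs before the next stage starts, and a manifest records the config
hash, the seed, and a checksum per output file, so deterministic stages can
be verified to reproduce byte-identically under the same seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort, inference, inspection, ptmodel
from .evidence import load_evidence_table

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "write_report",
    "STAGES",
]

STAGES = ("generate", "preprocess", "fit-pt", "fit-assoc", "report")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Pipeline settings.

    ``input_dir`` is None for a synthetic cohort, or a directory containing
    participants.csv / ratings.csv / events.csv / decisions.csv in the
    pipeline's schema (externally deposited data can be schema-mapped to
    these four files).
    """

    seed: int = 0
    out_dir: str = "vaxtrace_out"
    input_dir: str | None = None
    group_sizes: dict = field(
        default_factory=lambda: dict(cohort.STUDY_GROUP_SIZES)
    )
    fit_groups: tuple[str, ...] = ("anti", "neutral", "pro")
    pt_sampler: inference.SamplerConfig = inference.PT_SAMPLER_DEFAULTS
    assoc_sampler: inference.SamplerConfig = inference.ASSOCIATION_SAMPLER_DEFAULTS

    def __post_init__(self) -> None:
        if self.input_dir is None and not self.group_sizes:
            raise ValueError("synthetic runs need group sizes")
        bad = set(self.fit_groups) - set(cohort.ATTITUDES)
        if bad:
            raise ValueError(f"unknown attitude groups {sorted(bad)}")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a YAML/JSON config file into a PipelineConfig."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    for key in ("pt_sampler", "assoc_sampler"):
        if key in raw and isinstance(raw[key], dict):
            base = (
                inference.PT_SAMPLER_DEFAULTS
                if key == "pt_sampler"
                else inference.ASSOCIATION_SAMPLER_DEFAULTS
            )
            raw[key] = replace(base, **raw[key])
    if "fit_groups" in raw:
        raw["fit_groups"] = tuple(raw["fit_groups"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _log(stage: str, message: str) -> None:
    print(f"[vaxtrace:{stage}] {message}", file=sys.stderr)


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = STAGES
) -> dict:
    """Execute the requested stages in order; returns the manifest dict.

    Stage outputs land under ``config.out_dir``: data/ (cohort files),
    preprocessing outputs, per-group model fits, regression effects, and the
    final report.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError("config", f"unknown stages {sorted(unknown)}")
    out = Path(config.out_dir)
    data_dir = out / "data"
    out.mkdir(parents=True, exist_ok=True)
    table = load_evidence_table()
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "completed"
        for p in paths:
            manifest["checksums"][str(p.relative_to(out))] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if "generate" in stages:
        try:
            if config.input_dir is not None:
                _log("generate", f"using existing data in {config.input_dir}")
                data_dir = Path(config.input_dir)
            else:
                _log("generate", f"sampling synthetic cohort (seed {config.seed})")
                cohort_config = cohort.default_cohort_config(
                    sizes=config.group_sizes, table=table
                )
                cohort.generate_cohort(cohort_config, config.seed, out_dir=data_dir)
                record(
                    "generate",
                    *[
                        data_dir / f
                        for f in (
                            "participants.csv", "ratings.csv",
                            "events.csv", "decisions.csv", "truth.json",
                        )
                    ],
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("generate", str(exc)) from exc
    elif config.input_dir is not None:
        data_dir = Path(config.input_dir)

    participants = pd.read_csv(data_dir / "participants.csv")
    groups_map = dict(
        zip(participants["participant_id"].astype(str), participants["attitude"])
    )

    if "preprocess" in stages:
        try:
            _log("preprocess", "filtering hover logs and building indices")
            events = pd.read_csv(data_dir / "events.csv")
            decisions = pd.read_csv(data_dir / "decisions.csv")
            inspection.process_events(
                events,
                decisions,
                table,
                out_summaries=out / "ignorance_summaries.csv",
                out_descriptives=out / "group_descriptives.json",
                groups=groups_map,
            )
            record(
                "preprocess",
                out / "ignorance_summaries.csv",
                out / "group_descriptives.json",
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("preprocess", str(exc)) from exc

    if "fit-pt" in stages:
        try:
            summaries = pd.read_csv(out / "ignorance_summaries.csv")
            ratings = pd.read_csv(data_dir / "ratings.csv")
            decisions = pd.read_csv(data_dir / "decisions.csv")
            for group in config.fit_groups:
                pids = {p for p, g in groups_map.items() if g == group}
                if not pids:
                    continue
                _log("fit-pt", f"sampling posterior for group {group!r}")
                ds = ptmodel.build_model_dataset(
                    table,
                    ratings[ratings["participant_id"].astype(str).isin(pids)],
                    summaries[summaries["participant_id"].astype(str).isin(pids)],
                    decisions[decisions["participant_id"].astype(str).isin(pids)],
                )
                fit = inference.fit_pt_model(
                    ds, replace(config.pt_sampler, seed=config.seed)
                )
                _write_pt_fit(fit, ds, out, group)
                record(
                    "fit-pt",
                    out / f"pt_draws_{group}.csv",
                    out / f"pt_diagnostics_{group}.json",
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("fit-pt", str(exc)) from exc

    if "fit-assoc" in stages:
        try:
            _log("fit-assoc", "hierarchical logistic regression of decisions")
            summaries = pd.read_csv(out / "ignorance_summaries.csv")
            decisions = pd.read_csv(data_dir / "decisions.csv")
            merged = decisions.merge(
                summaries, on=["participant_id", "trial_index", "vaccine"]
            )
            merged["attitude"] = merged["participant_id"].astype(str).map(groups_map)
            merged["accepted"] = (merged["decision"] == "accept").astype(int)
            spec = association.RegressionSpec(
                outcome="accepted",
                family="bernoulli",
                predictors=("attitude", "vaccine", "ignorance_level"),
            )
            fit = association.fit_hierarchical_logistic(
                merged, spec, replace(config.assoc_sampler, seed=config.seed)
            )
            effects = {
                "outcome": spec.outcome,
                "max_rhat": fit.max_rhat(),
                "odds_ratios": association.odds_ratios(fit).to_dict(orient="records"),
                "predicted_levels": {},
                "pairwise": {},
            }
            for factor in spec.predictors:
                effects["predicted_levels"][factor] = association.predicted_levels(
                    fit, factor
                ).to_dict(orient="records")
                levels = fit.design.factor_levels[factor]
                effects["pairwise"][factor] = {
                    f"{a} vs {b}": association.pairwise_difference(fit, factor, a, b)
                    for i, a in enumerate(levels)
                    for b in levels[i + 1 :]
                }
            (out / "effects.json").write_text(json.dumps(effects, indent=2))
            record("fit-assoc", out / "effects.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("fit-assoc", str(exc)) from exc

    if "report" in stages:
        try:
            write_report(out, config)
            record("report", out / "report.json", out / "report.md")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("report", str(exc)) from exc
    return manifest


def _write_pt_fit(
    fit: inference.PosteriorSamples,
    dataset: ptmodel.ModelDataset,
    out: Path,
    group: str,
) -> None:
    """Persist group-level draws (long format) and a diagnostics JSON."""
    post = fit.group_posterior()
    n_chains, n_kept, _ = fit.draws.shape
    chains = np.repeat(np.arange(n_chains), n_kept)
    iters = np.tile(np.arange(n_kept), n_chains)
    frames = []
    for name, values in post.items():
        frames.append(
            pd.DataFrame(
                {
                    "chain": chains,
                    "iteration": iters,
                    "parameter": name,
                    "value": values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        out / f"pt_draws_{group}.csv", index=False
    )
    diagnostics = {
        "group": group,
        "n_participants": dataset.n_participants,
        "n_recorded_draws": fit.n_recorded,
        "max_rhat": fit.max_rhat(),
        "rhat_group_level": {
            k: v for k, v in fit.rhat.items() if not k.startswith("z[")
        },
        "divergences": sum(s["divergences"] for s in fit.chain_stats),
        "balanced_accuracy_in_sample": inference.posterior_predictive_accuracy(
            fit, dataset, "in_sample"
        ),
        "config": asdict(fit.config),
    }
    (out / f"pt_diagnostics_{group}.json").write_text(
        json.dumps(diagnostics, indent=2)
    )


def write_report(out: Path, config: PipelineConfig) -> dict:
    """Assemble the human-readable summary from previously written stage
    outputs; raises if an expected artifact is missing."""
    out = Path(out)
    missing = []
    report: dict = {"seed": config.seed}
    desc_path = out / "group_descriptives.json"
    if desc_path.exists():
        report["descriptives"] = json.loads(desc_path.read_text())
    else:
        missing.append(str(desc_path))

    report["pt_model"] = {}
    for group in config.fit_groups:
        draws_path = out / f"pt_draws_{group}.csv"
        diag_path = out / f"pt_diagnostics_{group}.json"
        if not draws_path.exists():
            continue
        if not diag_path.exists():
            missing.append(str(diag_path))
            continue
        draws = pd.read_csv(draws_path)
        summary = {}
        for name, sub in draws.groupby("parameter"):
            values = sub["value"].to_numpy()
            lo, hi = inference.hdi(values, 0.95)
            summary[name] = {
                "median": float(np.median(values)),
                "hdi_low": lo,
                "hdi_high": hi,
            }
        report["pt_model"][group] = {
            "parameters": summary,
            "diagnostics": json.loads(diag_path.read_text()),
        }

    effects_path = out / "effects.json"
    if effects_path.exists():
        report["associations"] = json.loads(effects_path.read_text())
    if missing:
        raise PipelineError("report", f"missing artifacts: {missing}")

    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# vaxtrace pipeline report", ""]
    if "descriptives" in report:
        lines += ["## Deliberate ignorance and probability neglect", ""]
        lines.append(
            "| group | full | partial | none | SE neglect | benefit neglect |"
        )
        lines.append("|---|---|---|---|---|---|")
        for rec in report["descriptives"]:
            lines.append(
                "| {group} | {prop_full:.1%} | {prop_partial:.1%} | {prop_none:.1%} "
                "| {prop_neglect_side_effects:.1%} | {prop_neglect_benefits:.1%} |".format(
                    **rec
                )
            )
        lines.append("")
    for group, block in report.get("pt_model", {}).items():
        lines += [f"## Decision model: {group} group", ""]
        lines.append("| parameter | median | 95% HDI |")
        lines.append("|---|---|---|")
        for name in ("beta", "Lambda", "gamma", "alpha", "phi"):
            if name in block["parameters"]:
                p = block["parameters"][name]
                lines.append(
                    f"| {name} | {p['median']:.3f} | "
                    f"[{p['hdi_low']:.3f}, {p['hdi_high']:.3f}] |"
                )
        diag = block["diagnostics"]
        lines.append("")
        lines.append(
            f"max R-hat {diag['max_rhat']:.4f}, "
            f"{diag['n_recorded_draws']} recorded draws, "
            f"in-sample balanced accuracy "
            f"{diag['balanced_accuracy_in_sample']:.3f}"
        )
        lines.append("")
    return "\n".join(lines)
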