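"""End-to-end analysis pipeline: config, per-domain blocks, report bundle."""

from __future__ import annotations

import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import trajarea
from trajarea.dataset import TrialDataset, read_dataset
from trajarea.occasions import OccasionSpec
from trajarea.sur import fit_sur
from trajarea.effects import area_between_curves, standardize
from trajarea.resampling import bootstrap_area

logger = logging.getLogger(__name__)


@dataclass
class BlockSpec:
    """One reported domain: a list of occasions plus the baseline anchor."""

    name: str
    occasions: list
    anchor_time: float | None = None

    def __post_init__(self):
        self.occasions = [
            s if isinstance(s, OccasionSpec) else OccasionSpec.from_dict(s)
            for s in self.occasions
        ]
        times = [s.time for s in self.occasions]
        if times != sorted(set(times)):
            raise ValueError(f"block {self.name!r}: occasion times must be strictly increasing")


@dataclass
class AnalysisConfig:
    dataset: str
    blocks: list
    output_dir: str = "trajarea_out"
    seed: int = 0
    bootstrap_B: int = 1000
    bootstrap_level: float = 0.95
    bonferroni: bool = False
    make_plots: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        self.blocks = [b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in self.blocks]
        if not self.blocks:
            raise ValueError("analysis config defines no blocks")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        blocks = []
        for name, bd in (raw.pop("blocks", {}) or {}).items():
            blocks.append(BlockSpec(name=name, occasions=bd.get("occasions", []),
                                    anchor_time=bd.get("anchor_time")))
        boot = raw.pop("bootstrap", {}) or {}
        return cls(
            dataset=raw.pop("dataset"),
            blocks=blocks,
            output_dir=raw.pop("output_dir", "trajarea_out"),
            seed=raw.pop("seed", 0),
            bootstrap_B=boot.get("B", 1000),
            bootstrap_level=boot.get("level", 0.95),
            bonferroni=raw.pop("bonferroni", False),
            make_plots=raw.pop("make_plots", True),
            log_level=raw.pop("log_level", "INFO"),
        )

    def validate_against(self, dataset: TrialDataset) -> None:
        """Fail before any computation if a referenced column is absent."""
        cols = set(dataset.df.columns)
        problems = []
        for block in self.blocks:
            for spec in block.occasions:
                referenced = [spec.outcome_column, spec.treatment_column,
                              *spec.covariate_columns]
                if spec.baseline_column:
                    referenced.append(spec.baseline_column)
                if spec.sd_stratum_column:
                    referenced.append(spec.sd_stratum_column)
                for c in referenced:
                    if c not in cols:
                        problems.append(f"block {block.name!r}, occasion {spec.label!r}: "
                                        f"column {c!r} not in dataset")
        if problems:
            raise ValueError("invalid analysis config:\n  " + "\n  ".join(problems))


def _plot_block(traj, area, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "trajarea"
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.errorbar(traj.times, traj.d, yerr=1.96 * traj.se, fmt="o-", capsize=3, color="C0")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("standardized effect (d)")
    ax.set_title(f"area = {area.area:.2f} ES·months, averaged ES = {area.averaged_es:.2f}, "
                 f"p = {area.p:.3f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def run_pipeline(config: AnalysisConfig, dataset: TrialDataset | None = None) -> dict:
    """Run every domain block: joint fit, trajectory, area, bootstrap, plot.

    A failing stage aborts only its block; the summary flags failed blocks.
    Writes ``summary.json``, ``report.md``, per-block trajectory CSVs and
    SVG profile plots into ``config.output_dir`` and returns the summary.
    """
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, config.log_level.upper(), 20))
    if dataset is None:
        dataset = read_dataset(config.dataset)
    config.validate_against(dataset)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = len(config.blocks)

    summary = {
        "package_version": trajarea.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_participants": len(dataset),
        "bootstrap": {"B": config.bootstrap_B, "level": config.bootstrap_level},
        "bonferroni": config.bonferroni,
        "blocks": {},
    }
    for i, block in enumerate(config.blocks):
        logger.info("block %s: fitting %d occasions", block.name, len(block.occasions))
        entry = {"failed": False}
        try:
            fit = fit_sur(dataset, block.occasions)
            traj = standardize(fit, dataset, block.occasions, anchor_time=block.anchor_time)
            area = area_between_curves(traj)
            boot = bootstrap_area(
                dataset, block.occasions, B=config.bootstrap_B, level=config.bootstrap_level,
                seed=config.seed + i, anchor_time=block.anchor_time,
            )
            p = area.p
            if config.bonferroni:
                p = min(1.0, p * m)
            entry.update(
                fit={"loglik": fit.loglik, "converged": fit.converged,
                     "n_iter": fit.n_iter, "n_per_equation": fit.n_per_equation.tolist(),
                     "n_dropped_covariate_missing": fit.problem.n_dropped},
                trajectory=traj.to_dict(),
                area={**area.to_dict(), "p_adjusted": p},
                bootstrap=boot.to_dict(),
            )
            pd.DataFrame({
                "time": traj.times, "d": traj.d, "se": traj.se,
                "sd_within": traj.sd_within, "beta": traj.beta,
            }).to_csv(out / f"block_{block.name}.csv", index=False)
            if config.make_plots:
                _plot_block(traj, area, out / f"block_{block.name}.svg")
        except Exception as exc:  # noqa: BLE001 — block errors must not abort the run
            logger.error("block %s failed: %s", block.name, exc)
            entry["failed"] = True
            entry["error"] = str(exc)
        summary["blocks"][block.name] = entry

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_report(summary, out / "report.md")
    return summary


def _write_report(summary: dict, path: Path) -> None:
    lines = [
        "# Longitudinal trial analysis report",
        "",
        f"- package: trajarea {summary['package_version']} (python {summary['python']})",
        f"- participants: {summary['n_participants']}",
        f"- seed: {summary['seed']}; bootstrap B={summary['bootstrap']['B']} "
        f"level={summary['bootstrap']['level']}",
        "",
        "| block | averaged ES | direction | area (ES·mo) | Wald z | p | "
        f"{int(summary['bootstrap']['level'] * 100)}% bootstrap CI (avg ES) |",
        "|---|---|---|---|---|---|---|",
    ]
    for name, entry in summary["blocks"].items():
        if entry.get("failed"):
            lines.append(f"| {name} | FAILED: {entry.get('error', '?')} | | | | | |")
            continue
        area = entry["area"]
        ci = entry["bootstrap"]["ci_averaged"]
        es = area["averaged_es"]
        direction = "benefit (reduction)" if es < 0 else "increase"
        lines.append(
            f"| {name} | {abs(es):.2f} | {direction} | {area['area']:.2f} | "
            f"{area['z']:.2f} | {area['p']:.3f} | [{ci[0]:.2f}, {ci[1]:.2f}] |"
        )
    lines.append("")
    path.write_text("\n".join(lines))


def default_analysis_config(dataset_path: str = "trial.csv", **overrides) -> AnalysisConfig:
    """Analysis blocks matching the default synthetic battery: symptoms,
    parent and child dyadic interaction, language, adaptive behaviour."""
    common = ("centre", "ethnicity", "maternal_education")

    def occ(label, time, outcome, baseline, transform="identity", sd_stratum=None):
        return dict(label=label, time=time, outcome=outcome, baseline=baseline,
                    transform=transform, covariates=[*common, f"age_{time}"],
                    sd_stratum=sd_stratum)

    blocks = [
        BlockSpec("symptoms", anchor_time=9, occasions=[
            occ("aosi_15", 15, "aosi_15", "aosi_9"),
            occ("ados_27", 27, "ados_27", "aosi_9", transform="log1p"),
            occ("ados_39", 39, "ados_39", "aosi_9", transform="log1p",
                sd_stratum="ados_module_39"),
        ]),
        BlockSpec("parent_dyadic", anchor_time=9, occasions=[
            occ("nondir_15", 15, "maci_nondir_15", "maci_nondir_9"),
            occ("nondir_27", 27, "maci_nondir_27", "maci_nondir_9"),
            occ("sync_39", 39, "dcma_sync_39", "maci_nondir_9"),
        ]),
        BlockSpec("child_dyadic", anchor_time=9, occasions=[
            occ("att_15", 15, "maci_att_15", "maci_att_9"),
            occ("att_27", 27, "maci_att_27", "maci_att_9"),
            occ("init_39", 39, "dcma_init_39", "maci_att_9"),
        ]),
        BlockSpec("language", anchor_time=9, occasions=[
            occ("rl_15", 15, "mullen_rl_15", "mullen_rl_9"),
            occ("rl_27", 27, "mullen_rl_27", "mullen_rl_9"),
            occ("rl_39", 39, "mullen_rl_39", "mullen_rl_9"),
        ]),
        BlockSpec("adaptive", anchor_time=9, occasions=[
            occ("soc_15", 15, "vineland_soc_15", "vineland_soc_9"),
            occ("soc_27", 27, "vineland_soc_27", "vineland_soc_9"),
            occ("soc_39", 39, "vineland_soc_39", "vineland_soc_9"),
        ]),
    ]
    kwargs = dict(dataset=dataset_path, blocks=blocks)
    kwargs.update(overrides)
    return AnalysisConfig(**kwargs)
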