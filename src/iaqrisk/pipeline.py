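"""End-to-end study orchestration: generate → fit → screen → simulate → assess.

One :class:`~iaqrisk.synthetic.ScenarioConfig` drives every stage. All
randomness flows from the single root seed, split per stage with
``numpy.random.SeedSequence``, so re-running with an identical config
produces byte-identical outputs. A run manifest (config hash, seed, package
version, per-stage output paths) is written atomically at run end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concentration import exceedance_analytic, exceedance_empirical
from .exposure import simulate_personal_exposure, summarize_exposure
from .guidelines import Registry, default_registry
from .risk import DecayScenario, cancer_risk, decay_scenario, summarize_risk
from .synthetic import ScenarioConfig, generate_building_records, records_to_frame

__all__ = ["RunManifest", "StageError", "run_study", "render_report"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _config_hash(config: ScenarioConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: object) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_study(
    config: ScenarioConfig,
    outdir: str | Path,
    registry: Registry | None = None,
) -> RunManifest:
    """Run the full assessment and write all stage outputs under ``outdir``.

    Stages: building-record generation, per-stratum summary + lognormal fit,
    guideline screening (analytic and empirical exceedance), exposure Monte
    Carlo per compound, cancer-risk tables under both IUR sources, and the
    concentration-decay scenario. Any stage failure removes that run's
    partial outputs and raises :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = registry or default_registry()
    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=_config_hash(config),
        seed=config.seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    # independent child seeds per stage, all derived from the root seed
    stage_seeds = np.random.SeedSequence(config.seed).spawn(2)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "generate"
        records = generate_building_records(
            config, seed=np.random.default_rng(stage_seeds[0])
        )
        frame = records_to_frame(records)
        records_path = outdir / "records.csv"
        frame.to_csv(records_path, index=False)
        written.append(records_path)
        manifest.outputs["records"] = str(records_path)
        logger.info("generate: %d records across %d strata", len(frame), len(config.strata))

        stage = "fit_and_screen"
        summary: dict[str, dict] = {}
        for s in config.strata:
            params = config.lognormal(s.building_type, s.compound)
            mask = (frame.building_type == s.building_type) & (frame.compound == s.compound)
            values = frame.loc[mask, "concentration_ug_m3"].to_numpy()
            exceedance = {}
            for g in registry.guidelines_for(s.compound):
                key = f"{g.source}/{g.effect_class}"
                exceedance[key] = {
                    "threshold_ug_m3": g.threshold,
                    "analytic": exceedance_analytic(params, g.threshold),
                    "empirical": exceedance_empirical(values, g.threshold),
                }
            summary[f"{s.building_type}/{s.compound}"] = {
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "median": s.median,
                "lognormal": {"mu": params.mu, "sigma": params.sigma},
                "exceedance": exceedance,
            }
        screen_path = outdir / "exceedance.json"
        _write_json(screen_path, summary)
        written.append(screen_path)
        manifest.outputs["exceedance"] = str(screen_path)
        logger.info("fit_and_screen: %d strata screened", len(summary))

        stage = "simulate_exposure"
        exposure_rng = np.random.default_rng(stage_seeds[1])
        draws_by_compound = {}
        exposure_summary = {}
        draw_frames = []
        for compound in config.compounds():
            draws = simulate_personal_exposure(
                home_params=config.lognormal("dwelling", compound),
                office_params=config.lognormal("office", compound),
                time_use=config.time_use,
                n_trials=config.n_trials,
                seed=exposure_rng,
                compound=compound,
            )
            draws_by_compound[compound] = draws
            exposure_summary[compound] = summarize_exposure(draws)
            draw_frames.append(
                pd.DataFrame(
                    {
                        "draw_id": np.arange(draws.n_trials),
                        "compound": compound,
                        "e_home": draws.e_home,
                        "e_office": draws.e_office,
                        "e_total": draws.e_total,
                    }
                )
            )
        draws_path = outdir / "exposure_draws.csv"
        pd.concat(draw_frames, ignore_index=True).to_csv(draws_path, index=False)
        written.append(draws_path)
        manifest.outputs["exposure_draws"] = str(draws_path)
        exp_path = outdir / "exposure_summary.json"
        _write_json(exp_path, exposure_summary)
        written.append(exp_path)
        manifest.outputs["exposure_summary"] = str(exp_path)
        logger.info(
            "simulate_exposure: %d trials x %d compounds",
            config.n_trials,
            len(draws_by_compound),
        )

        stage = "assess_risk"
        rows = []
        decay_rows = []
        for source in ("OEHHA", "U.S. EPA IRIS"):
            for compound, draws in draws_by_compound.items():
                factor = registry.toxicity_factor(compound, source)
                risks = cancer_risk(draws, factor)
                rs = summarize_risk(risks)
                rows.append(
                    {
                        "iur_source": source,
                        "compound": compound,
                        "iur_per_ug_m3": factor.iur,
                        "mean": rs.mean,
                        "sd": rs.sd,
                        "median": rs.median,
                        "p95": rs.p95,
                        "home_share": rs.home_share,
                        "office_share": rs.office_share,
                    }
                )
                if compound in config.decay:
                    scenario = DecayScenario(compound, config.decay[compound])
                    decayed = decay_scenario(rs, scenario)
                    decay_rows.append(
                        {
                            "iur_source": source,
                            "compound": compound,
                            "retained_fraction": scenario.retained_fraction,
                            "median_initial": rs.median,
                            "median_decayed": decayed.median,
                        }
                    )
        risk_path = outdir / "risk_table.csv"
        pd.DataFrame(rows).to_csv(risk_path, index=False)
        written.append(risk_path)
        manifest.outputs["risk_table"] = str(risk_path)
        decay_path = outdir / "decay_table.csv"
        pd.DataFrame(decay_rows).to_csv(decay_path, index=False)
        written.append(decay_path)
        manifest.outputs["decay_table"] = str(decay_path)
        logger.info("assess_risk: %d risk rows, %d decay rows", len(rows), len(decay_rows))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest_path = outdir / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    _write_json(tmp, manifest.to_dict())
    tmp.replace(manifest_path)  # atomic write
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def _fmt_pct(fraction: float) -> str:
    return f"{fraction * 100:.1f}%"


def _fmt_int(value: float) -> str:
    return f"{round(value):,}"


def render_report(manifest: RunManifest) -> str:
    """Human-readable markdown summary of a completed run.

    Exceedance fractions are printed to one decimal percentage; risk
    statistics as integers with thousands separators.
    """
    if not manifest.outputs:
        raise ValueError("manifest has no stage outputs to report")
    for key in ("exceedance", "exposure_summary", "risk_table", "decay_table"):
        if key not in manifest.outputs or not Path(manifest.outputs[key]).exists():
            raise FileNotFoundError(f"missing stage output {key!r}")

    lines = [
        "# Indoor air-toxics risk assessment",
        "",
        f"Config hash `{manifest.config_hash}`, seed {manifest.seed}, "
        f"iaqrisk {manifest.version}.",
        "",
        "## Guideline exceedance (fitted lognormal tails)",
        "",
    ]
    with open(manifest.outputs["exceedance"]) as fh:
        screening = json.load(fh)
    for stratum, info in screening.items():
        lines.append(f"### {stratum}")
        lines.append("")
        for guideline, exc in sorted(info["exceedance"].items()):
            lines.append(
                f"- {guideline} ({exc['threshold_ug_m3']:g} µg/m³): "
                f"{_fmt_pct(exc['analytic'])} above"
            )
        lines.append("")

    with open(manifest.outputs["exposure_summary"]) as fh:
        exposure = json.load(fh)
    lines += ["## Personal exposure (µg/m³)", ""]
    for compound, envs in exposure.items():
        parts = ", ".join(
            f"{env} {st['mean']:.1f}±{st['sd']:.1f} (median {st['median']:.1f})"
            for env, st in envs.items()
        )
        lines.append(f"- {compound}: {parts}")
    lines.append("")

    risk = pd.read_csv(manifest.outputs["risk_table"])
    lines += [
        "## Lifetime cancer risk (excess cases per million)",
        "",
        "| IUR source | Compound | Mean | SD | Median | 95% | Home share |",
        "|---|---|---|---|---|---|---|",
    ]
    for row in risk.itertuples(index=False):
        lines.append(
            f"| {row.iur_source} | {row.compound} | {_fmt_int(row.mean)} | "
            f"{_fmt_int(row.sd)} | {_fmt_int(row.median)} | {_fmt_int(row.p95)} | "
            f"{_fmt_pct(row.home_share)} |"
        )
    lines.append("")

    decay = pd.read_csv(manifest.outputs["decay_table"])
    if len(decay):
        lines += ["## Post-remodeling decay scenario", ""]
        for row in decay.itertuples(index=False):
            lines.append(
                f"- {row.compound} ({row.iur_source}): median "
                f"{_fmt_int(row.median_initial)} → {_fmt_int(row.median_decayed)} "
                f"per million at {row.retained_fraction:.0%} retained concentration"
            )
        lines.append("")
    return "\n".join(lines)
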