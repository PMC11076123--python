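"""End-to-end reproduction pipeline.

One call chains data (synthetic generator or user files) → caste source
compositions → Monte-Carlo and analytic efficiency curves for the worker-
and nymph-source scenarios → minimum propagule sizes → the alate
threshold-exceedance table, and writes everything with a manifest so a run
is reproducible from its config and master seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import average_composition, read_samples, write_samples
from .simulate import (
    SimulationConfig,
    analytic_reference_threshold,
    efficiency_curve,
    minimum_cells_for_full_transmission,
)
from .stats import fraction_above_threshold
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("propagule.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Configuration of one reproduction run.

    Exactly one input mode is active: ``synthetic`` (the generator supplies
    the dataset) or ``files`` (``samples_path`` points to a CSV/TSV of
    per-individual counts).  ``source_castes`` names the two transmission
    scenarios compared; ``exceedance_caste`` is the alate group compared
    against the resulting minimum propagule sizes.
    """

    input_mode: str = "synthetic"
    samples_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    source_castes: tuple[str, str] = ("nymph", "worker")
    colonies: tuple[str, ...] | None = ("I", "II")
    exceedance_caste: str = "A7"
    master_seed: int = 0
    make_figure: bool = False

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ValueError("input_mode must be 'synthetic' or 'files'")
        if self.input_mode == "files" and not self.samples_path:
            raise ValueError("files mode requires samples_path")
        if self.input_mode == "synthetic" and self.samples_path:
            raise ValueError("exactly one input mode: synthetic mode takes no samples_path")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML/JSON with full defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimulationConfig(**{**raw.pop("simulation", {}), })
    synth_kwargs = raw.pop("synthetic", {})
    synth = SyntheticConfig(**synth_kwargs)
    if "source_castes" in raw:
        raw["source_castes"] = tuple(raw["source_castes"])
    if raw.get("colonies") is not None:
        raw["colonies"] = tuple(raw["colonies"])
    return PipelineConfig(simulation=sim, synthetic=synth, **raw)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [float(x) for x in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full reproduction and write its outputs under ``out_dir``.

    Writes ``samples.csv`` (synthetic mode), ``curves.tsv`` (long table:
    scenario × mode × N × efficiency), ``min_cells.json``,
    ``exceedance.tsv`` and ``manifest.json``; optionally a curve figure.
    Returns the report bundle as a dict.  All randomness flows from
    ``config.master_seed`` (data seed and per-scenario simulation seeds are
    derived substreams), so identical config+seed gives identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.master_seed)
    data_seed, *scenario_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + len(config.source_castes))
    ]

    # --- input stage -------------------------------------------------------
    if config.input_mode == "synthetic":
        try:
            samples, _truth = generate_dataset(config.synthetic, seed=data_seed)
        except Exception as e:  # pragma: no cover - config already validated
            raise PipelineError("generate_dataset", str(e)) from e
        write_samples(samples, out_dir / "samples.csv")
        colonies = None  # generator colonies always included
    else:
        try:
            samples = read_samples(config.samples_path)
        except Exception as e:
            raise PipelineError("read_samples", str(e)) from e
        colonies = config.colonies
    log.info("loaded %d individual samples", len(samples))

    # --- compositions and curves ------------------------------------------
    curves_rows = []
    min_cells: dict[str, Any] = {}
    analytic_thr = analytic_reference_threshold(config.simulation.iterations)
    for caste, seed in zip(config.source_castes, scenario_seeds):
        try:
            comp = average_composition(samples, caste_group=caste, colonies=colonies)
        except Exception as e:
            raise PipelineError("average_composition", str(e)) from e
        try:
            mc_cfg = dataclasses.replace(config.simulation, mode="monte_carlo", seed=seed)
            an_cfg = dataclasses.replace(config.simulation, mode="analytic")
            mc_curve = efficiency_curve(comp, mc_cfg)
            an_curve = efficiency_curve(comp, an_cfg)
        except Exception as e:
            raise PipelineError("efficiency_curve", str(e)) from e
        mc_min = minimum_cells_for_full_transmission(
            mc_curve, config.simulation.efficiency_threshold
        )
        an_min = minimum_cells_for_full_transmission(an_curve, analytic_thr)
        min_cells[caste] = {
            "monte_carlo": mc_min.min_cells,
            "monte_carlo_threshold": mc_min.threshold,
            "analytic": an_min.min_cells,
            "analytic_threshold": an_min.threshold,
            "seed": seed,
            "rarest_proportion": float(comp.proportions.min()),
        }
        log.info(
            "%s source: MC min-N=%s, analytic min-N=%s", caste, mc_min.min_cells, an_min.min_cells
        )
        for curve in (mc_curve, an_curve):
            for n, e in zip(curve.n_values, curve.efficiency):
                curves_rows.append(
                    {"scenario": caste, "mode": curve.mode, "n_cells": n, "efficiency": e}
                )

    curves = pd.DataFrame(curves_rows)
    curves.to_csv(out_dir / "curves.tsv", sep="\t", index=False)
    (out_dir / "min_cells.json").write_text(json.dumps(_jsonable(min_cells), indent=2))

    # --- exceedance stage --------------------------------------------------
    exceedance_rows = []
    alate = config.exceedance_caste
    if any(s.caste_group == alate for s in samples):
        thresholds = sorted(
            {v["monte_carlo"] for v in min_cells.values() if v["monte_carlo"] is not None}
        )
        for thr in thresholds:
            k, n, frac = fraction_above_threshold(samples, alate, thr)
            exceedance_rows.append(
                {"caste_group": alate, "threshold_cells": thr, "k_above": k, "n": n, "fraction": frac}
            )
    else:
        log.warning("no %s individuals; exceedance table left empty", alate)
    exceedance = pd.DataFrame(
        exceedance_rows, columns=["caste_group", "threshold_cells", "k_above", "n", "fraction"]
    )
    exceedance.to_csv(out_dir / "exceedance.tsv", sep="\t", index=False)

    # --- manifest ----------------------------------------------------------
    cfg_json = json.dumps(_jsonable(config), sort_keys=True)
    manifest = {
        "package": "propagule",
        "version": __version__,
        "numpy_version": np.__version__,
        "master_seed": config.master_seed,
        "derived_seeds": {"data": data_seed, "scenarios": scenario_seeds},
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": ["curves.tsv", "min_cells.json", "exceedance.tsv"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if config.make_figure:
        try:
            _plot_curves(curves, out_dir / "curves.png")
        except Exception as e:  # plotting failures never fail the pipeline
            log.warning("figure generation failed: %s", e)

    return {"min_cells": min_cells, "curves": curves, "exceedance": exceedance, "manifest": manifest}


def _plot_curves(curves: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (scenario, mode), sub in curves.groupby(["scenario", "mode"]):
        style = "-" if mode == "monte_carlo" else "--"
        ax.plot(sub["n_cells"], sub["efficiency"], style, label=f"{scenario} ({mode})")
    ax.set_xlabel("cells transmitted (N)")
    ax.set_ylabel("transmission efficiency E(N)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
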