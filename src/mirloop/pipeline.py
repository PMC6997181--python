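"""End-to-end pipeline: simulate → metrics (→ calibrate → synth/qpcr).

All randomness flows from the single config seed.  Data go to files;
logging goes to stderr.  Each run writes a manifest (config hash, seed,
package version, artifact list) for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .kinetics import build_default_network
from .metrics import response_metrics_table
from .model import SynapticHomeostasisModel
from .observations import read_observations_csv
from .qpcr import quantify_table
from .simulate import simulate_genotypes
from .synthetic import builtin_presets, generate_ct_data

log = logging.getLogger("mirloop")

__all__ = ["run_full_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_full_pipeline(
    config: PipelineConfig,
    outdir,
    observations_csv=None,
    calibrate: bool = False,
    run_qpcr: bool = True,
    tidy_curves: bool = True,
) -> dict:
    """Execute the full pipeline and return the manifest dict.

    Writes: curves.csv, metrics.csv, optionally calibration.json (if
    ``calibrate`` or an observations CSV is given), quantification.csv for
    every builtin synthetic preset (if ``run_qpcr``), and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    network = build_default_network(config.params)
    genotypes = list(config.genotypes.values())

    stage = "simulate"
    try:
        log.info("simulating %d genotypes over %g lifetimes",
                 len(genotypes), config.horizon)
        responses = simulate_genotypes(network, genotypes, config.stimulus,
                                       config.horizon, config.solver)
        frames = []
        for name, resp in responses.items():
            frames.append(pd.DataFrame({"genotype": name, "time": resp.times,
                                        "v_norm": resp.v_norm}))
        curves = pd.concat(frames, ignore_index=True)
        if not tidy_curves:
            curves = curves.pivot(index="time", columns="genotype",
                                  values="v_norm").reset_index()
        curves_path = outdir / "curves.csv"
        curves.to_csv(curves_path, index=False)
        artifacts.append(curves_path.name)

        stage = "metrics"
        mtable = response_metrics_table(responses, config.threshold)
        metrics_path = outdir / "metrics.csv"
        mtable.to_csv(metrics_path, index=False)
        artifacts.append(metrics_path.name)

        if calibrate or observations_csv is not None:
            stage = "calibrate"
            obs = read_observations_csv(observations_csv) \
                if observations_csv is not None else None
            model = SynapticHomeostasisModel(observations=obs,
                                             params=config.params,
                                             genotypes=config.genotypes)
            results = model.fit(seed=config.seed)
            calib_path = outdir / "calibration.json"
            calib_path.write_text(json.dumps(results.as_dict(), indent=2))
            artifacts.append(calib_path.name)

        if run_qpcr:
            stage = "synth+qpcr"
            quant_rows = []
            for i, preset in enumerate(builtin_presets()):
                ct = generate_ct_data(preset, seed=config.seed * 1000 + i)
                res = quantify_table(ct, alpha=config.alpha,
                                     ct_threshold=config.ct_threshold)
                res.insert(0, "preset", preset.name)
                res["true_fold_change"] = preset.true_fold_change
                quant_rows.append(res)
            quant = pd.concat(quant_rows, ignore_index=True)
            quant_path = outdir / "quantification.csv"
            quant.to_csv(quant_path, index=False)
            artifacts.append(quant_path.name)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
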