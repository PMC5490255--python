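"""Pipeline driver: simulate -> process -> align -> fit -> quantify.

``run_pipeline`` executes the whole chain from a :class:`RunConfig` and
returns a JSON-serializable report with every stage's parameters and
intermediates; ``write_report`` persists it atomically (a partial write
never clobbers a complete report).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

from . import __version__
from .config import RunConfig
from .impurity import QuantifyConfig, quantify_impurity
from .simulate import simulate_impurity_experiment
from .substances import default_library

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulated impurity-quantification pipeline."""
    sim = config.simulate
    logger.info("simulate: fraction=10^%.2f, %d animals, seed=%d",
                sim.true_fraction_log10, sim.n_animals, config.seed)
    acq_overrides = {"channel_offset": sim.channel_offset}
    if sim.noise_sd is not None:
        acq_overrides["noise_sd"] = sim.noise_sd
    experiment = simulate_impurity_experiment(
        true_fraction_log10=sim.true_fraction_log10,
        sample_dilutions_log10=tuple(sim.sample_dilutions_log10),
        calibration_dilutions_log10=tuple(sim.calibration_dilutions_log10),
        n_animals=sim.n_animals,
        seed=config.seed,
        main=sim.main,
        contaminant=sim.contaminant,
        reference=sim.reference,
        gain_spread=sim.gain_spread,
        acq_overrides=acq_overrides,
    )
    lib = default_library()
    qcfg = QuantifyConfig(
        window_halfwidth=config.analysis.window_halfwidth,
        prominence_mult=config.analysis.prominence_mult,
        detection_mult=config.analysis.detection_mult,
        saturation_frac=config.analysis.saturation_frac,
        alignment_search_window=config.analysis.alignment_search_window,
        mask_z=config.analysis.mask_z,
    )
    logger.info("quantify: contaminant=%s reference=%s",
                sim.contaminant, sim.reference)
    report = quantify_impurity(
        experiment.calibration, experiment.samples,
        contaminant=lib[sim.contaminant], reference=lib[sim.reference],
        config=qcfg,
    )
    out = {
        "odortrace_version": __version__,
        "config": config.model_dump(),
        "true_fraction_log10": experiment.true_fraction_log10,
        "report": report.to_dict(),
    }
    if report.estimate is not None:
        out["recovery_error_log10"] = (
            report.estimate.fraction_log10 - experiment.true_fraction_log10)
    return out


def write_report(report: dict, path: Path | str) -> Path:
    """Write a report as JSON, atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(report, fh, indent=1)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_report(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())
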