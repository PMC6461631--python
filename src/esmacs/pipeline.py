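"""End-to-end orchestration: energy tables → estimates → ranking report.

A :class:`RunConfig` names the input tables, the protocol and the
statistics settings; :func:`run_pipeline` produces a per-ligand estimates
CSV, a metrics CSV, a plain-text report and a run manifest (inputs, config
hash, seed, package version). Outputs are staged in a quarantine directory
and moved to their final names only when every stage has succeeded, so a
failed run never overwrites previous results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .engine import (ProtocolSpec, aggregate_estimates, estimates_to_frame)
from .io import read_energy_table, read_experimental_table
from .model import ValidationError
from .stats import BootstrapSpec, evaluate_protocol

log = logging.getLogger("esmacs")


@dataclass
class RunConfig:
    complex_csv: str
    experimental_csv: str | None = None
    receptor_csv: str | None = None
    ligand_csv: str | None = None
    out_dir: str = "esmacs_out"
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def validate_paths(self) -> None:
        for name in ("complex_csv", "experimental_csv", "receptor_csv", "ligand_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")


def _config_hash(config: RunConfig) -> str:
    doc = {
        "complex_csv": config.complex_csv,
        "experimental_csv": config.experimental_csv,
        "receptor_csv": config.receptor_csv,
        "ligand_csv": config.ligand_csv,
        "protocol": dataclasses.asdict(config.protocol),
        "bootstrap": dataclasses.asdict(config.bootstrap),
        "constants": dataclasses.asdict(config.constants),
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def format_report(metrics_rows: pd.DataFrame) -> str:
    """Metrics table as a plain-text report."""
    lines = ["Protocol performance (bootstrap errors in brackets)",
             "-" * 56]
    for _, row in metrics_rows.iterrows():
        lines.append(
            f"{row['protocol']:>9s}  n={int(row['n_ligands']):2d}  "
            f"cMUE {row['cmue']:.2f}({row['cmue_err']:.2f})  "
            f"PI {row['pi']:.2f}({row['pi_err']:.2f})  "
            f"r {row['r']:.2f}({row['r_err']:.2f})  "
            f"r_s {row['r_s']:.2f}({row['r_s_err']:.2f})")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Run aggregate (+ optional ranking); returns paths of the artifacts."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    staging = out_dir / ".staging"
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)

    log.info("reading complex energy table %s", config.complex_csv)
    complex_table = read_energy_table(Path(config.complex_csv))
    receptor_table = (read_energy_table(Path(config.receptor_csv))
                      if config.receptor_csv else None)
    ligand_table = (read_energy_table(Path(config.ligand_csv))
                    if config.ligand_csv else None)

    estimates = aggregate_estimates(
        config.protocol, complex_table, receptor_table, ligand_table,
        bootstrap=config.bootstrap, constants=config.constants)
    est_df = estimates_to_frame(estimates)
    est_df.to_csv(staging / "estimates.csv", index=False)
    artifacts = {"estimates": str(out_dir / "estimates.csv")}

    if config.experimental_csv:
        experimental = read_experimental_table(Path(config.experimental_csv))
        use_total = config.protocol.entropy == "variational"
        calc = {e.ligand_id: (e.total if use_total else e.dG) for e in estimates}
        metrics = evaluate_protocol(calc, experimental, config.bootstrap,
                                    config.constants)
        row = {"protocol": config.protocol.protocol, **metrics.as_dict()}
        metrics_df = pd.DataFrame([row])
        metrics_df.to_csv(staging / "metrics.csv", index=False)
        (staging / "report.txt").write_text(format_report(metrics_df))
        artifacts["metrics"] = str(out_dir / "metrics.csv")
        artifacts["report"] = str(out_dir / "report.txt")

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.bootstrap.seed,
        "esmacs_version": __version__,
        "inputs": {k: getattr(config, k) for k in
                   ("complex_csv", "receptor_csv", "ligand_csv", "experimental_csv")},
        "protocol": dataclasses.asdict(config.protocol),
    }
    (staging / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(out_dir / "run_manifest.json")

    # promote the staged outputs only after every stage succeeded
    for item in staging.iterdir():
        target = out_dir / item.name
        if target.exists():
            target.unlink()
        item.rename(target)
    staging.rmdir()
    return artifacts
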