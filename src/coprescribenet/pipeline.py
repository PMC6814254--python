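"""End-to-end orchestration: synth -> network -> centrality -> outcomes -> models.

A single :class:`RunConfig` drives a fully deterministic run.  Every
stage writes its artifact as delimited text into the run directory, and
a manifest records the seed, package version and a SHA-256 checksum per
file, so reruns with the same config are verifiable bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .centrality import CentralityParams, centrality_table
from .network import filter_opioid_claims
from .outcomes import assemble_panel
from .panel_models import run_model_suite, decompose, fit_glmm, margins
from .synth import SynthConfig, generate_study, write_tables

log = logging.getLogger("coprescribenet")

__all__ = ["RunConfig", "run", "validate_inputs", "verify_manifest"]


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    centrality: CentralityParams = field(default_factory=CentralityParams)
    window_width: int = 3
    out_dir: str = "run_out"
    metrics: tuple = ("pr_pct",)
    outcomes: tuple = ("n_rx", "mme_gt90", "overdose_any", "oud")
    samples: tuple = ("main",)
    margins_outcome: str | None = "n_rx"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        cent = CentralityParams(**raw.pop("centrality", {}))
        for key in ("metrics", "outcomes", "samples"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, centrality=cent, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("metrics", "outcomes", "samples"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Artifacts: the generated claims tables, a centrality table, the
    analysis panel, the model report, a margins grid, the echoed config
    and a checksum manifest.  A stage failure halts the run with the
    stage name; artifacts written so far are kept.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "synth"
    try:
        log.info("stage %s: generating synthetic study (seed=%d)", stage, config.synth.seed)
        study = generate_study(config.synth, centrality_params=config.centrality)
        write_tables(out, study["patients"], study["prescribers"], study["rx"],
                     study["dx"], truth=study["truth"])

        stage = "centrality"
        log.info("stage %s: scoring prominence on post-planting claims", stage)
        rx_f = filter_opioid_claims(study["rx"])
        cent = centrality_table(
            rx_f, config.synth.panel_quarters, params=config.centrality,
            width=config.window_width, max_quarter=config.synth.n_quarters - 1,
        )
        cent.to_csv(out / "centrality.csv", index=False)

        stage = "outcomes"
        log.info("stage %s: assembling the analysis panel", stage)
        panel = assemble_panel(
            study["patients"], study["rx"], study["dx"], cent,
            config.synth.panel_quarters,
        )
        panel.to_csv(out / "panel.csv", index=False)

        stage = "models"
        log.info("stage %s: fitting the model suite", stage)
        report = run_model_suite(
            panel, outcomes=config.outcomes, metrics=config.metrics,
            samples=config.samples,
        )
        report.to_csv(out / "model_report.csv", index=False)

        if config.margins_outcome:
            stage = "margins"
            df = decompose(panel, column=config.metrics[0],
                           scale=10.0 if config.metrics[0].endswith("_pct") else 1.0)
            res = fit_glmm(df, outcome=config.margins_outcome,
                           metric=config.metrics[0])
            grids = []
            for term in ("bp", "wp"):
                g = margins(res, df, term=term)
                g.insert(0, "term", term)
                grids.append(g)
            pd.concat(grids, ignore_index=True).to_csv(
                out / "margins.csv", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.synth.seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %s", out)
    return out


def verify_manifest(run_dir) -> list[str]:
    """Recompute checksums; returns the names of files that do not match."""
    out = Path(run_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for name, digest in manifest["files"].items():
        p = out / name
        if not p.exists() or _sha256(p) != digest:
            bad.append(name)
    return bad


_RX_SCHEMA = {
    "patient_id": "object", "prescriber_id": "object", "quarter": "int",
    "daily_dose_mg": "float", "mme_factor": "float", "is_mat": "int",
}
_DX_SCHEMA = {"patient_id": "object", "quarter": "int", "icd10_code": "object"}
_PT_SCHEMA = {
    "patient_id": "object", "female": "int", "age_years": "float",
    "insurance": "object", "state": "object",
}


def _check_table(df: pd.DataFrame, schema: dict, name: str, violations: list) -> None:
    for col in schema:
        if col not in df.columns:
            violations.append({"table": name, "error": f"missing column {col!r}"})
    if name == "prescriptions" and "daily_dose_mg" in df.columns:
        bad = df.index[df["daily_dose_mg"] <= 0]
        for i in list(bad[:20]):
            violations.append(
                {"table": name, "row": int(i), "error": "nonpositive daily_dose_mg"}
            )
    if "quarter" in df.columns and len(df):
        bad = df.index[df["quarter"] < 0]
        for i in list(bad[:20]):
            violations.append({"table": name, "row": int(i), "error": "negative quarter"})


def validate_inputs(
    patients_path, prescriptions_path, diagnoses_path
) -> list[dict]:
    """Schema / range / referential-integrity checks on external claims.

    Column order is irrelevant (tables are header-keyed).  Returns a
    list of violation records; empty means the inputs are usable.
    """
    violations: list[dict] = []
    patients = pd.read_csv(patients_path)
    rx = pd.read_csv(prescriptions_path)
    dx = pd.read_csv(diagnoses_path)
    _check_table(patients, _PT_SCHEMA, "patients", violations)
    _check_table(rx, _RX_SCHEMA, "prescriptions", violations)
    _check_table(dx, _DX_SCHEMA, "diagnoses", violations)
    if "patient_id" in rx.columns and "patient_id" in patients.columns:
        known = set(patients["patient_id"])
        orphans = rx.loc[~rx["patient_id"].isin(known)]
        for i in list(orphans.index[:20]):
            violations.append(
                {"table": "prescriptions", "row": int(i),
                 "error": "patient_id not in patients table"}
            )
    return violations
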