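"""Plain-text input/output: curves, cohort manifests, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CalibrationDataset, PatientRecord, TruthParameters
from .metrics import EnhancementMetrics
from .pbpk import ContrastAgent, InjectionProtocol, PatientModel
from .transport import SolverSettings, TimeDensityCurve

__all__ = [
    "write_curve", "read_curve", "write_dataset", "read_dataset",
    "load_config", "protocol_from_config", "patient_from_config",
    "settings_from_config",
]


def write_curve(curve: TimeDensityCurve, path) -> None:
    """One tabular text file: time (s), concentration (mgI/ml), HU."""
    frame = pd.DataFrame({
        "time_s": curve.time,
        "concentration_mgi_ml": curve.iodine_concentration,
        "enhancement_hu": curve.enhancement,
    })
    with open(path, "w") as fh:
        fh.write(f"# roi: {curve.roi}\n# baseline_hu: {curve.baseline_hu}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_curve(path) -> TimeDensityCurve:
    roi, baseline = "unknown", 0.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "roi":
                roi = val.strip()
            elif key.strip() == "baseline_hu":
                baseline = float(val)
    frame = pd.read_csv(path, sep="\t", comment="#")
    return TimeDensityCurve(
        roi=roi, time=frame["time_s"].to_numpy(),
        iodine_concentration=frame["concentration_mgi_ml"].to_numpy(),
        enhancement=frame["enhancement_hu"].to_numpy(), baseline_hu=baseline)


def write_dataset(dataset: CalibrationDataset, directory) -> None:
    """Manifest table plus one curve file per patient."""
    directory = Path(directory)
    (directory / "curves").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in dataset.records:
        row = {"patient_id": r.patient_id, "height_cm": r.patient.height,
               "weight_kg": r.patient.weight,
               "cardiac_output_ml_min": r.patient.cardiac_output,
               "in_calibration_split":
                   r.patient_id in dataset.calibration_ids}
        for tag, m in (("measured", r.measured), ("truth", r.truth)):
            row[f"{tag}_at_s"] = m.cm_at if m else np.nan
            row[f"{tag}_pt_s"] = m.pt if m else np.nan
            row[f"{tag}_pctn_hu"] = m.pctn if m else np.nan
        rows.append(row)
        write_curve(r.curve, directory / "curves" / f"{r.patient_id}.tsv")
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t",
                              index=False)
    meta = {"truth": None if dataset.truth is None else vars(dataset.truth),
            "out_of_band_fraction": dataset.out_of_band_fraction}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(directory) -> CalibrationDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    records, cal_ids = [], []
    for row in manifest.itertuples(index=False):
        patient = PatientModel(height=row.height_cm, weight=row.weight_kg,
                               cardiac_output=row.cardiac_output_ml_min)
        curve = read_curve(directory / "curves" / f"{row.patient_id}.tsv")

        def metrics_of(prefix):
            at = getattr(row, f"{prefix}_at_s")
            if np.isnan(at):
                return None
            return EnhancementMetrics(
                cm_at=at, pt=getattr(row, f"{prefix}_pt_s"),
                pctn=getattr(row, f"{prefix}_pctn_hu"))

        records.append(PatientRecord(
            patient_id=row.patient_id, patient=patient, curve=curve,
            measured=metrics_of("measured"), truth=metrics_of("truth")))
        if row.in_calibration_split:
            cal_ids.append(row.patient_id)
    truth = None
    meta_path = directory / "meta.json"
    out_frac = 0.0
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("truth"):
            truth = TruthParameters(**meta["truth"])
        out_frac = meta.get("out_of_band_fraction", 0.0)
    return CalibrationDataset(records=records, calibration_ids=tuple(cal_ids),
                              truth=truth, out_of_band_fraction=out_frac)


# --------------------------------------------------------------------------
# configuration files
# --------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def patient_from_config(cfg: dict) -> PatientModel:
    p = cfg.get("patient", cfg)
    return PatientModel(height=p["height_cm"], weight=p["weight_kg"],
                        cardiac_output=p.get("cardiac_output_ml_min"),
                        pulse_rate=p.get("pulse_rate"))


def protocol_from_config(cfg: dict) -> InjectionProtocol:
    a = cfg["agent"]
    agent = ContrastAgent(
        name=a.get("name", "custom"),
        iodine_concentration=a["iodine_concentration_mgi_ml"],
        viscosity=a["viscosity_mpas"],
        osmotic_ratio=a.get("osmotic_ratio"),
        osmolality=a.get("osmolality_mosm_kg"))
    pr = cfg["protocol"]
    return InjectionProtocol(
        cm_volume=pr["cm_volume_ml"], agent=agent,
        injection_duration=pr.get("injection_duration_s"),
        injection_rate=pr.get("injection_rate_ml_s"),
        flush_volume=pr.get("flush_volume_ml", 0.0),
        flush_rate=pr.get("flush_rate_ml_s"))


def settings_from_config(cfg: dict) -> SolverSettings:
    s = cfg.get("solver", {})
    defaults = SolverSettings()
    return SolverSettings(
        dt=s.get("dt_s", defaults.dt),
        horizon=s.get("horizon_s", defaults.horizon),
        hu_per_mgi_ml=s.get("hu_per_mgi_ml", defaults.hu_per_mgi_ml),
        k_ref=s.get("k_ref", defaults.k_ref),
        n_sub=s.get("n_sub", defaults.n_sub),
        readout=s.get("readout", defaults.readout),
        diffusion_mode=s.get("diffusion_mode", defaults.diffusion_mode))
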