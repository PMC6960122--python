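"""End-to-end pipeline orchestration, file I/O and run manifests.

Stage chain: simulate (optional) -> extract -> delta -> select -> respond
-> survive. Every stage reads and writes plain CSV/JSON artifacts in the
output directory, so each is idempotent and resumable from its on-disk
inputs; a run manifest (JSON) records the resolved configuration, input
digests and per-stage row counts, and suffices to reproduce the run.

Volumes travel as uncompressed NIfTI (.nii) referenced from a manifest CSV
(patient_id, fraction, image_path, mask_path). All randomness flows from
the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import delta as delta_mod
from . import response as resp_mod
from . import survival as surv_mod
from .selection import SelectionConfig, run_selection
from .simulate import CohortConfig, generate_cohort, week_of_fraction
from .textures import FeatureConfig, InputError, VolumeROI, extract_feature_table

__all__ = [
    "PipelineConfig",
    "StageError",
    "write_volume",
    "read_volume_pair",
    "load_volumes_from_manifest",
    "validate_inputs",
    "run_pipeline",
]

log = logging.getLogger("deltarad")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    detection_alpha: float = 0.05
    detection_mode: str = "sustained"
    max_survival_drfs: int = 3
    seed: int = 0

    def to_yaml(self) -> str:
        d = {
            "cohort": self.cohort.as_dict(),
            "features": {
                "n_levels": self.features.n_levels,
                "glcm_distance": self.features.glcm_distance,
                "nestd_radius": self.features.nestd_radius,
            },
            "selection": dataclasses.asdict(self.selection),
            "detection_alpha": self.detection_alpha,
            "detection_mode": self.detection_mode,
            "max_survival_drfs": self.max_survival_drfs,
            "seed": self.seed,
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        ch = d.get("cohort", {})
        if "volume_shape" in ch:
            ch["volume_shape"] = tuple(ch["volume_shape"])
        if "ca199_schedule" in ch:
            ch["ca199_schedule"] = tuple(ch["ca199_schedule"])
        cfg = cls(
            cohort=CohortConfig(**ch),
            features=FeatureConfig(**d.get("features", {})),
            selection=SelectionConfig(**d.get("selection", {})),
            detection_alpha=d.get("detection_alpha", 0.05),
            detection_mode=d.get("detection_mode", "sustained"),
            max_survival_drfs=d.get("max_survival_drfs", 3),
            seed=d.get("seed", 0),
        )
        return cfg


# ---------------------------------------------------------------------------
# volume I/O

def write_volume(vol: VolumeROI, image_path: Path, mask_path: Path) -> None:
    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), image_path)
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), mask_path)


def read_volume_pair(image_path: Path, mask_path: Path) -> VolumeROI:
    if not Path(image_path).exists():
        raise InputError(f"missing image file: {image_path}")
    if not Path(mask_path).exists():
        raise InputError(f"missing mask file: {mask_path}")
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj) > 0
    if data.shape != mask.shape:
        raise InputError(
            f"shape mismatch between {image_path} and {mask_path}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeROI(data, mask, spacing=zooms)


def load_volumes_from_manifest(manifest: pd.DataFrame, root: Path):
    volumes: dict[str, dict[int, VolumeROI]] = {}
    for _, row in manifest.iterrows():
        vol = read_volume_pair(root / row["image_path"], root / row["mask_path"])
        volumes.setdefault(str(row["patient_id"]), {})[int(row["fraction"])] = vol
    return volumes


# ---------------------------------------------------------------------------
# validation

def validate_inputs(tables: dict[str, pd.DataFrame]) -> dict:
    """Inclusion/exclusion screen across the cohort tables.

    Checks: a fraction-1 entry per patient in the imaging manifest or
    feature table, a CA19-9 baseline (fraction 0), a response label, a
    survival record with positive time, and duplicate-key sanity.
    Returns {"included": [...], "excluded": {pid: reason}, "errors": [...]}.
    """
    errors: list[str] = []
    excluded: dict[str, str] = {}
    labels = tables.get("labels")
    ca = tables.get("ca199")
    surv = tables.get("survival")
    feats = tables.get("features")
    manifest = tables.get("manifest")

    if labels is None or ca is None:
        raise ValueError("labels and ca199 tables are required")
    pids = list(labels["patient_id"].astype(str))
    if labels["patient_id"].duplicated().any():
        errors.append("duplicate patient_id in labels")
    if feats is not None and feats.duplicated(
        ["patient_id", "fraction", "feature"]
    ).any():
        errors.append("duplicate (patient, fraction, feature) rows in features")
    if errors:
        raise ValueError("; ".join(errors))

    for pid in pids:
        sub = ca[ca["patient_id"].astype(str) == pid]
        if 0 not in set(sub["fraction"]):
            excluded[pid] = "no CA19-9 baseline sample"
            continue
        if len(sub) < 2:
            excluded[pid] = "no CA19-9 samples within/after the course"
            continue
        if (sub["value"] <= 0).any():
            excluded[pid] = "non-positive CA19-9 value"
            continue
        grp = labels.loc[labels["patient_id"].astype(str) == pid, "group"].iloc[0]
        if grp not in ("good", "bad"):
            excluded[pid] = f"unknown response group {grp!r}"
            continue
        if surv is not None:
            srow = surv[surv["patient_id"].astype(str) == pid]
            if len(srow) == 0 or (srow["time_months"] <= 0).any():
                excluded[pid] = "missing or non-positive survival time"
                continue
        src = feats if feats is not None else manifest
        if src is not None:
            fr = src[src["patient_id"].astype(str) == pid]["fraction"]
            if 1 not in set(fr):
                excluded[pid] = "no fraction-1 volume"
                continue
    included = [p for p in pids if p not in excluded]
    return {"included": included, "excluded": excluded, "errors": errors}


# ---------------------------------------------------------------------------
# stages

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _round_floats(obj, ndigits=12):
    """Round floats to 12 significant digits so that last-bit solver jitter
    (e.g. BLAS threading inside scikit-learn) cannot break byte-identical
    re-runs of the same seed."""
    if isinstance(obj, float):
        return float(f"{obj:.{ndigits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.floating):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(
        json.dumps(_round_floats(obj), indent=1, sort_keys=True, default=float) + "\n"
    )


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    cohort = generate_cohort(cfg.cohort, with_volumes=True)
    voldir = out / "volumes"
    voldir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, fracs in cohort.volumes.items():
        for frac, vol in fracs.items():
            ip = voldir / f"{pid}_f{frac:02d}_img.nii"
            mp = voldir / f"{pid}_f{frac:02d}_msk.nii"
            write_volume(vol, ip, mp)
            rows.append((pid, frac, str(ip.relative_to(out)), str(mp.relative_to(out))))
    manifest = pd.DataFrame(
        rows, columns=["patient_id", "fraction", "image_path", "mask_path"]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    cohort.ca199.to_csv(out / "ca199.csv", index=False)
    cohort.labels.to_csv(out / "labels.csv", index=False)
    cohort.survival.to_csv(out / "survival.csv", index=False)
    _write_json(out / "truth.json", cohort.truth)
    return {"volumes": len(rows), "patients": cfg.cohort.n_patients}


def stage_extract(cfg: PipelineConfig, out: Path) -> dict:
    manifest = pd.read_csv(out / "manifest.csv")
    try:
        volumes = load_volumes_from_manifest(manifest, out)
        table = extract_feature_table(volumes, cfg.features)
    except InputError as e:
        raise StageError("extract", str(e)) from e
    table.to_csv(out / "features.csv", index=False)
    _write_json(out / "extraction_params.json", cfg.features.as_dict())
    return {"feature_rows": len(table)}


def stage_delta(cfg: PipelineConfig, out: Path) -> dict:
    feats = pd.read_csv(out / "features.csv")
    ca = pd.read_csv(out / "ca199.csv")
    labels = pd.read_csv(out / "labels.csv")
    drf, drf_skipped = delta_mod.compute_drf(feats)
    cac, ca_skipped = delta_mod.normalize_ca199(ca)
    drf.to_csv(out / "drf.csv", index=False)
    cac.to_csv(out / "ca199_change.csv", index=False)
    weekly_drf = delta_mod.aggregate_weekly(drf, labels, extra_keys=("feature",))
    weekly_ca = delta_mod.aggregate_weekly(cac, labels)
    weekly_ca.insert(2, "feature", "ca199")
    weekly = pd.concat([weekly_drf, weekly_ca], ignore_index=True)
    weekly.to_csv(out / "weekly.csv", index=False)
    return {
        "drf_rows": len(drf),
        "ca199_change_rows": len(cac),
        "skipped": [str(s) for s in drf_skipped + ca_skipped],
    }


def stage_select(cfg: PipelineConfig, out: Path) -> dict:
    drf = pd.read_csv(out / "drf.csv")
    labels = pd.read_csv(out / "labels.csv")
    report = run_selection(drf, labels, cfg.selection)
    report.to_csv(out / "selection_report.csv", index=False)
    return {
        "features": len(report),
        "selected": int(report["selected"].sum()),
    }


def _weekly_biomarker_values(
    drf: pd.DataFrame, cac: pd.DataFrame, features: list[str]
) -> pd.DataFrame:
    d = drf[drf["feature"].isin(features)].copy()
    d["week"] = week_of_fraction(d["fraction"])
    d = (
        d.groupby(["patient_id", "week", "feature"])["value"].mean().reset_index()
        .rename(columns={"feature": "biomarker"})
    )
    c = cac.copy()
    c["week"] = week_of_fraction(c["fraction"])
    c = c.sort_values("fraction").groupby(["patient_id", "week"]).tail(1)
    c = c[["patient_id", "week", "value"]]
    c["biomarker"] = "ca199"
    return pd.concat([d, c[["patient_id", "week", "biomarker", "value"]]], ignore_index=True)


def stage_respond(cfg: PipelineConfig, out: Path) -> dict:
    drf = pd.read_csv(out / "drf.csv")
    cac = pd.read_csv(out / "ca199_change.csv")
    labels = pd.read_csv(out / "labels.csv")
    report = pd.read_csv(out / "selection_report.csv")
    selected = report.loc[report["selected"], "feature"].tolist()
    if not selected:
        log.warning("no features selected; response model uses CA19-9 only")

    results = {}
    sets = {"ca199": []}
    if selected:
        sets["drf"] = selected
        sets["combined"] = selected
    for name, feats in sets.items():
        X, y = resp_mod.build_predictor_set(drf, cac, labels, feats)
        if name == "drf":
            X = X.drop(columns=["ca199_change"])
        fit = resp_mod.fit_response_model(X, y)
        results[name] = {
            "predictors": fit.predictors,
            "coefficients": fit.coefficients,
            "intercept": fit.intercept,
            "c_index": fit.c_index,
            "n": fit.n,
            "separation": fit.separation_flag,
        }
    _write_json(out / "response_model.json", results)

    weekly = _weekly_biomarker_values(drf, cac, selected)
    det_rows = []
    for name in sets:
        if name == "ca199":
            vals = weekly[weekly["biomarker"] == "ca199"]
        elif name == "drf":
            vals = resp_mod.combined_weekly_biomarker(
                weekly[weekly["biomarker"] != "ca199"]
            )
        else:
            vals = resp_mod.combined_weekly_biomarker(weekly)
        if "biomarker" in vals.columns:
            vals = vals[["patient_id", "week", "value"]]
        det = resp_mod.earliest_detection_week(
            vals, labels, alpha=cfg.detection_alpha, mode=cfg.detection_mode
        )
        for w, p in sorted(det.p_by_week.items()):
            det_rows.append((name, w, p, det.detection_week))
    pd.DataFrame(
        det_rows, columns=["biomarker_set", "week", "p", "detection_week"]
    ).to_csv(out / "detection_weeks.csv", index=False)
    return {"models": list(results), "selected_features": selected}


def stage_survive(cfg: PipelineConfig, out: Path) -> dict:
    surv = pd.read_csv(out / "survival.csv")
    cac = pd.read_csv(out / "ca199_change.csv")
    drf = pd.read_csv(out / "drf.csv")
    labels = pd.read_csv(out / "labels.csv")
    report = pd.read_csv(out / "selection_report.csv")
    selected = report.loc[report["selected"], "feature"].tolist()
    drf_names = selected[: cfg.max_survival_drfs]

    grouping = surv_mod.ca199_direction_group(cac)
    km = surv_mod.km_estimate(surv, grouping)
    curves = []
    for g, res in km.items():
        c = res.curve.copy()
        c.insert(0, "group", g)
        curves.append(c)
    pd.concat(curves, ignore_index=True).to_csv(out / "km_curves.csv", index=False)

    X, _ = resp_mod.build_predictor_set(drf, cac, labels, drf_names)
    X = X.rename(columns={f"drf_{f}": f for f in drf_names})
    ladder = (
        surv_mod.combined_prognostic_analysis(surv, X, drf_names)
        if drf_names
        else surv_mod.combined_prognostic_analysis(surv, X, [])
    )
    ladder.to_csv(out / "cox_ladder.csv", index=False)
    report_obj = {
        "km": {
            g: {
                "n": r.n,
                "events": r.n_events,
                "median_months": r.median,
                "survival_at_60m": r.survival_at_60,
            }
            for g, r in km.items()
        },
        "cox_ladder": ladder.to_dict(orient="records"),
    }
    _write_json(out / "survival_report.json", report_obj)
    return {"km_groups": list(km), "cox_models": len(ladder)}


STAGES = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "delta": stage_delta,
    "select": stage_select,
    "respond": stage_respond,
    "survive": stage_survive,
}


def run_pipeline(
    cfg: PipelineConfig,
    out: Path,
    stages: tuple[str, ...] = ("simulate", "extract", "delta", "select", "respond", "survive"),
) -> dict:
    """Run the stage chain, writing artifacts and a run manifest under out.

    Raises StageError naming the failing stage; the manifest of completed
    stages is still written.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cfg.cohort.seed = cfg.seed
    manifest: dict = {
        "package": "deltarad",
        "config": yaml.safe_load(cfg.to_yaml()),
        "stages": {},
        "inputs": {},
    }
    try:
        for name in stages:
            log.info("stage %s", name)
            try:
                counts = STAGES[name](cfg, out)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, str(e)) from e
            manifest["stages"][name] = counts
    finally:
        for f in sorted(out.glob("*.csv")):
            manifest["inputs"][f.name] = _digest(f)
        _write_json(out / "run_manifest.json", manifest)
    return manifest
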