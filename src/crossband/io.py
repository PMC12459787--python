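"""Plain-text readers and writers for the on-disk dataset layout.

Layout written by the simulator and consumed by the CLI::

    out/
      atlas.tsv
      dataset.json              # TR, EEG rate, subject/run listing
      ground_truth.json         # latents, memberships, gains, artifacts
      sub-01/
        run-01_bold_parcels.tsv # tr_index + one column per region
        run-01_motion.tsv
        run-01_eeg.csv          # time_s, O1, O2, Oz

All files are UTF-8, tab- (TSV) or comma- (CSV) delimited, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, load_atlas, write_atlas
from .data import Dataset, InvalidDataError, MotionTrace, ParcellatedRun, RawEEG, RunRecord
from .synth import SyntheticGroundTruth

__all__ = [
    "write_dataset", "read_dataset", "read_parcellated_run",
    "write_parcellated_run", "write_power_table", "read_power_table",
]

_FLOAT_FMT = "%.10g"


def write_parcellated_run(run: ParcellatedRun, path) -> None:
    df = pd.DataFrame(run.data, columns=run.region_labels)
    df.insert(0, "tr_index", np.arange(run.n_tr))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_parcellated_run(path, atlas: RegionAtlas, tr_seconds: float,
                         subject_id: str, run_id: str) -> ParcellatedRun:
    """Read a parcel TSV; column order is normalized to atlas order."""
    df = pd.read_csv(path, sep="\t")
    missing = [n for n in atlas.names if n not in df.columns]
    if missing:
        raise InvalidDataError(f"parcel table missing regions: {missing}")
    extra = [c for c in df.columns if c not in atlas.names and c != "tr_index"]
    if extra:
        import warnings
        warnings.warn(f"ignoring unknown columns: {extra}")
    data = df[atlas.names].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        bad = int(np.flatnonzero(~np.isfinite(data).all(axis=1))[0])
        raise InvalidDataError(f"non-numeric or non-finite value at row {bad}")
    return ParcellatedRun(data, list(atlas.names), tr_seconds, subject_id, run_id)


def write_power_table(power: dict, path) -> None:
    """TSV with tr_index and one column per band (artifact as artifact40_52)."""
    cols = {"tr_index": np.arange(len(next(iter(power.values())).values))}
    for name, series in power.items():
        col = "artifact40_52" if name == "artifact" else name
        cols[col] = series.values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_power_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _truth_to_json(truth: SyntheticGroundTruth) -> dict:
    return {
        "latent_names": truth.latent_names,
        "memberships": truth.memberships,
        "subject_gains": truth.subject_gains,
        "alpha_weights": truth.alpha_weights,
        "delta_weights": truth.delta_weights,
        "artifact_tr_indices": truth.artifact_tr_indices,
        "has_alpha": truth.has_alpha,
        "latents": {k: np.round(v, 8).tolist() for k, v in truth.latents.items()},
    }


def _truth_from_json(obj: dict) -> SyntheticGroundTruth:
    return SyntheticGroundTruth(
        latents={k: np.asarray(v) for k, v in obj["latents"].items()},
        latent_names=obj["latent_names"], memberships=obj["memberships"],
        subject_gains=obj["subject_gains"], alpha_weights=obj["alpha_weights"],
        delta_weights=obj["delta_weights"],
        artifact_tr_indices=obj["artifact_tr_indices"],
        has_alpha=obj["has_alpha"])


def write_dataset(dataset: Dataset, outdir,
                  truth: SyntheticGroundTruth | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(dataset.atlas, out / "atlas.tsv")
    meta = {
        "dataset_id": dataset.dataset_id,
        "tr_seconds": dataset.tr_seconds,
        "eeg_fs": dataset.runs[0].eeg.fs,
        "has_alpha": dataset.has_alpha,
        "runs": [{"subject_id": r.subject_id, "run_id": r.run_id}
                 for r in dataset.runs],
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for run in dataset.runs:
        sub_dir = out / run.subject_id
        sub_dir.mkdir(exist_ok=True)
        write_parcellated_run(run.parcels, sub_dir / f"{run.run_id}_bold_parcels.tsv")
        pd.DataFrame({"tr_index": np.arange(len(run.motion)),
                      "displacement_mm": run.motion.displacement_mm}).to_csv(
            sub_dir / f"{run.run_id}_motion.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        eeg_cols = {"time_s": run.eeg.times()}
        eeg_cols.update(run.eeg.channels)
        pd.DataFrame(eeg_cols).to_csv(sub_dir / f"{run.run_id}_eeg.csv",
                                      index=False, float_format=_FLOAT_FMT)
    if truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(_truth_to_json(truth), sort_keys=True))


def read_dataset(indir) -> tuple[Dataset, SyntheticGroundTruth | None]:
    src = Path(indir)
    atlas = load_atlas(src / "atlas.tsv")
    meta = json.loads((src / "dataset.json").read_text())
    runs = []
    for entry in meta["runs"]:
        sub, rid = entry["subject_id"], entry["run_id"]
        sub_dir = src / sub
        parcel_path = sub_dir / f"{rid}_bold_parcels.tsv"
        if not parcel_path.exists():
            raise InvalidDataError(f"missing parcel file for {sub}/{rid}")
        parcels = read_parcellated_run(parcel_path, atlas, meta["tr_seconds"], sub, rid)
        motion = pd.read_csv(sub_dir / f"{rid}_motion.tsv", sep="\t")
        eeg_path = sub_dir / f"{rid}_eeg.csv"
        if not eeg_path.exists():
            raise InvalidDataError(f"missing EEG file for {sub}/{rid}")
        eeg_df = pd.read_csv(eeg_path)
        channels = {c: eeg_df[c].to_numpy() for c in eeg_df.columns if c != "time_s"}
        t0 = float(eeg_df["time_s"].iloc[0])
        fs = meta["eeg_fs"]
        runs.append(RunRecord(
            parcels=parcels,
            motion=MotionTrace(motion["displacement_mm"].to_numpy()),
            eeg=RawEEG(channels=channels, fs=fs, start_time=t0)))
    truth = None
    truth_path = src / "ground_truth.json"
    if truth_path.exists():
        truth = _truth_from_json(json.loads(truth_path.read_text()))
    return Dataset(runs=runs, atlas=atlas, has_alpha=meta.get("has_alpha", {}),
                   dataset_id=meta.get("dataset_id", "A")), truth
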