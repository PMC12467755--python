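"""Readers and writers for the package's on-disk formats.

Keypoint trajectories travel as tidy CSV (one row per frame per joint:
``frame, time_s, joint, x_m, y_m, valid``) or as a JSON dialect (top-level
``times`` array plus per-joint objects with ``x``, ``y``, ``valid`` arrays).
Hold maps and run metadata are YAML or CSV; a cohort manifest is a CSV with
one row per run pointing at the keypoint file and carrying the metadata
fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import HoldMap, KeypointTrack, RunMetadata

KEYPOINT_COLUMNS = ["frame", "time_s", "joint", "x_m", "y_m", "valid"]
METADATA_FIELDS = ["run_id", "athlete_id", "sex", "technique", "ts", "tgt",
                   "frame_rate"]


# -- keypoints ---------------------------------------------------------------

def read_keypoints_csv(path) -> dict:
    """Read a keypoint CSV into a dict joint_name -> KeypointTrack."""
    df = pd.read_csv(path)
    missing = [c for c in KEYPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"keypoint CSV missing columns {missing}")
    tracks = {}
    for joint, g in df.groupby("joint", sort=True):
        g = g.sort_values("frame")
        tracks[joint] = KeypointTrack(
            joint_name=joint,
            times=g["time_s"].to_numpy(),
            positions=g[["x_m", "y_m"]].to_numpy(),
            valid_mask=g["valid"].to_numpy(dtype=bool),
        )
    return tracks


def write_keypoints_csv(tracks: dict, path) -> None:
    frames = []
    for joint in sorted(tracks):
        t = tracks[joint]
        frames.append(pd.DataFrame({
            "frame": np.arange(len(t)),
            "time_s": t.times,
            "joint": joint,
            "x_m": t.x,
            "y_m": t.y,
            "valid": t.valid_mask.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_keypoints_json(path) -> dict:
    """Read the JSON keypoint dialect (shared time base, per-joint arrays)."""
    with open(path) as fh:
        doc = json.load(fh)
    times = np.asarray(doc["times"], dtype=float)
    tracks = {}
    for joint, arrs in doc["joints"].items():
        pos = np.column_stack([arrs["x"], arrs["y"]])
        valid = np.asarray(arrs.get("valid", np.ones(len(times))), dtype=bool)
        tracks[joint] = KeypointTrack(joint, times, pos, valid)
    return tracks


def write_keypoints_json(tracks: dict, path) -> None:
    ref = next(iter(tracks.values()))
    doc = {"times": ref.times.tolist(), "joints": {}}
    for joint in sorted(tracks):
        t = tracks[joint]
        doc["joints"][joint] = {
            "x": t.x.tolist(), "y": t.y.tolist(),
            "valid": t.valid_mask.astype(int).tolist(),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# -- hold map ----------------------------------------------------------------

def read_hold_map(path) -> HoldMap:
    """Read a hold map from YAML (mapping or list) or CSV
    (columns hold_index, height_m)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        heights = doc["holds"] if isinstance(doc, dict) else doc
        return HoldMap(np.asarray(heights, dtype=float))
    df = pd.read_csv(path).sort_values("hold_index")
    return HoldMap(df["height_m"].to_numpy())


def write_hold_map(hold_map: HoldMap, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "w") as fh:
            yaml.safe_dump({"holds": [float(h) for h in hold_map.heights]}, fh)
    else:
        pd.DataFrame({
            "hold_index": np.arange(1, 21),
            "height_m": hold_map.heights,
        }).to_csv(path, index=False)


# -- run metadata ------------------------------------------------------------

def read_metadata(path) -> RunMetadata:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = pd.read_csv(path).iloc[0].to_dict()
    return RunMetadata(**{k: doc[k] for k in METADATA_FIELDS})


def write_metadata(meta: RunMetadata, path) -> None:
    doc = {k: getattr(meta, k) for k in METADATA_FIELDS}
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)
    else:
        pd.DataFrame([doc]).to_csv(path, index=False)


# -- cohort manifest ---------------------------------------------------------

def write_cohort(cohort, out_dir, fmt: str = "csv") -> Path:
    """Materialise a synthetic cohort: keypoint files plus a manifest CSV.

    Returns the manifest path.  The manifest has one row per run with the
    keypoint file path (relative to the manifest) and the metadata fields.
    """
    out_dir = Path(out_dir)
    (out_dir / "runs").mkdir(parents=True, exist_ok=True)
    rows = []
    for (tracks, meta, truth), cfg in zip(cohort.assemble(), cohort.configs):
        fname = f"runs/{meta.run_id}.{ 'json' if fmt == 'json' else 'csv' }"
        if fmt == "json":
            write_keypoints_json(tracks, out_dir / fname)
        else:
            write_keypoints_csv(tracks, out_dir / fname)
        row = {"keypoints": fname}
        row.update({k: getattr(meta, k) for k in METADATA_FIELDS})
        rows.append(row)
    write_hold_map(cohort.configs[0].hold_map, out_dir / "holds.csv")
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path):
    """Yield (tracks, RunMetadata) per manifest row."""
    path = Path(path)
    df = pd.read_csv(path)
    for _, row in df.iterrows():
        kp_path = path.parent / row["keypoints"]
        if kp_path.suffix.lower() == ".json":
            tracks = read_keypoints_json(kp_path)
        else:
            tracks = read_keypoints_csv(kp_path)
        meta = RunMetadata(**{k: row[k] for k in METADATA_FIELDS})
        yield tracks, meta
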