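"""Delimited-text readers and writers for every artifact the pipeline touches.

All formats are plain UTF-8 comma-separated text with headers and '.' decimal:
two-column ``(time_s, angle_deg)`` waveforms, the participants-by-features
table, square correlation/weight matrices, edge lists, and the per-participant
raw-recording layout used by the signal-extraction mode::

    <root>/P<id>/flexion-extension.csv      angle waveform per plane
    <root>/P<id>/rotation.csv
    <root>/P<id>/lateral-flexion.csv
    <root>/P<id>/relocation_trial<k>.csv    six marked relocation waveforms
    <root>/P<id>/relocation_markers.csv     (trial_id, start_index, end_index)
    <root>/P<id>/scalars.csv                strength peaks and TSK score
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import AngleWaveform

PLANES = ("flexion-extension", "rotation", "lateral-flexion")


def write_waveform(w: AngleWaveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": w.times, "angle_deg": w.samples}).to_csv(path, index=False)


def read_waveform(path: str | Path, plane: str | None = None) -> AngleWaveform:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        angle = df["angle_deg"].to_numpy(dtype=float)
    except (KeyError, ValueError) as err:
        raise ValueError(f"{path}: expected two-column (time_s, angle_deg) text: {err}") from err
    if t.size < 2:
        raise ValueError(f"{path}: waveform needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError(f"{path}: time column must be uniformly increasing")
    return AngleWaveform(angle, 1.0 / float(dt.mean()), plane or path.stem)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=True)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant" in df.columns:
        df = df.set_index("participant")
    return df


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix file must be square")
    return df


def write_cohort_recordings(cohort: dict, out_dir: str | Path) -> None:
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    for pid, rec in cohort.items():
        pdir = root / f"P{pid:03d}" if isinstance(pid, (int, np.integer)) else root / f"P{pid}"
        pdir.mkdir(exist_ok=True)
        for plane, w in rec["waveforms"].items():
            write_waveform(w, pdir / f"{plane}.csv")
        markers = []
        for k, trial in enumerate(rec["relocation"]):
            write_waveform(trial.waveform, pdir / f"relocation_trial{k}.csv")
            markers.append({"trial_id": k, "start_index": trial.start_index, "end_index": trial.end_index})
        pd.DataFrame(markers).to_csv(pdir / "relocation_markers.csv", index=False)
        pd.DataFrame([rec["scalars"]]).to_csv(pdir / "scalars.csv", index=False)


def read_cohort_recordings(root: str | Path) -> dict:
    from .simulate import RelocationTrial

    root = Path(root)
    cohort: dict = {}
    pdirs = sorted(d for d in root.iterdir() if d.is_dir() and d.name.startswith("P"))
    if not pdirs:
        raise ValueError(f"{root}: no participant directories (P*) found")
    for pdir in pdirs:
        waveforms = {}
        for plane in PLANES:
            f = pdir / f"{plane}.csv"
            if not f.exists():
                raise ValueError(f"{pdir.name}: missing waveform file {f.name}")
            waveforms[plane] = read_waveform(f, plane)
        markers = pd.read_csv(pdir / "relocation_markers.csv")
        trials = []
        for _, row in markers.sort_values("trial_id").iterrows():
            w = read_waveform(pdir / f"relocation_trial{int(row.trial_id)}.csv", "rotation")
            trials.append(RelocationTrial(w, int(row.start_index), int(row.end_index)))
        scalars = pd.read_csv(pdir / "scalars.csv").iloc[0].to_dict()
        cohort[pdir.name.lstrip("P").lstrip("0") or "0"] = {
            "waveforms": waveforms,
            "relocation": trials,
            "scalars": scalars,
        }
    return cohort
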