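"""On-disk formats: trial tables as TSV, cohorts as HDF5 + TSV.

The HDF5 container stores, per subject/channel, the epoched envelope (and
optionally raw) arrays under ``/envelopes`` and ``/raw``, the shared time
grid under ``/time``, coupled-pair envelopes under ``/pairs``, and the
channel ground truth as an attribute-free table; trial tables travel as
TSV next to the container so they stay human-readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "write_trials_tsv",
    "read_trials_tsv",
    "write_cohort",
    "read_cohort_arrays",
]

#: fixed column contract for behavioral trial tables
TRIAL_COLUMNS = [
    "trial_index", "block_index", "condition", "tolerance_ms",
    "rt_s", "outcome", "reward",
]


def write_trials_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table (optionally RL-augmented) as TSV."""
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table lacks required columns: {missing}")
    frame.to_csv(path, sep="\t", index=False)


def read_trials_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table lacks required columns: {missing}")
    return frame


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Persist a synthetic cohort: ``cohort.h5`` plus per-subject trial
    TSVs and a ground-truth TSV. Returns the HDF5 path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5_path = out / "cohort.h5"
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("time", data=np.asarray(cohort.time_grid, float))
        env = f.create_group("envelopes")
        for (subject, channel), arr in cohort.envelopes.items():
            env.create_dataset(f"{subject}/{channel}", data=arr)
        if cohort.raw:
            raw = f.create_group("raw")
            raw.create_dataset("times", data=np.asarray(cohort.raw_times, float))
            for (subject, channel), arr in cohort.raw.items():
                raw.create_dataset(f"{subject}/{channel}", data=arr)
        pairs = f.create_group("pairs")
        for (subject, ins, dmpfc), (a, b) in cohort.pair_envelopes.items():
            grp = pairs.create_group(f"{subject}/{ins}->{dmpfc}")
            grp.create_dataset("ins", data=a)
            grp.create_dataset("dmpfc", data=b)
        f.attrs["couplings"] = json.dumps(
            [c.__dict__ for c in cohort.couplings]
        )
    cohort.channel_table.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    for subject, frame in cohort.trials.items():
        write_trials_tsv(frame, out / f"trials_{subject}.tsv")
    return h5_path


def read_cohort_arrays(h5_path: str | Path) -> dict:
    """Load the array side of a cohort container: time grid, per-channel
    envelopes, per-pair envelope tuples, and coupling specs (as dicts)."""
    out: dict = {"envelopes": {}, "pairs": {}, "raw": {}}
    with h5py.File(h5_path, "r") as f:
        out["time"] = f["time"][()]
        for subject in f["envelopes"]:
            for channel in f[f"envelopes/{subject}"]:
                out["envelopes"][(subject, channel)] = f[
                    f"envelopes/{subject}/{channel}"
                ][()]
        for subject in f["pairs"]:
            for pair in f[f"pairs/{subject}"]:
                ins, dmpfc = pair.split("->")
                grp = f[f"pairs/{subject}/{pair}"]
                out["pairs"][(subject, ins, dmpfc)] = (
                    grp["ins"][()], grp["dmpfc"][()]
                )
        if "raw" in f:
            out["raw_times"] = f["raw/times"][()]
            for subject in f["raw"]:
                if subject == "times":
                    continue
                for channel in f[f"raw/{subject}"]:
                    out["raw"][(subject, channel)] = f[
                        f"raw/{subject}/{channel}"
                    ][()]
        out["couplings"] = json.loads(f.attrs["couplings"])
    return out
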