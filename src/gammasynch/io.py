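"""HDF5/CSV/YAML input-output for the documented data schemas.

HDF5 layout for trial-structured LFP::

    /subjects/<subject_id>/channels/<channel_id>/
        trials      (n_trials, n_samples)  float64
        mid_isi     (n_trials, n_mid)      float64
        prestim     (n_pre,)               float64
        stim_onsets (n_trials,)            float64
        attrs: sample_rate, trial_window, stim_duration, zscored

CSV schemas: spike times ``pair_id, unit_id, time_s``; sIPSC events
``pair_id, cell (a|b), time_s, amplitude_pa``; fluorescence cells
``integrated_density, area, background_mean, group, genotype``; Y-maze
``arm``; startle ``trial_type, amplitude``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import CellFluorescence, IPSCEventTrains, LFPTrialSet, SpikeTrainPair


def write_lfp_h5(path, trialsets: Iterable[LFPTrialSet], seed: int | None = None) -> None:
    """Write one or more LFP trial sets to the HDF5 schema above."""
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = int(seed)
        for ts in trialsets:
            g = f.require_group(f"subjects/{ts.subject_id}/channels/{ts.channel_id}")
            g.create_dataset("trials", data=ts.trials)
            g.create_dataset("mid_isi", data=ts.mid_isi)
            g.create_dataset("prestim", data=ts.prestim)
            g.create_dataset("stim_onsets", data=ts.stim_onsets)
            g.attrs["sample_rate"] = ts.sample_rate
            g.attrs["trial_window"] = list(ts.trial_window)
            g.attrs["stim_duration"] = ts.stim_duration
            g.attrs["zscored"] = ts.zscored


def read_lfp_h5(path) -> list[LFPTrialSet]:
    """Read every (subject, channel) trial set from an HDF5 file."""
    out: list[LFPTrialSet] = []
    with h5py.File(path, "r") as f:
        for sid in f["subjects"]:
            for cid in f[f"subjects/{sid}/channels"]:
                g = f[f"subjects/{sid}/channels/{cid}"]
                out.append(LFPTrialSet(
                    sample_rate=float(g.attrs["sample_rate"]),
                    trials=g["trials"][()],
                    mid_isi=g["mid_isi"][()],
                    prestim=g["prestim"][()],
                    stim_onsets=g["stim_onsets"][()],
                    trial_window=tuple(g.attrs["trial_window"]),
                    stim_duration=float(g.attrs["stim_duration"]),
                    subject_id=sid,
                    channel_id=cid,
                    zscored=bool(g.attrs["zscored"]),
                ))
    return out


def read_spike_pairs_csv(path, duration: float | None = None) -> dict[str, SpikeTrainPair]:
    """Read tetrode spike pairs keyed by ``pair_id``.

    Each pair must contain exactly two unit_ids.  ``duration`` defaults
    to the latest spike time rounded up to the next second.
    """
    df = pd.read_csv(path)
    required = {"pair_id", "unit_id", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"spike CSV needs columns {sorted(required)}")
    if duration is None:
        duration = float(np.ceil(df["time_s"].max()))
    pairs: dict[str, SpikeTrainPair] = {}
    for pid, grp in df.groupby("pair_id", sort=True):
        units = sorted(grp["unit_id"].unique())
        if len(units) != 2:
            raise ValueError(f"pair {pid!r} must have exactly 2 units, got {units}")
        times = [np.sort(grp.loc[grp["unit_id"] == u, "time_s"].to_numpy())
                 for u in units]
        pairs[str(pid)] = SpikeTrainPair(
            times_a=times[0], times_b=times[1], duration=duration,
            unit_ids=(str(units[0]), str(units[1])),
        )
    return pairs


def read_ipsc_events_csv(path, duration: float | None = None) -> dict[str, IPSCEventTrains]:
    """Read paired sIPSC event lists keyed by ``pair_id``."""
    df = pd.read_csv(path)
    required = {"pair_id", "cell", "time_s", "amplitude_pa"}
    if not required.issubset(df.columns):
        raise ValueError(f"sIPSC CSV needs columns {sorted(required)}")
    if duration is None:
        duration = float(np.ceil(df["time_s"].max()))
    pairs: dict[str, IPSCEventTrains] = {}
    for pid, grp in df.groupby("pair_id", sort=True):
        cells = {}
        for cell in ("a", "b"):
            sub = grp[grp["cell"] == cell].sort_values("time_s")
            cells[cell] = (sub["time_s"].to_numpy(), sub["amplitude_pa"].to_numpy())
        pairs[str(pid)] = IPSCEventTrains(
            times_a=cells["a"][0], amps_a=cells["a"][1],
            times_b=cells["b"][0], amps_b=cells["b"][1],
            duration=duration,
        )
    return pairs


def read_cells_csv(path) -> list[CellFluorescence]:
    df = pd.read_csv(path)
    required = {"integrated_density", "area", "background_mean"}
    if not required.issubset(df.columns):
        raise ValueError(f"cells CSV needs columns {sorted(required)}")
    return [
        CellFluorescence(
            integrated_density=row["integrated_density"],
            area=row["area"],
            background_mean=row["background_mean"],
            group=str(row.get("group", "non-PV")),
            genotype=str(row.get("genotype", "control")),
        )
        for _, row in df.iterrows()
    ]


def read_arm_entries_csv(path) -> list[str]:
    df = pd.read_csv(path)
    if "arm" not in df.columns:
        raise ValueError("Y-maze CSV needs an 'arm' column")
    return [str(a) for a in df["arm"]]


def read_startle_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_type", "amplitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"startle CSV needs columns {sorted(required)}")
    return df


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_yaml(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=True)
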