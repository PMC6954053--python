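"""Tabular on-disk schema for trial-structured datasets.

A dataset directory holds delimited text tables:

* ``spikes.csv``  — trial_id, electrode_id, spike_time_s
* ``events.csv``  — trial_id, condition, block, prompt_s, go_s, AO_s
  (empty for silent trials before faux-AO assignment), excluded
* ``hlfp.csv``    — trial_id, electrode_id, time_s, power (optional)
* ``meta.json``   — electrode ids, condition list, trial length, seed
* ``ground_truth.json`` — planted latents, written by the simulator CLI

Distance matrices are labeled CSV; trees are Newick.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DistanceMatrix
from .synthetic import Dataset, GroundTruth, Trial

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_ground_truth",
    "read_ground_truth",
    "write_distance_matrix",
    "read_distance_matrix",
]


def write_dataset(dataset: Dataset, out_dir: str | Path,
                  include_hlfp: bool = True) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spike_rows, event_rows, hlfp_frames = [], [], []
    for tid, tr in enumerate(dataset.trials):
        for e, st in zip(dataset.electrode_ids, tr.spike_times):
            for t in st:
                spike_rows.append((tid, e, float(t)))
        event_rows.append((tid, tr.condition, tr.block,
                           tr.events.get("prompt"), tr.events.get("go"),
                           tr.events.get("AO"), int(tr.excluded)))
        if include_hlfp and tr.hlfp_power is not None:
            n_t = tr.hlfp_times.size
            hlfp_frames.append(pd.DataFrame({
                "trial_id": tid,
                "electrode_id": np.repeat(dataset.electrode_ids, n_t),
                "time_s": np.tile(tr.hlfp_times, dataset.n_electrodes),
                "power": tr.hlfp_power.ravel(),
            }))
    pd.DataFrame(spike_rows, columns=["trial_id", "electrode_id",
                                      "spike_time_s"]).to_csv(
        out / "spikes.csv", index=False)
    pd.DataFrame(event_rows, columns=["trial_id", "condition", "block",
                                      "prompt_s", "go_s", "AO_s",
                                      "excluded"]).to_csv(
        out / "events.csv", index=False)
    if hlfp_frames:
        pd.concat(hlfp_frames).to_csv(out / "hlfp.csv", index=False,
                                      float_format="%.4f")
    (out / "meta.json").write_text(json.dumps({
        "electrode_ids": list(dataset.electrode_ids),
        "conditions": list(dataset.conditions),
        "silent_condition": dataset.silent_condition,
        "trial_length": dataset.trial_length,
        "meta": {k: v for k, v in dataset.meta.items()
                 if isinstance(v, (int, float, str))},
    }))


def read_dataset(in_dir: str | Path) -> Dataset:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    events = pd.read_csv(src / "events.csv")
    spikes = pd.read_csv(src / "spikes.csv")
    hlfp = None
    if (src / "hlfp.csv").exists():
        hlfp = pd.read_csv(src / "hlfp.csv")
    electrode_ids = list(meta["electrode_ids"])
    e_index = {e: i for i, e in enumerate(electrode_ids)}
    spike_groups = {k: g for k, g in spikes.groupby("trial_id")}
    hlfp_groups = {k: g for k, g in hlfp.groupby("trial_id")} if hlfp is not None else {}
    trials = []
    for row in events.itertuples():
        st: list[np.ndarray] = [np.empty(0) for _ in electrode_ids]
        g = spike_groups.get(row.trial_id)
        if g is not None:
            for e, sub in g.groupby("electrode_id"):
                st[e_index[e]] = np.sort(sub["spike_time_s"].to_numpy())
        hp = ht = None
        gh = hlfp_groups.get(row.trial_id)
        if gh is not None:
            ht = np.sort(gh["time_s"].unique())
            hp = np.zeros((len(electrode_ids), ht.size), dtype=np.float32)
            t_index = {t: i for i, t in enumerate(ht)}
            for e, sub in gh.groupby("electrode_id"):
                idx = [t_index[t] for t in sub["time_s"]]
                hp[e_index[e], idx] = sub["power"].to_numpy()
        ao = None if pd.isna(row.AO_s) else float(row.AO_s)
        trials.append(Trial(
            condition=row.condition, spike_times=st, hlfp_power=hp,
            hlfp_times=ht,
            events={"prompt": float(row.prompt_s), "go": float(row.go_s),
                    "AO": ao},
            block=int(row.block), excluded=bool(row.excluded)))
    return Dataset(trials=trials, electrode_ids=electrode_ids,
                   conditions=tuple(meta["conditions"]),
                   silent_condition=meta["silent_condition"],
                   trial_length=float(meta["trial_length"]),
                   meta=meta.get("meta", {}))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "cis_loading": truth.cis_loading.tolist(),
        "rot_plane": truth.rot_plane.tolist(),
        "prompt_loading": truth.prompt_loading.tolist(),
        "tuning_loadings": truth.tuning_loadings.tolist(),
        "baseline": truth.baseline.tolist(),
        "rot_freq": truth.rot_freq,
        "rot_phase": truth.rot_phase,
        "rot_amplitude": truth.rot_amplitude,
        "rot_onset_before_AO": truth.rot_onset_before_AO,
        "conditions": list(truth.conditions),
        "silent_condition": truth.silent_condition,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    p = json.loads(Path(path).read_text())
    return GroundTruth(
        cis_loading=np.asarray(p["cis_loading"]),
        rot_plane=np.asarray(p["rot_plane"]),
        prompt_loading=np.asarray(p["prompt_loading"]),
        tuning_loadings=np.asarray(p["tuning_loadings"]),
        baseline=np.asarray(p["baseline"]),
        rot_freq=p["rot_freq"], rot_phase=dict(p["rot_phase"]),
        rot_amplitude=p["rot_amplitude"],
        rot_onset_before_AO=p["rot_onset_before_AO"],
        conditions=tuple(p["conditions"]),
        silent_condition=p["silent_condition"])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.M, index=dm.labels, columns=dm.labels)
    df.insert(0, "group", [dm.groups[lab] for lab in dm.labels])
    df.to_csv(path)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    groups = dict(zip(df.index, df["group"]))
    m = df.drop(columns=["group"]).to_numpy(dtype=float)
    m = (m + m.T) / 2     # guard against round-trip asymmetry at print precision
    return DistanceMatrix(labels=list(df.index), groups=groups, M=m)
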