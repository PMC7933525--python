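"""File formats: TSV spike trains, JSON structures/ensembles, metrics.

Spike trains travel as TSV with columns ``branch_id`` (1-based, matching
the field convention ES_1..ES_n) and ``time_ms``; an optional ``pattern``
column packs several trains in one file.  Silent branches are simply
omitted rows.  Structures and ensembles serialise to JSON documents that
round-trip losslessly (binary64 via repr-exact floats).
"""

from __future__ import annotations

import json
import math
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .classifiers import Ensemble
from .lifl import NeuronParams
from .structure import NMNSDStructure, ParallelSpikeTrain, STDPParams

__all__ = [
    "write_train", "read_train", "write_trains", "read_trains",
    "structure_to_dict", "structure_from_dict",
    "write_structure", "read_structure",
    "ensemble_to_dict", "ensemble_from_dict",
    "write_ensemble", "read_ensemble",
    "write_metrics",
]

_COLS = ["branch_id", "time_ms"]


def write_train(x: ParallelSpikeTrain, path) -> None:
    """Write one parallel spike train as TSV (silent branches omitted)."""
    rows = [(i + 1, float(x.times[i])) for i in range(x.n)
            if not x.silent[i]]
    pd.DataFrame(rows, columns=_COLS).to_csv(path, sep="\t", index=False)


def _train_from_frame(df: pd.DataFrame, n: int | None,
                      origin: str) -> ParallelSpikeTrain:
    ids = df["branch_id"].to_numpy()
    if np.any(ids != ids.astype(int)) or np.any(ids < 1):
        raise ValueError(f"{origin}: branch ids must be 1-based integers")
    ids = ids.astype(int)
    dup = pd.Series(ids).duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{origin}: duplicate branch id {ids[row]} "
                         f"(row {row + 1}); one spike per branch")
    n = int(ids.max()) if n is None else n
    if ids.max() > n:
        raise ValueError(f"{origin}: branch id {ids.max()} exceeds n={n}")
    times = np.full(n, math.nan)
    times[ids - 1] = df["time_ms"].to_numpy(dtype=float)
    return ParallelSpikeTrain(times=times)


def read_train(path, n: int | None = None) -> ParallelSpikeTrain:
    """Read a single-pattern spike-train TSV.

    ``n`` forces the branch count (branches beyond the largest id present
    are silent); by default the largest id defines it.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty spike-train file")
    missing = [c for c in _COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return _train_from_frame(df, n, str(path))


def write_trains(trains: Sequence[ParallelSpikeTrain], path,
                 labels: Sequence[Hashable] | None = None) -> None:
    """Write several trains in one TSV using a ``pattern`` block column
    (and an optional ``label`` column)."""
    frames = []
    for k, x in enumerate(trains):
        rows = [(k, i + 1, float(x.times[i])) for i in range(x.n)
                if not x.silent[i]]
        df = pd.DataFrame(rows, columns=["pattern", *_COLS])
        if labels is not None:
            df["label"] = labels[k]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_trains(path, n: int | None = None):
    """Read a multi-pattern TSV; returns ``(trains, labels-or-None)``."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty spike-train file")
    if "pattern" not in df.columns:
        return [read_train(path, n)], None
    if n is None:
        n = int(df["branch_id"].max())
    trains, labels = [], []
    for k, grp in df.groupby("pattern", sort=True):
        trains.append(_train_from_frame(grp.reset_index(drop=True), n,
                                        f"{path} pattern {k}"))
        if "label" in df.columns:
            labels.append(grp["label"].iloc[0])
    return trains, (labels if labels else None)


def _params_to_dict(p: NeuronParams) -> dict:
    return {"d": p.d, "Ld": p.Ld, "S0": p.S0,
            "Smax": None if math.isinf(p.Smax) else p.Smax}


def _params_from_dict(d: dict) -> NeuronParams:
    return NeuronParams(d=d["d"], Ld=d["Ld"], S0=d.get("S0", 0.0),
                        Smax=math.inf if d.get("Smax") is None
                        else d["Smax"])


def structure_to_dict(s: NMNSDStructure,
                      stdp: STDPParams | None = None) -> dict:
    doc = {
        "n": s.n,
        "w_in": s.w_in.tolist(),
        "w_het": s.w_het.tolist(),
        "w_out": s.w_out.tolist(),
        "delay_params": _params_to_dict(s.delay_params),
        "target_params": _params_to_dict(s.target_params),
    }
    if stdp is not None:
        doc["stdp"] = {"A_plus": stdp.A_plus, "A_minus": stdp.A_minus,
                       "tau_plus": stdp.tau_plus,
                       "tau_minus": stdp.tau_minus}
    return doc


def structure_from_dict(doc: dict) -> NMNSDStructure:
    s = NMNSDStructure(
        w_in=np.array(doc["w_in"], dtype=float),
        w_out=np.array(doc["w_out"], dtype=float),
        w_het=np.array(doc["w_het"], dtype=float),
        delay_params=_params_from_dict(doc["delay_params"]),
        target_params=_params_from_dict(doc["target_params"]),
    )
    if s.n != doc["n"]:
        raise ValueError("structure document: inconsistent branch count")
    return s


def write_structure(s: NMNSDStructure, path,
                    stdp: STDPParams | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(structure_to_dict(s, stdp), fh, indent=2)


def read_structure(path) -> NMNSDStructure:
    with open(path) as fh:
        return structure_from_dict(json.load(fh))


def ensemble_to_dict(e: Ensemble) -> dict:
    return {
        "class_labels": [str(lab) for lab in e.class_labels],
        "redundancy": e.redundancy,
        "inhibition": e.inhibition,
        "structures": {str(lab): [structure_to_dict(st) for st in mods]
                       for lab, mods in e.structures.items()},
    }


def ensemble_from_dict(doc: dict) -> Ensemble:
    return Ensemble(
        structures={lab: [structure_from_dict(d) for d in mods]
                    for lab, mods in doc["structures"].items()},
        class_labels=list(doc["class_labels"]),
        redundancy=doc["redundancy"],
        inhibition=doc["inhibition"],
    )


def write_ensemble(e: Ensemble, path) -> None:
    with open(path, "w") as fh:
        json.dump(ensemble_to_dict(e), fh, indent=2)


def read_ensemble(path) -> Ensemble:
    with open(path) as fh:
        return ensemble_from_dict(json.load(fh))


def write_metrics(metrics: dict, path) -> None:
    """Metrics as JSON (``.json``) or a one-row TSV (anything else)."""
    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
    else:
        pd.DataFrame([metrics]).to_csv(path, sep="\t", index=False)
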