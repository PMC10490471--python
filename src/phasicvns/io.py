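"""Readers and writers for the on-disk formats (tidy TSV + JSON).

All floating-point columns round-trip at full precision (%.17g).  Malformed
tables raise a parse error carrying the offending line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import PupilTrace, ContSignal, EpochSet
from .cbpt import Cluster

__all__ = ["write_tsv", "read_tsv", "write_samples", "read_samples",
           "write_channels", "read_channels", "write_epochs", "read_epochs",
           "clusters_to_json", "clusters_from_json", "write_json", "read_json",
           "ParseError"]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed on-disk table, with file and line context."""


def write_tsv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except FileNotFoundError:
        raise


def write_samples(trace: PupilTrace, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"time_s": trace.time,
                       "pupil": np.where(trace.missing, np.nan, trace.pupil),
                       "missing": trace.missing.astype(int)})
    write_tsv(df, path)


def read_samples(path: Union[str, Path]) -> PupilTrace:
    df = read_tsv(path)
    for col in ("time_s", "pupil", "missing"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r} (line 1)")
    return PupilTrace(df["time_s"].to_numpy(), df["pupil"].to_numpy(),
                      df["missing"].to_numpy().astype(bool))


def write_channels(sig: ContSignal, path: Union[str, Path],
                   markers_path: Union[str, Path, None] = None) -> None:
    df = sig.channels.copy()
    df.insert(0, "time_s", sig.time)
    write_tsv(df, path)
    if markers_path is not None:
        write_tsv(pd.DataFrame({"onset_s": sig.markers}), markers_path)


def read_channels(path: Union[str, Path],
                  markers_path: Union[str, Path, None] = None) -> ContSignal:
    df = read_tsv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing column 'time_s' (line 1)")
    time = df.pop("time_s").to_numpy()
    rate = 1.0 / float(np.median(np.diff(time)))
    markers = np.empty(0)
    if markers_path is not None:
        markers = read_tsv(markers_path)["onset_s"].to_numpy()
    return ContSignal(time, df, rate, markers)


def write_epochs(epochs: EpochSet, prefix: Union[str, Path]) -> None:
    """Wide TSV (trial rows, time columns) plus a labels TSV."""
    prefix = Path(prefix)
    if epochs.data.ndim != 2:
        raise ValueError("wide TSV export supports 2-D epoch sets")
    cols = [f"t{t:.17g}" for t in epochs.times]
    wide = pd.DataFrame(epochs.data, columns=cols)
    write_tsv(wide, prefix.with_suffix(".data.tsv"))
    lab = epochs.labels.copy()
    lab["rejected"] = epochs.rejected.astype(int)
    lab["reason"] = epochs.reasons
    write_tsv(lab, prefix.with_suffix(".labels.tsv"))


def read_epochs(prefix: Union[str, Path]) -> EpochSet:
    prefix = Path(prefix)
    wide = read_tsv(prefix.with_suffix(".data.tsv"))
    lab = read_tsv(prefix.with_suffix(".labels.tsv"))
    times = np.array([float(c[1:]) for c in wide.columns])
    rejected = lab.pop("rejected").to_numpy().astype(bool)
    reasons = lab.pop("reason").fillna("").tolist()
    return EpochSet(data=wide.to_numpy(), times=times, labels=lab,
                    rejected=rejected, reasons=reasons)


def clusters_to_json(clusters, path: Union[str, Path]) -> None:
    payload = [c.to_dict() | {"indices": c.indices.tolist()} for c in clusters]
    write_json(payload, path)


def clusters_from_json(path: Union[str, Path]):
    payload = read_json(path)
    out = []
    for d in payload:
        out.append(Cluster(indices=np.asarray(d["indices"], dtype=int),
                           mass=d["mass"], direction=d["direction"],
                           p=d.get("p", float("nan")),
                           d_avg=d.get("d_avg", float("nan")),
                           d_max=d.get("d_max", float("nan")),
                           d_max_loc=d.get("d_max_loc"),
                           beta_avg=d.get("beta_avg", float("nan"))))
    return out


def write_json(obj, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def read_json(path: Union[str, Path]):
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
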