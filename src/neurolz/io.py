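"""Reading recordings and writing analysis reports.

Two input dialects are supported:

* long-format CSV with header
  ``cat,session,channel,condition,stim,sample_index,value`` plus a JSON
  sidecar (``<name>.json``) carrying at least ``{"fs": <Hz>}``;
* EDF, one file per session, read through :mod:`mne` when it is installed
  (condition and hierarchy labels then come from the sidecar).

Reports are plain CSV/JSON so reruns can be compared byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .preprocess import ConditionLabel, Recording

__all__ = ["read_signals", "write_signals_csv", "write_report"]

CSV_COLUMNS = ["cat", "session", "channel", "condition", "stim", "sample_index", "value"]


def _condition_from_label(label: str, stim: bool) -> ConditionLabel:
    if label in ("W", "LS", "SWS", "REM"):
        return ConditionLabel(kind="sleep", state=label, stimulated=stim)
    try:
        dose = int(label)
    except ValueError:
        raise ValueError(f"unrecognized condition label {label!r}") from None
    return ConditionLabel(kind="dose", dose=dose, stimulated=stim)


def read_signals(path: str | Path, fmt: str | None = None) -> list[Recording]:
    """Read one or more recordings from a CSV (or EDF) file.

    ``fmt`` defaults to the file extension. A long-format CSV may contain
    several (cat, session, condition) blocks; each becomes one Recording.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'edf'")


def _read_sidecar(path: Path) -> dict[str, Any]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"missing JSON sidecar {sidecar.name} (needs 'fs')")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta or meta["fs"] <= 0:
        raise ValueError(f"sidecar {sidecar.name}: field 'fs' missing or non-positive")
    return meta


def _read_csv(path: Path) -> list[Recording]:
    meta = _read_sidecar(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    recordings = []
    keys = ["cat", "session", "condition", "stim"]
    for (cat, session, cond, stim), block in df.groupby(keys, sort=True):
        channels = list(block["channel"].unique())  # first-appearance order
        per_ch = []
        lengths = set()
        for ch in channels:
            sub = block[block["channel"] == ch].sort_values("sample_index")
            per_ch.append(sub["value"].to_numpy(dtype=np.float64))
            lengths.add(len(sub))
        if len(lengths) != 1:
            raise ValueError(
                f"{path.name}: unequal channel lengths {sorted(lengths)} in "
                f"cat={cat} session={session} condition={cond}"
            )
        recordings.append(
            Recording(
                samples=np.vstack(per_ch),
                fs=float(meta["fs"]),
                channels=tuple(channels),
                cat=str(cat),
                session=str(session),
                condition=_condition_from_label(str(cond), bool(stim)),
            )
        )
    return recordings


def _read_edf(path: Path) -> list[Recording]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the 'mne' package") from exc
    meta = _read_sidecar(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return [
        Recording(
            samples=raw.get_data() * 1e6,  # volts -> microvolts
            fs=float(raw.info["sfreq"]),
            channels=tuple(raw.ch_names),
            cat=str(meta.get("cat", "cat1")),
            session=str(meta.get("session", "s1")),
            condition=_condition_from_label(
                str(meta.get("condition", "W")), bool(meta.get("stim", False))
            ),
        )
    ]


def write_signals_csv(recordings: list[Recording], path: str | Path) -> None:
    """Write recordings in the long CSV dialect with its JSON sidecar."""
    path = Path(path)
    frames = []
    fs = None
    for rec in recordings:
        if fs is None:
            fs = rec.fs
        elif fs != rec.fs:
            raise ValueError("all recordings in one file must share fs")
        for ch_i, ch in enumerate(rec.channels):
            vals = rec.samples[ch_i]
            frames.append(
                pd.DataFrame(
                    {
                        "cat": rec.cat,
                        "session": rec.session,
                        "channel": ch,
                        "condition": rec.condition.label,
                        "stim": rec.condition.stimulated,
                        "sample_index": np.arange(vals.size),
                        "value": vals,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps({"fs": fs}, indent=2) + "\n")


def write_report(bundle: dict[str, Any], out_dir: str | Path) -> list[Path]:
    """Write a report bundle: DataFrames as CSV, everything else as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    json_payload = {}
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
        else:
            json_payload[name] = obj
    if json_payload:
        p = out_dir / "report.json"
        p.write_text(json.dumps(json_payload, indent=2, sort_keys=True, default=str) + "\n")
        written.append(p)
    return written
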