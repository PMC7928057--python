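"""CSV / JSON file formats used by the pipeline stages.

All delimited files are comma-separated UTF-8 with a header row, '.'
decimals and LF endings.  Every file opens with a '#' comment line naming
the package version, config hash and seed (provenance contract); readers
skip comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .device import TrialRecording
from .traces import ForceTrace

__all__ = [
    "provenance_line",
    "write_csv",
    "read_csv",
    "traces_frame",
    "write_traces",
    "read_traces",
    "write_json_report",
]


def provenance_line(config_hash: str = "-", seed: int | str = "-") -> str:
    return f"# skinstretch v{__version__} config={config_hash} seed={seed}"


def write_csv(
    df: pd.DataFrame, path: str | Path, config_hash: str = "-", seed: int | str = "-"
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(provenance_line(config_hash, seed) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def traces_frame(trial_id: int, rec: TrialRecording) -> pd.DataFrame:
    """Long-format frame for one trial: channel x kind x time."""
    parts = []
    for channel, kind, trace in (
        ("vertical", "target", rec.target_v),
        ("horizontal", "target", rec.target_h),
        ("vertical", "measured", rec.measured_v),
        ("horizontal", "measured", rec.measured_h),
    ):
        parts.append(
            pd.DataFrame(
                {
                    "trial_id": trial_id,
                    "channel": channel,
                    "kind": kind,
                    "time_s": np.round(trace.times, 9),
                    "force_N": trace.values,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_traces(
    recordings: Iterable[TrialRecording],
    out_dir: str | Path,
    config_hash: str = "-",
    seed: int | str = "-",
) -> list[Path]:
    """One trace CSV per trial under ``out_dir``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(recordings, start=1):
        path = out_dir / f"trial_{i:04d}.csv"
        write_csv(traces_frame(i, rec), path, config_hash, seed)
        paths.append(path)
    return paths


def read_traces(path: str | Path, sample_rate: float | None = None) -> TrialRecording:
    """Reassemble one trial's :class:`TrialRecording` from its trace CSV.

    The sample rate is inferred from the time column unless given.  The
    commanded lag is not stored in trace files (it lives in the schedule
    manifest) and is set to NaN here.
    """
    df = read_csv(path)
    traces = {}
    for (channel, kind), grp in df.groupby(["channel", "kind"]):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        rate = sample_rate if sample_rate is not None else 1.0 / float(np.median(np.diff(t)))
        traces[(channel, kind)] = ForceTrace(rate, grp["force_N"].to_numpy(), t0=float(t[0]))
    return TrialRecording(
        commanded_lag=float("nan"),
        target_v=traces[("vertical", "target")],
        target_h=traces[("horizontal", "target")],
        measured_v=traces[("vertical", "measured")],
        measured_h=traces[("horizontal", "measured")],
    )


def write_json_report(
    data: dict, path: str | Path, config_hash: str = "-", seed: int | str = "-"
) -> None:
    payload = {
        "package": "skinstretch",
        "version": __version__,
        "config_hash": config_hash,
        "seed": seed,
        **data,
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, default=_jsonify) + "\n", encoding="utf-8"
    )


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
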