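"""CSV readers/writers for recordings, events, index series and feature tables.

All formats are comma-separated UTF-8 with a header line; times are seconds
as floats, conductance is microsiemens.

* recordings: ``time_s,eda_uS``
* stimulus events: ``subject_id,time_s``
* index series: ``time_s,tvsymp,mtvsymp,dpheda`` (streamed output adds
  ``emitted_at_s``)
* segment features: one row per segment (see the segments module).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import RawEDARecord, StimulusEventList, ValidationError


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _read_numeric_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def read_eda_recording(path: str | Path, subject_id: str | None = None) -> RawEDARecord:
    """Read a two-column ``time_s,eda_uS`` recording.

    The subject id defaults to the file stem.  Non-numeric rows and
    non-monotone timestamps raise with the offending line number.
    """
    path = Path(path)
    df = _read_numeric_csv(path, ["time_s", "eda_uS"])
    for col in ("time_s", "eda_uS"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna())
        if bad.size:
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
        if vals.isna().any():
            raise ParseError(f"{path}: empty value in column {col!r}")
        df[col] = vals
    t = df["time_s"].to_numpy(dtype=float)
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise ParseError(f"{path}: timestamps not strictly increasing at line {nonmono[0] + 3}")
    try:
        return RawEDARecord(
            subject_id=subject_id or path.stem,
            timestamps=t,
            conductance=df["eda_uS"].to_numpy(dtype=float),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_eda_recording(record: RawEDARecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": record.timestamps, "eda_uS": record.conductance}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_stimulus_events(path: str | Path) -> list[StimulusEventList]:
    """Read ``subject_id,time_s`` events, grouped per subject, sorted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty and list(df.columns) in ([], ["subject_id", "time_s"]):
        return []
    if not {"subject_id", "time_s"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns subject_id,time_s")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        bad = int(np.flatnonzero(times.isna())[0])
        raise ParseError(f"{path}: non-numeric time at line {bad + 2}")
    if (times < 0).any():
        raise ParseError(f"{path}: negative event time")
    out = []
    for sid, grp in df.assign(time_s=times).groupby("subject_id", sort=True):
        out.append(StimulusEventList(subject_id=str(sid), event_times=grp["time_s"].to_numpy()))
    return out


def write_stimulus_events(events: list[StimulusEventList], path: str | Path) -> None:
    rows = [
        {"subject_id": ev.subject_id, "time_s": t} for ev in events for t in ev.event_times
    ]
    pd.DataFrame(rows, columns=["subject_id", "time_s"]).to_csv(
        path, index=False, float_format="%.9f"
    )


def write_index_series(series: dict[str, "np.ndarray | tuple"], times: np.ndarray, path: str | Path) -> None:
    """Write aligned index series (columns: time_s plus one per index)."""
    data = {"time_s": times}
    for name, vals in series.items():
        data[name] = np.asarray(vals)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.9f")
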