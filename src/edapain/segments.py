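"""Painless/pain segment extraction and feature tables.

Around each pain stimulus two 5-second windows are cut from the three index
series: ``[t-5, t)`` is the *painless* segment (label 0) and ``[t, t+5)`` the
*pain* segment (label 1) — the evoked skin-conductance response starts about
1.5 s after the stimulus, well inside the pain window.  Per segment and index
the mean and maximum are recorded, giving the six features used for
statistics and classification:

``tvsymp_mean, tvsymp_max, mtvsymp_mean, mtvsymp_max, dpheda_mean, dpheda_max``

Windows are half-open and snapped to the 2 Hz grid, so the stimulus sample
itself belongs to the pain segment only and every window holds exactly
``5 * 2 = 10`` samples.  Events too close to a recording boundary are skipped
(not clipped) so all windows are the same length; labels stay balanced by
construction — one painless and one pain row per usable event.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .records import StimulusEventList, UniformSeries, ValidationError

logger = logging.getLogger(__name__)

SEGMENT_SECONDS = 5.0
FEATURE_COLUMNS = [
    "tvsymp_mean",
    "tvsymp_max",
    "mtvsymp_mean",
    "mtvsymp_max",
    "dpheda_mean",
    "dpheda_max",
]
INDEX_NAMES = ("tvsymp", "mtvsymp", "dpheda")


def extract_segments(
    index_series: dict[str, UniformSeries],
    events: StimulusEventList,
    seg_len: float = SEGMENT_SECONDS,
    dataset: str = "synthetic",
) -> pd.DataFrame:
    """Build the per-segment feature table for one subject.

    Parameters
    ----------
    index_series : dict
        ``{"tvsymp": ..., "mtvsymp": ..., "dpheda": ...}`` aligned 2 Hz
        series (equal start time and length).
    events : StimulusEventList
        Stimulus onsets, seconds (same clock as the series start times).
    seg_len : float
        Window length in seconds on each side of the event.
    dataset : str
        Dataset tag stored with every row (e.g. ``"TG"``, ``"EP"``).

    Returns
    -------
    pandas.DataFrame
        Two rows (painless then pain) per usable event with the six feature
        columns; events without a full window on both sides are skipped with
        a logged warning.
    """
    missing = [k for k in INDEX_NAMES if k not in index_series]
    if missing:
        raise ValidationError(f"missing index series: {missing}")
    ref = index_series[INDEX_NAMES[0]]
    rate = ref.rate
    n = len(ref)
    for k in INDEX_NAMES:
        s = index_series[k]
        if len(s) != n or s.rate != rate or abs(s.start_time - ref.start_time) > 1e-9:
            raise ValidationError("index series must be aligned (same rate, start, length)")
    win = int(round(seg_len * rate))

    rows: list[dict] = []
    skipped = 0
    for ev in events.event_times:
        center = int(round((ev - ref.start_time) * rate))
        if center - win < 0 or center + win > n:
            skipped += 1
            continue
        for label, sl in ((0, slice(center - win, center)), (1, slice(center, center + win))):
            row = {
                "subject_id": events.subject_id,
                "dataset": dataset,
                "event_time_s": float(ev),
                "label": label,
            }
            for k in INDEX_NAMES:
                seg = index_series[k].values[sl]
                row[f"{k}_mean"] = float(seg.mean())
                row[f"{k}_max"] = float(seg.max())
            rows.append(row)
    if skipped:
        logger.warning("skipped %d event(s) too close to the recording boundary", skipped)
    return pd.DataFrame(
        rows, columns=["subject_id", "dataset", "event_time_s", "label", *FEATURE_COLUMNS]
    )


def pool_datasets(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate feature tables from different datasets.

    Subjects must be disjoint across dataset tags (the same person cannot
    appear in two experiments); a duplicate subject id under different tags
    raises.
    """
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=["subject_id", "dataset", "event_time_s", "label", *FEATURE_COLUMNS])
    pooled = pd.concat(tables, ignore_index=True)
    per_subject_tags = pooled.groupby("subject_id")["dataset"].nunique()
    dupes = per_subject_tags[per_subject_tags > 1]
    if len(dupes):
        raise ValidationError(f"subject id(s) present in multiple datasets: {list(dupes.index)}")
    return pooled
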