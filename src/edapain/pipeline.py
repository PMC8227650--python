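"""End-to-end convenience pipelines tying the stages together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cvxeda import cvxeda_decompose
from .indices import dpheda, mtvsymp, tvsymp
from .preprocess import preprocess_eda
from .records import RawEDARecord, StimulusEventList, SyntheticDataset, UniformSeries
from .segments import extract_segments, pool_datasets
from .vfcdm import vfcdm_decompose


def compute_batch_indices(record: RawEDARecord) -> dict[str, UniformSeries]:
    """Full-recording (batch) TVSymp, MTVSymp and dPhEDA at 2 Hz."""
    pre = preprocess_eda(record)
    decomp = vfcdm_decompose(pre)
    tv = tvsymp(decomp)
    mtv = mtvsymp(tv)
    eda_parts = cvxeda_decompose(pre)
    dph = UniformSeries(
        values=dpheda(eda_parts.phasic, pre.rate), rate=pre.rate, start_time=pre.start_time
    )
    tv_series = UniformSeries(values=tv.amplitude, rate=pre.rate, start_time=pre.start_time)
    return {"tvsymp": tv_series, "mtvsymp": mtv, "dpheda": dph}


def subject_feature_table(
    record: RawEDARecord, events: StimulusEventList, dataset: str = "synthetic"
) -> pd.DataFrame:
    """Segment feature rows for one subject from batch indices."""
    idx = compute_batch_indices(record)
    return extract_segments(idx, events, dataset=dataset)


def dataset_feature_table(ds: SyntheticDataset, dataset: str = "synthetic") -> pd.DataFrame:
    """Segment feature table for a whole synthetic dataset."""
    tables = [
        subject_feature_table(rec, ev, dataset=dataset)
        for rec, ev in zip(ds.records, ds.events)
    ]
    return pool_datasets(tables)
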