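"""Sample inclusion/exclusion rules with an auditable exclusion log.

FFPE tumor specimens pass through a fixed battery of assay QC gates before
entering the analysis: RNA yield, RNA integrity (DV200), exonic alignment
fraction, unique deduplicated read counts, and pathologist-assessed tumor
cellularity.  A final cohort-level filter drops the stalest biopsies — the
configurable top fraction of samples by biopsy-to-treatment gap.

All numeric thresholds are inclusive ("at least" / "minimum" / "or
greater"): a sample sitting exactly on a boundary is retained.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLDS",
    "apply_sample_qc",
    "apply_staleness_filter",
]

# rule name -> (record field, inclusive minimum)
DEFAULT_THRESHOLDS: dict[str, float] = {
    "rna_yield_ng": 40.0,
    "dv200_pct": 20.0,
    "exonic_alignment_frac": 0.30,
    "unique_dedup_counts": 800_000,
    "tumor_cellularity_frac": 0.10,
}


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no QC records supplied")
    if "sample_id" not in df.columns:
        raise ValueError("records must carry a sample_id field")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    return df


def apply_sample_qc(
    records,
    thresholds: Mapping[str, float] | None = None,
    allowed_specimen_sites: Iterable[str] | None = None,
) -> tuple[list, pd.DataFrame]:
    """Retain samples passing every QC threshold; log each failure.

    Parameters
    ----------
    records
        DataFrame or iterable of mappings, one per sample, with a
        ``sample_id`` and the metric fields named in `thresholds`.
    thresholds
        Mapping of metric field -> inclusive minimum.  Defaults to the
        study battery (40 ng RNA yield, DV200 >= 20%, >= 30% exonic
        alignment, >= 800,000 unique deduplicated counts, >= 10% tumor
        cellularity).
    allowed_specimen_sites
        Optional allow-list checked against an optional ``specimen_site``
        column (e.g. to exclude bone/liver metastases).

    Returns
    -------
    (retained_ids, exclusion_log)
        `exclusion_log` has one row per failed rule per sample:
        sample_id, rule, observed, threshold.  A missing required field
        excludes the sample with reason "missing"; an unparseable value
        yields a per-record "malformed" entry rather than an exception.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    df = _records_frame(records)
    log_rows = []
    retained = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        ok = True
        for fieldname, cutoff in thresholds.items():
            raw = row.get(fieldname, None)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                log_rows.append((sid, f"{fieldname} missing", None, cutoff))
                ok = False
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                log_rows.append((sid, f"{fieldname} malformed", raw, cutoff))
                ok = False
                continue
            if value < cutoff:
                log_rows.append((sid, f"{fieldname} < {cutoff:g}", value, cutoff))
                ok = False
        if allowed_specimen_sites is not None:
            site = row.get("specimen_site", None)
            if site not in set(allowed_specimen_sites):
                log_rows.append((sid, "specimen_site not allowed", site, None))
                ok = False
        if ok:
            retained.append(sid)
    log = pd.DataFrame(log_rows, columns=["sample_id", "rule", "observed", "threshold"])
    return retained, log


def apply_staleness_filter(records, fraction: float = 0.10) -> tuple[list, float | None]:
    """Drop the top `fraction` of samples by biopsy-to-treatment gap.

    Removes the ceil(fraction * n) samples with the longest gap; any sample
    tied with the smallest removed gap is also removed (a percentile cut
    cannot distinguish ties).  Returns the retained ids and the empirical
    cutoff in months (the smallest removed gap; None when nothing is
    removed).
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    df = _records_frame(records)
    if "biopsy_to_treatment_months" not in df.columns:
        raise ValueError("records lack biopsy_to_treatment_months")
    gaps = pd.to_numeric(df["biopsy_to_treatment_months"], errors="raise")
    if gaps.isna().any():
        missing = df.loc[gaps.isna(), "sample_id"].tolist()
        raise ValueError(f"biopsy_to_treatment_months missing for {missing}")
    n = len(df)
    k = math.ceil(fraction * n)
    if k == 0:
        return df["sample_id"].tolist(), None
    cutoff = float(np.sort(gaps.to_numpy())[::-1][k - 1])
    keep = gaps < cutoff
    return df.loc[keep, "sample_id"].tolist(), cutoff
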