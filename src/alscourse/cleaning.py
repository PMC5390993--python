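"""Cleaning rules for raw long-format visit records.

The cleaning contract for pooled trial exports: records with a missing
time point, non-numeric or out-of-range ("ambiguous") values are
dropped and logged; duplicated (subject, variable, day) measurements
are averaged; synonymous variable headings are merged onto a canonical
name; and missing functional-scale cells that are arithmetically
derivable from the instrument total are back-calculated.  No other
imputation is performed, and the full chain is idempotent.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RejectionLog",
    "InstrumentSpec",
    "drop_invalid_records",
    "collapse_duplicates",
    "merge_synonyms",
    "backcalculate_score",
    "backcalculate_percent_normal",
    "clean_pipeline",
    "ALSFRS_R_INSTRUMENT",
]

_COLUMNS = ["subject_id", "variable", "day", "value"]


@dataclass
class RejectionLog:
    """Counts of dropped records by reason."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["reason", "n_records"]
        )


def drop_invalid_records(records: pd.DataFrame, valid_ranges=None):
    """Keep records with a present day and a parseable numeric value.

    ``valid_ranges`` maps variable name to an inclusive (lo, hi)
    physical-plausibility window; values outside are treated as
    ambiguous entries.  Returns ``(clean, RejectionLog)``; rejections
    are logged, never raised.
    """
    df = records.loc[:, _COLUMNS].copy()
    log = RejectionLog()

    missing_day = pd.to_numeric(df["day"], errors="coerce").isna()
    log.counts["missing_time"] = int(missing_day.sum())
    df = df[~missing_day]

    value = pd.to_numeric(df["value"], errors="coerce")
    non_numeric = value.isna()
    log.counts["non_numeric"] = int(non_numeric.sum())
    df = df[~non_numeric].assign(value=value[~non_numeric].astype(float))

    if valid_ranges:
        lo = df["variable"].map(lambda v: valid_ranges.get(v, (-np.inf, np.inf))[0])
        hi = df["variable"].map(lambda v: valid_ranges.get(v, (-np.inf, np.inf))[1])
        out = (df["value"] < lo) | (df["value"] > hi)
        log.counts["out_of_range"] = int(out.sum())
        df = df[~out]

    df = df.assign(day=pd.to_numeric(df["day"]).astype(int))
    log.counts = +log.counts  # drop zero-count reasons
    return df.reset_index(drop=True), log


def collapse_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Average duplicated (subject, variable, day) measurements."""
    return (
        records.groupby(["subject_id", "variable", "day"], as_index=False, sort=True)[
            "value"
        ]
        .mean()
        .loc[:, _COLUMNS]
    )


def merge_synonyms(records: pd.DataFrame, synonym_map) -> pd.DataFrame:
    """Rewrite synonymous variable headings to their canonical name.

    ``synonym_map``: canonical name -> list of synonymous headings.  A
    heading claimed by two canonical names is a configuration error.
    Where both a synonym and its canonical carry values for the same
    (subject, day), they are averaged under the duplicate rule, with a
    warning (merged headings are expected to be mutually exclusive).
    """
    rename = {}
    for canonical, synonyms in synonym_map.items():
        for heading in list(synonyms) + [canonical]:
            if rename.get(heading, canonical) != canonical:
                raise ValueError(
                    f"synonym map conflict: {heading!r} maps to both "
                    f"{rename[heading]!r} and {canonical!r}"
                )
            rename[heading] = canonical
    out = records.copy()
    out["variable"] = out["variable"].map(lambda v: rename.get(v, v))
    dup = out.duplicated(["subject_id", "variable", "day"], keep=False)
    if dup.any():
        spread = (
            out[dup].groupby(["subject_id", "variable", "day"])["value"].nunique()
        )
        if (spread > 1).any():
            logger.warning(
                "merge_synonyms: %d (subject, variable, day) cells had "
                "conflicting values across synonymous headings; averaged",
                int((spread > 1).sum()),
            )
        out = collapse_duplicates(out)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class InstrumentSpec:
    """A summed instrument: total = sum of items, each in item_range."""

    total: str
    items: tuple
    item_range: tuple = (0.0, 4.0)


ALSFRS_R_INSTRUMENT = InstrumentSpec(
    total="alsfrs_r_total",
    items=tuple(f"alsfrs_r_q{i}" for i in range(1, 13)),
    item_range=(0.0, 4.0),
)


def backcalculate_score(records: pd.DataFrame,
                        instrument: InstrumentSpec = ALSFRS_R_INSTRUMENT):
    """Fill instrument cells derivable from the total score.

    Per (subject, day): a missing total with all items present becomes
    the item sum; a single missing item with the total present becomes
    total minus the other items.  Anything else is left untouched — no
    imputation.  A derived item outside its valid range is discarded
    (warning logged).  Returns the completed records.
    """
    names = set(instrument.items) | {instrument.total}
    mask = records["variable"].isin(names)
    sub = records[mask]
    if sub.empty:
        return records.copy()
    wide = sub.pivot_table(
        index=["subject_id", "day"], columns="variable", values="value",
        aggfunc="mean",
    ).reindex(columns=[instrument.total, *instrument.items])

    items = wide[list(instrument.items)]
    n_missing = items.isna().sum(axis=1)
    total_missing = wide[instrument.total].isna()

    new_rows = []
    fill_total = total_missing & (n_missing == 0)
    for (sid, day) in wide.index[fill_total]:
        new_rows.append((sid, instrument.total, day,
                         float(items.loc[(sid, day)].sum())))

    lo, hi = instrument.item_range
    fill_item = (~total_missing) & (n_missing == 1)
    n_bad = 0
    for (sid, day) in wide.index[fill_item]:
        row = items.loc[(sid, day)]
        missing_item = row.index[row.isna()][0]
        derived = float(wide.loc[(sid, day), instrument.total] - row.sum())
        if lo <= derived <= hi:
            new_rows.append((sid, missing_item, day, derived))
        else:
            n_bad += 1
    if n_bad:
        logger.warning(
            "backcalculate_score: %d derived items fell outside %s; left missing",
            n_bad, instrument.item_range,
        )
    if not new_rows:
        return records.copy()
    added = pd.DataFrame(new_rows, columns=_COLUMNS)
    return (
        pd.concat([records, added], ignore_index=True)
        .sort_values(["subject_id", "variable", "day"], kind="stable")
        .reset_index(drop=True)
    )


def backcalculate_percent_normal(records: pd.DataFrame, raw: str, pct: str,
                                 predicted_normal: pd.Series) -> pd.DataFrame:
    """Fill raw vs percent-of-predicted vital-capacity cells.

    For spirometry variables recorded both as a raw volume (``raw``)
    and as percent of the subject's predicted normal (``pct``), either
    cell is derivable from the other given the per-subject predicted
    normal: ``pct = 100 * raw / normal``.  Cells already present are
    left untouched; subjects without a predicted normal are skipped.
    """
    sub = records[records["variable"].isin((raw, pct))]
    if sub.empty:
        return records.copy()
    wide = sub.pivot_table(
        index=["subject_id", "day"], columns="variable", values="value",
        aggfunc="mean",
    ).reindex(columns=[raw, pct])
    new_rows = []
    for (sid, day), row in wide.iterrows():
        normal = predicted_normal.get(sid)
        if normal is None or not np.isfinite(normal) or normal <= 0:
            continue
        if pd.isna(row[pct]) and pd.notna(row[raw]):
            new_rows.append((sid, pct, day, 100.0 * row[raw] / normal))
        elif pd.isna(row[raw]) and pd.notna(row[pct]):
            new_rows.append((sid, raw, day, row[pct] * normal / 100.0))
    if not new_rows:
        return records.copy()
    added = pd.DataFrame(new_rows, columns=_COLUMNS)
    return (
        pd.concat([records, added], ignore_index=True)
        .sort_values(["subject_id", "variable", "day"], kind="stable")
        .reset_index(drop=True)
    )


def clean_pipeline(records: pd.DataFrame, synonym_map=None, valid_ranges=None,
                   instruments=(ALSFRS_R_INSTRUMENT,)):
    """Full cleaning chain; returns ``(clean records, RejectionLog)``."""
    clean, log = drop_invalid_records(records, valid_ranges)
    if synonym_map:
        clean = merge_synonyms(clean, synonym_map)
    clean = collapse_duplicates(clean)
    for instrument in instruments:
        clean = backcalculate_score(clean, instrument)
    return clean, log
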