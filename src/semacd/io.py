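"""CSV schemas and frame-level scoring helpers.

Two input schemas are defined:

* **ratings CSV** — one row per video x reader x read-occasion with the raw
  SEMA-CD entries: ``video_id, patient_id, timepoint, reader_id, occasion,
  ileum, colon_overall, seg_ascending, seg_transverse, seg_descending,
  seg_rectum, video_quality``.  ``ileum``/``colon_overall`` accept ``NA`` for
  a region that was not assessed; the ``seg_*`` columns are 0/1 involvement
  flags.
* **SES CSV** — one row per video x bowel segment with the four SES-CD item
  grades: ``video_id, segment, ulcer_size, ulcerated_surface,
  affected_surface, narrowing, assessed``.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .scoring import (
    COLON_SEGMENTS,
    NOT_ASSESSED,
    ScoringError,
    SemaRating,
    SesSegmentItems,
    classify_sema,
    compute_sema_total,
    compute_ses_total,
)

RATINGS_COLUMNS = [
    "video_id",
    "patient_id",
    "timepoint",
    "reader_id",
    "occasion",
    "ileum",
    "colon_overall",
    "seg_ascending",
    "seg_transverse",
    "seg_descending",
    "seg_rectum",
    "video_quality",
]

SES_COLUMNS = [
    "video_id",
    "segment",
    "ulcer_size",
    "ulcerated_surface",
    "affected_surface",
    "narrowing",
    "assessed",
]

_SEG_COLS = {s: f"seg_{s}" for s in COLON_SEGMENTS}


def _parse_grade(value) -> Optional[int]:
    if pd.isna(value) or (isinstance(value, str) and value.strip().upper() in {"NA", ""}):
        return NOT_ASSESSED
    return int(value)


def rating_from_row(row) -> SemaRating:
    """Build a validated :class:`SemaRating` from one ratings-CSV row."""
    involved = frozenset(s for s, c in _SEG_COLS.items() if int(row[c]) == 1)
    return SemaRating(
        video_id=str(row["video_id"]),
        reader_id=str(row["reader_id"]),
        occasion=str(row["occasion"]),
        ileum=_parse_grade(row["ileum"]),
        colon_overall=_parse_grade(row["colon_overall"]),
        involved_segments=involved,
    )


def read_ratings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ileum": "object", "colon_overall": "object"})
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ScoringError(f"ratings CSV missing column(s): {missing}")
    return df


def score_ratings_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``sema_total``, ``partial`` and ``severity_band`` columns.

    Rows violating a scoring invariant are rejected with a message naming the
    offending 0-based row index.
    """
    totals, partials, bands = [], [], []
    for idx, row in df.iterrows():
        try:
            score = compute_sema_total(rating_from_row(row))
        except ScoringError as exc:
            raise ScoringError(f"row {idx}: {exc}") from exc
        totals.append(score.total)
        partials.append(score.partial)
        bands.append(classify_sema(score.total) if score.total is not None else "")
    out = df.copy()
    out["sema_total"] = totals
    out["partial"] = partials
    out["severity_band"] = bands
    return out


def read_ses_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SES_COLUMNS if c not in df.columns]
    if missing:
        raise ScoringError(f"SES CSV missing column(s): {missing}")
    return df


def ses_totals_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Per-video SES-CD totals from a long segment-level SES table."""
    records = []
    for video_id, grp in df.groupby("video_id", sort=True):
        items = [
            SesSegmentItems(
                segment=row["segment"],
                ulcer_size=int(row["ulcer_size"]),
                ulcerated_surface=int(row["ulcerated_surface"]),
                affected_surface=int(row["affected_surface"]),
                narrowing=int(row["narrowing"]),
                assessed=bool(row["assessed"]),
            )
            for _, row in grp.iterrows()
        ]
        score = compute_ses_total(items)
        records.append(
            {
                "video_id": video_id,
                "ses_total": score.total,
                "n_assessed_segments": score.n_assessed_segments,
            }
        )
    return pd.DataFrame.from_records(records)
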