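"""Central-reading workflow: blinded double reads, adjudication, re-reads.

Each video is scored independently by two central readers drawn from a pool
(four readers in the validation study).  When the two primary totals disagree
by strictly more than the adjudication threshold (5 points on the SEMA-CD
scale), a third, standby adjudication reader scores the video.  The video's
final score is the median of the available totals — the arithmetic mean of
two reads, or the middle order statistic of three.

For intra-rater reliability a fraction of videos (15% in the study) is
reassigned to one of its original readers after a minimum wash-out gap
(two weeks by protocol; at least 22 days observed); re-reads never enter the
final score and never trigger adjudication.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .scoring import ScoringError, SemaRating, compute_sema_total

logger = logging.getLogger(__name__)

DEFAULT_ADJUDICATION_THRESHOLD = 5.0
DEFAULT_REREAD_FRACTION = 0.15
MIN_REREAD_GAP_DAYS = 14


class PanelError(ValueError):
    """Raised for infeasible panel configurations."""


@dataclass(frozen=True)
class VideoAssignment:
    reader_1: str
    reader_2: str
    adjudicator: str


@dataclass
class PanelAssignment:
    """Reader assignment for a whole study."""

    reader_pool: tuple
    per_video: dict  # video_id -> VideoAssignment
    reread_set: dict  # video_id -> reader_id (one of that video's primaries)
    reread_gap_days: int = 22

    def __post_init__(self):
        if self.reread_gap_days < MIN_REREAD_GAP_DAYS:
            raise PanelError(
                f"reread_gap_days must be >= {MIN_REREAD_GAP_DAYS}, got {self.reread_gap_days}"
            )


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_panel(
    video_ids: Sequence[str],
    reader_pool: Sequence[str],
    reread_fraction: float = DEFAULT_REREAD_FRACTION,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    reread_gap_days: int = 22,
) -> PanelAssignment:
    """Assign two primary readers plus a standby adjudicator to every video.

    Primary pairs are rotated round-robin over the unordered reader pairs so
    that pair loads differ by at most one; the adjudicator is rotated over
    the readers outside the pair.  The re-read subset (size = round-half-up
    of ``reread_fraction * n_videos``) is sampled uniformly without
    replacement and each re-read goes back to one of that video's original
    primary readers.
    """
    pool = tuple(dict.fromkeys(str(r) for r in reader_pool))
    if len(pool) < 3:
        raise PanelError(f"reader pool must contain >= 3 readers, got {len(pool)}")
    if not 0.0 <= reread_fraction <= 1.0:
        raise PanelError(f"reread_fraction must be in [0, 1], got {reread_fraction}")
    if rng is None:
        rng = np.random.default_rng(seed)

    pairs = list(itertools.combinations(pool, 2))
    per_video = {}
    adjudicator_cycle = {pair: 0 for pair in pairs}
    for i, vid in enumerate(video_ids):
        pair = pairs[i % len(pairs)]
        others = [r for r in pool if r not in pair]
        adjudicator = others[adjudicator_cycle[pair] % len(others)]
        adjudicator_cycle[pair] += 1
        per_video[str(vid)] = VideoAssignment(pair[0], pair[1], adjudicator)

    n_reread = round_half_up(reread_fraction * len(video_ids))
    chosen = rng.choice(len(video_ids), size=n_reread, replace=False) if n_reread else []
    reread_set = {}
    for j in sorted(chosen):
        vid = str(video_ids[int(j)])
        asg = per_video[vid]
        reread_set[vid] = asg.reader_1 if rng.random() < 0.5 else asg.reader_2
    return PanelAssignment(pool, per_video, reread_set, reread_gap_days=reread_gap_days)


@dataclass
class VideoReadSet:
    """All reads of one video with the resolved final score.

    ``final_score`` is the median of the two primary totals (their mean), or
    of the three totals including adjudication when the primaries disagree by
    more than the threshold.  The optional re-read is kept for intra-rater
    analysis only and never contributes to ``final_score``.
    """

    video_id: str
    read_1: SemaRating
    read_2: SemaRating
    adjudication: Optional[SemaRating]
    final_score: float
    adjudicated: bool
    reread: Optional[SemaRating] = None
    reread_gap_days: Optional[int] = None

    @property
    def totals(self):
        reads = [self.read_1, self.read_2] + ([self.adjudication] if self.adjudication else [])
        return [compute_sema_total(r).total for r in reads]


def resolve_reads(
    read_1: SemaRating,
    read_2: SemaRating,
    adjudicator_read_supplier: Optional[Callable[[], SemaRating]] = None,
    threshold: float = DEFAULT_ADJUDICATION_THRESHOLD,
) -> VideoReadSet:
    """Resolve a video's two primary reads into a final median score.

    Adjudication is requested from ``adjudicator_read_supplier`` iff the
    absolute difference of the two totals is strictly greater than
    ``threshold`` (a difference of exactly 5 does not adjudicate).  Partial
    totals (ileum not assessed) enter the comparison as recorded; a mismatch
    in assessed-region flags is logged as a data-quality warning.
    """
    if read_1.video_id != read_2.video_id:
        raise ScoringError(
            f"reads are for different videos: {read_1.video_id!r} vs {read_2.video_id!r}"
        )
    if read_1.reader_id == read_2.reader_id:
        raise ScoringError(f"primary reads must come from distinct readers ({read_1.reader_id!r})")
    s1, s2 = compute_sema_total(read_1), compute_sema_total(read_2)
    if s1.total is None or s2.total is None:
        raise ScoringError(f"video {read_1.video_id!r}: a fully unassessed read cannot be resolved")
    if (s1.ileum_assessed, s1.colon_assessed) != (s2.ileum_assessed, s2.colon_assessed):
        logger.warning(
            "video %s: assessed-region flags differ between readers %s and %s",
            read_1.video_id,
            read_1.reader_id,
            read_2.reader_id,
        )
    adjudicated = abs(s1.total - s2.total) > threshold
    adjudication = None
    if adjudicated:
        if adjudicator_read_supplier is None:
            raise PanelError(
                f"video {read_1.video_id!r}: adjudication required "
                f"(|{s1.total} - {s2.total}| > {threshold}) but no adjudicator supplied"
            )
        adjudication = adjudicator_read_supplier()
        if adjudication.reader_id in (read_1.reader_id, read_2.reader_id):
            raise ScoringError("adjudicator must differ from both primary readers")
        s3 = compute_sema_total(adjudication)
        final = float(np.median([s1.total, s2.total, s3.total]))
    else:
        final = (s1.total + s2.total) / 2.0
    return VideoReadSet(
        video_id=read_1.video_id,
        read_1=read_1,
        read_2=read_2,
        adjudication=adjudication,
        final_score=final,
        adjudicated=adjudicated,
    )
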