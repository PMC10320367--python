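"""SEMA-CD and SES-CD score computation and severity classification.

SEMA-CD (Simplified Endoscopic Mucosal Assessment for Crohn's Disease) grades
two bowel regions on an ordinal 0-4 scale: the terminal ileum, and the colon
as a whole (graded by its most severe segment).  The reader additionally
checks which of the four colonic segments (ascending, transverse, descending,
rectum) show any degree of active disease.  The total is

    total = ileum_grade + colon_grade * n_involved_segments

and ranges 0-20.  Either region may be "not assessed" (e.g. non-intubation of
the ileum without stricture); the total is then computed from the assessed
region alone and flagged as partial.  A stricture of the ileocecal valve is by
convention reflected in the ileum grade, so the calculator itself needs no
special case for it.

SES-CD (Simple Endoscopic Score for Crohn's Disease) is the established
comparator: five bowel segments (ileum, right/transverse/left colon, rectum),
each graded 0-3 on four items (ulcer size, ulcerated surface, affected
surface, narrowing), summed over assessed segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "NOT_ASSESSED",
    "COLON_SEGMENTS",
    "SES_SEGMENTS",
    "SEMA_BANDS",
    "SES_BANDS",
    "SemaRating",
    "SemaScore",
    "SesSegmentItems",
    "SesScore",
    "ScoringError",
    "compute_sema_total",
    "compute_ses_total",
    "classify_sema",
    "classify_ses",
]

#: Sentinel for a region the reader could not assess (rendered "NA" in CSV).
NOT_ASSESSED = None

COLON_SEGMENTS = ("ascending", "transverse", "descending", "rectum")
SES_SEGMENTS = ("ileum", "right_colon", "transverse_colon", "left_colon", "rectum")
SES_ITEMS = ("ulcer_size", "ulcerated_surface", "affected_surface", "narrowing")

READ_OCCASIONS = ("primary_1", "primary_2", "adjudication", "reread")

# Candidate SEMA-CD cutoffs, realised as half-open real intervals so that
# half-integer medians of two reads classify deterministically.  On the
# integer grid 0..20 these restrict exactly to the printed bands
# (0 inactive; 1 minimal; 2-4 mild; 5-9 moderate; >=10 severe).
SEMA_BANDS = (
    ("inactive", 0.0, 1.0),
    ("minimal", 1.0, 2.0),
    ("mild", 2.0, 5.0),
    ("moderate", 5.0, 10.0),
    ("severe", 10.0, 20.0 + 1e-9),
)

# SES-CD severity strata (integer totals): inactive 0-2, mild 3-6,
# moderate 7-15, severe >=16.
SES_BANDS = (
    ("inactive", 0, 2),
    ("mild", 3, 6),
    ("moderate", 7, 15),
    ("severe", 16, None),
)


class ScoringError(ValueError):
    """Raised when a rating or score violates an index invariant."""


def _check_grade(value: Optional[int], name: str) -> Optional[int]:
    if value is NOT_ASSESSED:
        return value
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ScoringError(f"{name}: grade must be an integer 0-4 or NOT_ASSESSED, got {value!r}")
    if not 0 <= value <= 4:
        raise ScoringError(f"{name}: grade must be in 0..4, got {value}")
    return value


@dataclass(frozen=True)
class SemaRating:
    """One reader's SEMA-CD assessment of one video.

    ``ileum`` and ``colon_overall`` are ordinal grades 0-4 or
    :data:`NOT_ASSESSED`.  ``involved_segments`` must be consistent with the
    colon grade: empty iff the colon grade is 0 (the overall colon grade is
    the grade of the worst involved segment, so a nonzero grade implies at
    least one flagged segment).
    """

    video_id: str
    reader_id: str
    occasion: str = "primary_1"
    ileum: Optional[int] = 0
    colon_overall: Optional[int] = 0
    involved_segments: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.occasion not in READ_OCCASIONS:
            raise ScoringError(f"occasion: must be one of {READ_OCCASIONS}, got {self.occasion!r}")
        _check_grade(self.ileum, "ileum")
        _check_grade(self.colon_overall, "colon_overall")
        segs = frozenset(self.involved_segments)
        object.__setattr__(self, "involved_segments", segs)
        unknown = segs - set(COLON_SEGMENTS)
        if unknown:
            raise ScoringError(f"involved_segments: unknown segment(s) {sorted(unknown)}")
        if self.colon_overall is NOT_ASSESSED:
            if segs:
                raise ScoringError(
                    "involved_segments: must be empty when colon_overall is NOT_ASSESSED"
                )
        elif self.colon_overall == 0 and segs:
            raise ScoringError("involved_segments: must be empty when colon_overall = 0")
        elif isinstance(self.colon_overall, int) and self.colon_overall > 0 and not segs:
            raise ScoringError(
                "involved_segments: at least one segment must be flagged when "
                f"colon_overall = {self.colon_overall} > 0"
            )


@dataclass(frozen=True)
class SemaScore:
    """A computed SEMA-CD total with component breakdown and assessment flags."""

    total: Optional[float]
    ileum_component: Optional[int]
    colon_component: Optional[int]
    ileum_assessed: bool
    colon_assessed: bool

    @property
    def partial(self) -> bool:
        """True when at least one region was not assessed."""
        return not (self.ileum_assessed and self.colon_assessed)


def compute_sema_total(rating: SemaRating) -> SemaScore:
    """Compute the SEMA-CD total ``ileum + colon_overall * n_involved``.

    A region graded :data:`NOT_ASSESSED` contributes nothing and the score is
    flagged partial; if neither region was assessed the total is ``None``.
    """
    ileum_assessed = rating.ileum is not NOT_ASSESSED
    colon_assessed = rating.colon_overall is not NOT_ASSESSED
    ileum_component = rating.ileum if ileum_assessed else None
    colon_component = (
        rating.colon_overall * len(rating.involved_segments) if colon_assessed else None
    )
    if not ileum_assessed and not colon_assessed:
        total = None
    else:
        total = float((ileum_component or 0) + (colon_component or 0))
    return SemaScore(
        total=total,
        ileum_component=ileum_component,
        colon_component=colon_component,
        ileum_assessed=ileum_assessed,
        colon_assessed=colon_assessed,
    )


@dataclass(frozen=True)
class SesSegmentItems:
    """SES-CD item grades (each 0-3) for one bowel segment."""

    segment: str
    ulcer_size: int = 0
    ulcerated_surface: int = 0
    affected_surface: int = 0
    narrowing: int = 0
    assessed: bool = True

    def __post_init__(self):
        if self.segment not in SES_SEGMENTS:
            raise ScoringError(f"segment: must be one of {SES_SEGMENTS}, got {self.segment!r}")
        if self.assessed:
            for item in SES_ITEMS:
                v = getattr(self, item)
                if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 3:
                    raise ScoringError(f"{item}: must be an integer 0..3, got {v!r}")

    @property
    def subtotal(self) -> int:
        return self.ulcer_size + self.ulcerated_surface + self.affected_surface + self.narrowing


@dataclass(frozen=True)
class SesScore:
    total: int
    n_assessed_segments: int


def compute_ses_total(items: Iterable[SesSegmentItems]) -> SesScore:
    """Sum the four SES-CD items over assessed segments (no renormalisation)."""
    items = list(items)
    seen = set()
    for it in items:
        if it.segment in seen:
            raise ScoringError(f"duplicate segment record: {it.segment!r}")
        seen.add(it.segment)
    assessed = [it for it in items if it.assessed]
    if not assessed:
        raise ScoringError("all segments unassessed: SES-CD total undefined")
    return SesScore(
        total=sum(it.subtotal for it in assessed),
        n_assessed_segments=len(assessed),
    )


def classify_sema(total: float) -> str:
    """Severity band of a SEMA-CD total (half-integers from 2-read medians allowed).

    Bands: [0,1) inactive, [1,2) minimal, [2,5) mild, [5,10) moderate,
    [10,20] severe.
    """
    t = float(total)
    if not 0.0 <= t <= 20.0:
        raise ScoringError(f"SEMA-CD total out of range [0, 20]: {total!r}")
    for label, lo, hi in SEMA_BANDS:
        if lo <= t < hi:
            return label
    raise AssertionError("unreachable: bands partition [0, 20]")


def classify_ses(total: int) -> str:
    """Severity band of an SES-CD total: 0-2 inactive, 3-6 mild, 7-15 moderate, >=16 severe."""
    if total < 0:
        raise ScoringError(f"SES-CD total must be non-negative, got {total!r}")
    t = int(total)
    for label, lo, hi in SES_BANDS:
        if t >= lo and (hi is None or t <= hi):
            return label
    raise AssertionError("unreachable")
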