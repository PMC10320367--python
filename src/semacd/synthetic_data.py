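"""Synthetic central-reading study generator.

Emulates the layout of a two-trial SEMA-CD validation study: ~110 Crohn's
disease patients (about a third pediatric), one pre- and one post-treatment
ileocolonoscopy video each, a 4-reader central-reading pool with two blinded
primary reads per video, standby adjudication for >5-point disagreements, and
a 15% re-read subset for intra-rater analysis.

The data-generating model is a single latent severity scalar ``theta`` per
video that drives all five bowel segments through a cumulative-ordinal link:
segment grade = number of (segment-shifted) thresholds exceeded by
``theta + jitter``.  Ground-truth SES-CD items are a fixed monotone map of
the segment grade; ground-truth SEMA-CD region grades are the ileum grade and
the maximum colonic grade with involvement flags.  Baseline severity is
matched to a configurable mix over SES-CD severity bands (defaults emulate
the validation study's marginals: 4.5% inactive, 19.1% mild, 40.9% moderate,
35.5% severe) by rejection on the realised baseline SES-CD band.

Reader noise is region-level ordinal misclassification: each region grade is
kept with probability ``p_exact`` and otherwise moved one step up or down
(clipped to 0-4), with the direction set by a per-reader bias.  A region
graded NOT_ASSESSED is never perturbed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import io as scio
from .reader_panel import PanelAssignment, assign_panel, resolve_reads, round_half_up
from .scoring import (
    COLON_SEGMENTS,
    NOT_ASSESSED,
    SemaRating,
    compute_sema_total,
)

#: Bowel segments in anatomical order (generator naming).
SEGMENTS = ("ileum",) + COLON_SEGMENTS

#: Generator segment -> SES-CD segment naming.
SES_SEGMENT_NAME = {
    "ileum": "ileum",
    "ascending": "right_colon",
    "transverse": "transverse_colon",
    "descending": "left_colon",
    "rectum": "rectum",
}

#: Cumulative-ordinal thresholds on the latent scale (grade g when theta+eps
#: exceeds g of them) and additive per-segment shifts (distal colon less
#: frequently involved).
GRADE_THRESHOLDS = (2.0, 4.0, 6.0, 8.0)
SEGMENT_SHIFTS = {
    "ileum": 0.0,
    "ascending": 0.4,
    "transverse": 0.7,
    "descending": 0.3,
    "rectum": 0.9,
}

#: Fixed monotone map from the 0-4 region/segment grade to SES-CD items
#: (ulcer_size, ulcerated_surface, affected_surface, narrowing).  Grade 0 is
#: all-normal; grade 4 ("widespread large ulcers / non-passable stricture")
#: saturates ulcer size and narrowing at 3.
GRADE_TO_SES_ITEMS = {
    0: (0, 0, 0, 0),
    1: (1, 1, 1, 0),
    2: (2, 1, 1, 1),
    3: (2, 2, 2, 2),
    4: (3, 3, 3, 3),
}

#: Latent theta sampling windows per target baseline SES-CD severity band.
THETA_WINDOWS = {
    "inactive": (-1.5, 2.2),
    "mild": (1.2, 4.5),
    "moderate": (3.0, 6.8),
    "severe": (5.5, 9.5),
}

SEVERITY_BAND_ORDER = ("inactive", "mild", "moderate", "severe")

#: 7-point ease-of-scoring scale relative to the comparator index.
USABILITY_SCALE = (
    "much_easier",
    "somewhat_easier",
    "slightly_easier",
    "neither",
    "slightly_more_difficult",
    "somewhat_more_difficult",
    "much_more_difficult",
)


class ReaderProfile(BaseModel):
    """Ordinal misclassification profile of one central reader."""

    p_exact: float = Field(0.8, gt=0.0, le=1.0)
    bias: float = Field(0.0, ge=-1.0, le=1.0)


class GeneratorConfig(BaseModel):
    """Study-design and noise parameters for :func:`generate_study`."""

    n_patients: int = Field(110, ge=1)
    prop_pediatric: float = Field(36 / 110, ge=0.0, le=1.0)
    severity_mix: Dict[str, float] = Field(
        default_factory=lambda: {
            "inactive": 0.045,
            "mild": 0.191,
            "moderate": 0.409,
            "severe": 0.355,
        }
    )
    treatment_effect: float = 1.5  # mean latent improvement, pre -> post
    treatment_effect_sd: float = 1.5
    reader_pool: tuple = ("R1", "R2", "R3", "R4")
    reader_profiles: Dict[str, ReaderProfile] = Field(default_factory=dict)
    reread_fraction: float = Field(0.15, ge=0.0, le=1.0)
    adjudication_threshold: float = 5.0
    quality_optimal_prob: float = Field(0.482, ge=0.0, le=1.0)
    ileum_nonintubation_prob: float = Field(0.02, ge=0.0, le=1.0)
    jitter_sd: float = Field(1.0, gt=0.0)
    usability_mix: Dict[str, float] = Field(
        default_factory=lambda: {
            "much_easier": 0.24,
            "somewhat_easier": 0.20,
            "slightly_easier": 0.19,
            "neither": 0.366,
            "slightly_more_difficult": 0.004,
            "somewhat_more_difficult": 0.0,
            "much_more_difficult": 0.0,
        }
    )
    seed: int

    @field_validator("severity_mix")
    @classmethod
    def _mix_valid(cls, v):
        if set(v) != set(SEVERITY_BAND_ORDER):
            raise ValueError(f"severity_mix must have keys {SEVERITY_BAND_ORDER}")
        if abs(sum(v.values()) - 1.0) > 1e-6 or any(p < 0 for p in v.values()):
            raise ValueError("severity_mix must be non-negative and sum to 1")
        return v

    @field_validator("usability_mix")
    @classmethod
    def _usability_valid(cls, v):
        if set(v) != set(USABILITY_SCALE):
            raise ValueError(f"usability_mix must have keys {USABILITY_SCALE}")
        if abs(sum(v.values()) - 1.0) > 1e-6 or any(p < 0 for p in v.values()):
            raise ValueError("usability_mix must be non-negative and sum to 1")
        return v

    @model_validator(mode="after")
    def _fill_profiles(self):
        for r in self.reader_pool:
            self.reader_profiles.setdefault(str(r), ReaderProfile())
        return self

    def profile(self, reader_id: str) -> ReaderProfile:
        return self.reader_profiles[str(reader_id)]

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Latent-state and truth generation


def _segment_grades(theta: float, rng: np.random.Generator, jitter_sd: float) -> Dict[str, int]:
    grades = {}
    for seg in SEGMENTS:
        x = theta + rng.normal(0.0, jitter_sd)
        shift = SEGMENT_SHIFTS[seg]
        grades[seg] = int(sum(x > t + shift for t in GRADE_THRESHOLDS))
    return grades


def ses_total_from_grades(grades: Dict[str, int]) -> int:
    return sum(sum(GRADE_TO_SES_ITEMS[g]) for g in grades.values())


def true_sema_rating(video_id: str, grades: Dict[str, int],
                     ileum_assessed: bool = True) -> SemaRating:
    """Ground-truth SEMA-CD rating implied by per-segment grades."""
    colon_grades = {s: grades[s] for s in COLON_SEGMENTS}
    colon_overall = max(colon_grades.values())
    involved = frozenset(s for s, g in colon_grades.items() if g > 0)
    return SemaRating(
        video_id=video_id,
        reader_id="TRUTH",
        occasion="primary_1",
        ileum=grades["ileum"] if ileum_assessed else NOT_ASSESSED,
        colon_overall=colon_overall,
        involved_segments=involved,
    )


def perturb_rating(
    true_rating: SemaRating,
    profile: ReaderProfile,
    rng: np.random.Generator,
    reader_id: Optional[str] = None,
    occasion: str = "primary_1",
) -> SemaRating:
    """Apply region-level ordinal reader noise to a ground-truth rating.

    Each assessed region grade is kept with probability ``p_exact`` and
    otherwise moved one step, upward with probability ``(1 + bias) / 2``,
    clipped to 0-4.  NOT_ASSESSED regions are never perturbed.  Involvement
    flags stay consistent with the perturbed colon grade: a colon grade of 0
    empties them; a nonzero colon grade arising from a true grade of 0 flags
    one randomly chosen segment; otherwise the true involved set is kept.
    """

    def jitter(grade):
        if grade is NOT_ASSESSED:
            return grade
        if rng.random() < profile.p_exact:
            return grade
        step = 1 if rng.random() < (1.0 + profile.bias) / 2.0 else -1
        return int(np.clip(grade + step, 0, 4))

    ileum = jitter(true_rating.ileum)
    colon = jitter(true_rating.colon_overall)
    if colon is NOT_ASSESSED or colon == 0:
        involved = frozenset()
    elif true_rating.involved_segments:
        involved = true_rating.involved_segments
    else:
        involved = frozenset({COLON_SEGMENTS[int(rng.integers(len(COLON_SEGMENTS)))]})
    return SemaRating(
        video_id=true_rating.video_id,
        reader_id=reader_id if reader_id is not None else true_rating.reader_id,
        occasion=occasion,
        ileum=ileum,
        colon_overall=colon,
        involved_segments=involved,
    )


# ---------------------------------------------------------------------------
# Full-study generation


@dataclass
class StudyData:
    """All tables of one synthetic study."""

    config: GeneratorConfig
    patients: pd.DataFrame
    findings: pd.DataFrame
    ses: pd.DataFrame
    ratings: pd.DataFrame
    resolved: pd.DataFrame
    truth: pd.DataFrame
    panel: PanelAssignment

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "findings", "ses", "ratings", "resolved", "truth"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "config.yaml").write_text(
            yaml.safe_dump(self.config.model_dump(mode="json"), sort_keys=True)
        )

    @classmethod
    def read(cls, indir) -> "StudyData":
        ind = Path(indir)
        config = GeneratorConfig.from_yaml(ind / "config.yaml")
        frames = {
            name: pd.read_csv(ind / f"{name}.csv",
                              dtype={"ileum": "object", "colon_overall": "object"}
                              if name == "ratings" else None)
            for name in ("patients", "findings", "ses", "ratings", "resolved", "truth")
        }
        return cls(config=config, panel=None, **frames)


def _draw_baseline(band: str, rng: np.random.Generator, jitter_sd: float,
                   max_tries: int = 500):
    """Rejection-sample (theta, segment grades) whose SES-CD band matches."""
    lo, hi = THETA_WINDOWS[band]
    last = None
    for _ in range(max_tries):
        theta = float(rng.uniform(lo, hi))
        grades = _segment_grades(theta, rng, jitter_sd)
        last = (theta, grades)
        from .scoring import classify_ses

        if classify_ses(ses_total_from_grades(grades)) == band:
            return last
    return last  # extremely unlikely; accept the final draw


def generate_study(config: GeneratorConfig) -> StudyData:
    """Generate a complete synthetic study, reproducible from ``config.seed``.

    Produces per-patient latent states, pre/post videos with per-segment
    ground truth, SES-CD comparator scores (derived noiselessly from the
    ground-truth segment states), noisy SEMA-CD reader ratings under the
    panel design (double reads, adjudication, re-reads), and a truth table
    for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    panel_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))

    n_ped = round_half_up(config.prop_pediatric * config.n_patients)
    bands = list(config.severity_mix)
    probs = np.array([config.severity_mix[b] for b in bands])

    patients, videos = [], []  # videos: (video_id, patient_id, timepoint, theta, grades)
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        cohort = "pediatric" if i < n_ped else "adult"
        band = bands[int(rng.choice(len(bands), p=probs))]
        theta_pre, grades_pre = _draw_baseline(band, rng, config.jitter_sd)
        improvement = float(rng.normal(config.treatment_effect, config.treatment_effect_sd))
        theta_post = float(np.clip(theta_pre - improvement, -2.0, 10.0))
        grades_post = _segment_grades(theta_post, rng, config.jitter_sd)
        patients.append(
            {"patient_id": pid, "cohort": cohort, "theta_pre": theta_pre,
             "theta_post": theta_post, "baseline_band": band}
        )
        videos.append((f"{pid}-pre", pid, "pre", theta_pre, grades_pre))
        videos.append((f"{pid}-post", pid, "post", theta_post, grades_post))

    video_ids = [v[0] for v in videos]
    panel = assign_panel(
        video_ids,
        config.reader_pool,
        reread_fraction=config.reread_fraction,
        rng=panel_rng,
        reread_gap_days=22,
    )

    findings_rows, ses_rows, ratings_rows, resolved_rows, truth_rows = [], [], [], [], []
    cohort_of = {p["patient_id"]: p["cohort"] for p in patients}

    for video_id, pid, timepoint, theta, grades in videos:
        quality = (
            "optimal" if rng.random() < config.quality_optimal_prob else "readable_not_optimal"
        )
        ileum_assessed = True
        if grades["ileum"] < 4 and rng.random() < config.ileum_nonintubation_prob:
            ileum_assessed = False  # non-intubation without stricture
        truth_rating = true_sema_rating(video_id, grades, ileum_assessed=ileum_assessed)
        true_sema = compute_sema_total(truth_rating)
        true_ses = ses_total_from_grades(grades)

        for seg in SEGMENTS:
            items = GRADE_TO_SES_ITEMS[grades[seg]]
            findings_rows.append({"video_id": video_id, "segment": seg, "grade": grades[seg]})
            ses_rows.append(
                {
                    "video_id": video_id,
                    "segment": SES_SEGMENT_NAME[seg],
                    "ulcer_size": items[0],
                    "ulcerated_surface": items[1],
                    "affected_surface": items[2],
                    "narrowing": items[3],
                    "assessed": True,
                }
            )
        truth_rows.append(
            {
                "video_id": video_id,
                "patient_id": pid,
                "timepoint": timepoint,
                "cohort": cohort_of[pid],
                "theta": theta,
                "true_sema_total": true_sema.total,
                "true_ses_total": true_ses,
                "ileum_assessed": ileum_assessed,
                "video_quality": quality,
            }
        )

        asg = panel.per_video[video_id]
        read_1 = perturb_rating(truth_rating, config.profile(asg.reader_1), rng,
                                reader_id=asg.reader_1, occasion="primary_1")
        read_2 = perturb_rating(truth_rating, config.profile(asg.reader_2), rng,
                                reader_id=asg.reader_2, occasion="primary_2")

        def supplier():
            return perturb_rating(truth_rating, config.profile(asg.adjudicator), rng,
                                  reader_id=asg.adjudicator, occasion="adjudication")

        readset = resolve_reads(read_1, read_2, supplier,
                                threshold=config.adjudication_threshold)

        reads = [read_1, read_2] + ([readset.adjudication] if readset.adjudicated else [])
        reread_total = None
        if video_id in panel.reread_set:
            reread = perturb_rating(truth_rating, config.profile(panel.reread_set[video_id]),
                                    rng, reader_id=panel.reread_set[video_id],
                                    occasion="reread")
            reads.append(reread)
            reread_total = compute_sema_total(reread).total

        for r in reads:
            ratings_rows.append(_rating_row(r, pid, timepoint, quality))
        totals = readset.totals
        resolved_rows.append(
            {
                "video_id": video_id,
                "total_read1": totals[0],
                "total_read2": totals[1],
                "total_adjud": totals[2] if readset.adjudicated else None,
                "adjudicated": readset.adjudicated,
                "final_score": readset.final_score,
                "reread_total": reread_total,
                "reread_gap_days": panel.reread_gap_days
                if video_id in panel.reread_set
                else None,
            }
        )

    return StudyData(
        config=config,
        patients=pd.DataFrame(patients),
        findings=pd.DataFrame(findings_rows),
        ses=pd.DataFrame(ses_rows),
        ratings=pd.DataFrame(ratings_rows, columns=scio.RATINGS_COLUMNS),
        resolved=pd.DataFrame(resolved_rows),
        truth=pd.DataFrame(truth_rows),
        panel=panel,
    )


def _rating_row(r: SemaRating, patient_id: str, timepoint: str, quality: str) -> dict:
    row = {
        "video_id": r.video_id,
        "patient_id": patient_id,
        "timepoint": timepoint,
        "reader_id": r.reader_id,
        "occasion": r.occasion,
        "ileum": "NA" if r.ileum is NOT_ASSESSED else r.ileum,
        "colon_overall": "NA" if r.colon_overall is NOT_ASSESSED else r.colon_overall,
        "video_quality": quality,
    }
    for seg in COLON_SEGMENTS:
        row[f"seg_{seg}"] = int(seg in r.involved_segments)
    return row
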