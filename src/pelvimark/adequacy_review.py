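"""Majority-rule resolution of multi-assessor annotation-adequacy reviews.

Three assessors independently review every landmark of every image, either
declaring all five annotations satisfactory or flagging specific
annotators with a reason (bad image quality, anatomical anomaly, outlier
placement, or other).  Verdicts from two or more assessors are treated as
ground truth, giving three independent majority clauses:

1. *landmark-wise inadequacy* — ≥2 assessors flagged at least one
   annotation of the landmark (not necessarily the same one);
2. *reason-wise inadequacy* — ≥2 assessors cited the same reason for the
   landmark, regardless of which annotator each attached it to;
3. *annotation-level exclusion* — ≥2 assessors flagged the same annotator
   on the landmark; that annotation, and the tilt parameter computed from
   it, leave the "adequate" dataset.

Reviews happen at the level of derived landmarks (e.g. the calculated
femoral-head centre stands for both head contours), so an exclusion maps
directly to one of the three tilt parameters.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .geometry import Parameter

__all__ = [
    "Reason",
    "ReviewLandmark",
    "Flag",
    "AssessorRating",
    "AdequacyResolution",
    "CoverageError",
    "PARAMETER_OF_LANDMARK",
    "resolve",
    "tabulate_landmark_wise",
    "tabulate_reason_wise",
    "exclusion_mask",
    "excluded_parameters",
    "read_ratings",
    "write_ratings",
]


class Reason(enum.StrEnum):
    BAD_QUALITY = "bad_quality"
    ANOMALY = "anomaly"
    OUTLIER = "outlier"
    OTHER = "other"


class ReviewLandmark(enum.StrEnum):
    """Landmarks at review granularity (derived, parameter-facing)."""

    ASIS_CENTRE = "asis_centre"
    PUBIC_TUBERCLE = "pubic_tubercle"
    FEMORAL_HEAD_CENTRE_CAL = "femoral_head_centre_cal"
    FEMORAL_HEAD_CENTRE_EST = "femoral_head_centre_est"
    SACRAL_MIDPOINT_CAL = "sacral_midpoint_cal"
    SACRAL_MIDPOINT_EST = "sacral_midpoint_est"


#: Which tilt parameter a review-level landmark feeds.
PARAMETER_OF_LANDMARK: Mapping[ReviewLandmark, Parameter] = {
    ReviewLandmark.ASIS_CENTRE: Parameter.PT_A,
    ReviewLandmark.PUBIC_TUBERCLE: Parameter.PT_A,
    ReviewLandmark.FEMORAL_HEAD_CENTRE_CAL: Parameter.PT_M_CAL,
    ReviewLandmark.SACRAL_MIDPOINT_CAL: Parameter.PT_M_CAL,
    ReviewLandmark.FEMORAL_HEAD_CENTRE_EST: Parameter.PT_M_EST,
    ReviewLandmark.SACRAL_MIDPOINT_EST: Parameter.PT_M_EST,
}


class CoverageError(ValueError):
    """A (image, landmark) key is not covered by the expected assessor count."""


@dataclass(frozen=True)
class Flag:
    annotator_id: str
    reason: Reason


@dataclass
class AssessorRating:
    """One assessor's verdict for one landmark on one image.

    The verdict is implied by the flag list: an empty list means all five
    annotations were judged satisfactory.  At most one flag per annotator.
    """

    image_id: str
    assessor_id: str
    landmark: ReviewLandmark
    flags: list[Flag] = field(default_factory=list)

    def __post_init__(self) -> None:
        annotators = [f.annotator_id for f in self.flags]
        if len(annotators) != len(set(annotators)):
            raise ValueError(
                f"assessor {self.assessor_id!r} flagged an annotator twice on "
                f"({self.image_id!r}, {self.landmark})"
            )

    @property
    def all_satisfactory(self) -> bool:
        return not self.flags


@dataclass
class AdequacyResolution:
    """Majority-rule consensus for one (image, landmark)."""

    image_id: str
    landmark: ReviewLandmark
    landmark_inadequate: bool
    reasons_majority: frozenset[Reason]
    excluded_annotations: frozenset[str]


def resolve(
    ratings: Iterable[AssessorRating],
    *,
    n_assessors: int = 3,
    majority: int = 2,
) -> list[AdequacyResolution]:
    """Resolve assessor ratings into per-(image, landmark) consensus.

    Defaults implement the study's 2-of-3 majority; both counts are
    configurable for other review designs.  Raises :class:`CoverageError`
    when any (image, landmark) is not rated by exactly ``n_assessors``.
    """
    grouped: dict[tuple[str, ReviewLandmark], list[AssessorRating]] = defaultdict(list)
    for rating in ratings:
        grouped[(rating.image_id, rating.landmark)].append(rating)

    resolutions = []
    for (image_id, landmark), group in sorted(grouped.items()):
        assessors = {r.assessor_id for r in group}
        if len(group) != n_assessors or len(assessors) != n_assessors:
            raise CoverageError(
                f"({image_id!r}, {landmark}) rated by {len(assessors)} distinct "
                f"assessor(s) in {len(group)} rating(s); expected {n_assessors}"
            )
        n_flagging = sum(1 for r in group if r.flags)
        reason_votes = Counter()
        annotator_votes = Counter()
        for r in group:
            # Each clause counts assessors, so de-duplicate within a rating.
            for reason in {f.reason for f in r.flags}:
                reason_votes[reason] += 1
            for annotator in {f.annotator_id for f in r.flags}:
                annotator_votes[annotator] += 1
        resolutions.append(
            AdequacyResolution(
                image_id=image_id,
                landmark=landmark,
                landmark_inadequate=n_flagging >= majority,
                reasons_majority=frozenset(
                    r for r, v in reason_votes.items() if v >= majority
                ),
                excluded_annotations=frozenset(
                    a for a, v in annotator_votes.items() if v >= majority
                ),
            )
        )
    return resolutions


_ANY_COLUMN = "any_landmark"


def tabulate_landmark_wise(
    resolutions: Iterable[AdequacyResolution], n_images: int
) -> pd.DataFrame:
    """Per-landmark inadequate-image counts and percentages.

    Columns are the six review landmarks plus an ``any_landmark`` union
    column; rows are ``cases`` and ``percentage`` (100·count/n_images,
    rounded to 2 decimals).
    """
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    per_landmark: dict[ReviewLandmark, set[str]] = {lm: set() for lm in ReviewLandmark}
    any_images: set[str] = set()
    for res in resolutions:
        if res.landmark_inadequate:
            per_landmark[res.landmark].add(res.image_id)
            any_images.add(res.image_id)
    columns = [str(lm) for lm in ReviewLandmark] + [_ANY_COLUMN]
    counts = [len(per_landmark[lm]) for lm in ReviewLandmark] + [len(any_images)]
    pct = [round(100.0 * c / n_images, 2) for c in counts]
    return pd.DataFrame([counts, pct], index=["cases", "percentage"], columns=columns)


def tabulate_reason_wise(
    resolutions: Iterable[AdequacyResolution], n_images: int
) -> pd.DataFrame:
    """Per-(landmark, reason) counts of images with that majority reason.

    Reason majorities are independent of the landmark-wise and exclusion
    clauses, so no ordering between the tables is guaranteed.
    """
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    counts: Counter[tuple[ReviewLandmark, Reason]] = Counter()
    for res in resolutions:
        for reason in res.reasons_majority:
            counts[(res.landmark, reason)] += 1
    rows = []
    for landmark in ReviewLandmark:
        for reason in Reason:
            c = counts[(landmark, reason)]
            rows.append(
                {
                    "landmark": str(landmark),
                    "reason": str(reason),
                    "cases": c,
                    "percentage": round(100.0 * c / n_images, 2),
                }
            )
    return pd.DataFrame(rows, columns=["landmark", "reason", "cases", "percentage"])


def exclusion_mask(
    resolutions: Iterable[AdequacyResolution],
) -> set[tuple[str, ReviewLandmark, str]]:
    """The (image, landmark, annotator) triples excluded from the adequate set."""
    mask = set()
    for res in resolutions:
        for annotator in res.excluded_annotations:
            mask.add((res.image_id, res.landmark, annotator))
    return mask


def excluded_parameters(
    mask: Iterable[tuple[str, ReviewLandmark, str]],
) -> set[tuple[str, str, Parameter]]:
    """Map landmark exclusions to (image, annotator, parameter) removals.

    Excluding a landmark removes every tilt measurement whose computation
    uses it for that annotator; the sibling parameter computed from other
    landmarks is retained.
    """
    return {
        (image_id, annotator, PARAMETER_OF_LANDMARK[landmark])
        for image_id, landmark, annotator in mask
    }


# ---------------------------------------------------------------------------
# Ratings CSV: one all-satisfactory row (empty annotator_id/reason) or one
# row per flag, per (image, assessor, landmark).
# ---------------------------------------------------------------------------

RATING_COLUMNS = ["image_id", "assessor_id", "landmark", "annotator_id", "reason"]


def write_ratings(ratings: Iterable[AssessorRating], path: str | Path) -> None:
    rows = []
    for r in ratings:
        if r.all_satisfactory:
            rows.append(
                {"image_id": r.image_id, "assessor_id": r.assessor_id,
                 "landmark": str(r.landmark), "annotator_id": "", "reason": ""}
            )
        else:
            for f in r.flags:
                rows.append(
                    {"image_id": r.image_id, "assessor_id": r.assessor_id,
                     "landmark": str(r.landmark), "annotator_id": f.annotator_id,
                     "reason": str(f.reason)}
                )
    df = pd.DataFrame(rows, columns=RATING_COLUMNS)
    df = df.sort_values(RATING_COLUMNS, kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False)


def read_ratings(path: str | Path) -> list[AssessorRating]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings table is missing column(s): {', '.join(missing)}")
    ratings = []
    for (image_id, assessor_id, landmark), rows in df.groupby(
        ["image_id", "assessor_id", "landmark"], sort=True
    ):
        flags = [
            Flag(annotator_id=row.annotator_id, reason=Reason(row.reason))
            for row in rows.itertuples()
            if row.annotator_id != ""
        ]
        ratings.append(
            AssessorRating(
                image_id=str(image_id),
                assessor_id=str(assessor_id),
                landmark=ReviewLandmark(str(landmark)),
                flags=flags,
            )
        )
    return ratings
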