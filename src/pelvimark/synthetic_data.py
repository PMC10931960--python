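"""Synthetic annotation studies with known ground truth.

Real radiographs are not needed to exercise the pipeline: it consumes
pixel coordinates, so the generator builds a 2-D stick-figure pelvis per
image — two femoral-head circles, a sacral endplate, and the anatomical
(ASIS–pubic) line — placed so that the geometry module recovers the drawn
true tilt exactly from the noiseless landmarks.

Corruption mechanisms mirror the reasons assessors cite in practice:

* per-point Gaussian jitter (ordinary annotator imprecision);
* *outliers* — a landmark displaced far from its target; for the ASIS
  centre the canonical failure is a lateral shift toward one side's ASIS
  when the contralateral side is overlooked;
* *bad-quality* images, where every annotator's jitter is inflated;
* *anatomical anomalies*, where the apparent sacral endplate is offset
  (e.g. a lumbosacral transitional vertebra) and every annotator marks
  the offset plate.

Assessors are modelled as distance thresholds on the derived landmark
positions, with an independent verdict-flip probability; flag reasons are
read back from the corruption ledger.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .adequacy_review import AssessorRating, Flag, Reason, ReviewLandmark
from .geometry import DegenerateGeometryError, PosteriorDirection
from .landmarks_io import AnnotationSet, Landmark, LandmarkAnnotation, Method, Point2D

__all__ = [
    "PelvisTemplate",
    "NoiseModel",
    "AssessorModel",
    "SimulatedStudy",
    "REVIEW_OF_RAW",
    "generate_truth",
    "corrupt",
    "simulate_assessors",
    "simulate_study",
    "models_from_config",
]

#: Raw landmark → review-granularity landmark.
REVIEW_OF_RAW: Mapping[Landmark, ReviewLandmark] = {
    Landmark.ASIS_CENTRE: ReviewLandmark.ASIS_CENTRE,
    Landmark.PUBIC_TUBERCLE: ReviewLandmark.PUBIC_TUBERCLE,
    Landmark.FEMORAL_HEAD_1_CONTOUR: ReviewLandmark.FEMORAL_HEAD_CENTRE_CAL,
    Landmark.FEMORAL_HEAD_2_CONTOUR: ReviewLandmark.FEMORAL_HEAD_CENTRE_CAL,
    Landmark.SACRAL_PLATE_ANTERIOR: ReviewLandmark.SACRAL_MIDPOINT_CAL,
    Landmark.SACRAL_PLATE_POSTERIOR: ReviewLandmark.SACRAL_MIDPOINT_CAL,
    Landmark.FEMORAL_HEAD_CENTRE_EST: ReviewLandmark.FEMORAL_HEAD_CENTRE_EST,
    Landmark.SACRAL_MIDPOINT_EST: ReviewLandmark.SACRAL_MIDPOINT_EST,
}

_SACRAL_RAW = frozenset(
    {Landmark.SACRAL_PLATE_ANTERIOR, Landmark.SACRAL_PLATE_POSTERIOR,
     Landmark.SACRAL_MIDPOINT_EST}
)

# Contour sampling angles on each femoral-head circle (degrees): well
# spread so annotation noise is not amplified by a narrow arc.
_CONTOUR_ANGLES_DEG = (20.0, 140.0, 260.0)
# Fixed apparent sacral-slope of the synthetic endplate (degrees from
# horizontal); only the endplate *midpoint* enters the tilt, so this is
# cosmetic realism.
_ENDPLATE_SLOPE_DEG = 40.0
# Anterior offset of the ASIS–pubic line's reference origin from the
# femoral centre (px); translation-invariant, cosmetic only.
_APP_ANTERIOR_OFFSET_PX = 80.0


@dataclass(frozen=True)
class PelvisTemplate:
    """Geometric template of the synthetic pelvis.

    Distances are pixels at an EOS-like sagittal scale of roughly
    0.36 mm/px: a 25 mm femoral head is ~70 px and the femoral-centre to
    sacral-midpoint distance (~110 mm) is ~300 px.  Angles are degrees,
    posterior tilt positive.
    """

    true_pt_m: float = 13.0
    true_pt_a: float = 6.0
    femoral_centre: Point2D = Point2D(600.0, 900.0)
    head_separation: float = 30.0
    head_radius: float = 70.0
    sacral_distance: float = 300.0
    endplate_halfwidth: float = 70.0
    asis_distance: float = 160.0
    pubic_distance: float = 160.0
    posterior_direction: PosteriorDirection = PosteriorDirection.NEG_X


def _default_sigma() -> dict[Landmark, float]:
    return {lm: 1.0 for lm in Landmark}


def _default_outlier_prob() -> dict[Landmark, float]:
    # Relative frequencies follow the observed failure pattern: ASIS
    # outliers dominate, estimated femoral centres next, contour-based
    # landmarks rarely.
    return {
        Landmark.ASIS_CENTRE: 0.08,
        Landmark.PUBIC_TUBERCLE: 0.015,
        Landmark.FEMORAL_HEAD_1_CONTOUR: 0.01,
        Landmark.FEMORAL_HEAD_2_CONTOUR: 0.01,
        Landmark.FEMORAL_HEAD_CENTRE_EST: 0.07,
        Landmark.SACRAL_PLATE_ANTERIOR: 0.01,
        Landmark.SACRAL_PLATE_POSTERIOR: 0.01,
        Landmark.SACRAL_MIDPOINT_EST: 0.02,
    }


@dataclass
class NoiseModel:
    """Annotator corruption model; probabilities in [0, 1], sigmas >= 0."""

    sigma_px: dict[Landmark, float] = field(default_factory=_default_sigma)
    outlier_prob: dict[Landmark, float] = field(default_factory=_default_outlier_prob)
    outlier_shift_px: tuple[float, float] = (30.0, 60.0)
    bad_quality_image_prob: float = 0.15
    bad_quality_sigma_multiplier: float = 3.0
    anomaly_image_prob: float = 0.07
    anomaly_endplate_offset_px: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = list(self.outlier_prob.values()) + [
            self.bad_quality_image_prob, self.anomaly_image_prob
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(s < 0.0 for s in self.sigma_px.values()):
            raise ValueError("sigmas must be non-negative")


@dataclass
class AssessorModel:
    """Threshold assessor: flag when a derived landmark strays from truth."""

    flag_threshold_px: float = 15.0
    assessor_error_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flag_threshold_px <= 0.0:
            raise ValueError("flag threshold must be positive")
        if not 0.0 <= self.assessor_error_prob <= 1.0:
            raise ValueError("error probability must lie in [0, 1]")


def _up_vector(angle_deg: float, posterior: PosteriorDirection, length: float) -> tuple[float, float]:
    """Displacement from inferior to superior endpoint of a tilted body line."""
    rad = math.radians(angle_deg)
    run = length * math.sin(rad)
    if posterior == PosteriorDirection.NEG_X:
        run = -run
    return run, -length * math.cos(rad)  # y decreases upward


def _template_landmarks(template: PelvisTemplate, pt_m: float, pt_a: float) -> dict[Landmark, tuple[Point2D, ...]]:
    fc = template.femoral_centre
    pd_ = template.posterior_direction
    anterior_sign = 1.0 if pd_ == PosteriorDirection.NEG_X else -1.0

    half_sep = template.head_separation / 2.0
    centres = (Point2D(fc.x + half_sep, fc.y), Point2D(fc.x - half_sep, fc.y))
    contours = []
    for c in centres:
        pts = tuple(
            Point2D(c.x + template.head_radius * math.cos(math.radians(a)),
                    c.y + template.head_radius * math.sin(math.radians(a)))
            for a in _CONTOUR_ANGLES_DEG
        )
        contours.append(pts)

    dx, dy = _up_vector(pt_m, pd_, template.sacral_distance)
    sacral_mid = Point2D(fc.x + dx, fc.y + dy)
    slope = math.radians(_ENDPLATE_SLOPE_DEG)
    ex = anterior_sign * template.endplate_halfwidth * math.cos(slope)
    ey = template.endplate_halfwidth * math.sin(slope)
    anterior = Point2D(sacral_mid.x + ex, sacral_mid.y + ey)
    posterior = Point2D(sacral_mid.x - ex, sacral_mid.y - ey)

    origin = Point2D(fc.x + anterior_sign * _APP_ANTERIOR_OFFSET_PX, fc.y)
    ax, ay = _up_vector(pt_a, pd_, template.asis_distance)
    px, py = _up_vector(pt_a, pd_, template.pubic_distance)
    asis = Point2D(origin.x + ax, origin.y + ay)
    pubic = Point2D(origin.x - px, origin.y - py)

    return {
        Landmark.FEMORAL_HEAD_1_CONTOUR: contours[0],
        Landmark.FEMORAL_HEAD_2_CONTOUR: contours[1],
        Landmark.SACRAL_PLATE_ANTERIOR: (anterior,),
        Landmark.SACRAL_PLATE_POSTERIOR: (posterior,),
        Landmark.FEMORAL_HEAD_CENTRE_EST: (fc,),
        Landmark.SACRAL_MIDPOINT_EST: (sacral_mid,),
        Landmark.ASIS_CENTRE: (asis,),
        Landmark.PUBIC_TUBERCLE: (pubic,),
    }


_METHOD_OF_RAW = {
    Landmark.FEMORAL_HEAD_1_CONTOUR: Method.CALCULATION,
    Landmark.FEMORAL_HEAD_2_CONTOUR: Method.CALCULATION,
    Landmark.SACRAL_PLATE_ANTERIOR: Method.CALCULATION,
    Landmark.SACRAL_PLATE_POSTERIOR: Method.CALCULATION,
    Landmark.FEMORAL_HEAD_CENTRE_EST: Method.ESTIMATION,
    Landmark.SACRAL_MIDPOINT_EST: Method.ESTIMATION,
    Landmark.ASIS_CENTRE: Method.ESTIMATION,
    Landmark.PUBIC_TUBERCLE: Method.ESTIMATION,
}

TRUTH_ANNOTATOR = "truth"


def generate_truth(
    template: PelvisTemplate,
    n_images: int,
    pt_jitter_deg: float = 5.0,
    seed: int = 0,
) -> tuple[list[AnnotationSet], pd.DataFrame]:
    """Noiseless per-image annotation sets plus a truth table.

    Each image draws its true tilts uniformly within ±``pt_jitter_deg`` of
    the template values; landmark coordinates invert the tilt geometry so
    measurement recovers the drawn truth exactly.
    """
    rng = np.random.default_rng(seed)
    sets: list[AnnotationSet] = []
    rows = []
    for i in range(n_images):
        image_id = f"img_{i:04d}"
        pt_m = template.true_pt_m + rng.uniform(-pt_jitter_deg, pt_jitter_deg)
        pt_a = template.true_pt_a + rng.uniform(-pt_jitter_deg, pt_jitter_deg)
        landmarks = _template_landmarks(template, pt_m, pt_a)
        annotations = [
            LandmarkAnnotation(
                image_id=image_id,
                annotator_id=TRUTH_ANNOTATOR,
                method=_METHOD_OF_RAW[lm],
                landmark=lm,
                points=pts,
            )
            for lm, pts in landmarks.items()
        ]
        sets.append(AnnotationSet(image_id=image_id, annotations=annotations))
        rows.append({"image_id": image_id, "true_pt_m_deg": pt_m, "true_pt_a_deg": pt_a})
    truth = pd.DataFrame(rows, columns=["image_id", "true_pt_m_deg", "true_pt_a_deg"])
    return sets, truth


def corrupt(
    truth_sets: Sequence[AnnotationSet],
    n_annotators: int,
    noise: NoiseModel,
) -> tuple[list[AnnotationSet], list[dict]]:
    """Replicate the truth across annotators with injected corruption.

    Returns the corrupted sets and a ledger of every injected corruption:
    image-level ``bad_quality``/``anomaly`` records and per-annotation
    ``outlier`` records (with the review-level landmark and shift size).
    """
    rng = np.random.default_rng(noise.seed)
    annotators = [f"ann{j + 1}" for j in range(n_annotators)]
    out_sets: list[AnnotationSet] = []
    ledger: list[dict] = []
    lo, hi = noise.outlier_shift_px
    for truth_set in truth_sets:
        image_id = truth_set.image_id
        truth_by_lm = {a.landmark: a for a in truth_set.annotations}
        bad = rng.random() < noise.bad_quality_image_prob
        anomalous = rng.random() < noise.anomaly_image_prob
        if bad:
            ledger.append({"image_id": image_id, "kind": "bad_quality"})
        if anomalous:
            ledger.append({"image_id": image_id, "kind": "anomaly"})
        annotations = []
        for annotator in annotators:
            outlier_seen: set[ReviewLandmark] = set()
            for lm in Landmark:
                truth_ann = truth_by_lm[lm]
                pts = np.array([[p.x, p.y] for p in truth_ann.points], float)
                if anomalous and lm in _SACRAL_RAW:
                    # All annotators mark the apparent (offset) plate.
                    pts[:, 1] -= noise.anomaly_endplate_offset_px
                sigma = noise.sigma_px[lm]
                if bad:
                    sigma *= noise.bad_quality_sigma_multiplier
                if sigma > 0:
                    pts += rng.normal(0.0, sigma, pts.shape)
                if rng.random() < noise.outlier_prob[lm]:
                    shift = rng.uniform(lo, hi)
                    if lm == Landmark.ASIS_CENTRE:
                        # Contralateral-ASIS failure: purely lateral shift.
                        direction = np.array([rng.choice([-1.0, 1.0]), 0.0])
                    else:
                        theta = rng.uniform(0.0, 2.0 * math.pi)
                        direction = np.array([math.cos(theta), math.sin(theta)])
                    pts += shift * direction
                    review_lm = REVIEW_OF_RAW[lm]
                    if review_lm not in outlier_seen:
                        outlier_seen.add(review_lm)
                        ledger.append(
                            {"image_id": image_id, "annotator_id": annotator,
                             "kind": "outlier", "landmark": review_lm,
                             "shift_px": float(shift)}
                        )
                annotations.append(
                    LandmarkAnnotation(
                        image_id=image_id,
                        annotator_id=annotator,
                        method=truth_ann.method,
                        landmark=lm,
                        points=tuple(Point2D(float(x), float(y)) for x, y in pts),
                    )
                )
        out_sets.append(AnnotationSet(image_id=image_id, annotations=annotations))
    return out_sets, ledger


def _derived_positions(annotation_set: AnnotationSet, annotator: str) -> dict[ReviewLandmark, Point2D | None]:
    """Review-level landmark positions as an assessor would judge them."""
    out: dict[ReviewLandmark, Point2D | None] = {}
    get = annotation_set.get
    for lm, review in (
        (Landmark.ASIS_CENTRE, ReviewLandmark.ASIS_CENTRE),
        (Landmark.PUBIC_TUBERCLE, ReviewLandmark.PUBIC_TUBERCLE),
        (Landmark.FEMORAL_HEAD_CENTRE_EST, ReviewLandmark.FEMORAL_HEAD_CENTRE_EST),
        (Landmark.SACRAL_MIDPOINT_EST, ReviewLandmark.SACRAL_MIDPOINT_EST),
    ):
        ann = get(annotator, lm)
        out[review] = ann.points[0] if ann else None
    try:
        out[ReviewLandmark.FEMORAL_HEAD_CENTRE_CAL] = geometry.femoral_head_centre_cal(
            annotation_set, annotator
        )
    except (DegenerateGeometryError, KeyError):
        out[ReviewLandmark.FEMORAL_HEAD_CENTRE_CAL] = None
    try:
        out[ReviewLandmark.SACRAL_MIDPOINT_CAL] = geometry.sacral_midpoint_cal(
            annotation_set, annotator
        )
    except KeyError:
        out[ReviewLandmark.SACRAL_MIDPOINT_CAL] = None
    return out


def simulate_assessors(
    corrupted: Sequence[AnnotationSet],
    truth_sets: Sequence[AnnotationSet],
    model: AssessorModel,
    n_assessors: int = 3,
    ledger: Iterable[dict] | None = None,
) -> list[AssessorRating]:
    """Threshold assessors rating every (image, landmark, annotator).

    An assessor flags an annotation when its derived review-level position
    lies farther than ``flag_threshold_px`` from the truth (or cannot be
    computed), then flips the verdict independently with
    ``assessor_error_prob``.  Flag reasons are looked up in the corruption
    ledger: an injected outlier → outlier, an anomalous image's sacral
    landmarks → anomaly, a bad-quality image → bad quality, anything else
    → other.
    """
    if len(corrupted) != len(truth_sets):
        raise ValueError("corrupted and truth collections are not aligned")
    outliers: set[tuple[str, str, ReviewLandmark]] = set()
    bad_images: set[str] = set()
    anomalous_images: set[str] = set()
    for rec in ledger or ():
        if rec["kind"] == "outlier":
            outliers.add((rec["image_id"], rec["annotator_id"], rec["landmark"]))
        elif rec["kind"] == "bad_quality":
            bad_images.add(rec["image_id"])
        elif rec["kind"] == "anomaly":
            anomalous_images.add(rec["image_id"])

    def reason_for(image_id: str, annotator: str, review_lm: ReviewLandmark) -> Reason:
        if (image_id, annotator, review_lm) in outliers:
            return Reason.OUTLIER
        if image_id in anomalous_images and review_lm in (
            ReviewLandmark.SACRAL_MIDPOINT_CAL, ReviewLandmark.SACRAL_MIDPOINT_EST
        ):
            return Reason.ANOMALY
        if image_id in bad_images:
            return Reason.BAD_QUALITY
        return Reason.OTHER

    truth_positions = {}
    corrupted_positions = {}
    annotators_by_image = {}
    for truth_set, corr_set in zip(truth_sets, corrupted):
        if truth_set.image_id != corr_set.image_id:
            raise ValueError("corrupted and truth collections are not aligned")
        truth_positions[truth_set.image_id] = _derived_positions(
            truth_set, truth_set.annotator_ids[0]
        )
        annotators = corr_set.annotator_ids
        annotators_by_image[corr_set.image_id] = annotators
        corrupted_positions[corr_set.image_id] = {
            a: _derived_positions(corr_set, a) for a in annotators
        }

    rng = np.random.default_rng(model.seed)
    ratings: list[AssessorRating] = []
    for j in range(n_assessors):
        assessor_id = f"assessor{j + 1}"
        for corr_set in corrupted:
            image_id = corr_set.image_id
            for review_lm in ReviewLandmark:
                flags = []
                for annotator in annotators_by_image[image_id]:
                    pos = corrupted_positions[image_id][annotator][review_lm]
                    ref = truth_positions[image_id][review_lm]
                    if pos is None or ref is None:
                        would_flag = True
                    else:
                        would_flag = math.hypot(pos.x - ref.x, pos.y - ref.y) > model.flag_threshold_px
                    flip = rng.random() < model.assessor_error_prob
                    if would_flag != flip:
                        flags.append(Flag(annotator, reason_for(image_id, annotator, review_lm)))
                ratings.append(
                    AssessorRating(
                        image_id=image_id,
                        assessor_id=assessor_id,
                        landmark=review_lm,
                        flags=flags,
                    )
                )
    return ratings


@dataclass
class SimulatedStudy:
    """All artefacts of one synthetic annotation study."""

    truth_sets: list[AnnotationSet]
    truth_table: pd.DataFrame
    corrupted_sets: list[AnnotationSet]
    corruption_ledger: list[dict]
    ratings: list[AssessorRating]


def simulate_study(
    template: PelvisTemplate | None = None,
    noise: NoiseModel | None = None,
    assessor_model: AssessorModel | None = None,
    *,
    n_images: int = 115,
    n_annotators: int = 5,
    n_assessors: int = 3,
    pt_jitter_deg: float = 5.0,
    seed: int = 0,
) -> SimulatedStudy:
    """Run truth generation, corruption and assessor review end to end.

    ``seed`` deterministically derives independent sub-seeds for the three
    stages; seeds set explicitly on the models are overridden.
    """
    template = template or PelvisTemplate()
    noise = noise or NoiseModel()
    assessor_model = assessor_model or AssessorModel()
    sub = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    truth_sets, truth_table = generate_truth(
        template, n_images, pt_jitter_deg, seed=int(sub[0])
    )
    noise = dataclasses.replace(noise, seed=int(sub[1]))
    corrupted, ledger = corrupt(truth_sets, n_annotators, noise)
    assessor_model = dataclasses.replace(assessor_model, seed=int(sub[2]))
    ratings = simulate_assessors(
        corrupted, truth_sets, assessor_model, n_assessors, ledger
    )
    return SimulatedStudy(
        truth_sets=truth_sets,
        truth_table=truth_table,
        corrupted_sets=corrupted,
        corruption_ledger=ledger,
        ratings=ratings,
    )


def models_from_config(config: Mapping) -> tuple[PelvisTemplate, NoiseModel, AssessorModel]:
    """Build the three simulation models from a (YAML-loaded) mapping.

    Recognised top-level keys: ``template``, ``noise``, ``assessor``; each
    maps field names to values.  Landmark-keyed maps use landmark names.
    """
    tconf = dict(config.get("template", {}))
    if "femoral_centre" in tconf:
        tconf["femoral_centre"] = Point2D(*tconf["femoral_centre"])
    if "posterior_direction" in tconf:
        tconf["posterior_direction"] = PosteriorDirection(tconf["posterior_direction"])
    nconf = dict(config.get("noise", {}))
    for key in ("sigma_px", "outlier_prob"):
        if key in nconf:
            base = _default_sigma() if key == "sigma_px" else _default_outlier_prob()
            base.update({Landmark(k): float(v) for k, v in nconf[key].items()})
            nconf[key] = base
    if "outlier_shift_px" in nconf:
        nconf["outlier_shift_px"] = tuple(nconf["outlier_shift_px"])
    aconf = dict(config.get("assessor", {}))
    return PelvisTemplate(**tconf), NoiseModel(**nconf), AssessorModel(**aconf)
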