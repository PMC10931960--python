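"""Pelvic-tilt geometry: circumcentres, landmark constructions and angles.

Two pelvic-tilt definitions are supported, both measured against the
gravity line (the image vertical):

* **mechanical tilt** (``PT_m``) — angle between the vertical and the line
  from the femoral-head centre (inferior) to the sacral-endplate midpoint
  (superior);
* **anatomical tilt** (``PT_a``) — angle between the vertical and the line
  from the pubic tubercle (inferior) to the ASIS centre (superior), i.e.
  the anterior-pelvic-plane definition.

The mechanical tilt comes in two method variants: *calculation* (femoral
centre = midpoint of the circumcentres of the two 3-point head contours;
sacral midpoint = midpoint of the annotated endplate ends) and
*estimation* (both points clicked directly).  The anatomical tilt uses
clicked points only.

Sign convention: posterior pelvic tilt is positive.  Because a patient may
face either image direction, the caller states which x direction is
posterior (``neg_x`` or ``pos_x``) per dataset.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .landmarks_io import AnnotationSet, Landmark, Method, Point2D

__all__ = [
    "Definition",
    "PosteriorDirection",
    "Parameter",
    "PTMeasurement",
    "DegenerateGeometryError",
    "MissingLandmarkError",
    "OrientationError",
    "circumcentre",
    "femoral_head_centre_cal",
    "sacral_midpoint_cal",
    "angle_to_vertical",
    "compute_pt",
    "compute_all",
    "measurements_to_frame",
    "frame_to_measurements",
    "COLLINEARITY_TOL",
]

#: Triangle area below ``tol * longest_side**2`` is treated as collinear.
COLLINEARITY_TOL = 1e-6


class Definition(enum.StrEnum):
    PT_A = "PT_a"
    PT_M = "PT_m"


class PosteriorDirection(enum.StrEnum):
    NEG_X = "neg_x"
    POS_X = "pos_x"


class Parameter(enum.StrEnum):
    """The three tilt parameters the study reports."""

    PT_M_CAL = "PT_m_cal"
    PT_M_EST = "PT_m_est"
    PT_A = "PT_a"

    @classmethod
    def from_definition_method(cls, definition: Definition, method: Method) -> "Parameter":
        if definition == Definition.PT_A:
            return cls.PT_A
        return cls.PT_M_CAL if method == Method.CALCULATION else cls.PT_M_EST


class DegenerateGeometryError(ValueError):
    """Contour points are collinear within tolerance; no circle exists."""


class MissingLandmarkError(KeyError):
    """A landmark required by the requested parameter is absent."""


class OrientationError(ValueError):
    """Line endpoints coincide or the superior point is not above the inferior."""


@dataclass(frozen=True)
class PTMeasurement:
    """A signed pelvic-tilt angle for (image, annotator, definition, method)."""

    image_id: str
    annotator_id: str
    definition: Definition
    method: Method
    angle: float  # degrees, posterior tilt positive

    def __post_init__(self) -> None:
        if not -90.0 < self.angle < 90.0:
            raise ValueError(f"pelvic tilt {self.angle}° outside (−90°, 90°)")
        if self.definition == Definition.PT_A and self.method != Method.ESTIMATION:
            raise ValueError("anatomical tilt is defined from clicked points only")

    @property
    def parameter(self) -> Parameter:
        return Parameter.from_definition_method(self.definition, self.method)


def circumcentre(
    p1: Point2D, p2: Point2D, p3: Point2D, *, context: str = "contour"
) -> Point2D:
    """Centre of the unique circle through three non-collinear points.

    Collinearity is judged scale-free: the triangle is degenerate when its
    area falls below ``COLLINEARITY_TOL`` times the squared longest side.
    """
    ax, ay = p1.x, p1.y
    bx, by = p2.x, p2.y
    cx, cy = p3.x, p3.y
    # Twice the signed triangle area.
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    longest_sq = max(
        (ax - bx) ** 2 + (ay - by) ** 2,
        (bx - cx) ** 2 + (by - cy) ** 2,
        (cx - ax) ** 2 + (cy - ay) ** 2,
    )
    if abs(d) / 2.0 <= COLLINEARITY_TOL * longest_sq or longest_sq == 0.0:
        raise DegenerateGeometryError(
            f"collinear {context} points; cannot fit a circle"
        )
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    return Point2D(ux, uy)


def _require(annotation_set: AnnotationSet, annotator: str, landmark: Landmark):
    ann = annotation_set.get(annotator, landmark)
    if ann is None:
        raise MissingLandmarkError(
            f"annotator {annotator!r} has no {landmark} on image "
            f"{annotation_set.image_id!r}"
        )
    return ann


def femoral_head_centre_cal(annotation_set: AnnotationSet, annotator: str) -> Point2D:
    """Femoral-head centre from the two 3-point contours.

    Each contour determines its head centre exactly (circumcentre); the
    bicoxofemoral centre is the midpoint of the two head centres.
    """
    c1 = circumcentre(
        *_require(annotation_set, annotator, Landmark.FEMORAL_HEAD_1_CONTOUR).points,
        context=f"{Landmark.FEMORAL_HEAD_1_CONTOUR} (image {annotation_set.image_id!r})",
    )
    c2 = circumcentre(
        *_require(annotation_set, annotator, Landmark.FEMORAL_HEAD_2_CONTOUR).points,
        context=f"{Landmark.FEMORAL_HEAD_2_CONTOUR} (image {annotation_set.image_id!r})",
    )
    return Point2D((c1.x + c2.x) / 2.0, (c1.y + c2.y) / 2.0)


def sacral_midpoint_cal(annotation_set: AnnotationSet, annotator: str) -> Point2D:
    """Midpoint of the annotated anterior and posterior sacral-endplate ends."""
    a = _require(annotation_set, annotator, Landmark.SACRAL_PLATE_ANTERIOR).points[0]
    p = _require(annotation_set, annotator, Landmark.SACRAL_PLATE_POSTERIOR).points[0]
    return Point2D((a.x + p.x) / 2.0, (a.y + p.y) / 2.0)


def angle_to_vertical(
    inferior: Point2D,
    superior: Point2D,
    posterior_direction: PosteriorDirection | str,
) -> float:
    """Signed angle (degrees) between a body line and the upward vertical.

    The line runs from the inferior to the superior point; the superior
    point must lie strictly above (smaller y).  The angle is positive when
    the superior point leans toward the stated posterior direction,
    i.e. posterior tilt positive.
    """
    posterior_direction = PosteriorDirection(posterior_direction)
    rise = inferior.y - superior.y  # >0 when superior is above (y grows downward)
    run = superior.x - inferior.x
    if rise == 0.0 and run == 0.0:
        raise OrientationError("line endpoints coincide")
    if rise <= 0.0:
        raise OrientationError(
            "superior point must lie strictly above the inferior point"
        )
    signed_run = -run if posterior_direction == PosteriorDirection.NEG_X else run
    return math.degrees(math.atan2(signed_run, rise))


def compute_pt(
    annotation_set: AnnotationSet,
    annotator: str,
    definition: Definition | str,
    method: Method | str,
    posterior_direction: PosteriorDirection | str = PosteriorDirection.NEG_X,
) -> PTMeasurement:
    """Compute one pelvic-tilt measurement from an annotation set.

    Raises :class:`MissingLandmarkError` when the required landmarks are
    absent and :class:`DegenerateGeometryError` for collinear contours.
    """
    definition = Definition(definition)
    method = Method(method)
    if definition == Definition.PT_A:
        if method != Method.ESTIMATION:
            raise ValueError("anatomical tilt exists only with clicked points")
        inferior = _require(annotation_set, annotator, Landmark.PUBIC_TUBERCLE).points[0]
        superior = _require(annotation_set, annotator, Landmark.ASIS_CENTRE).points[0]
    else:
        if method == Method.CALCULATION:
            inferior = femoral_head_centre_cal(annotation_set, annotator)
            superior = sacral_midpoint_cal(annotation_set, annotator)
        else:
            inferior = _require(
                annotation_set, annotator, Landmark.FEMORAL_HEAD_CENTRE_EST
            ).points[0]
            superior = _require(
                annotation_set, annotator, Landmark.SACRAL_MIDPOINT_EST
            ).points[0]
    angle = angle_to_vertical(inferior, superior, posterior_direction)
    return PTMeasurement(
        image_id=annotation_set.image_id,
        annotator_id=annotator,
        definition=definition,
        method=method,
        angle=angle,
    )


_VARIANTS: tuple[tuple[Definition, Method], ...] = (
    (Definition.PT_M, Method.CALCULATION),
    (Definition.PT_M, Method.ESTIMATION),
    (Definition.PT_A, Method.ESTIMATION),
)


def compute_all(
    sets: Iterable[AnnotationSet],
    posterior_direction: PosteriorDirection | str = PosteriorDirection.NEG_X,
    *,
    on_error: str = "skip",
) -> list[PTMeasurement]:
    """Compute every available parameter variant per annotator per image.

    ``on_error='skip'`` silently omits variants whose landmarks are missing
    or degenerate (partial annotation sets are normal in practice);
    ``on_error='raise'`` propagates the first failure.
    """
    out: list[PTMeasurement] = []
    for annotation_set in sets:
        for annotator in annotation_set.annotator_ids:
            for definition, method in _VARIANTS:
                try:
                    out.append(
                        compute_pt(annotation_set, annotator, definition, method,
                                   posterior_direction)
                    )
                except (MissingLandmarkError, DegenerateGeometryError):
                    if on_error == "raise":
                        raise
    return out


def measurements_to_frame(measurements: Iterable[PTMeasurement]) -> pd.DataFrame:
    """Tidy measurement table: image_id, annotator_id, definition, method, angle_deg."""
    df = pd.DataFrame(
        [
            {
                "image_id": m.image_id,
                "annotator_id": m.annotator_id,
                "definition": str(m.definition),
                "method": str(m.method),
                "angle_deg": m.angle,
            }
            for m in measurements
        ],
        columns=["image_id", "annotator_id", "definition", "method", "angle_deg"],
    )
    return df.sort_values(
        ["image_id", "annotator_id", "definition", "method"], kind="stable"
    ).reset_index(drop=True)


def frame_to_measurements(df: pd.DataFrame) -> list[PTMeasurement]:
    return [
        PTMeasurement(
            image_id=str(r.image_id),
            annotator_id=str(r.annotator_id),
            definition=Definition(r.definition),
            method=Method(r.method),
            angle=float(r.angle_deg),
        )
        for r in df.itertuples()
    ]
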