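"""Data model and I/O for radiographic pelvic-landmark annotations.

Coordinate convention: image pixel coordinates, origin at the top-left
corner, ``x`` along image columns, ``y`` along image rows and increasing
downward.  The gravity line is the image vertical (standing biplanar
acquisition implies a plumb vertical).  All distances are in pixels; no
physical calibration is required because pelvic tilt is an angle.

Each image carries annotations from several independent annotators, each
using two measurement styles:

* the *calculation* method derives landmarks from annotated bone contours
  (three points per femoral-head contour, two points for the anterior and
  posterior ends of the sacral endplate);
* the *estimation* method places a single click on the presumed landmark
  location (femoral-head centre, sacral-endplate midpoint).

The ASIS-centre and pubic-tubercle clicks that define the anatomical
pelvic-tilt line are single clicked points and are stored under the
estimation method by convention.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Point2D",
    "Method",
    "Landmark",
    "LandmarkAnnotation",
    "AnnotationSet",
    "SchemaError",
    "ValidationError",
    "EXPECTED_POINT_COUNT",
    "LANDMARKS_BY_METHOD",
    "read_landmarks",
    "write_landmarks",
    "render_overlay",
]

LANDMARK_COLUMNS = ["image_id", "annotator_id", "method", "landmark", "point_index", "x", "y"]


class SchemaError(ValueError):
    """A landmark table is missing required columns/keys."""


class ValidationError(ValueError):
    """An annotation violates the data-model invariants."""


@dataclass(frozen=True)
class Point2D:
    """A pixel coordinate (x = column, y = row, y increases downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinates ({self.x}, {self.y})")


class Method(enum.StrEnum):
    CALCULATION = "calculation"
    ESTIMATION = "estimation"


class Landmark(enum.StrEnum):
    ASIS_CENTRE = "asis_centre"
    PUBIC_TUBERCLE = "pubic_tubercle"
    FEMORAL_HEAD_1_CONTOUR = "femoral_head_1_contour"
    FEMORAL_HEAD_2_CONTOUR = "femoral_head_2_contour"
    FEMORAL_HEAD_CENTRE_EST = "femoral_head_centre_est"
    SACRAL_PLATE_ANTERIOR = "sacral_plate_anterior"
    SACRAL_PLATE_POSTERIOR = "sacral_plate_posterior"
    SACRAL_MIDPOINT_EST = "sacral_midpoint_est"


#: Number of points each landmark must carry.
EXPECTED_POINT_COUNT: Mapping[Landmark, int] = {
    Landmark.ASIS_CENTRE: 1,
    Landmark.PUBIC_TUBERCLE: 1,
    Landmark.FEMORAL_HEAD_1_CONTOUR: 3,
    Landmark.FEMORAL_HEAD_2_CONTOUR: 3,
    Landmark.FEMORAL_HEAD_CENTRE_EST: 1,
    Landmark.SACRAL_PLATE_ANTERIOR: 1,
    Landmark.SACRAL_PLATE_POSTERIOR: 1,
    Landmark.SACRAL_MIDPOINT_EST: 1,
}

#: Landmarks legal under each method.  The anatomical-definition clicks
#: (ASIS centre, pubic tubercle) are single clicked points and therefore
#: travel with the estimation method.
LANDMARKS_BY_METHOD: Mapping[Method, frozenset[Landmark]] = {
    Method.CALCULATION: frozenset(
        {
            Landmark.FEMORAL_HEAD_1_CONTOUR,
            Landmark.FEMORAL_HEAD_2_CONTOUR,
            Landmark.SACRAL_PLATE_ANTERIOR,
            Landmark.SACRAL_PLATE_POSTERIOR,
        }
    ),
    Method.ESTIMATION: frozenset(
        {
            Landmark.ASIS_CENTRE,
            Landmark.PUBIC_TUBERCLE,
            Landmark.FEMORAL_HEAD_CENTRE_EST,
            Landmark.SACRAL_MIDPOINT_EST,
        }
    ),
}


@dataclass(frozen=True)
class LandmarkAnnotation:
    """One annotator's placement(s) for one landmark on one image."""

    image_id: str
    annotator_id: str
    method: Method
    landmark: Landmark
    points: tuple[Point2D, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        expected = EXPECTED_POINT_COUNT[self.landmark]
        if len(self.points) != expected:
            raise ValidationError(
                f"landmark {self.landmark} on image {self.image_id!r} by annotator "
                f"{self.annotator_id!r} has {len(self.points)} point(s); expected {expected}"
            )
        if self.landmark not in LANDMARKS_BY_METHOD[self.method]:
            raise ValidationError(
                f"landmark {self.landmark} is not valid under method {self.method} "
                f"(image {self.image_id!r}, annotator {self.annotator_id!r})"
            )


@dataclass
class AnnotationSet:
    """All landmark annotations for one image, across annotators and methods."""

    image_id: str
    annotations: list[LandmarkAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, Method, Landmark]] = set()
        for ann in self.annotations:
            if ann.image_id != self.image_id:
                raise ValidationError(
                    f"annotation for image {ann.image_id!r} placed in set {self.image_id!r}"
                )
            key = (ann.annotator_id, ann.method, ann.landmark)
            if key in seen:
                raise ValidationError(
                    f"duplicate annotation {key} on image {self.image_id!r}"
                )
            seen.add(key)

    @property
    def annotator_ids(self) -> list[str]:
        return sorted({a.annotator_id for a in self.annotations})

    def get(self, annotator_id: str, landmark: Landmark) -> LandmarkAnnotation | None:
        for ann in self.annotations:
            if ann.annotator_id == annotator_id and ann.landmark == landmark:
                return ann
        return None


# ---------------------------------------------------------------------------
# Readers / writers
#
# CSV: comma-separated, UTF-8, header required, one row per point with a
# 0-based point_index.  JSON: a list of annotation objects each holding its
# point list.  Both dialects round-trip exactly.
# ---------------------------------------------------------------------------


def _sets_from_rows(df: pd.DataFrame) -> list[AnnotationSet]:
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"landmark table is missing column(s): {', '.join(missing)}")
    unknown = set(df["landmark"].astype(str)) - {str(lm) for lm in Landmark}
    if unknown:
        raise ValidationError(f"unknown landmark name(s): {', '.join(sorted(unknown))}")

    sets: list[AnnotationSet] = []
    for image_id, img_rows in df.groupby("image_id", sort=True):
        annotations = []
        group_cols = ["annotator_id", "method", "landmark"]
        for (annotator, method, landmark), rows in img_rows.groupby(group_cols, sort=True):
            rows = rows.sort_values("point_index")
            points = tuple(Point2D(float(x), float(y)) for x, y in zip(rows["x"], rows["y"]))
            annotations.append(
                LandmarkAnnotation(
                    image_id=str(image_id),
                    annotator_id=str(annotator),
                    method=Method(str(method)),
                    landmark=Landmark(str(landmark)),
                    points=points,
                )
            )
        sets.append(AnnotationSet(image_id=str(image_id), annotations=annotations))
    return sets


def _rows_from_sets(sets: Iterable[AnnotationSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        for ann in s.annotations:
            for i, p in enumerate(ann.points):
                rows.append(
                    {
                        "image_id": s.image_id,
                        "annotator_id": ann.annotator_id,
                        "method": str(ann.method),
                        "landmark": str(ann.landmark),
                        "point_index": i,
                        "x": p.x,
                        "y": p.y,
                    }
                )
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    return df.sort_values(LANDMARK_COLUMNS[:5], kind="stable").reset_index(drop=True)


def _infer_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "json" if str(path).lower().endswith(".json") else "csv"


def read_landmarks(path: str | Path, dialect: str | None = None) -> list[AnnotationSet]:
    """Read landmark annotations from CSV or JSON into validated sets.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for unknown landmark names or wrong point
    counts.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        df = pd.read_csv(
            path,
            dtype={"image_id": str, "annotator_id": str},
            float_precision="round_trip",
        )
    elif dialect == "json":
        with open(path, encoding="utf-8") as fh:
            records = json.load(fh)
        rows = []
        for rec in records:
            for key in ("image_id", "annotator_id", "method", "landmark", "points"):
                if key not in rec:
                    raise SchemaError(f"landmark JSON record is missing key: {key}")
            for i, (x, y) in enumerate(rec["points"]):
                rows.append(
                    {
                        "image_id": rec["image_id"],
                        "annotator_id": rec["annotator_id"],
                        "method": rec["method"],
                        "landmark": rec["landmark"],
                        "point_index": i,
                        "x": x,
                        "y": y,
                    }
                )
        df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _sets_from_rows(df)


def write_landmarks(
    sets: Iterable[AnnotationSet], path: str | Path, dialect: str | None = None
) -> None:
    """Write annotation sets with a deterministic row order.

    Rows are sorted by (image_id, annotator_id, method, landmark,
    point_index); an empty collection yields a header-only CSV or an empty
    JSON list.
    """
    dialect = _infer_dialect(path, dialect)
    df = _rows_from_sets(sets)
    if dialect == "csv":
        df.to_csv(path, index=False)
    elif dialect == "json":
        records = []
        for (image, annotator, method, landmark), rows in df.groupby(
            ["image_id", "annotator_id", "method", "landmark"], sort=True
        ):
            rows = rows.sort_values("point_index")
            records.append(
                {
                    "image_id": image,
                    "annotator_id": annotator,
                    "method": method,
                    "landmark": landmark,
                    "points": [[float(x), float(y)] for x, y in zip(rows["x"], rows["y"])],
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# Marker shapes follow the annotated-figure convention: round markers for
# directly clicked (estimation) points, triangles for points that belong to
# contour-based (calculation) landmarks.
_METHOD_MARKER = {Method.ESTIMATION: ("o", "clicked (estimation)"),
                  Method.CALCULATION: ("^", "contour-derived (calculation)")}


def render_overlay(
    annotation_set: AnnotationSet,
    out: str | Path,
    background=None,
) -> None:
    """Render one image's annotations to a PNG.

    Colour encodes the annotator; marker shape encodes the method (round =
    directly clicked estimation points, triangle = calculation-method
    contour points).  ``background`` is an optional 2-D grayscale array.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if background is not None:
        ax.imshow(background, cmap="gray")
    cmap = plt.get_cmap("tab10")
    annotators = annotation_set.annotator_ids
    for ai, annotator in enumerate(annotators):
        colour = cmap(ai % 10)
        for method, (marker, _) in _METHOD_MARKER.items():
            xs, ys = [], []
            for ann in annotation_set.annotations:
                if ann.annotator_id == annotator and ann.method == method:
                    xs.extend(p.x for p in ann.points)
                    ys.extend(p.y for p in ann.points)
            if xs:
                ax.scatter(xs, ys, color=colour, marker=marker, s=30,
                           label=f"{annotator} · {_METHOD_MARKER[method][1]}")
    if annotators:
        ax.legend(fontsize=6, loc="upper right")
    ax.set_title(f"image {annotation_set.image_id}")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.invert_yaxis()  # y grows downward in image space
    ax.set_aspect("equal")
    fig.savefig(out, dpi=100, metadata={"Software": None})
    plt.close(fig)
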