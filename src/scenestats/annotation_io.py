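"""Reading, writing and cleaning polygon scene annotations.

Annotations follow the LabelMe dialect: one XML document per image, holding
the image dimensions and one ``<object>`` element per labeled region with a
free-text name and a polygon given as an ordered list of vertices.
Coordinates are continuous, 0-based, ``x`` rightward and ``y`` downward from
the top-left corner.

Free-text labeling produces typos, plural/singular variants, subordinate or
superordinate names and synonyms; :func:`normalize_labels` applies a
user-supplied normalization table (rename or delete, each entry tagged with
the class of change) to bring the vocabulary to canonical form.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from lxml import etree

logger = logging.getLogger(__name__)

SUPERORDINATES = ("indoor", "urban", "natural")

ChangeClass = Literal[
    "misspelling",
    "plural",
    "subordinate",
    "superordinate",
    "synonym",
    "container",
    "part",
    "other",
]

CHANGE_CLASSES = (
    "misspelling",
    "plural",
    "subordinate",
    "superordinate",
    "synonym",
    "container",
    "part",
    "other",
)


@dataclass(frozen=True)
class Polygon:
    """A closed bounding region given by its vertex ring.

    Vertices are stored as an ``(n, 2)`` float array of ``(x, y)`` pixel
    coordinates.  At least three vertices are required; the ring is treated
    as implicitly closed (no repeated first/last vertex).
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if v.shape[0] < 3:
            raise ValueError(f"polygon needs >=3 vertices, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ValueError("polygon vertices must be finite")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Polygon):
            return NotImplemented
        return self.vertices.shape == other.vertices.shape and bool(
            np.array_equal(self.vertices, other.vertices)
        )

    def __hash__(self) -> int:
        return hash(self.vertices.tobytes())

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the vertex ring."""
        v = self.vertices
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )


@dataclass(frozen=True)
class ObjectAnnotation:
    """One labeled region: a basic-level name attached to a polygon."""

    label: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("object label must be non-empty")


@dataclass(frozen=True)
class SceneAnnotation:
    """One annotated image: category, dimensions, and labeled polygons."""

    scene_id: str
    width: float
    height: float
    category: str
    objects: tuple[ObjectAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        object.__setattr__(self, "objects", tuple(self.objects))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(o.label for o in self.objects)


@dataclass(frozen=True)
class SceneDatabase:
    """A collection of annotated scenes plus the category taxonomy.

    ``taxonomy`` maps every basic-level category to its superordinate
    (``indoor``, ``urban`` or ``natural``).  The vocabulary is always the
    sorted union of labels over all scenes.
    """

    scenes: tuple[SceneAnnotation, ...]
    taxonomy: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenes", tuple(self.scenes))
        for s in self.scenes:
            if s.category not in self.taxonomy:
                raise ValueError(
                    f"scene {s.scene_id!r} has category {s.category!r} "
                    "absent from the taxonomy"
                )

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(sorted({o.label for s in self.scenes for o in s.objects}))

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.taxonomy))

    def categories_of(self, superordinate: str) -> tuple[str, ...]:
        return tuple(
            c for c in self.categories if self.taxonomy[c] == superordinate
        )

    def scenes_of(self, category: str) -> tuple[SceneAnnotation, ...]:
        return tuple(s for s in self.scenes if s.category == category)

    def superordinate_labels(self) -> tuple[str, ...]:
        """Per-scene superordinate labels, in scene order."""
        return tuple(self.taxonomy[s.category] for s in self.scenes)


@dataclass(frozen=True)
class NormalizationEntry:
    action: Literal["rename", "delete"]
    target: str | None
    change_class: str

    def __post_init__(self) -> None:
        if self.action == "rename" and not self.target:
            raise ValueError("rename entries require a target label")
        if self.action == "delete" and self.target is not None:
            raise ValueError("delete entries must not have a target")
        if self.change_class not in CHANGE_CLASSES:
            raise ValueError(f"unknown change class {self.change_class!r}")


@dataclass(frozen=True)
class LabelNormalizationTable:
    """Raw-label -> (rename/delete) mapping used to clean a database.

    Rename targets must themselves be canonical: a target that is also a
    raw key would require chained application and makes the table invalid.
    """

    entries: dict[str, NormalizationEntry] = field(default_factory=dict)

    def validate(self) -> None:
        for raw, entry in self.entries.items():
            if entry.action == "rename" and entry.target in self.entries:
                raise ValueError(
                    f"rename chain: {raw!r} -> {entry.target!r} is itself "
                    "a raw key in the table"
                )


# ---------------------------------------------------------------------------
# LabelMe XML
# ---------------------------------------------------------------------------


def parse_labelme_xml(
    document: str | bytes,
    *,
    width: float | None = None,
    height: float | None = None,
    category: str | None = None,
) -> SceneAnnotation:
    """Parse one LabelMe annotation document into a :class:`SceneAnnotation`.

    Labels are preserved verbatim (cleaning is a separate, table-driven
    step).  Objects marked ``<deleted>1</deleted>`` are dropped, as are
    objects with fewer than 3 vertices (logged as a warning).  Image
    dimensions come from the ``<imagesize>`` element unless supplied.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed annotation XML: {exc}") from exc

    scene_id = (root.findtext("filename") or "").strip() or "unnamed"
    folder = (root.findtext("folder") or "").strip()
    if category is None:
        category = folder or "unknown"

    if width is None or height is None:
        size = root.find("imagesize")
        if size is None:
            raise ValueError(
                "annotation has no <imagesize> and no external dimensions"
            )
        height = float(size.findtext("nrows"))
        width = float(size.findtext("ncols"))

    objects: list[ObjectAnnotation] = []
    for obj in root.iterfind("object"):
        deleted = (obj.findtext("deleted") or "0").strip()
        if deleted == "1":
            continue
        label = (obj.findtext("name") or "").strip()
        pts = [
            (float(pt.findtext("x")), float(pt.findtext("y")))
            for pt in obj.iterfind("polygon/pt")
        ]
        if len(pts) < 3:
            logger.warning(
                "scene %s: skipping object %r with %d < 3 vertices",
                scene_id,
                label,
                len(pts),
            )
            continue
        objects.append(ObjectAnnotation(label, Polygon(np.array(pts))))

    return SceneAnnotation(
        scene_id=scene_id,
        width=float(width),
        height=float(height),
        category=category,
        objects=tuple(objects),
    )


def _fmt(x: float) -> str:
    """Shortest exact decimal for a float (round-trip safe)."""
    return repr(float(x))


def write_labelme_xml(scene: SceneAnnotation) -> str:
    """Serialize a scene to LabelMe XML; inverse of :func:`parse_labelme_xml`.

    Serialization is deterministic (byte-stable under repeated write) and
    round-trips labels, vertex coordinates and image dimensions exactly.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = scene.scene_id
    etree.SubElement(root, "folder").text = scene.category
    size = etree.SubElement(root, "imagesize")
    etree.SubElement(size, "nrows").text = _fmt(scene.height)
    etree.SubElement(size, "ncols").text = _fmt(scene.width)
    for obj in scene.objects:
        el = etree.SubElement(root, "object")
        etree.SubElement(el, "name").text = obj.label
        etree.SubElement(el, "deleted").text = "0"
        poly = etree.SubElement(el, "polygon")
        for x, y in obj.polygon.vertices:
            pt = etree.SubElement(poly, "pt")
            etree.SubElement(pt, "x").text = _fmt(x)
            etree.SubElement(pt, "y").text = _fmt(y)
    return etree.tostring(
        root, pretty_print=True, encoding="unicode", xml_declaration=False
    )


def read_database(
    folder: str | Path, taxonomy: dict[str, str]
) -> SceneDatabase:
    """Read every ``*.xml`` annotation under ``folder`` into a database."""
    folder = Path(folder)
    scenes = [
        parse_labelme_xml(p.read_bytes())
        for p in sorted(folder.rglob("*.xml"))
    ]
    return SceneDatabase(scenes=tuple(scenes), taxonomy=dict(taxonomy))


def write_database(db: SceneDatabase, folder: str | Path) -> list[Path]:
    """Write one XML file per scene under ``folder/<category>/``."""
    folder = Path(folder)
    written = []
    for scene in db.scenes:
        sub = folder / scene.category
        sub.mkdir(parents=True, exist_ok=True)
        path = sub / f"{scene.scene_id}.xml"
        path.write_text(write_labelme_xml(scene), encoding="utf-8")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def normalize_labels(
    db: SceneDatabase, table: LabelNormalizationTable
) -> tuple[SceneDatabase, dict[str, int]]:
    """Apply a normalization table to every annotation in the database.

    Raw labels found in the table are renamed to their canonical target or
    deleted; labels absent from the table pass through unchanged.  A single
    application suffices (the table validator rejects rename chains), so
    the operation is idempotent.

    Returns the cleaned database and a change-count summary: one count per
    change class plus ``"deletions"`` and ``"renames"`` totals, counting
    affected annotations.
    """
    table.validate()
    counts: dict[str, int] = {c: 0 for c in CHANGE_CLASSES}
    counts["renames"] = 0
    counts["deletions"] = 0

    new_scenes = []
    for scene in db.scenes:
        objs = []
        for obj in scene.objects:
            entry = table.entries.get(obj.label)
            if entry is None:
                objs.append(obj)
            elif entry.action == "delete":
                counts[entry.change_class] += 1
                counts["deletions"] += 1
            else:
                counts[entry.change_class] += 1
                counts["renames"] += 1
                objs.append(replace(obj, label=entry.target))
        new_scenes.append(replace(scene, objects=tuple(objs)))
    return SceneDatabase(tuple(new_scenes), dict(db.taxonomy)), counts


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def polygon_area(p: Polygon) -> float:
    """Absolute shoelace area of the vertex ring, in pixels squared.

    Orientation-independent.  For self-intersecting rings this is the
    absolute algebraic area, which matches even-odd rasterization only
    approximately; annotation polygons are expected to be simple.
    """
    v = p.vertices
    x, y = v[:, 0], v[:, 1]
    return float(
        abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0
    )


def object_bbox_center(p: Polygon) -> tuple[float, float]:
    """Midpoint of the polygon's bounding box: ((xmin+xmax)/2, (ymin+ymax)/2)."""
    xmin, ymin, xmax, ymax = p.bbox
    return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)


def points_in_polygon(points: np.ndarray, p: Polygon) -> np.ndarray:
    """Even-odd (crossing-number) membership test for an array of points.

    ``points`` is ``(m, 2)``; returns a boolean mask.  Points exactly on an
    edge may land on either side (the pixel-center convention below never
    places test points on integer-coordinate edges).
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    v = p.vertices
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    inside = np.zeros(len(pts), dtype=bool)
    for i in range(len(v)):
        if y1[i] == y2[i]:
            continue
        crosses = (y1[i] > y) != (y2[i] > y)
        xi = x1[i] + (y - y1[i]) * (x2[i] - x1[i]) / (y2[i] - y1[i])
        inside ^= crosses & (x < xi)
    return inside


def rasterize_mask(
    p: Polygon, width: int, height: int, *, scale: tuple[float, float] | None = None
) -> np.ndarray:
    """Boolean occupancy mask of a polygon on a ``height x width`` grid.

    A cell is set when its center lies inside the polygon (even-odd rule).
    With ``scale=(sx, sy)`` the polygon coordinates are first multiplied by
    the given factors, which resamples native-size annotations onto a
    common normalized grid.
    """
    if scale is not None:
        p = Polygon(p.vertices * np.asarray(scale, dtype=float))
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    xmin, ymin, xmax, ymax = p.bbox
    mask = np.zeros(width * height, dtype=bool)
    # restrict the point-in-polygon test to the bbox for speed
    cand = (
        (pts[:, 0] >= xmin)
        & (pts[:, 0] <= xmax)
        & (pts[:, 1] >= ymin)
        & (pts[:, 1] <= ymax)
    )
    if cand.any():
        mask[np.flatnonzero(cand)] = points_in_polygon(pts[cand], p)
    return mask.reshape(height, width)


def label_coverage(scene: SceneAnnotation) -> float:
    """Fraction of image pixels assigned to at least one label.

    Pixel centers on the native grid are tested against the union of all
    object polygons; overlapping polygons count each pixel once.
    """
    w, h = int(round(scene.width)), int(round(scene.height))
    if w <= 0 or h <= 0:
        raise ValueError("zero-area image")
    union = np.zeros((h, w), dtype=bool)
    for obj in scene.objects:
        union |= rasterize_mask(obj.polygon, w, h)
    return float(union.sum()) / (w * h)


# ---------------------------------------------------------------------------
# Tabular side files
# ---------------------------------------------------------------------------


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a 2-column CSV (basic, superordinate) into a taxonomy map."""
    taxonomy: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "basic" and row[1] == "superordinate":
                continue  # header
            taxonomy[row[0].strip()] = row[1].strip()
    return taxonomy


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["basic", "superordinate"])
        for basic in sorted(taxonomy):
            writer.writerow([basic, taxonomy[basic]])


def read_normalization_table(path: str | Path) -> LabelNormalizationTable:
    """Read a 3-column CSV (raw, action[:target], change_class).

    The action column is either ``delete`` or ``rename:<target>``.
    """
    entries: dict[str, NormalizationEntry] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "raw" and row[1] == "action":
                continue
            raw, action, change_class = (c.strip() for c in row[:3])
            if action == "delete":
                entries[raw] = NormalizationEntry("delete", None, change_class)
            elif action.startswith("rename:"):
                entries[raw] = NormalizationEntry(
                    "rename", action.split(":", 1)[1], change_class
                )
            else:
                raise ValueError(f"unknown action {action!r} for {raw!r}")
    table = LabelNormalizationTable(entries)
    table.validate()
    return table


def write_normalization_table(
    table: LabelNormalizationTable, path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["raw", "action", "change_class"])
        for raw in sorted(table.entries):
            entry = table.entries[raw]
            action = (
                "delete" if entry.action == "delete" else f"rename:{entry.target}"
            )
            writer.writerow([raw, action, entry.change_class])
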