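"""File formats touched by the picking pipeline.

Micrographs travel as 2-D float MRC (mode 2); ground-truth particles as
COCO JSON plus per-micrograph tab-separated center/diameter tables; picks
as per-micrograph box files merged into a single STAR loop block that
RELION/CryoSPARC-style tools accept.

Coordinate convention used everywhere: 0-based pixel coordinates with the
origin at the top-left of the pixel array, x = column index, y = row
index.  Downstream tools wanting a flipped y axis must flip on import;
no flip is applied here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import mrcfile
import numpy as np

__all__ = [
    "Micrograph",
    "ParticleAnnotation",
    "StarRecord",
    "read_mrc",
    "write_mrc",
    "export_coco",
    "import_coco",
    "write_star",
    "read_star",
    "write_box",
    "read_box",
    "write_coord_table",
    "read_coord_table",
]


@dataclass
class Micrograph:
    """A single 2-D intensity image, the unit of detection."""

    pixels: np.ndarray  # (H, W) float
    name: str
    pixel_size: float | None = None  # Angstrom / pixel

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ParticleAnnotation:
    """Ground-truth particle: a center and diameter on a named micrograph.

    The bounding box is the axis-aligned square of side ``diameter``
    centered on (center_x, center_y), matching COCO bbox semantics.
    """

    center_x: float
    center_y: float
    diameter: float
    image_ref: str
    particle_id: int = 0
    category: int = 1

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        d = self.diameter
        return (self.center_x - d / 2.0, self.center_y - d / 2.0, d, d)

    @property
    def area(self) -> float:
        return float(self.diameter) ** 2


@dataclass
class StarRecord:
    """One row of the merged particle table."""

    micrograph_name: str
    coordinate_x: float
    coordinate_y: float
    confidence: float | None = None


# ---------------------------------------------------------------- MRC

def read_mrc(path) -> Micrograph:
    """Load a 2-D MRC micrograph as float32."""
    path = Path(path)
    with mrcfile.open(path, permissive=True) as f:
        data = np.asarray(f.data)
        if data.ndim == 3:
            if data.shape[0] == 1:
                data = data[0]
            else:
                raise ValueError(
                    f"{path} holds a 3-D volume/stack of {data.shape[0]} "
                    "sections; only single 2-D micrographs are supported"
                )
        elif data.ndim != 2:
            raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")
        vx = float(f.voxel_size.x) if f.voxel_size.x else None
    pixels = data.astype(np.float32)
    if not np.all(np.isfinite(pixels)):
        raise ValueError(f"{path}: non-finite pixel values after load")
    return Micrograph(pixels=pixels, name=path.stem, pixel_size=vx)


def write_mrc(micrograph: Micrograph, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with mrcfile.new(path, overwrite=True) as f:
        f.set_data(micrograph.pixels.astype(np.float32))
        if micrograph.pixel_size:
            f.voxel_size = micrograph.pixel_size


# ---------------------------------------------------------------- COCO

def export_coco(
    annotations: list[ParticleAnnotation],
    image_index: dict[str, tuple[int, int]],
) -> dict:
    """Build a COCO document.

    ``image_index`` maps micrograph name -> (height, width); every
    annotation's ``image_ref`` must appear in it.
    """
    dangling = sorted({a.image_ref for a in annotations} - set(image_index))
    if dangling:
        raise ValueError(f"annotations reference unknown images: {dangling}")
    image_ids = {name: i + 1 for i, name in enumerate(image_index)}
    images = [
        {"id": image_ids[name], "file_name": f"{name}.mrc",
         "height": int(h), "width": int(w)}
        for name, (h, w) in image_index.items()
    ]
    ann_records = []
    for k, a in enumerate(annotations):
        x, y, w, h = a.bbox
        ann_records.append(
            {
                "id": int(a.particle_id) if a.particle_id else k + 1,
                "image_id": image_ids[a.image_ref],
                "category_id": int(a.category),
                "bbox": [float(x), float(y), float(w), float(h)],
                "area": float(w) * float(h),
                "iscrowd": 0,
            }
        )
    return {
        "images": images,
        "annotations": ann_records,
        "categories": [{"id": 1, "name": "particle"}],
    }


def import_coco(document: dict) -> list[ParticleAnnotation]:
    names = {img["id"]: Path(img["file_name"]).stem for img in document["images"]}
    out = []
    for rec in document["annotations"]:
        x, y, w, h = rec["bbox"]
        out.append(
            ParticleAnnotation(
                center_x=x + w / 2.0,
                center_y=y + h / 2.0,
                diameter=w,
                image_ref=names[rec["image_id"]],
                particle_id=int(rec["id"]),
                category=int(rec["category_id"]),
            )
        )
    return out


def save_coco(document: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(document, indent=1))


def load_coco(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- STAR

_STAR_COLUMNS = ["_rlnMicrographName", "_rlnCoordinateX", "_rlnCoordinateY"]
_STAR_FOM = "_rlnAutopickFigureOfMerit"


def write_star(records: list[StarRecord], path) -> None:
    """Write one ``data_particles`` loop block.

    Column order is fixed: MicrographName, CoordinateX, CoordinateY and,
    when any record carries a confidence, AutopickFigureOfMerit.
    Coordinates are written with 6 decimals (exact for integer-valued
    picks), confidences with 6 decimals.
    """
    if not records:
        raise ValueError("refusing to write an empty star file")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with_conf = any(r.confidence is not None for r in records)
    cols = _STAR_COLUMNS + ([_STAR_FOM] if with_conf else [])
    lines = ["", "data_particles", "", "loop_"]
    lines += [f"{c} #{i + 1}" for i, c in enumerate(cols)]
    for r in records:
        row = [r.micrograph_name, f"{r.coordinate_x:.6f}", f"{r.coordinate_y:.6f}"]
        if with_conf:
            row.append(f"{0.0 if r.confidence is None else r.confidence:.6f}")
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_star(path) -> list[StarRecord]:
    lines = Path(path).read_text().splitlines()
    cols: list[str] = []
    records: list[StarRecord] = []
    in_loop = False
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            cols = []
            continue
        if in_loop and line.startswith("_"):
            cols.append(line.split()[0])
            continue
        if in_loop and cols:
            parts = line.split()
            row = dict(zip(cols, parts))
            records.append(
                StarRecord(
                    micrograph_name=row["_rlnMicrographName"],
                    coordinate_x=float(row["_rlnCoordinateX"]),
                    coordinate_y=float(row["_rlnCoordinateY"]),
                    confidence=(
                        float(row[_STAR_FOM]) if _STAR_FOM in row else None
                    ),
                )
            )
    return records


# ---------------------------------------------------------------- box / tables

def write_box(records: list[StarRecord], path) -> None:
    """Per-micrograph box file: one ``x<TAB>y[<TAB>confidence]`` per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for r in records:
        cells = [f"{r.coordinate_x:.6f}", f"{r.coordinate_y:.6f}"]
        if r.confidence is not None:
            cells.append(f"{r.confidence:.6f}")
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_box(path, micrograph_name: str | None = None) -> list[StarRecord]:
    path = Path(path)
    name = micrograph_name or path.stem
    records = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        conf = float(parts[2]) if len(parts) > 2 else None
        records.append(StarRecord(name, float(parts[0]), float(parts[1]), conf))
    return records


def write_coord_table(annotations: list[ParticleAnnotation], path) -> None:
    """CryoPPP-style ground-truth table: center x/y + diameter, tab-separated."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["X-Coordinate\tY-Coordinate\tDiameter"]
    for a in annotations:
        lines.append(f"{a.center_x:.6f}\t{a.center_y:.6f}\t{a.diameter:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_coord_table(path, image_ref: str | None = None) -> list[ParticleAnnotation]:
    path = Path(path)
    ref = image_ref or path.stem
    out = []
    for i, line in enumerate(path.read_text().splitlines()):
        if i == 0 and line.lower().startswith("x"):
            continue
        parts = line.split()
        if not parts:
            continue
        out.append(
            ParticleAnnotation(
                center_x=float(parts[0]),
                center_y=float(parts[1]),
                diameter=float(parts[2]),
                image_ref=ref,
                particle_id=i,
            )
        )
    return out
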