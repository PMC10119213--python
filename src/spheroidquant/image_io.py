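"""Read/write of every external artifact: TIFF stacks, boundary ROIs
(ImageJ ``.roi``/``.zip`` and a JSON polygon dialect), annotation tables,
result tables and run configuration.

JSON polygon dialect::

    {"core_rim": [[row, col], ...], "rim_invasion": [[row, col], ...]}

ImageJ ROI support is limited to polygon-type ROIs, which is what a
boundary drawn with the polygon selection tool produces.
"""

from __future__ import annotations

import json
import logging
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

from .calibration import ImageStack, PixelCalibration

logger = logging.getLogger("spheroidquant")

ACCEPTED_BOUNDARY_LABELS = ("core_rim", "rim_invasion")


class FormatError(ValueError):
    """Raised when a file is readable but not in an accepted format."""


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, calibration: PixelCalibration) -> ImageStack:
    """Read a single- or multi-page TIFF as a calibrated stack.

    Pages become slices in page order. Calibration stored in the file is
    never trusted: the explicit argument always wins, with a logged warning
    when file metadata disagrees.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            if n_pages == 0:
                raise FormatError(f"{path}: TIFF contains no pages")
            shapes = {tif.pages[i].shape for i in range(n_pages)}
            if len(shapes) != 1:
                raise FormatError(f"{path}: mixed page shapes {sorted(shapes)}")
            data = tif.asarray()
            _warn_on_metadata_mismatch(tif, calibration, path)
    except FormatError:
        raise
    except (tifffile.TiffFileError, struct.error) as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if data.ndim == 2:
        data = data[None]
    return ImageStack(voxels=data, calibration=calibration)


def _warn_on_metadata_mismatch(tif: tifffile.TiffFile,
                               calibration: PixelCalibration,
                               path: Path) -> None:
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    if res is None:
        return
    num, den = res.value
    if num == 0:
        return
    file_xy = den / num  # units per pixel in the file's resolution unit
    if not np.isclose(file_xy, calibration.xy_size, rtol=0.01):
        logger.warning(
            "%s: file metadata implies %.4g units/px, overriding with "
            "explicit calibration %.4g µm/px", path, file_xy, calibration.xy_size
        )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF (one page per slice)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# boundary polygons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryPolygon:
    """A zone boundary as an ordered ring of (row, col) pixel coordinates.

    ``label`` names which transition the curve marks: ``core_rim`` (core to
    compact rim) or ``rim_invasion`` (rim to invasion zone).
    """

    vertices: np.ndarray  # (n, 2) float, (row, col)
    label: str

    def __post_init__(self) -> None:
        verts = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if verts.shape[0] < 3 or verts.shape[1] != 2:
            raise FormatError(
                f"boundary polygon needs >= 3 (row, col) vertices, "
                f"got shape {verts.shape}"
            )
        if self.label not in ACCEPTED_BOUNDARY_LABELS:
            raise FormatError(
                f"unknown boundary label {self.label!r}; accepted labels: "
                f"{', '.join(ACCEPTED_BOUNDARY_LABELS)}"
            )
        # shapely works in (x, y); use (col, row)
        ring = _ShapelyPolygon(verts[:, ::-1])
        if not ring.is_simple:
            raise FormatError(
                f"boundary polygon {self.label!r} self-intersects after closure"
            )
        object.__setattr__(self, "vertices", verts)


def read_boundaries(path: str | Path) -> list[BoundaryPolygon]:
    """Read zone boundaries from a JSON polygon file or ImageJ ROI file.

    Accepts ``.json``, a single ImageJ ``.roi``, or a ``.zip`` of ROIs.
    Labels come from JSON keys or ROI names and must be one of
    ``core_rim`` / ``rim_invasion``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        with open(path) as fh:
            data = json.load(fh)
        return [BoundaryPolygon(np.asarray(v, dtype=float), k)
                for k, v in data.items()]
    if suffix == ".roi":
        name, verts = _read_imagej_roi(path.read_bytes())
        return [BoundaryPolygon(verts, name or path.stem)]
    if suffix == ".zip":
        out = []
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                if not entry.lower().endswith(".roi"):
                    continue
                name, verts = _read_imagej_roi(zf.read(entry))
                out.append(BoundaryPolygon(verts, name or Path(entry).stem))
        if not out:
            raise FormatError(f"{path}: zip contains no .roi entries")
        return out
    raise FormatError(f"{path}: expected .json, .roi or .zip boundary file")


# Minimal ImageJ ROI codec (polygon type only). Byte layout follows the
# ImageJ source (ij.io.RoiDecoder/RoiEncoder): 64-byte big-endian header,
# then int16 x- and y-offsets relative to the bounding box; the ROI name
# lives behind header2 as UTF-16BE.
_ROI_POLYGON = 0
_HEADER2_NAME_OFFSET = 16
_HEADER2_NAME_LENGTH = 20


def _read_imagej_roi(buf: bytes) -> tuple[str | None, np.ndarray]:
    if len(buf) < 64 or buf[:4] != b"Iout":
        raise FormatError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = buf[6]
    if roi_type != _ROI_POLYGON:
        raise FormatError(
            f"unsupported ImageJ ROI type {roi_type}; only polygon ROIs "
            "(type 0) are accepted as zone boundaries"
        )
    top, left, _bottom, _right, n = struct.unpack(">hhhhH", buf[8:18])
    if n < 3:
        raise FormatError(f"polygon ROI has only {n} vertices (>= 3 required)")
    xs = np.frombuffer(buf, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(buf, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    name = None
    (h2off,) = struct.unpack(">i", buf[60:64])
    if 0 < h2off <= len(buf) - 64:
        noff, nlen = struct.unpack(
            ">ii", buf[h2off + _HEADER2_NAME_OFFSET:h2off + _HEADER2_NAME_LENGTH + 4]
        )
        if noff > 0 and nlen > 0 and noff + 2 * nlen <= len(buf):
            name = buf[noff:noff + 2 * nlen].decode("utf-16-be")
    return name, np.column_stack([ys, xs])  # (row, col)


def write_imagej_roi(polygon: BoundaryPolygon, path: str | Path) -> Path:
    """Write a polygon boundary as a single ImageJ ``.roi`` file."""
    verts = polygon.vertices
    rows = np.round(verts[:, 0]).astype(int)
    cols = np.round(verts[:, 1]).astype(int)
    top, left = int(rows.min()), int(cols.min())
    n = len(rows)
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = _ROI_POLYGON
    struct.pack_into(">hhhhH", header, 8, top, left,
                     int(rows.max()), int(cols.max()), n)
    coords = (cols - left).astype(">i2").tobytes() + (rows - top).astype(">i2").tobytes()
    h2off = 64 + len(coords)
    struct.pack_into(">i", header, 60, h2off)
    header2 = bytearray(64)
    name_bytes = polygon.label.encode("utf-16-be")
    struct.pack_into(">i", header2, _HEADER2_NAME_OFFSET, h2off + 64)
    struct.pack_into(">i", header2, _HEADER2_NAME_LENGTH, len(polygon.label))
    path = Path(path)
    path.write_bytes(bytes(header) + coords + bytes(header2) + name_bytes)
    return path


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

ACCEPTED_EVENT_LABELS = ("mitosis",)


@dataclass
class AnnotationTable:
    """Manually annotated events, e.g. mitoses counted by eye.

    ``rows`` has columns ``slice``, ``row``, ``col``, ``label``.
    """

    rows: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"slice", "row", "col", "label"}
        missing = required - set(self.rows.columns)
        if missing:
            raise FormatError(f"annotation table missing columns: {sorted(missing)}")
        bad = set(self.rows["label"]) - set(ACCEPTED_EVENT_LABELS)
        if bad:
            raise FormatError(
                f"unknown event labels {sorted(bad)}; accepted: "
                f"{list(ACCEPTED_EVENT_LABELS)}"
            )


def read_annotations(path: str | Path, provenance: str = "") -> AnnotationTable:
    df = pd.read_csv(path)
    return AnnotationTable(rows=df, provenance=provenance or str(path))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(result, out_dir: str | Path, *, timestamp: str | None = None) -> dict:
    """Write a :class:`~spheroidquant.events.QuantResult` as CSV + JSON.

    Emits ``nuclei.csv`` (one row per nucleus), ``zone_summary.csv``,
    ``snr_profile.csv`` (when an SNR profile is attached) and
    ``run_metadata.json``; returns a manifest mapping artifact names to
    paths. Outputs are deterministic except the timestamp field.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    manifest: dict[str, str] = {}

    nuclei = result.nuclei_table()
    p = out_dir / "nuclei.csv"
    nuclei.to_csv(p, index=False)
    manifest["nuclei"] = str(p)

    summary = result.zone_summary_table()
    p = out_dir / "zone_summary.csv"
    summary.to_csv(p, index=False)
    manifest["zone_summary"] = str(p)

    if result.snr_profile is not None:
        p = out_dir / "snr_profile.csv"
        result.snr_profile.to_frame().to_csv(p, index=False)
        manifest["snr_profile"] = str(p)

    meta = dict(result.metadata)
    meta["timestamp"] = timestamp if timestamp is not None else pd.Timestamp.now().isoformat()
    p = out_dir / "run_metadata.json"
    with open(p, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=_json_default)
    manifest["run_metadata"] = str(p)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_config(path: str | Path) -> dict:
    """Load a YAML or JSON run-configuration file as a plain dict."""
    import yaml

    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
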