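"""Folder discovery, per-image pipeline execution and CSV/XLSX export.

An analysis run scans a target folder for images (TIFF/JPG/PNG,
case-insensitive), pairs each with its polygon sidecar
``<stem>.polygons.json`` and an optional DAPI support image from a
``support/`` subfolder (matched when the first three filename characters
agree; with several matches the lexicographically first is used), runs
detection + relative-radius geometry per islet, and exports one results table
as CSV and XLSX.

Support images exist purely so a human can draw the islet border on poorly
contrasted fluorescence channels; they are contrast-stretched for display
only and have no effect whatsoever on the computed results.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import AnalysisConfig, ConfigError, default_config
from .detection import detect
from .geometry import IsletResult, analyze_islet

__all__ = [
    "CSV_COLUMNS",
    "ResultsTable",
    "WorkItem",
    "analyze_folder",
    "discover",
    "enhance_support_for_display",
    "export",
    "load_image",
    "match_support",
]

log = logging.getLogger("isletradius")

IMAGE_EXTENSIONS = {".tif", ".tiff", ".jpg", ".jpeg", ".png"}

CSV_COLUMNS = [
    "image_id",
    "islet_id",
    "stain_mode",
    "n_cell_pixels",
    "n_islet_pixels",
    "relative_area_pct",
    "mean_relative_radius_pct",
    "n_included",
    "n_excluded",
    "pct_excluded",
    "polygon_was_invalid",
    "excluded_no_staining",
]


@dataclass
class WorkItem:
    """One image queued for analysis, with its sidecar and optional support image."""

    main_image_path: Path
    polygon_file_path: Path | None
    support_image_path: Path | None
    stain_mode: str
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class ResultsTable:
    """Ordered per-islet results plus run metadata.

    Excluded islets stay in the table with their exclusion flag set — they
    are never silently dropped. Metadata (config hash, timestamp, version) is
    kept out of the CSV body so repeated runs are byte-identical.
    """

    rows: list[IsletResult] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        records = [{col: getattr(r, col) for col in CSV_COLUMNS} for r in self.rows]
        return pd.DataFrame(records, columns=CSV_COLUMNS)


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def polygon_sidecar_path(image_path: Path) -> Path:
    return image_path.with_name(image_path.stem + ".polygons.json")


def match_support(main_image_path: str | Path, support_folder: str | Path) -> Path | None:
    """First support image whose first three filename characters match.

    Candidates are taken in lexicographic order, so a non-unique prefix
    deterministically resolves to the first match; a missing support folder
    yields None.
    """
    main = Path(main_image_path)
    folder = Path(support_folder)
    if not folder.is_dir():
        return None
    prefix = main.name[:3]
    for candidate in sorted(p for p in folder.iterdir() if p.is_file()):
        if candidate.name[:3] == prefix:
            return candidate
    return None


def discover(
    folder: str | Path, stain_mode: str, support_dir: str = "support"
) -> list[WorkItem]:
    """One WorkItem per image file in ``folder``, sorted lexicographically.

    Images without a polygon sidecar are kept in the list but flagged
    ``skipped`` with a warning, so no input is silently lost.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"target folder does not exist: {folder}")
    images = sorted(
        p
        for p in folder.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not images:
        log.warning("no images found in %s", folder)
    items: list[WorkItem] = []
    for img in images:
        sidecar = polygon_sidecar_path(img)
        support = match_support(img, folder / support_dir)
        if sidecar.is_file():
            items.append(WorkItem(img, sidecar, support, stain_mode))
        else:
            log.warning("no polygon file for %s (expected %s); skipping", img.name, sidecar.name)
            items.append(
                WorkItem(img, None, support, stain_mode, skipped=True,
                         skip_reason="missing polygon file")
            )
    return items


# ---------------------------------------------------------------------------
# image loading / support display
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Load one image; for multi-page TIFFs only the first page, with a warning."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        # a leading page axis: (pages, h, w) or (pages, h, w, c)
        if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] not in (3, 4)):
            warnings.warn(
                f"multi-page TIFF {path.name}: using first page only",
                UserWarning,
                stacklevel=2,
            )
            arr = arr[0]
        return arr
    return np.asarray(iio.imread(path))


def enhance_support_for_display(image: np.ndarray) -> np.ndarray:
    """Min-max contrast stretch of a grayscale support image, display only.

    Returns a float copy spanning [0, 1]; a constant image is returned
    unchanged. The result must never feed into detection or geometry — the
    analysis contract is that outputs are identical with and without it.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return img.copy()
    return (img - lo) / (hi - lo)


def read_polygon_file(path: str | Path) -> list[dict]:
    """Parse a ``.polygons.json`` sidecar into a list of islet dicts."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    islets = data.get("islets")
    if not isinstance(islets, list):
        raise ConfigError(f"{path}: expected an 'islets' list")
    for islet in islets:
        if "id" not in islet or "vertices" not in islet:
            raise ConfigError(f"{path}: each islet needs 'id' and 'vertices'")
    return islets


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def analyze_folder(
    folder: str | Path,
    stain_mode: str,
    config: AnalysisConfig | None = None,
    support_dir: str = "support",
) -> ResultsTable:
    """Run the detection + relative-radius pipeline over a target folder."""
    config = config or default_config()
    det_cfg = config.detection_for(stain_mode)
    items = discover(folder, stain_mode, support_dir=support_dir)
    n_analyzed = n_skipped = 0
    table = ResultsTable(
        metadata={
            "software_version": __version__,
            "config_hash": config.config_hash(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "stain_mode": stain_mode,
            "folder": str(folder),
        }
    )
    for item in items:
        if item.skipped:
            n_skipped += 1
            continue
        image = load_image(item.main_image_path)
        if item.support_image_path is not None:
            # loaded + stretched for parity with interactive use; display only
            enhance_support_for_display(
                np.asarray(load_image(item.support_image_path), dtype=float)
            )
        mask = detect(image, det_cfg)
        islets = read_polygon_file(item.polygon_file_path)
        log.info(
            "%s: %d islet(s), %d positive pixel(s)",
            item.main_image_path.name, len(islets), int(mask.sum()),
        )
        for islet in islets:
            result, n_outside = analyze_islet(
                mask,
                np.asarray(islet["vertices"], dtype=float),
                image_id=item.main_image_path.name,
                islet_id=islet["id"],
                stain_mode=stain_mode,
                centroid_method=config.centroid_method,
            )
            if result.polygon_was_invalid:
                log.warning(
                    "%s islet %s: invalid polygon auto-sorted by angle",
                    result.image_id, result.islet_id,
                )
            log.debug(
                "%s islet %s: mean rel. radius %.2f%%, %d px outside polygon discarded",
                result.image_id, result.islet_id,
                result.mean_relative_radius_pct, n_outside,
            )
            table.rows.append(result)
        n_analyzed += 1
    log.info("discovered %d image(s): %d analyzed, %d skipped",
             len(items), n_analyzed, n_skipped)
    return table


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export(results: ResultsTable, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` and ``<prefix>.xlsx``.

    The CSV holds only the results table (UTF-8, 6-decimal floats) so two
    identical runs produce byte-identical files; run metadata including the
    timestamp goes to a separate XLSX sheet.
    """
    out_prefix = Path(out_prefix)
    csv_path = out_prefix.with_suffix(".csv")
    xlsx_path = out_prefix.with_suffix(".xlsx")
    df = results.to_dataframe()
    try:
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(csv_path, index=False, float_format="%.6f")
        with pd.ExcelWriter(xlsx_path, engine="openpyxl") as writer:
            df.to_excel(writer, sheet_name="results", index=False)
            meta = pd.DataFrame(
                sorted(results.metadata.items()), columns=["key", "value"]
            )
            meta.to_excel(writer, sheet_name="metadata", index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {out_prefix}: {exc}") from exc
    return csv_path, xlsx_path
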