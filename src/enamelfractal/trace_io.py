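"""Reading enamel-trace rasters and specimen tables.

Traces are binary images of the occlusal enamel band of a single tooth,
one specimen per image.  Specimen metadata (taxon, tribe, tooth position,
occlusal surface area in cm^2) comes in as a CSV and is joined to the
per-specimen fractal dimension D computed downstream.  Species-level
summaries (n, mean, SD of D and of area) are the unit of the comparative
analyses, which require species averages.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

VALID_TRIBES = ("Hipparionini", "Equini")
#: Tooth positions retained for analysis; P2 and M3 differ in enamel
#: complexity and are excluded.
VALID_POSITIONS = ("P3", "P4", "M1", "M2")


class EmptyTraceError(ValueError):
    """Raised when a trace image has no foreground pixels."""


@dataclass
class RasterTrace:
    """A binary raster of an enamel-band trace.

    ``pixels`` is a 2-D uint8/bool array where 1 marks trace ink
    (the enamel-band border) and 0 background.
    """

    pixels: np.ndarray
    specimen_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"trace must be 2-D, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"trace too small: {px.shape}")
        self.pixels = (px != 0).astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SpecimenRecord:
    """One tooth: identity, taxonomy, and measured traits."""

    specimen_id: str
    taxon: str
    tribe: str
    tooth_position: str
    area: float | None = None  # occlusal surface area, cm^2
    D: float | None = None  # fractal dimension, filled by the pipeline


@dataclass
class SpeciesSummary:
    """Per-species sample sizes, means and SDs for D and area.

    ``sd_*`` is the sample standard deviation (n-1 denominator) and is
    ``None`` when n < 2; ``mean_area``/``sd_area`` are ``None`` when no
    specimen of the species has a measured area.
    """

    taxon: str
    tribe: str
    n_D: int
    mean_D: float
    sd_D: float | None
    n_area: int
    mean_area: float | None
    sd_area: float | None


_QUOTES = "\"'“”‘’"


def normalize_taxon(name: str) -> str:
    """Canonicalize a taxon name for matching tables to tree tips.

    Strips quotation marks and asterisks (typographic markers for
    questionable generic assignments, e.g. "Neohipparion" republicanus),
    and collapses runs of whitespace.
    """
    s = str(name)
    s = re.sub(f"[{_QUOTES}*]", "", s)
    s = re.sub(r"\s+", " ", s).strip()
    return s


def binarize(
    gray: np.ndarray, threshold: float = 0.5, dark_foreground: bool = True
) -> np.ndarray:
    """Threshold a grayscale array in [0, 1] to a {0, 1} trace mask.

    Polarity: with ``dark_foreground`` (the default) a pixel is foreground
    when its gray level is <= ``threshold`` — trace ink is dark on a light
    background.  With ``dark_foreground=False`` the comparison flips to
    ``>= threshold`` for white-on-black traces.

    Thresholding an already-binary {0, 1} image at the default threshold
    returns it unchanged up to polarity (idempotence).
    """
    g = np.asarray(gray, dtype=float)
    if dark_foreground:
        fg = g <= threshold
    else:
        fg = g >= threshold
    return fg.astype(np.uint8)


def read_trace(
    path: str | Path,
    threshold: float = 0.5,
    dark_foreground: bool = True,
    specimen_id: str | None = None,
) -> RasterTrace:
    """Read a trace image (TIFF/PNG; 8-bit gray or RGB) and binarize it.

    RGB images are converted to luminance; an alpha channel is ignored.
    Gray levels are scaled to [0, 1] before thresholding, so an 8-bit
    value v is foreground iff v/255 <= threshold (dark ink polarity).

    Raises
    ------
    EmptyTraceError
        If no pixel survives thresholding ("empty trace").
    """
    path = Path(path)
    with Image.open(path) as img:
        if img.mode not in ("L", "I;16", "I"):
            img = img.convert("RGB").convert("L")
        arr = np.asarray(img, dtype=float)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    mask = binarize(arr, threshold=threshold, dark_foreground=dark_foreground)
    if mask.sum() == 0:
        raise EmptyTraceError(f"empty trace: no foreground pixels in {path}")
    return RasterTrace(mask, specimen_id=specimen_id or path.stem)


def load_specimens(path: str | Path) -> list[SpecimenRecord]:
    """Load a specimen table (CSV with header) into records.

    Expected columns: ``specimen_id, taxon, tribe, tooth_position,
    area_cm2`` (area may be blank).  Rows whose tooth position is outside
    P3-M2 are excluded with a logged reason; missing areas are preserved
    as ``None``.

    Raises
    ------
    ValueError
        On an unknown tribe label or a duplicate specimen_id.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    required = {"specimen_id", "taxon", "tribe", "tooth_position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("specimen table %s is empty", path)
        return []

    dupes = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate specimen_id(s): {sorted(set(dupes))}")
    bad_tribe = sorted(set(df["tribe"]) - set(VALID_TRIBES))
    if bad_tribe:
        raise ValueError(f"unknown tribe label(s): {bad_tribe}")

    keep = df["tooth_position"].isin(VALID_POSITIONS)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "excluded %d specimen(s) with tooth position outside %s: %s",
            n_excluded,
            "P3-M2",
            sorted(set(df.loc[~keep, "tooth_position"])),
        )
    df = df[keep]

    records = []
    for row in df.itertuples(index=False):
        area = getattr(row, "area_cm2", None)
        if area is not None and pd.isna(area):
            area = None
        if area is not None:
            area = float(area)
            if area <= 0:
                raise ValueError(
                    f"non-positive area for specimen {row.specimen_id}: {area}"
                )
        d_val = getattr(row, "D", None)
        if d_val is not None and pd.isna(d_val):
            d_val = None
        records.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id),
                taxon=normalize_taxon(row.taxon),
                tribe=str(row.tribe),
                tooth_position=str(row.tooth_position),
                area=area,
                D=float(d_val) if d_val is not None else None,
            )
        )
    return records


def _mean_sd(values: Sequence[float]) -> tuple[int, float | None, float | None]:
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return 0, None, None
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n >= 2 else None
    return n, mean, sd


def summarize_species(records: Iterable[SpecimenRecord]) -> list[SpeciesSummary]:
    """Collapse specimens to per-species n/mean/SD for D and for area.

    Every record must carry a D value.  SDs use the n-1 denominator and
    are absent for singletons; species with no measured areas get
    ``n_area = 0`` and missing area statistics.  Output is sorted by
    (tribe, taxon) and is invariant to input row order.
    """
    by_taxon: dict[str, list[SpecimenRecord]] = {}
    for rec in records:
        if rec.D is None:
            raise ValueError(f"specimen {rec.specimen_id} has no D value")
        by_taxon.setdefault(rec.taxon, []).append(rec)

    out = []
    for taxon, recs in by_taxon.items():
        tribes = {r.tribe for r in recs}
        if len(tribes) > 1:
            raise ValueError(f"taxon {taxon!r} spans multiple tribes: {tribes}")
        n_D, mean_D, sd_D = _mean_sd([r.D for r in recs])
        n_area, mean_area, sd_area = _mean_sd(
            [r.area for r in recs if r.area is not None]
        )
        out.append(
            SpeciesSummary(
                taxon=taxon,
                tribe=recs[0].tribe,
                n_D=n_D,
                mean_D=mean_D,
                sd_D=sd_D,
                n_area=n_area,
                mean_area=mean_area,
                sd_area=sd_area,
            )
        )
    out.sort(key=lambda s: (s.tribe, s.taxon))
    return out


def summaries_to_frame(summaries: Iterable[SpeciesSummary]) -> pd.DataFrame:
    """Tabulate SpeciesSummary rows as a DataFrame (Table-1 layout)."""
    return pd.DataFrame(
        [
            {
                "tribe": s.tribe,
                "taxon": s.taxon,
                "n_D": s.n_D,
                "mean_D": s.mean_D,
                "sd_D": s.sd_D,
                "n_area": s.n_area,
                "mean_area": s.mean_area,
                "sd_area": s.sd_area,
            }
            for s in summaries
        ]
    )
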