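"""Readers and writers for spot tables, cell tables, probe panels, regions and bulk VAFs.

All downstream modules consume the typed containers defined here; files are only
touched in this module. Coordinates are micrometres with the origin at the image
top-left, x increasing rightwards and y downwards. A :class:`DialectConfig`
supplies column names and a pixel-size scale when the source table is in pixels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry
from shapely.geometry.polygon import Polygon
from shapely.geometry.multipolygon import MultiPolygon

logger = logging.getLogger(__name__)

MUTANT = "mutant"
WILDTYPE = "wildtype"
COPY_NUMBER = "copy_number"
ALLELE_CLASSES = (MUTANT, WILDTYPE, COPY_NUMBER)


class FormatError(ValueError):
    """A file violated the expected tabular or geometric format."""


class ValidationError(ValueError):
    """Parsed content violated a hard invariant."""


@dataclass
class DialectConfig:
    """Column naming and unit conventions of an input table.

    ``scale`` multiplies the raw coordinates; use e.g. 0.325 for tables in
    pixels at 0.325 µm/px. ``sep=None`` asks pandas to sniff the delimiter.
    """

    x: str = "x"
    y: str = "y"
    probe: str = "probe_id"
    quality: str | None = "quality"
    replicate: str | None = "replicate_id"
    scale: float = 1.0
    sep: str | None = None


# ---------------------------------------------------------------------------
# Spot tables
# ---------------------------------------------------------------------------


@dataclass
class SpotTable:
    """Decoded in situ sequencing signals with spatial coordinates.

    ``data`` has columns x, y (µm), probe_id, quality, replicate_id and a
    boolean ``feasible`` flag (False when the barcode does not resolve against
    the probe panel's codebook).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"x", "y", "probe_id", "quality", "replicate_id", "feasible"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"SpotTable missing columns: {sorted(missing)}")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("non-finite spot coordinate")
        if (xy < 0).any():
            raise ValidationError("negative spot coordinate")
        q = self.data["quality"].to_numpy(dtype=float)
        if ((q < 0) | (q > 1)).any():
            raise ValidationError("quality score outside [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_feasible(self) -> int:
        return int(self.data["feasible"].sum())

    def feasible_only(self) -> "SpotTable":
        return SpotTable(self.data[self.data["feasible"]].reset_index(drop=True))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of all spots, in µm."""
        if len(self.data) == 0:
            raise ValidationError("empty spot table has no bounding box")
        x = self.data["x"].to_numpy(float)
        y = self.data["y"].to_numpy(float)
        return float(x.min()), float(y.min()), float(x.max()), float(y.max())


def read_spot_table(
    path: str | Path,
    dialect: DialectConfig | None = None,
    panel: "ProbePanel | None" = None,
) -> SpotTable:
    """Read a decoded spot table from CSV/TSV.

    Rows whose barcode/probe id is absent from ``panel``'s codebook are kept
    but flagged infeasible so the misdecoding fraction stays measurable.
    Raises :class:`FormatError` for a missing mandatory column and a row-level
    error (with the 1-based data line number) for a non-numeric coordinate.
    """
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, sep=dialect.sep, engine="python")
    for col in (dialect.x, dialect.y, dialect.probe):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path}")
    out = pd.DataFrame()
    for axis, col in (("x", dialect.x), ("y", dialect.y)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
        elif vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
        else:
            line = None
        if line is not None:
            raise FormatError(
                f"non-numeric {axis} coordinate at line {line} of {path}"
            )
        out[axis] = vals.to_numpy(dtype=float) * dialect.scale
    out["probe_id"] = df[dialect.probe].astype(str)
    if dialect.quality and dialect.quality in df.columns:
        out["quality"] = pd.to_numeric(df[dialect.quality]).clip(0.0, 1.0)
    else:
        out["quality"] = 1.0
    if dialect.replicate and dialect.replicate in df.columns:
        out["replicate_id"] = df[dialect.replicate].astype(str)
    else:
        out["replicate_id"] = "r0"
    if panel is not None:
        known = set(panel.data["probe_id"]) | set(panel.data["barcode"])
        out["feasible"] = out["probe_id"].isin(known)
    else:
        out["feasible"] = True
    spots = SpotTable(out)
    logger.info(
        "read %d spots from %s (%d feasible)", len(spots), path, spots.n_feasible
    )
    return spots


def write_spot_table(spots: SpotTable, path: str | Path) -> None:
    spots.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------


@dataclass
class CellTable:
    """Nucleus centroids, optionally with a cell-type label and gene counts.

    ``data`` holds x, y (µm) and cell_type; ``gene_counts`` is an optional
    cells × genes integer DataFrame aligned with ``data``'s index.
    """

    data: pd.DataFrame
    gene_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not {"x", "y"} <= set(self.data.columns):
            raise ValidationError("CellTable needs x and y columns")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("non-finite cell coordinate")
        if "cell_type" not in self.data.columns:
            self.data = self.data.assign(cell_type=pd.NA)
        if self.gene_counts is not None:
            g = self.gene_counts.to_numpy()
            if (g < 0).any() or not np.issubdtype(g.dtype, np.integer):
                raise ValidationError("gene counts must be non-negative integers")
            if not self.gene_counts.index.equals(self.data.index):
                raise ValidationError("gene_counts index does not match cells")

    def __len__(self) -> int:
        return len(self.data)


def read_cell_table(path: str | Path, dialect: DialectConfig | None = None) -> CellTable:
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, sep=dialect.sep, engine="python")
    for col in (dialect.x, dialect.y):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path}")
    out = pd.DataFrame(
        {
            "x": pd.to_numeric(df[dialect.x]) * dialect.scale,
            "y": pd.to_numeric(df[dialect.y]) * dialect.scale,
        }
    )
    out["cell_type"] = df["cell_type"] if "cell_type" in df.columns else pd.NA
    return CellTable(out)


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    cells.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Probe panel
# ---------------------------------------------------------------------------


@dataclass
class ProbePanel:
    """Padlock-probe panel: targeted locus, allele class, phylogeny branch, barcode.

    Mutant probes must pair with a wildtype probe at the same locus (copy-number
    targets are exempt); barcodes are unique. Validation warnings (e.g. an
    unpaired mutant probe) are collected in ``warnings`` rather than raised.
    """

    data: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"probe_id", "locus_id", "allele_class", "branch_id", "barcode"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"ProbePanel missing columns: {sorted(missing)}")
        bad_class = set(self.data["allele_class"]) - set(ALLELE_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown allele_class values: {sorted(bad_class)}")
        dup_bc = self.data["barcode"][self.data["barcode"].duplicated()]
        if len(dup_bc):
            raise ValidationError(f"duplicate barcode(s): {sorted(set(dup_bc))}")
        dup_la = self.data[self.data.duplicated(["locus_id", "allele_class"])]
        if len(dup_la):
            pairs = sorted(
                set(zip(dup_la["locus_id"], dup_la["allele_class"]))
            )
            raise ValidationError(f"duplicate (locus_id, allele_class): {pairs}")
        for _, row in self.data[self.data["allele_class"] == MUTANT].iterrows():
            mate = self.data[
                (self.data["locus_id"] == row["locus_id"])
                & (self.data["allele_class"] == WILDTYPE)
            ]
            if mate.empty:
                self.warnings.append(
                    f"mutant probe {row['probe_id']} has no wildtype mate "
                    f"at locus {row['locus_id']}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data["probe_id"])

    def pairs(self) -> list[tuple[str, str, str]]:
        """(locus_id, mutant probe_id, wildtype probe_id) for every paired SNV locus."""
        out = []
        wt = self.data[self.data["allele_class"] == WILDTYPE].set_index("locus_id")
        for _, row in self.data[self.data["allele_class"] == MUTANT].iterrows():
            if row["locus_id"] in wt.index:
                out.append(
                    (row["locus_id"], row["probe_id"], wt.loc[row["locus_id"], "probe_id"])
                )
        return out


def read_probe_panel(path: str | Path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise FormatError(f"no probes parsed from {path}")
    df["probe_id"] = df["probe_id"].astype(str)
    df["locus_id"] = df["locus_id"].astype(str)
    df["barcode"] = df["barcode"].astype(str)
    return ProbePanel(df.reset_index(drop=True))


def write_probe_panel(panel: ProbePanel, path: str | Path) -> None:
    panel.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass
class Region:
    region_id: str
    label: str
    polygon: BaseGeometry
    histology: dict = field(default_factory=dict)

    def contains(self, x: float, y: float) -> bool:
        return self.polygon.contains(Point(x, y))


@dataclass
class RegionSet:
    """Named polygons (µm coordinates); holes are honoured in containment tests."""

    regions: list[Region]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate region_id")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]


def read_regions(path: str | Path) -> RegionSet:
    """Read a GeoJSON FeatureCollection of (multi)polygons.

    Self-intersecting polygons are a hard error naming the offending region;
    non-polygon geometries are skipped with a warning.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path} is not a GeoJSON FeatureCollection")
    regions: list[Region] = []
    warnings: list[str] = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        rid = str(props.get("region_id", f"region_{i}"))
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Polygon, MultiPolygon)):
            warnings.append(f"{rid}: non-polygon geometry skipped")
            continue
        if not geom.is_valid:
            raise ValidationError(f"region {rid}: invalid (self-intersecting?) polygon")
        regions.append(
            Region(
                region_id=rid,
                label=str(props.get("label", rid)),
                polygon=geom,
                histology=dict(props.get("histology", {})),
            )
        )
    return RegionSet(regions, warnings)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    feats = []
    for r in regions:
        feats.append(
            {
                "type": "Feature",
                "geometry": r.polygon.__geo_interface__,
                "properties": {
                    "region_id": r.region_id,
                    "label": r.label,
                    "histology": r.histology,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# Bulk VAF tables
# ---------------------------------------------------------------------------


@dataclass
class BulkVAFTable:
    """Per (sample, locus) variant allele fraction and read depth from bulk WGS."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "locus_id", "vaf", "depth"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"BulkVAFTable missing columns: {sorted(missing)}")
        v = self.data["vaf"].to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValidationError("vaf outside [0, 1]")
        d = self.data["depth"].to_numpy()
        if (d < 1).any():
            raise ValidationError("depth must be >= 1")

    def __len__(self) -> int:
        return len(self.data)


def read_bulk_vaf(path: str | Path) -> BulkVAFTable:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    df["locus_id"] = df["locus_id"].astype(str)
    return BulkVAFTable(df)


def write_bulk_vaf(table: BulkVAFTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


def validation_report(objs: Sequence[object]) -> tuple[str, bool]:
    """Human-readable summary of collected warnings; second value is True if clean."""
    lines = []
    clean = True
    for obj in objs:
        name = type(obj).__name__
        warns = getattr(obj, "warnings", [])
        n = len(obj) if hasattr(obj, "__len__") else "?"
        lines.append(f"{name}: {n} records, {len(warns)} warning(s)")
        for w in warns:
            lines.append(f"  - {w}")
        if isinstance(obj, SpotTable):
            lines.append(
                f"  feasible: {obj.n_feasible}/{len(obj)}"
            )
    return "\n".join(lines), clean
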