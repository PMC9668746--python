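"""Presentation-layer products of a fitted clone map.

Dominant-clone fields follow the rendering rule used throughout the study:
a tile shows its most prevalent tumour clone only where that clone's cancer
cell fraction exceeds 25% and the local cell density exceeds 300 cells/mm²;
otherwise the tile is masked with a recorded reason. "CCF" here is the
dominant tumour component's fraction among all cells of the tile (normal cells
included in the denominator); tumour-only renormalization is available via a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gridding import DensityField
from .io import RegionSet, ValidationError
from .model import CloneMap, tiles_in_regions

MASK_NONE = ""
MASK_LOW_CCF = "low_ccf"
MASK_LOW_DENSITY = "low_density"

DEFAULT_CCF_THRESHOLD = 0.25
DEFAULT_DENSITY_THRESHOLD = 300.0  # cells per mm²


@dataclass
class DominantCloneField:
    """Per-tile dominant tumour clone label, or a mask reason."""

    grid: object
    labels: np.ndarray        # (T,) object array: clone label or "" when masked
    mask_reason: np.ndarray   # (T,) one of MASK_* constants
    tie_flags: np.ndarray     # (T,) bool, exact argmax ties broken by clone order

    def label_at_tiles(self, tile_idx: np.ndarray) -> np.ndarray:
        return self.labels[tile_idx]


def dominant_clone_map(
    cmap: CloneMap,
    ccf_threshold: float = DEFAULT_CCF_THRESHOLD,
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD,
    tumour_only: bool = False,
    component_thresholds: dict[str, float] | None = None,
) -> DominantCloneField:
    """Project the most prevalent tumour clone per tile, masked by CCF and density.

    ``component_thresholds`` overrides the CCF threshold per clone (used e.g.
    to lower the cutoff for a diffusely infiltrating clone in high-normal
    regions). Exact ties are broken by clone order in the map and flagged.
    """
    tumour = cmap.tumour_components
    t_idx = [cmap.components.index(c) for c in tumour]
    Wt = cmap.w_mean[:, t_idx]
    if tumour_only:
        denom = Wt.sum(axis=1, keepdims=True)
        frac = np.divide(Wt, denom, out=np.zeros_like(Wt), where=denom > 0)
    else:
        frac = Wt
    best = np.argmax(frac, axis=1)  # first index wins on exact ties
    ties = (frac == frac[np.arange(len(frac)), best][:, None]).sum(axis=1) > 1
    best_frac = frac[np.arange(len(frac)), best]
    dens = cmap.density.cells_per_mm2
    thr = np.array(
        [
            (component_thresholds or {}).get(tumour[b], ccf_threshold)
            for b in best
        ]
    )
    labels = np.array([tumour[b] for b in best], dtype=object)
    reason = np.full(len(labels), MASK_NONE, dtype=object)
    reason[best_frac <= thr] = MASK_LOW_CCF
    reason[dens <= density_threshold] = MASK_LOW_DENSITY
    labels[reason != MASK_NONE] = ""
    return DominantCloneField(cmap.grid, labels, reason, ties)


def dominant_clone_table(fieldmap: DominantCloneField) -> pd.DataFrame:
    """Audit TSV content: one row per tile with label and mask reason."""
    grid = fieldmap.grid
    iy, ix = np.divmod(np.arange(grid.n_tiles), grid.nx)
    return pd.DataFrame(
        {
            "tile_ix": ix,
            "tile_iy": iy,
            "label": fieldmap.labels,
            "mask_reason": fieldmap.mask_reason,
            "tie": fieldmap.tie_flags,
        }
    )


@dataclass
class CompositionMatrix:
    """Regions × components matrix of density-weighted mean clone fractions."""

    data: pd.DataFrame  # rows: region_id, cols: components; NaN rows = empty region

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        rows = np.nansum(vals, axis=1)
        filled = ~np.isnan(vals).all(axis=1)
        if not np.allclose(rows[filled], 1.0, atol=1e-6):
            raise ValidationError("composition rows must sum to 1")


def region_composition(
    cmap: CloneMap, density: DensityField, regions: RegionSet
) -> CompositionMatrix:
    """Density-weighted mean component fractions per region (the heatmap rows)."""
    tiles = tiles_in_regions(cmap.grid, regions)
    n = np.asarray(density.n, float)
    rows = {}
    for rid, idx in tiles.items():
        mass = n[idx].sum() if len(idx) else 0.0
        if mass <= 0:
            rows[rid] = np.full(len(cmap.components), np.nan)
        else:
            rows[rid] = (n[idx, None] * cmap.w_mean[idx]).sum(axis=0) / mass
    return CompositionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=cmap.components)
    )


@dataclass
class ConcordanceResult:
    per_locus: pd.Series      # Pearson r per locus (NaN + flag when degenerate)
    pooled: float
    zero_variance: list[str] = field(default_factory=list)


def replicate_concordance(
    vaf_a: pd.DataFrame, vaf_b: pd.DataFrame, min_pairs: int = 3
) -> ConcordanceResult:
    """Pearson correlation of two regional VAF matrices, per locus and pooled.

    Matrices must share region/locus indexing; missing pairs are dropped
    listwise; loci with zero variance in either replicate get NaN with a flag.
    """
    if not vaf_a.index.equals(vaf_b.index) or not vaf_a.columns.equals(vaf_b.columns):
        raise ValidationError("replicate VAF matrices are not aligned")
    per_locus = {}
    zero_var = []
    for locus in vaf_a.columns:
        a = vaf_a[locus].to_numpy(float)
        b = vaf_b[locus].to_numpy(float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < min_pairs:
            per_locus[locus] = np.nan
            continue
        if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            per_locus[locus] = np.nan
            zero_var.append(locus)
            continue
        per_locus[locus] = stats.pearsonr(a[ok], b[ok]).statistic
    a = vaf_a.to_numpy(float).ravel()
    b = vaf_b.to_numpy(float).ravel()
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < min_pairs or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        pooled = np.nan
    else:
        pooled = stats.pearsonr(a[ok], b[ok]).statistic
    return ConcordanceResult(pd.Series(per_locus), float(pooled), zero_var)
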