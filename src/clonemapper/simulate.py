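"""Forward simulator of allele-specific in situ sequencing experiments.

Generates tissues with known clone territories, places cells, and emits the
same spot/cell/bulk tables the readers produce, with the relevant noise
processes of the real assay: per-probe efficiency variation, per-locus
expression scales, a target mean number of detected signals per nucleus
(default 0.82), barcode misdecoding (default 3% of signals end up infeasible,
with an equal share landing on a wrong feasible barcode), and uniform
unspecific background signals. Generation is cell-level so per-nucleus
detection questions remain explorable. Every stage is reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from shapely.geometry import Point, box

from ._svi import kernel_matrix
from .genotype import (
    NORMAL_CLONE,
    CloneTree,
    GenotypeMatrix,
    build_genotype_matrix,
    expected_vaf,
)
from .gridding import DensityField, Grid, make_grid
from .io import (
    MUTANT,
    WILDTYPE,
    BulkVAFTable,
    CellTable,
    ProbePanel,
    Region,
    RegionSet,
    SpotTable,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Default tree and panel: 4 tumour clones, 25 paired SNV loci
# ---------------------------------------------------------------------------


def default_tree() -> CloneTree:
    """Branching 4-clone phylogeny: trunk c1 -> c2 -> c3, with c4 off the trunk."""
    return CloneTree(
        parent={"c1": None, "c2": "c1", "c3": "c2", "c4": "c1"},
        colors={"c1": "grey", "c2": "blue", "c3": "green", "c4": "orange"},
    )


def _barcodes(n: int, length: int = 5) -> list[str]:
    codes = ["".join(c) for c in product("ACGT", repeat=length)]
    step = len(codes) // n
    return [codes[i * step] for i in range(n)]  # well-separated in Hamming space


def default_panel(n_loci: int = 25, tree: CloneTree | None = None) -> ProbePanel:
    """Mutant/wildtype probe pairs for ``n_loci`` SNVs spread over the branches."""
    tree = tree or default_tree()
    branches = tree.clones
    rows = []
    codes = iter(_barcodes(2 * n_loci))
    for l in range(n_loci):
        branch = branches[l % len(branches)]
        locus = f"L{l:02d}"
        rows.append((f"{locus}_mut", locus, MUTANT, branch, next(codes)))
        rows.append((f"{locus}_wt", locus, WILDTYPE, branch, next(codes)))
    return ProbePanel(
        pd.DataFrame(
            rows,
            columns=["probe_id", "locus_id", "allele_class", "branch_id", "barcode"],
        )
    )


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions of a simulated experiment (defaults = the benchmark)."""

    extent_um: tuple[float, float] = (5000.0, 5000.0)
    tile_size: float = 100.0
    territory_mode: str = "gp_field"    # gp_field | duct_mosaic | half_split
    gp_lengthscale_um: float = 800.0
    gp_variance: float = 4.0
    n_lobules: int = 8
    n_discs: int = 20
    disc_radius_um: float = 150.0
    disc_purity: float = 0.98
    cell_density_per_mm2: float = 1000.0
    disc_density_per_mm2: float = 2500.0
    background_density_per_mm2: float = 500.0
    target_signals_per_nucleus: float = 0.82
    misdecode_fraction: float = 0.03     # fraction of signals lost to infeasible codes
    efficiency_sd: float = 0.5           # lognormal sd of per-probe efficiency
    expression_sd: float = 0.3           # lognormal sd of per-locus expression
    unspecific_fraction: float = 0.05    # share of signals that are background
    spot_jitter_um: float = 5.0
    replicate_count: int = 2
    bulk_depth: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.misdecode_fraction, self.unspecific_fraction, self.disc_purity):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if min(self.extent_um) <= 0:
            raise ValidationError("extent must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated tissue: the benchmark yardstick."""

    config: SimConfig
    grid: Grid
    components: list[str]        # clone order incl. the normal component
    w_star: np.ndarray           # (T, K) true per-tile clone fractions
    cells: pd.DataFrame          # x, y, clone (the reference cell population)
    tree: CloneTree
    panel: ProbePanel
    G: GenotypeMatrix
    efficiency: np.ndarray       # (J,) true probe efficiencies, geometric mean 1
    expression: np.ndarray       # (L,) true per-locus expression scales
    locus_idx: np.ndarray        # (J,) locus index per probe
    scale: float | None = None   # set by calibrate_signal_scale

    def __post_init__(self) -> None:
        rows = self.w_star.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValidationError("true weight rows must sum to 1")

    def density(self) -> DensityField:
        tiles = self.grid.tile_indices(
            self.cells["x"].to_numpy(), self.cells["y"].to_numpy()
        )
        n = np.bincount(tiles[tiles >= 0], minlength=self.grid.n_tiles).astype(float)
        return DensityField(n, self.grid)

    def cell_table(self) -> CellTable:
        return CellTable(self.cells[["x", "y"]].copy())

    def clone_weights_in(self, tile_idx: np.ndarray) -> np.ndarray:
        """Cell-count clone mixture over a tile subset (exact, from the cell list)."""
        tiles = self.grid.tile_indices(
            self.cells["x"].to_numpy(), self.cells["y"].to_numpy()
        )
        sel = np.isin(tiles, tile_idx)
        sub = self.cells[sel]
        counts = np.array(
            [(sub["clone"] == c).sum() for c in self.components], dtype=float
        )
        total = counts.sum()
        return counts / total if total > 0 else counts

    def regional_vaf(self, regions: RegionSet) -> pd.DataFrame:
        """True per-region VAF matrix from the exact cell composition."""
        from .model import tiles_in_regions

        tiles = tiles_in_regions(self.grid, regions)
        rows = {}
        loci = None
        for rid, idx in tiles.items():
            w = self.clone_weights_in(idx)
            if w.sum() == 0:
                rows[rid] = None
                continue
            vaf, _, loci = expected_vaf(self.G, w)
            rows[rid] = vaf
        n_loci = len(loci) if loci else 0
        return pd.DataFrame.from_dict(
            {
                rid: (v if v is not None else np.full(n_loci, np.nan))
                for rid, v in rows.items()
            },
            orient="index",
            columns=loci,
        )


# ---------------------------------------------------------------------------
# Territory generation
# ---------------------------------------------------------------------------


def _sample_gp_fields(
    centres: np.ndarray, n_fields: int, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    K = kernel_matrix(centres, centres, "matern32", cfg.gp_lengthscale_um, cfg.gp_variance)
    K[np.diag_indices_from(K)] += 1e-6 * cfg.gp_variance
    L = cholesky(K, lower=True)
    return (L @ rng.standard_normal((len(centres), n_fields)))


def _place_cells_uniform(
    extent: tuple[float, float], density_mm2: float, rng: np.random.Generator
) -> np.ndarray:
    area_mm2 = extent[0] * extent[1] / 1e6
    n = rng.poisson(density_mm2 * area_mm2)
    return rng.uniform((0, 0), extent, size=(n, 2))


def simulate_territories(
    config: SimConfig,
    seed: int | None = None,
    tree: CloneTree | None = None,
    panel: ProbePanel | None = None,
) -> SyntheticTruth:
    """Draw a ground-truth clone-weight field and a cell population.

    ``gp_field`` softmaxes independent GP draws per component into smooth
    interdigitated territories; ``duct_mosaic`` scatters single-clone discs
    ("acini") grouped into lobules over a normal background, emulating
    microanatomically confined near-complete clonal sweeps; ``half_split`` is
    a deterministic two-clone vertical split for boundary benchmarks.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tree = tree or default_tree()
    panel = panel or default_panel(tree=tree)
    G = build_genotype_matrix(tree, panel)
    components = G.clones
    if len(components) < 2:
        raise ValidationError("need at least one tumour clone")
    K = len(components)
    grid = make_grid((0, 0, *config.extent_um), config.tile_size)
    centres = grid.tile_centres()
    T = grid.n_tiles

    if config.territory_mode == "gp_field":
        F = _sample_gp_fields(centres, K, config, rng)
        F -= F.max(axis=1, keepdims=True)
        E = np.exp(F)
        w_star = E / E.sum(axis=1, keepdims=True)
        cells_xy = _place_cells_uniform(config.extent_um, config.cell_density_per_mm2, rng)
        tiles = grid.tile_indices(cells_xy[:, 0], cells_xy[:, 1])
        probs = w_star[tiles]
        u = rng.random(len(cells_xy))
        clone_idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        cells = pd.DataFrame(
            {
                "x": cells_xy[:, 0],
                "y": cells_xy[:, 1],
                "clone": [components[i] for i in clone_idx],
            }
        )
    elif config.territory_mode == "half_split":
        a, b = components[0], components[1]
        w_star = np.zeros((T, K))
        left = centres[:, 0] < config.extent_um[0] / 2
        w_star[left, components.index(a)] = 0.8
        w_star[~left, components.index(b)] = 0.8
        w_star[:, components.index(NORMAL_CLONE)] += 0.2
        cells_xy = _place_cells_uniform(config.extent_um, config.cell_density_per_mm2, rng)
        tiles = grid.tile_indices(cells_xy[:, 0], cells_xy[:, 1])
        probs = w_star[tiles]
        u = rng.random(len(cells_xy))
        clone_idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        cells = pd.DataFrame(
            {
                "x": cells_xy[:, 0],
                "y": cells_xy[:, 1],
                "clone": [components[i] for i in clone_idx],
            }
        )
    elif config.territory_mode == "duct_mosaic":
        tumour = [c for c in components if c != NORMAL_CLONE]
        lob_centres = rng.uniform(
            (config.disc_radius_um, config.disc_radius_um),
            (
                config.extent_um[0] - config.disc_radius_um,
                config.extent_um[1] - config.disc_radius_um,
            ),
            size=(config.n_lobules, 2),
        )
        # each lobule mixes up to two clones; each disc sweeps a single clone
        lob_clones = [
            rng.choice(len(tumour), size=min(2, len(tumour)), replace=False)
            for _ in range(config.n_lobules)
        ]
        disc_lob = rng.integers(config.n_lobules, size=config.n_discs)
        disc_xy = lob_centres[disc_lob] + rng.normal(0, 300.0, size=(config.n_discs, 2))
        disc_xy = np.clip(disc_xy, 0, config.extent_um)
        disc_clone = np.array(
            [tumour[rng.choice(lob_clones[l])] for l in disc_lob], dtype=object
        )
        # background normal cells
        bg = _place_cells_uniform(config.extent_um, config.background_density_per_mm2, rng)
        rows = [pd.DataFrame({"x": bg[:, 0], "y": bg[:, 1], "clone": NORMAL_CLONE,
                              "disc": -1})]
        area_mm2 = np.pi * config.disc_radius_um**2 / 1e6
        for d in range(config.n_discs):
            n = rng.poisson(config.disc_density_per_mm2 * area_mm2)
            r = config.disc_radius_um * np.sqrt(rng.random(n))
            th = rng.uniform(0, 2 * np.pi, n)
            xy = disc_xy[d] + np.column_stack([r * np.cos(th), r * np.sin(th)])
            is_clone = rng.random(n) < config.disc_purity
            rows.append(
                pd.DataFrame(
                    {
                        "x": xy[:, 0],
                        "y": xy[:, 1],
                        "clone": np.where(is_clone, disc_clone[d], NORMAL_CLONE),
                        "disc": d,
                    }
                )
            )
        cells = pd.concat(rows, ignore_index=True)
        cells = cells[
            (cells["x"] >= 0) & (cells["x"] < config.extent_um[0])
            & (cells["y"] >= 0) & (cells["y"] < config.extent_um[1])
        ].reset_index(drop=True)
        # expected composition per tile via 4x4 supersampling of disc membership
        w_star = np.zeros((T, K))
        offs = (np.arange(4) + 0.5) / 4 * config.tile_size - config.tile_size / 2
        sub = np.array([(dx, dy) for dx in offs for dy in offs])
        pts = centres[:, None, :] + sub[None, :, :]
        dens = np.full((T, len(sub)), config.background_density_per_mm2)
        owner = np.full((T, len(sub)), -1)
        for d in range(config.n_discs):
            inside = (
                np.linalg.norm(pts - disc_xy[d], axis=2) <= config.disc_radius_um
            ) & (owner == -1)
            owner[inside] = d
            dens[inside] += config.disc_density_per_mm2
        for k, comp in enumerate(components):
            share = np.where(
                owner >= 0,
                np.where(
                    np.array([disc_clone[o] if o >= 0 else "" for o in owner.ravel()])
                    .reshape(owner.shape) == comp,
                    config.disc_purity * config.disc_density_per_mm2,
                    0.0,
                )
                + (
                    (1 - config.disc_purity) * config.disc_density_per_mm2
                    + config.background_density_per_mm2
                    if comp == NORMAL_CLONE
                    else 0.0
                ),
                config.background_density_per_mm2 if comp == NORMAL_CLONE else 0.0,
            )
            w_star[:, k] = (share / dens).mean(axis=1)
    else:
        raise ValidationError(f"unknown territory mode '{config.territory_mode}'")

    J = G.n_probes
    loci = G.locus_of_probe()
    locus_list = list(dict.fromkeys(loci))
    locus_idx = np.array([locus_list.index(l) for l in loci])
    le = rng.normal(0, config.efficiency_sd, J)
    efficiency = np.exp(le - le.mean())
    expression = np.exp(rng.normal(0, config.expression_sd, len(locus_list)))
    return SyntheticTruth(
        config=config,
        grid=grid,
        components=components,
        w_star=w_star,
        cells=cells[["x", "y", "clone"]].copy(),
        tree=tree,
        panel=panel,
        G=G,
        efficiency=efficiency,
        expression=expression,
        locus_idx=locus_idx,
    )


# ---------------------------------------------------------------------------
# Signal-scale calibration
# ---------------------------------------------------------------------------


def calibrate_signal_scale(
    config: SimConfig, G: GenotypeMatrix, truth: SyntheticTruth | None = None
) -> float:
    """Global scalar on e_j·s_l making E[signals per nucleus] hit the target.

    The expected per-cell signal count is linear in the scale, so the solution
    is closed form. The target covers all detected signals; the share set
    aside for unspecific background (``unspecific_fraction``) is emitted by the
    uniform background process instead, so cell-derived signals aim at
    target·(1 − f).
    """
    if config.target_signals_per_nucleus <= 0:
        raise ValidationError("target signals per nucleus must be positive")
    if truth is not None:
        counts = np.array(
            [(truth.cells["clone"] == c).sum() for c in truth.G.clones], dtype=float
        )
        wk = counts / counts.sum()
        per_cell = truth.efficiency * truth.expression[truth.locus_idx]
        A = float(per_cell @ (G.G @ wk))
    else:
        wk = np.full(G.n_clones, 1.0 / G.n_clones)
        A = float(np.sum(G.G @ wk))
    if A <= 0:
        raise ValidationError("degenerate panel: zero expected signal")
    scale = config.target_signals_per_nucleus * (1 - config.unspecific_fraction) / A
    if truth is not None:
        truth.scale = scale
    return scale


# ---------------------------------------------------------------------------
# Experiment generation
# ---------------------------------------------------------------------------


def quadrant_regions(extent: tuple[float, float]) -> RegionSet:
    """Four rectangular pseudo-bulk samples tiling the tissue."""
    hx, hy = extent[0] / 2, extent[1] / 2
    regions = []
    for i, (x0, y0) in enumerate([(0, 0), (hx, 0), (0, hy), (hx, hy)]):
        regions.append(
            Region(f"bulk_q{i}", f"quadrant {i}", box(x0, y0, x0 + hx, y0 + hy))
        )
    return RegionSet(regions)


def _draw_cells_like(truth: SyntheticTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Fresh cell population from the same truth field (a serial section)."""
    cfg = truth.config
    dens = truth.density()
    lam = dens.n  # expected cells per tile taken from the reference section
    n_per_tile = rng.poisson(lam)
    tiles = np.repeat(np.arange(truth.grid.n_tiles), n_per_tile)
    iy, ix = np.divmod(tiles, truth.grid.nx)
    xy = np.column_stack(
        [
            truth.grid.origin[0] + (ix + rng.random(len(tiles))) * cfg.tile_size,
            truth.grid.origin[1] + (iy + rng.random(len(tiles))) * cfg.tile_size,
        ]
    )
    probs = truth.w_star[tiles]
    u = rng.random(len(tiles))
    clone_idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "clone": [truth.components[i] for i in clone_idx],
        }
    )


def simulate_experiment(
    truth: SyntheticTruth,
    G: GenotypeMatrix,
    config: SimConfig,
    seed: int | None = None,
) -> dict:
    """Generate replicate spot/cell tables and bulk VAFs from a calibrated truth.

    Per cell and probe the detected count is Poisson(scale·e_j·s_l·G_{j,clone});
    spot positions are jittered around the cell (sd ``spot_jitter_um``).
    2·misdecode_fraction of all signals are reassigned to a random other
    barcode — half to infeasible codes (so the feasible fraction is
    1 − misdecode_fraction) and half to a wrong feasible barcode. Unspecific
    signals are a uniform Poisson field sized to ``unspecific_fraction`` of the
    target detection rate. Replicates are independent draws (fresh serial-
    section cell populations) from the same truth; bulk VAFs are exact from the
    truth composition with binomial depth noise.
    """
    if truth.scale is None:
        raise ValidationError("run calibrate_signal_scale before simulate_experiment")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    J = G.n_probes
    probe_ids = np.array(G.probe_ids)
    per_probe = truth.scale * truth.efficiency * truth.expression[truth.locus_idx]
    replicates = []
    for rep in range(config.replicate_count):
        cells = truth.cells if rep == 0 else _draw_cells_like(truth, rng)
        xs, ys, pid = [], [], []
        for k, clone in enumerate(G.clones):
            sub = cells[cells["clone"] == clone]
            if sub.empty:
                continue
            rate = per_probe * G.G[:, k]
            counts = rng.poisson(rate, size=(len(sub), J))
            cell_i, probe_i = np.nonzero(counts)
            reps = counts[cell_i, probe_i]
            cell_i = np.repeat(cell_i, reps)
            probe_i = np.repeat(probe_i, reps)
            xs.append(sub["x"].to_numpy()[cell_i])
            ys.append(sub["y"].to_numpy()[cell_i])
            pid.append(probe_i)
        xs = np.concatenate(xs) if xs else np.empty(0)
        ys = np.concatenate(ys) if ys else np.empty(0)
        pid = np.concatenate(pid) if pid else np.empty(0, int)
        xs = xs + rng.normal(0, config.spot_jitter_um, len(xs))
        ys = ys + rng.normal(0, config.spot_jitter_um, len(ys))
        # uniform unspecific background
        f = config.unspecific_fraction
        n_unspec = rng.poisson(
            f * config.target_signals_per_nucleus * len(cells)
        )
        ux = rng.uniform(0, config.extent_um[0], n_unspec)
        uy = rng.uniform(0, config.extent_um[1], n_unspec)
        up = rng.integers(J, size=n_unspec)
        xs = np.concatenate([xs, ux])
        ys = np.concatenate([ys, uy])
        pid = np.concatenate([pid, up])
        probe = probe_ids[pid].astype(object)
        # misdecoding: half to infeasible codes, half to a wrong feasible barcode
        n = len(probe)
        n_mis = rng.binomial(n, 2 * config.misdecode_fraction)
        mis = rng.choice(n, size=n_mis, replace=False)
        half = n_mis // 2
        probe[mis[:half]] = "_infeasible"
        if n_mis - half > 0:
            shift = rng.integers(1, J, size=n_mis - half)
            probe[mis[half:]] = probe_ids[(pid[mis[half:]] + shift) % J]
        spots = SpotTable(
            pd.DataFrame(
                {
                    "x": np.clip(xs, 0, None),
                    "y": np.clip(ys, 0, None),
                    "probe_id": probe,
                    "quality": 1.0,
                    "replicate_id": f"rep{rep}",
                    "feasible": probe != "_infeasible",
                }
            )
        )
        replicates.append(
            {
                "spots": spots,
                "cells": CellTable(cells[["x", "y"]].reset_index(drop=True)),
            }
        )
    # bulk pseudo-samples: quadrants, exact truth VAF + binomial depth noise
    bulk_regions = quadrant_regions(config.extent_um)
    truth_bulk = truth.regional_vaf(bulk_regions)
    rows = []
    for rid in truth_bulk.index:
        for locus in truth_bulk.columns:
            v = truth_bulk.loc[rid, locus]
            if np.isnan(v):
                continue
            d = config.bulk_depth
            rows.append((rid, locus, rng.binomial(d, v) / d, d))
    bulk = BulkVAFTable(
        pd.DataFrame(rows, columns=["sample_id", "locus_id", "vaf", "depth"])
    )
    return {
        "replicates": replicates,
        "bulk": bulk,
        "bulk_regions": bulk_regions,
        "truth_bulk_vaf": truth_bulk,
    }


# ---------------------------------------------------------------------------
# Validation regions and recovery metrics
# ---------------------------------------------------------------------------


def validation_regions(
    truth: SyntheticTruth, n_regions: int = 11, radius_um: float = 600.0, seed: int = 0
) -> RegionSet:
    """Circular validation regions spread across distinct clone territories.

    Round-robins over components, picking for each the densest-territory tile
    centre still far from previously chosen regions, so the region set spans
    the clone space (the benchmark analog of multi-region validation sampling).
    The default radius puts regions at the millimetre scale of laser-capture
    microdissection samples.
    """
    centres = truth.grid.tile_centres()
    chosen: list[np.ndarray] = []
    regions: list[Region] = []
    K = truth.w_star.shape[1]
    k = 0
    guard = 0
    while len(regions) < n_regions and guard < 10 * n_regions:
        guard += 1
        comp = k % K
        k += 1
        score = truth.w_star[:, comp].copy()
        for c in chosen:
            score[np.linalg.norm(centres - c, axis=1) < 1.5 * radius_um] = -np.inf
        margin = radius_um
        ok = (
            (centres[:, 0] > margin)
            & (centres[:, 0] < truth.config.extent_um[0] - margin)
            & (centres[:, 1] > margin)
            & (centres[:, 1] < truth.config.extent_um[1] - margin)
        )
        score[~ok] = -np.inf
        if not np.isfinite(score).any():
            continue
        c = centres[int(np.argmax(score))]
        chosen.append(c)
        regions.append(
            Region(
                f"region_{len(regions):02d}",
                f"territory {truth.components[comp]}",
                Point(c).buffer(radius_um, quad_segs=32),
            )
        )
    return RegionSet(regions)


def _mean_per_locus_r(vaf: pd.DataFrame, truth_vaf: pd.DataFrame) -> float:
    from scipy import stats

    rs = []
    for locus in truth_vaf.columns:
        if locus not in vaf.columns:
            continue
        a = vaf[locus].reindex(truth_vaf.index).to_numpy(float)
        b = truth_vaf[locus].to_numpy(float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            continue
        rs.append(stats.pearsonr(a[ok], b[ok]).statistic)
    return float(np.mean(rs)) if rs else np.nan


def _boundary_displacement(
    truth: SyntheticTruth, w_fit: np.ndarray, components: list[str]
) -> float:
    """Mean per-row displacement (in tiles) of a two-clone vertical boundary."""
    grid = truth.grid
    tum = [c for c in truth.components if c != NORMAL_CLONE][:2]
    ti = [truth.components.index(c) for c in tum]
    fi = [components.index(c) for c in tum]
    lab_t = (truth.w_star[:, ti[1]] > truth.w_star[:, ti[0]]).reshape(grid.ny, grid.nx)
    lab_f = (w_fit[:, fi[1]] > w_fit[:, fi[0]]).reshape(grid.ny, grid.nx)
    disps = []
    for row_t, row_f in zip(lab_t, lab_f):
        bt = np.flatnonzero(np.diff(row_t.astype(int)))
        bf = np.flatnonzero(np.diff(row_f.astype(int)))
        if len(bt) == 1 and len(bf) >= 1:
            disps.append(np.min(np.abs(bf - bt[0])))
    return float(np.mean(disps)) if disps else np.nan


def benchmark_recovery(
    truth: SyntheticTruth,
    fitted,
    imputed_vaf: pd.DataFrame | None = None,
    raw_vaf: pd.DataFrame | None = None,
    truth_vaf: pd.DataFrame | None = None,
) -> dict:
    """Recovery metrics of a fitted map against the simulation truth.

    Reports the per-tile fraction RMSE over the truth components (restricted
    to tiles containing cells), mean per-locus Pearson correlations of the raw
    and model-imputed regional VAF matrices against truth, and — for two-clone
    layouts — the boundary displacement in tiles.
    """
    if fitted.grid != truth.grid:
        raise ValidationError("fitted map and truth use different grids")
    shared = [fitted.components.index(c) for c in truth.components]
    occupied = truth.density().n > 0
    diff = fitted.w_mean[np.ix_(occupied, shared)] - truth.w_star[occupied]
    out = {"fraction_rmse": float(np.sqrt(np.mean(diff**2)))}
    if truth_vaf is not None and imputed_vaf is not None:
        out["imputed_vaf_r"] = _mean_per_locus_r(imputed_vaf, truth_vaf)
    if truth_vaf is not None and raw_vaf is not None:
        out["raw_vaf_r"] = _mean_per_locus_r(raw_vaf, truth_vaf)
    n_tumour = len([c for c in truth.components if c != NORMAL_CLONE])
    if n_tumour == 2:
        out["boundary_displacement_tiles"] = _boundary_displacement(
            truth, fitted.w_mean, fitted.components
        )
    return out
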