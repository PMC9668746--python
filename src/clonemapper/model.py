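"""Variational clone-field model.

Per-tile clone fractions are the softmax of latent 2-D Gaussian-process fields
(one per component, the normal component pinned at zero as softmax reference).
Signal counts per (tile, probe) arise from the clone mixture through the
genotype matrix, a per-probe detection efficiency (geometric mean constrained
to 1), a per-locus expression scale shared by the mutant/wildtype pair, an
optional barcode-confusion (misdecoding) matrix, and a per-probe unspecific
background rate, all multiplied by the local nucleus count as exposure.
Inference is stochastic variational (reparameterized one-sample ELBO, Adam),
optionally augmented by a binomial pseudo-likelihood on bulk-WGS variant
allele fractions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import shapely

from . import _svi
from .genotype import GenotypeMatrix
from .gridding import CountTensor, DensityField, Grid
from .io import COPY_NUMBER, ProbePanel, RegionSet, BulkVAFTable, ValidationError

logger = logging.getLogger(__name__)

ARTEFACT_COMPONENT = "artefact"


@dataclass
class ModelConfig:
    """Tunable knobs of the clone-field model; defaults follow the package docs."""

    kernel: str = "matern32"
    lengthscale: float = 300.0          # µm
    variance: float = 1.0
    inducing_spacing_tiles: float = 2.0
    likelihood: str = "negbin"          # or "poisson"
    overdispersion_prior_median: float = 10.0
    overdispersion_prior_sd: float = 1.0
    efficiency_prior_sd: float = 0.5
    expression_prior_sd: float = 0.5
    unspecific_prior_median: float = 0.002  # signals per cell per probe
    unspecific_prior_sd: float = 1.0
    artefact_component: bool = True
    artefact_genotype_value: float = 0.1
    kappa: float = 1.0                  # bulk-augmentation weight
    steps: int = 3000
    learning_rate: float = 0.05
    seed: int = 0
    posterior_samples: int = 64

    def __post_init__(self) -> None:
        if self.lengthscale <= 0 or self.variance <= 0:
            raise ValidationError("lengthscale and variance must be positive")
        if self.steps < 1:
            raise ValidationError("steps must be >= 1")
        if self.kappa < 0:
            raise ValidationError("kappa must be non-negative")
        if self.likelihood not in ("poisson", "negbin"):
            raise ValidationError(f"unknown likelihood '{self.likelihood}'")

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class LatentState:
    """Point summary of the variational posterior (plus the raw parameters)."""

    weights: np.ndarray          # (T, K) component fractions at posterior mean
    efficiency: np.ndarray       # (J,) per-probe efficiency, geometric mean 1
    expression: np.ndarray       # (L,) per-locus expression scale
    unspecific: np.ndarray       # (J,) background rate per cell per probe
    scale: float = 1.0           # global signal scale
    overdispersion: float | None = None
    artefact_value: float = 0.0
    params: dict | None = None   # raw variational parameters (internal layout)

    def __post_init__(self) -> None:
        if (self.efficiency <= 0).any() or (self.expression <= 0).any():
            raise ValidationError("efficiency and expression scales must be positive")
        if (self.unspecific < 0).any():
            raise ValidationError("unspecific rates must be non-negative")


@dataclass
class CloneMap:
    """Posterior per-tile clone-fraction field with uncertainty and provenance."""

    grid: Grid
    components: list[str]
    w_mean: np.ndarray           # (T, K)
    w_lo: np.ndarray             # 5% credible bound
    w_hi: np.ndarray             # 95% credible bound
    density: DensityField
    Gx: np.ndarray               # (J, K) genotype incl. any artefact column
    probe_ids: list[str]
    normal_component: str
    provenance: dict = field(default_factory=dict)
    elbo_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.w_mean < -1e-9).any():
            raise ValidationError("negative clone fraction")
        rows = self.w_mean.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValidationError("clone fractions do not sum to 1 per tile")

    @property
    def tumour_components(self) -> list[str]:
        return [
            c for c in self.components
            if c not in (self.normal_component, ARTEFACT_COMPONENT)
        ]


# ---------------------------------------------------------------------------
# Misdecoding matrix
# ---------------------------------------------------------------------------


def hamming_misdecode_matrix(panel: ProbePanel, error_rate: float) -> np.ndarray:
    """Confusion matrix M[observed, true] from per-cycle base-call errors.

    Each barcode position is misread independently with probability
    ``error_rate``, uniformly over the 3 alternative symbols. Column mass not
    landing on a panel barcode (infeasible codes) is dropped, so columns sum
    to <= 1.
    """
    codes = [str(b) for b in panel.data["barcode"]]
    J = len(codes)
    M = np.zeros((J, J))
    for jt, true in enumerate(codes):
        for jo, obs in enumerate(codes):
            if len(obs) != len(true):
                continue
            d = sum(a != b for a, b in zip(obs, true))
            M[jo, jt] = (1 - error_rate) ** (len(true) - d) * (error_rate / 3) ** d
    return M


# ---------------------------------------------------------------------------
# Expected counts (generative mean)
# ---------------------------------------------------------------------------


def _extended_G(G: GenotypeMatrix, state_K: int, artefact_value: float) -> np.ndarray:
    if state_K == G.n_clones:
        return G.G
    if state_K == G.n_clones + 1:
        return np.hstack([G.G, np.full((G.n_probes, 1), artefact_value)])
    raise ValidationError("weight matrix width matches neither K nor K+1 components")


def expected_counts(
    state: LatentState,
    G: GenotypeMatrix,
    density: DensityField,
    misdecode: np.ndarray | None = None,
) -> np.ndarray:
    """Mean count rate λ[tile, probe] of the generative model.

    λ_ij = n_i · [ Σ_j' M_jj' · e_j' · s_l(j') · Σ_k w_ik G_j'k + b_j ].
    """
    n = np.asarray(density.n, dtype=float)
    if (n < 0).any():
        raise ValidationError("negative density")
    Gx = _extended_G(G, state.weights.shape[1], state.artefact_value)
    loci = G.locus_of_probe()
    locus_list = list(dict.fromkeys(loci))
    locus_idx = np.array([locus_list.index(l) for l in loci])
    sp = state.expression[locus_idx]
    M = np.eye(G.n_probes) if misdecode is None else np.asarray(misdecode, float)
    U = state.weights @ Gx.T
    R = U * (state.scale * state.efficiency * sp)[None, :]
    return n[:, None] * (R @ M.T + state.unspecific[None, :])


# ---------------------------------------------------------------------------
# Assembling the data bundle
# ---------------------------------------------------------------------------


def _locus_index(G: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    loci = G.locus_of_probe()
    locus_list = list(dict.fromkeys(loci))
    return np.array([locus_list.index(l) for l in loci]), locus_list


def _bulk_arrays(
    bulk: BulkVAFTable,
    bulk_tiles: dict[str, np.ndarray] | None,
    G: GenotypeMatrix,
    Gx: np.ndarray,
    density: DensityField,
):
    pairs = G.snv_pairs()
    pair_loci = [p[0] for p in pairs]
    mut = np.array([Gx[mi] for _, mi, _ in pairs])
    tot = np.array([Gx[mi] + Gx[wi] for _, mi, wi in pairs])
    samples = sorted(set(bulk.data["sample_id"]))
    n = np.asarray(density.n, float)
    weights, m_rows, d_rows = [], [], []
    for sid in samples:
        if bulk_tiles is not None and sid in bulk_tiles:
            idx = np.asarray(bulk_tiles[sid], int)
        else:
            idx = np.arange(len(n))
        omega = np.zeros(len(n))
        mass = n[idx].sum()
        if mass <= 0:
            continue
        omega[idx] = n[idx] / mass
        sub = bulk.data[bulk.data["sample_id"] == sid].set_index("locus_id")
        m = np.zeros(len(pairs))
        d = np.zeros(len(pairs))
        for li, locus in enumerate(pair_loci):
            if locus in sub.index:
                row = sub.loc[locus]
                d[li] = float(row["depth"])
                m[li] = float(row["vaf"]) * d[li]
        weights.append(omega)
        m_rows.append(m)
        d_rows.append(d)
    if not weights:
        return [], None, None, None, None
    return weights, mut, tot, np.array(m_rows), np.array(d_rows)


def build_model_data(
    counts: CountTensor,
    density: DensityField,
    G: GenotypeMatrix,
    config: ModelConfig,
    bulk: BulkVAFTable | None = None,
    bulk_tiles: dict[str, np.ndarray] | None = None,
    misdecode: np.ndarray | None = None,
) -> _svi.ModelData:
    grid = counts.grid
    K = G.n_clones + (1 if config.artefact_component else 0)
    Gx = _extended_G(G, K, config.artefact_genotype_value)
    locus_idx, locus_list = _locus_index(G)
    X = grid.tile_centres()
    spacing = config.inducing_spacing_tiles * grid.tile_size
    X_ind = _svi.inducing_grid(
        grid.origin, (grid.nx * grid.tile_size, grid.ny * grid.tile_size), spacing
    )
    B = _svi.predictive_projector(
        X, X_ind, config.kernel, config.lengthscale, config.variance
    )
    if bulk is not None and config.kappa > 0:
        bw, bmut, btot, bm, bd = _bulk_arrays(bulk, bulk_tiles, G, Gx, density)
    else:
        bw, bmut, btot, bm, bd = [], None, None, None, None
    return _svi.ModelData(
        N=np.asarray(counts.N, float),
        n=np.asarray(density.n, float),
        B=B,
        G=Gx,
        M=np.eye(G.n_probes) if misdecode is None else np.asarray(misdecode, float),
        locus_idx=locus_idx,
        n_loci=len(locus_list),
        normal_idx=G.clone_index(G.normal_clone),
        likelihood=config.likelihood,
        efficiency_prior_sd=config.efficiency_prior_sd,
        expression_prior_sd=config.expression_prior_sd,
        unspecific_prior_logmean=float(np.log(config.unspecific_prior_median)),
        unspecific_prior_sd=config.unspecific_prior_sd,
        overdispersion_prior_logmean=float(np.log(config.overdispersion_prior_median)),
        overdispersion_prior_sd=config.overdispersion_prior_sd,
        kappa=config.kappa,
        bulk_weights=bw,
        bulk_mut=bmut,
        bulk_tot=btot,
        bulk_m=bm,
        bulk_d=bd,
    )


def elbo(
    state: LatentState,
    counts: CountTensor,
    density: DensityField,
    G: GenotypeMatrix,
    config: ModelConfig,
    bulk: BulkVAFTable | None = None,
    bulk_tiles: dict[str, np.ndarray] | None = None,
    eps: dict | None = None,
) -> float:
    """One-sample ELBO estimate at the state's variational parameters.

    With ``eps=None`` the noise is zeroed, giving the estimate at the
    variational means (useful for deterministic checks).
    """
    if state.params is None:
        raise ValidationError("state carries no variational parameters")
    data = build_model_data(counts, density, G, config, bulk, bulk_tiles)
    e = eps if eps is not None else _svi.zero_noise(data)
    value, _, parts = _svi.elbo_and_grad(state.params, data, e)
    for name, v in parts.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite ELBO term '{name}'")
    return value


def _state_from_params(
    params: dict, data: _svi.ModelData, config: ModelConfig
) -> LatentState:
    em = params["em"]
    e = np.exp(em - em.mean())
    return LatentState(
        weights=_svi.sample_weights(params, data, _svi.zero_noise(data)),
        efficiency=e,
        expression=np.exp(params["sm"]),
        unspecific=np.exp(params["bm"]),
        scale=float(np.exp(params["log_scale"])),
        overdispersion=(
            float(np.exp(params["phim"])) if data.likelihood == "negbin" else None
        ),
        artefact_value=(
            config.artefact_genotype_value if config.artefact_component else 0.0
        ),
        params=params,
    )


def fit_clone_fields(
    counts: CountTensor,
    density: DensityField,
    G: GenotypeMatrix,
    bulk: BulkVAFTable | None = None,
    config: ModelConfig | None = None,
    bulk_tiles: dict[str, np.ndarray] | None = None,
    misdecode: np.ndarray | None = None,
) -> tuple[LatentState, CloneMap]:
    """Fit the clone-field model by stochastic variational inference.

    Deterministic given ``config.seed``. Returns the fitted latent state and a
    :class:`CloneMap` with the posterior mean and 5–95% credible band of the
    per-tile component fractions, evaluated through the inducing-point
    predictive at tile centres.
    """
    config = config or ModelConfig()
    if not (np.asarray(density.n) > 0).any():
        raise ValidationError("need at least one tile with nonzero density")
    components = list(G.clones) + (
        [ARTEFACT_COMPONENT] if config.artefact_component else []
    )
    data = build_model_data(counts, density, G, config, bulk, bulk_tiles, misdecode)
    # warn when a non-normal clone is not identifiable from the panel: its
    # genotype column is identical to another component's column
    for k, comp in enumerate(components):
        if comp == G.normal_clone:
            continue
        for k2 in range(k):
            if np.array_equal(data.G[:, k], data.G[:, k2]):
                warnings.warn(
                    f"component {comp!r} has no probe distinguishing it from "
                    f"{components[k2]!r}"
                )
                break

    rng = np.random.default_rng(config.seed)
    params = _svi.init_params(data, rng)

    if counts.N.sum() == 0:
        warnings.warn("all-zero counts: returning a normal-dominated map")
        T, K = data.N.shape[0], data.G.shape[1]
        W = np.zeros((T, K))
        W[:, data.normal_idx] = 1.0
        state = _state_from_params(params, data, config)
        state.weights = W
        cmap = CloneMap(
            grid=counts.grid, components=components, w_mean=W, w_lo=W, w_hi=W,
            density=density, Gx=data.G, probe_ids=counts.probe_ids,
            normal_component=G.normal_clone,
            provenance={"config_hash": config.hash(), "seed": config.seed},
            elbo_trace=np.array([]),
        )
        return state, cmap

    opt = _svi.Adam(params, lr=config.learning_rate)
    trace = np.empty(config.steps)
    for step in range(config.steps):
        eps = _svi.draw_noise(data, rng)
        value, grads, _ = _svi.elbo_and_grad(params, data, eps)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"ELBO diverged at step {step}; trace head: {trace[:step][:5]}"
            )
        opt.step(params, grads)
        trace[step] = value

    state = _state_from_params(params, data, config)
    # posterior summaries of the fraction field from GP-noise samples
    S = config.posterior_samples
    W_samp = np.empty((S, *state.weights.shape))
    for s in range(S):
        eps = _svi.zero_noise(data)
        eps["z"] = rng.standard_normal(eps["z"].shape)
        W_samp[s] = _svi.sample_weights(params, data, eps)
    w_mean = W_samp.mean(axis=0)
    w_lo = np.quantile(W_samp, 0.05, axis=0)
    w_hi = np.quantile(W_samp, 0.95, axis=0)
    cmap = CloneMap(
        grid=counts.grid,
        components=components,
        w_mean=w_mean,
        w_lo=w_lo,
        w_hi=w_hi,
        density=density,
        Gx=data.G,
        probe_ids=counts.probe_ids,
        normal_component=G.normal_clone,
        provenance={"config_hash": config.hash(), "seed": config.seed},
        elbo_trace=trace,
    )
    return state, cmap


# ---------------------------------------------------------------------------
# Regional VAF matrices
# ---------------------------------------------------------------------------


def tiles_in_regions(grid: Grid, regions: RegionSet) -> dict[str, np.ndarray]:
    """Tile indices whose centre falls inside each region polygon."""
    centres = grid.tile_centres()
    out = {}
    for r in regions:
        inside = shapely.contains_xy(r.polygon, centres[:, 0], centres[:, 1])
        out[r.region_id] = np.flatnonzero(inside)
    return out


def impute_vaf(
    cmap: CloneMap,
    G: GenotypeMatrix,
    density: DensityField,
    regions: RegionSet,
) -> pd.DataFrame:
    """Model-imputed VAF per (region, paired SNV locus).

    Density-weighted average of the posterior fraction field over each
    region's tiles, pushed through the genotype mixture. Empty regions yield a
    row of NaN.
    """
    pairs = G.snv_pairs()
    tiles = tiles_in_regions(cmap.grid, regions)
    n = np.asarray(density.n, float)
    rows = {}
    for rid, idx in tiles.items():
        mass = n[idx].sum() if len(idx) else 0.0
        if mass <= 0:
            rows[rid] = np.full(len(pairs), np.nan)
            continue
        wbar = (n[idx, None] * cmap.w_mean[idx]).sum(axis=0) / mass
        vals = np.empty(len(pairs))
        for li, (_, mi, wi) in enumerate(pairs):
            num = float(wbar @ cmap.Gx[mi])
            den = float(wbar @ (cmap.Gx[mi] + cmap.Gx[wi]))
            vals[li] = num / den if den > 0 else np.nan
        rows[rid] = vals
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[p[0] for p in pairs]
    )


def raw_vaf(
    counts: CountTensor, panel: ProbePanel, regions: RegionSet
) -> pd.DataFrame:
    """Raw regional VAF: mutant signals / (mutant + wildtype signals) per locus.

    Copy-number-class probes are excluded (they have no allelic counterpart);
    regions with no signals at a locus yield NaN.
    """
    n_cn = int((panel.data["allele_class"] == COPY_NUMBER).sum())
    if n_cn:
        logger.info("raw_vaf: excluding %d copy-number probes", n_cn)
    pidx = {p: i for i, p in enumerate(counts.probe_ids)}
    pairs = [
        (locus, pidx[m], pidx[w])
        for locus, m, w in panel.pairs()
        if m in pidx and w in pidx
    ]
    tiles = tiles_in_regions(counts.grid, regions)
    rows = {}
    for rid, idx in tiles.items():
        vals = np.empty(len(pairs))
        for li, (_, mi, wi) in enumerate(pairs):
            m = counts.N[idx, mi].sum() if len(idx) else 0
            w = counts.N[idx, wi].sum() if len(idx) else 0
            vals[li] = m / (m + w) if (m + w) > 0 else np.nan
        rows[rid] = vals
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[p[0] for p in pairs]
    )


def save_clone_map(cmap: CloneMap, path: str) -> None:
    """Serialize a CloneMap as NPZ with a JSON metadata sidecar."""
    np.savez_compressed(
        path,
        w_mean=cmap.w_mean,
        w_lo=cmap.w_lo,
        w_hi=cmap.w_hi,
        density_n=cmap.density.n,
        Gx=cmap.Gx,
        elbo_trace=cmap.elbo_trace if cmap.elbo_trace is not None else np.empty(0),
    )
    grid = cmap.grid
    meta = {
        "origin": list(grid.origin),
        "tile_size": grid.tile_size,
        "nx": grid.nx,
        "ny": grid.ny,
        "components": cmap.components,
        "probe_ids": cmap.probe_ids,
        "normal_component": cmap.normal_component,
        "provenance": cmap.provenance,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_clone_map(path: str) -> CloneMap:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    arrs = np.load(path)
    grid = Grid(tuple(meta["origin"]), meta["tile_size"], meta["nx"], meta["ny"])
    return CloneMap(
        grid=grid,
        components=list(meta["components"]),
        w_mean=arrs["w_mean"],
        w_lo=arrs["w_lo"],
        w_hi=arrs["w_hi"],
        density=DensityField(arrs["density_n"], grid),
        Gx=arrs["Gx"],
        probe_ids=list(meta["probe_ids"]),
        normal_component=meta["normal_component"],
        provenance=dict(meta["provenance"]),
        elbo_trace=arrs["elbo_trace"],
    )
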