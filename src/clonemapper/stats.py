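"""Clone-territory phenotype statistics.

Cells are assigned to clone territories through the dominant-clone field;
differential expression between territories uses per-cell panel-normalized
counts with a two-sided rank-sum test, Benjamini–Hochberg FDR control and a
symmetric fold-change rule (default FDR < 0.1, fold change > 1.5 both ways).
Cell-type enrichment is a Bayesian Poisson generalized linear mixed model with
a region-specific random effect; clone–histology association uses Fisher's
exact test with Bonferroni correction across features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import CellTable, ValidationError
from .postprocess import DominantCloneField

MASKED = "masked"


# ---------------------------------------------------------------------------
# Territory assignment
# ---------------------------------------------------------------------------


@dataclass
class TerritoryAssignment:
    """Per-cell clone-territory label (or 'masked') and the source tile index."""

    labels: np.ndarray
    tile_idx: np.ndarray

    def cells_in(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def assign_cells(cells: CellTable, fieldmap: DominantCloneField) -> TerritoryAssignment:
    """Label each cell by the dominant clone of its tile (masked tiles -> 'masked')."""
    grid = fieldmap.grid
    tiles = grid.tile_indices(cells.data["x"].to_numpy(), cells.data["y"].to_numpy())
    labels = np.full(len(cells), MASKED, dtype=object)
    inb = tiles >= 0
    lab = fieldmap.labels[tiles[inb]]
    lab = np.where(lab == "", MASKED, lab)
    labels[inb] = lab
    return TerritoryAssignment(labels, tiles)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    cells: CellTable,
    assignment: TerritoryAssignment,
    group_a: str,
    group_b: str,
    fdr: float = 0.1,
    fc: float = 1.5,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two clone territories.

    Counts are normalized per cell by the total over panel genes (targeted
    panels lack a global depth), tested with a two-sided Mann–Whitney U test,
    BH-corrected, and flagged significant iff q < ``fdr`` and the group-mean
    fold change exceeds ``fc`` in either direction.
    """
    if cells.gene_counts is None:
        raise ValidationError("cells carry no gene counts")
    ia = assignment.cells_in(group_a)
    ib = assignment.cells_in(group_b)
    if len(ia) < min_cells or len(ib) < min_cells:
        raise ValidationError(
            f"group sizes {group_a}: {len(ia)}, {group_b}: {len(ib)} "
            f"below min_cells={min_cells}"
        )
    counts = cells.gene_counts.to_numpy(float)
    totals = counts.sum(axis=1, keepdims=True)
    ok = totals[:, 0] > 0
    norm = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    ia = ia[ok[ia]]
    ib = ib[ok[ib]]
    genes = list(cells.gene_counts.columns)
    pvals = np.empty(len(genes))
    fcs = np.empty(len(genes))
    for g in range(len(genes)):
        a, b = norm[ia, g], norm[ib, g]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[g] = 1.0
        else:
            pvals[g] = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        ma, mb = a.mean(), b.mean()
        eps = 1e-12
        fcs[g] = (ma + eps) / (mb + eps)
    qvals = benjamini_hochberg(pvals)
    flag = (qvals < fdr) & ((fcs > fc) | (fcs < 1 / fc))
    return pd.DataFrame(
        {
            "gene": genes,
            "log2_fc": np.log2(fcs),
            "fold_change": fcs,
            "p": pvals,
            "q": qvals,
            "significant": flag,
            "n_a": len(ia),
            "n_b": len(ib),
        }
    ).set_index("gene")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone in p-rank, q >= p)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Cell-type enrichment GLMM
# ---------------------------------------------------------------------------


@dataclass
class GLMMResult:
    summary: pd.DataFrame                 # per (cell_type, clone) posterior summary
    samples: dict = field(default_factory=dict)


def _glmm_log_posterior(theta, y, x, log_offset, beta_sd=5.0, tau_scale=1.0):
    b0, b1 = theta[0], theta[1]
    u = theta[2:-1]
    log_tau = theta[-1]
    tau = np.exp(log_tau)
    eta = log_offset + b0 + b1 * x + u
    if np.any(eta > 50):
        return -np.inf
    ll = np.sum(y * eta - np.exp(eta))
    lp = -(b0**2 + b1**2) / (2 * beta_sd**2)
    lp += -np.sum(u**2) / (2 * tau**2) - len(u) * log_tau
    lp += -(tau**2) / (2 * tau_scale**2) + log_tau  # half-normal + jacobian
    return ll + lp


def celltype_glmm(
    celltype_counts: pd.DataFrame,
    clone_fraction: pd.DataFrame,
    total_cells: pd.Series,
    seed: int = 0,
    n_steps: int = 4000,
    burn: int = 1500,
    fdr: float = 0.1,
    keep_samples: bool = False,
) -> GLMMResult:
    """Clone-specific cell-type enrichment via a Bayesian Poisson GLMM.

    For each (cell type, clone): log E[count_r] = log(total_r) + β0 +
    β_clone·fraction_r + u_r with u_r ~ N(0, τ²), weakly-informative N(0, 2²)
    priors on β and half-Normal(1) on τ, sampled with an ensemble MCMC
    (differential-evolution moves) at a fixed seed. Two-sided posterior tail probabilities are
    BH-corrected across all (type, clone) comparisons; fits with split-R̂ of
    β_clone above 1.05 are flagged unconverged.

    ``celltype_counts``: regions × cell types; ``clone_fraction``: regions ×
    clones in [0, 1]; ``total_cells``: per-region totals (the offset).
    """
    import emcee

    regions = celltype_counts.index
    if len(regions) < 5:
        raise ValidationError(f"need >= 5 regions, got {len(regions)}")
    frac = clone_fraction.loc[regions]
    if ((frac.to_numpy() < 0) | (frac.to_numpy() > 1)).any():
        raise ValidationError("clone fractions must lie in [0, 1]")
    log_off = np.log(total_cells.loc[regions].to_numpy(float))
    rng = np.random.default_rng(seed)
    rows = []
    samples = {}
    for ct in celltype_counts.columns:
        y = celltype_counts[ct].to_numpy(float)
        for clone in frac.columns:
            # centre the covariate: decorrelates slope and intercept, which
            # otherwise trade off through the intercept prior
            x = frac[clone].to_numpy(float)
            x = x - x.mean()
            ndim = 2 + len(regions) + 1
            nwalkers = max(2 * ndim + 2, 16)
            b0_hat = float(np.log((y.sum() + 0.5) / np.exp(log_off).sum()))
            p0 = 0.05 * rng.standard_normal((nwalkers, ndim))
            p0[:, 0] += b0_hat
            p0[:, -1] = np.log(0.5) + 0.1 * rng.standard_normal(nwalkers)
            sampler = emcee.EnsembleSampler(
                nwalkers,
                ndim,
                _glmm_log_posterior,
                args=(y, x, log_off),
                # differential-evolution moves mix far better than the default
                # stretch move on this correlated, high-dimensional posterior
                moves=[
                    (emcee.moves.DEMove(), 0.8),
                    (emcee.moves.DESnookerMove(), 0.2),
                ],
            )
            sampler.random_state = np.random.RandomState(
                rng.integers(2**31)
            ).get_state()
            sampler.run_mcmc(p0, n_steps, progress=False)
            chain = sampler.get_chain(discard=burn)  # (steps, walkers, ndim)
            beta = chain[:, :, 1]
            rhat = _split_rhat(beta)
            flat = beta.ravel()
            p_pos = float(np.mean(flat > 0))
            tail = 2 * min(p_pos, 1 - p_pos)
            rows.append(
                {
                    "cell_type": ct,
                    "clone": clone,
                    "beta_mean": float(flat.mean()),
                    "beta_sd": float(flat.std()),
                    "ci_lo": float(np.quantile(flat, 0.025)),
                    "ci_hi": float(np.quantile(flat, 0.975)),
                    "p_tail": max(tail, 1.0 / flat.size),
                    "rhat": rhat,
                    "converged": rhat < 1.05,
                }
            )
            if keep_samples:
                samples[(ct, clone)] = flat
    summary = pd.DataFrame(rows)
    summary["q"] = benjamini_hochberg(summary["p_tail"].to_numpy())
    summary["significant"] = summary["q"] < fdr
    return GLMMResult(summary.set_index(["cell_type", "clone"]), samples)


def _split_rhat(chain: np.ndarray) -> float:
    """Split-R̂ over an ensemble chain of shape (steps, walkers)."""
    s, w = chain.shape
    half = s // 2
    parts = np.concatenate([chain[:half], chain[half: 2 * half]], axis=1)  # (half, 2w)
    means = parts.mean(axis=0)
    varw = parts.var(axis=0, ddof=1)
    W = varw.mean()
    B = half * means.var(ddof=1)
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W)) if W > 0 else np.inf


# ---------------------------------------------------------------------------
# Clone-histology association
# ---------------------------------------------------------------------------


def _table_log_prob(table: np.ndarray) -> float:
    """log P(table | fixed margins) under the multivariate hypergeometric null."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray):
    """All non-negative integer tables with the given margins (small tables only)."""
    n_r, n_c = len(rows), len(cols)

    def rec(i, remaining_cols, current):
        if i == n_r - 1:
            last = remaining_cols
            if (last >= 0).all():
                yield current + [list(last)]
            return
        target = rows[i]
        ranges = [range(min(target, remaining_cols[j]) + 1) for j in range(n_c - 1)]
        for combo in itertools.product(*ranges):
            lastcell = target - sum(combo)
            if lastcell < 0 or lastcell > remaining_cols[-1]:
                continue
            row = list(combo) + [lastcell]
            yield from rec(i + 1, remaining_cols - np.array(row), current + [row])

    yield from rec(0, cols.copy(), [])


def fisher_exact_rxc(
    table: np.ndarray,
    max_enumeration: int = 200_000,
    n_mc: int = 20_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher exact p for an r×c contingency table.

    2×2 tables defer to the standard routine; small tables sum the fixed-margin
    probabilities of all tables at most as probable as the observed one; large
    tables fall back to a Monte-Carlo estimate over random fixed-margin tables.
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    lp_obs = _table_log_prob(table)
    n_cand = np.prod([min(r, cols.sum()) + 1 for r in rows[:-1] for _ in cols[:-1]])
    if n_cand <= max_enumeration:
        p = 0.0
        for t in _enumerate_tables(rows, cols):
            lp = _table_log_prob(np.array(t))
            if lp <= lp_obs + 1e-9:
                p += np.exp(lp)
        return float(min(p, 1.0))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        t = sps.random_table(rows, cols).rvs(random_state=rng)
        if _table_log_prob(np.asarray(t, int)) <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def histology_association(
    region_table: pd.DataFrame,
    clone_column: str = "dominant_clone",
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Clone × histology-category association per feature, Bonferroni-corrected.

    ``region_table`` has one row per region with the dominant clone and one
    categorical column per histology feature; features with a single observed
    category are skipped with a notice in the output.
    """
    clones = region_table[clone_column]
    if clones.nunique() < 2:
        raise ValidationError("need >= 2 clones represented")
    features = features or [c for c in region_table.columns if c != clone_column]
    rows = []
    tested = []
    for feat in features:
        cats = region_table[feat].dropna()
        if cats.nunique() < 2:
            rows.append(
                {"feature": feat, "p": np.nan, "p_bonferroni": np.nan,
                 "note": "single category: skipped"}
            )
            continue
        ct = pd.crosstab(clones[cats.index], cats)
        p = fisher_exact_rxc(ct.to_numpy())
        rows.append({"feature": feat, "p": p, "p_bonferroni": np.nan, "note": ""})
        tested.append(len(rows) - 1)
    out = pd.DataFrame(rows).set_index("feature")
    m = len(tested)
    if m:
        idx = out.index[tested]
        out.loc[idx, "p_bonferroni"] = np.minimum(out.loc[idx, "p"] * m, 1.0)
    return out
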