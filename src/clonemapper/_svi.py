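"""Stochastic variational inference internals for the clone-field model.

The ELBO estimator uses a single reparameterized Monte-Carlo sample per step.
Gradients are analytic (hand-derived backward pass through the generative
chain: whitened inducing values -> GP field -> softmax weights -> count rates
-> Poisson / negative-binomial likelihood, plus the bulk binomial term and
closed-form Gaussian KLs). Everything is float64 numpy; the backward pass is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import digamma, gammaln

Params = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# GP kernels and inducing-point geometry
# ---------------------------------------------------------------------------


def kernel_matrix(
    X1: np.ndarray, X2: np.ndarray, kind: str, lengthscale: float, variance: float
) -> np.ndarray:
    r = cdist(X1, X2)
    if kind == "matern32":
        a = np.sqrt(3.0) * r / lengthscale
        return variance * (1.0 + a) * np.exp(-a)
    if kind == "rbf":
        return variance * np.exp(-0.5 * (r / lengthscale) ** 2)
    raise ValueError(f"unknown kernel '{kind}'")


def inducing_grid(
    origin: tuple[float, float],
    extent: tuple[float, float],
    spacing: float,
) -> np.ndarray:
    """Regular inducing-point lattice covering the tile grid with a half-spacing margin."""
    xs = np.arange(origin[0] - spacing / 2, origin[0] + extent[0] + spacing, spacing)
    ys = np.arange(origin[1] - spacing / 2, origin[1] + extent[1] + spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def predictive_projector(
    X_tiles: np.ndarray,
    X_ind: np.ndarray,
    kind: str,
    lengthscale: float,
    variance: float,
    jitter: float = 1e-6,
) -> np.ndarray:
    """B such that the latent field at tiles is f = B z for whitened inducing z.

    With K_uu = L Lᵀ and u = L z (z ~ N(0, I) a priori), the predictive mean is
    K_xu K_uu⁻¹ u = K_xu L⁻ᵀ z, so B = K_xu L⁻ᵀ.
    """
    K_uu = kernel_matrix(X_ind, X_ind, kind, lengthscale, variance)
    K_uu[np.diag_indices_from(K_uu)] += jitter * variance
    L = cholesky(K_uu, lower=True)
    K_xu = kernel_matrix(X_tiles, X_ind, kind, lengthscale, variance)
    # B = K_xu L^{-T}  <=>  B L^T = K_xu
    return solve_triangular(L, K_xu.T, lower=True).T


# ---------------------------------------------------------------------------
# Model constants bundle
# ---------------------------------------------------------------------------


@dataclass
class ModelData:
    """Fixed tensors the ELBO is evaluated against."""

    N: np.ndarray              # (T, J) counts
    n: np.ndarray              # (T,) cell exposure per tile
    B: np.ndarray              # (T, M) whitened GP projector
    G: np.ndarray              # (J, K) expected allele copies incl. artefact column
    M: np.ndarray              # (J, J) misdecoding matrix, M[obs, true]
    locus_idx: np.ndarray      # (J,) locus index per probe
    n_loci: int
    normal_idx: int            # softmax reference component (field fixed at 0)
    likelihood: str            # "poisson" | "negbin"
    efficiency_prior_sd: float
    expression_prior_sd: float
    unspecific_prior_logmean: float
    unspecific_prior_sd: float
    overdispersion_prior_logmean: float
    overdispersion_prior_sd: float
    kappa: float = 0.0
    # bulk augmentation: per sample, (tile-weight vector summing to 1, and per
    # paired locus the mutant/total genotype rows and observed mutant/depth)
    bulk_weights: list[np.ndarray] = field(default_factory=list)
    bulk_mut: np.ndarray | None = None     # (n_pairs, K) mutant allele copies
    bulk_tot: np.ndarray | None = None     # (n_pairs, K) mutant + wildtype copies
    bulk_m: np.ndarray | None = None       # (n_samples, n_pairs) mutant reads
    bulk_d: np.ndarray | None = None       # (n_samples, n_pairs) depths

    @property
    def shapes(self) -> tuple[int, int, int, int]:
        T, J = self.N.shape
        K = self.G.shape[1]
        M = self.B.shape[1]
        return T, J, K, M


def init_params(data: ModelData, rng: np.random.Generator) -> Params:
    T, J, K, M = data.shapes
    K_lat = K - 1
    p: Params = {
        "zm": 0.01 * rng.standard_normal((K_lat, M)),
        "zs_raw": np.full((K_lat, M), np.log(0.1)),
        "em": np.zeros(J),
        "es_raw": np.full(J, np.log(0.05)),
        "sm": np.zeros(data.n_loci),
        "ss_raw": np.full(data.n_loci, np.log(0.05)),
        "bm": np.full(J, data.unspecific_prior_logmean),
        "bs_raw": np.full(J, np.log(0.1)),
        "log_scale": np.array(0.0),
    }
    if data.likelihood == "negbin":
        p["phim"] = np.array(data.overdispersion_prior_logmean)
        p["phis_raw"] = np.array(np.log(0.05))
    return p


def draw_noise(data: ModelData, rng: np.random.Generator) -> Params:
    T, J, K, M = data.shapes
    eps = {
        "z": rng.standard_normal((K - 1, M)),
        "e": rng.standard_normal(J),
        "s": rng.standard_normal(data.n_loci),
        "b": rng.standard_normal(J),
    }
    if data.likelihood == "negbin":
        eps["phi"] = rng.standard_normal()
    return eps


def zero_noise(data: ModelData) -> Params:
    T, J, K, M = data.shapes
    eps = {
        "z": np.zeros((K - 1, M)),
        "e": np.zeros(J),
        "s": np.zeros(data.n_loci),
        "b": np.zeros(J),
    }
    if data.likelihood == "negbin":
        eps["phi"] = 0.0
    return eps


# ---------------------------------------------------------------------------
# Forward / backward ELBO
# ---------------------------------------------------------------------------

_VAF_EPS = 1e-7


def _softmax_full(F_lat: np.ndarray, normal_idx: int) -> np.ndarray:
    T, K_lat = F_lat.shape
    F = np.insert(F_lat, normal_idx, 0.0, axis=1)
    F = F - F.max(axis=1, keepdims=True)
    E = np.exp(F)
    return E / E.sum(axis=1, keepdims=True)


def sample_weights(params: Params, data: ModelData, eps: Params) -> np.ndarray:
    """Per-tile component fractions W (T, K) for one noise draw."""
    z = params["zm"] + np.exp(params["zs_raw"]) * eps["z"]
    F_lat = data.B @ z.T
    return _softmax_full(F_lat, data.normal_idx)


def elbo_and_grad(
    params: Params, data: ModelData, eps: Params
) -> tuple[float, Params, dict[str, float]]:
    """One-sample reparameterized ELBO estimate and its exact gradient.

    Deterministic given ``eps``; the parts dict reports the likelihood, bulk
    and KL contributions separately.
    """
    T, J, K, M = data.shapes
    grads: Params = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}

    # ---- forward -----------------------------------------------------------
    zs = np.exp(params["zs_raw"])
    z = params["zm"] + zs * eps["z"]                      # (K_lat, M)
    F_lat = data.B @ z.T                                  # (T, K_lat)
    W = _softmax_full(F_lat, data.normal_idx)             # (T, K)

    es = np.exp(params["es_raw"])
    le = params["em"] + es * eps["e"]
    le_c = le - le.mean()                                 # geometric-mean-1 constraint
    e = np.exp(le_c)

    ss = np.exp(params["ss_raw"])
    ls = params["sm"] + ss * eps["s"]
    s = np.exp(ls)
    sp = s[data.locus_idx]                                # (J,)

    bs = np.exp(params["bs_raw"])
    lb = params["bm"] + bs * eps["b"]
    b = np.exp(lb)

    scale = np.exp(float(params["log_scale"]))
    c = scale * e * sp                                    # (J,)

    U = W @ data.G.T                                      # (T, J)
    R = U * c[None, :]
    P = R @ data.M.T
    mask = data.n > 0
    lam = data.n[:, None] * (P + b[None, :])
    lam_m = np.clip(lam[mask], 1e-12, None)
    N_m = data.N[mask]

    if data.likelihood == "poisson":
        loglik = float(np.sum(N_m * np.log(lam_m) - lam_m - gammaln(N_m + 1.0)))
        dl_dlam = N_m / lam_m - 1.0
        phi = None
    else:
        phis = np.exp(params["phis_raw"])
        lphi = float(params["phim"]) + float(phis) * eps["phi"]
        phi = np.exp(lphi)
        loglik = float(
            np.sum(
                gammaln(N_m + phi) - gammaln(phi) - gammaln(N_m + 1.0)
                + phi * np.log(phi / (phi + lam_m))
                + N_m * np.log(lam_m / (phi + lam_m))
            )
        )
        dl_dlam = N_m / lam_m - (N_m + phi) / (phi + lam_m)
        dl_dphi = float(
            np.sum(
                digamma(N_m + phi) - digamma(phi)
                + np.log(phi / (phi + lam_m)) + 1.0
                - (N_m + phi) / (phi + lam_m)
            )
        )

    # ---- bulk binomial pseudo-likelihood -----------------------------------
    bulk_ll = 0.0
    gW_bulk = np.zeros_like(W)
    if data.kappa > 0 and data.bulk_weights:
        for si, omega in enumerate(data.bulk_weights):
            wbar = omega @ W                               # (K,)
            num = data.bulk_mut @ wbar                     # (n_pairs,)
            den = data.bulk_tot @ wbar
            ok = den > 1e-12
            v = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
            inner = (v > _VAF_EPS) & (v < 1 - _VAF_EPS) & ok
            vc = np.clip(v, _VAF_EPS, 1 - _VAF_EPS)
            m_obs = data.bulk_m[si]
            d_obs = data.bulk_d[si]
            bulk_ll += float(np.sum(m_obs * np.log(vc) + (d_obs - m_obs) * np.log1p(-vc)))
            dv = np.where(inner, m_obs / vc - (d_obs - m_obs) / (1 - vc), 0.0)
            gnum = dv / np.where(ok, den, 1.0)
            gden = -dv * num / np.where(ok, den**2, 1.0)
            gwbar = gnum @ data.bulk_mut + gden @ data.bulk_tot
            gW_bulk += np.outer(omega, gwbar)
        gW_bulk *= data.kappa

    # ---- KL terms (closed form) -------------------------------------------
    kl = 0.0
    # whitened inducing values vs N(0, I)
    kl_z = float(np.sum(0.5 * (zs**2 + params["zm"] ** 2 - 1.0) - params["zs_raw"]))
    kl += kl_z
    grads["zm"] -= params["zm"]
    grads["zs_raw"] -= zs**2 - 1.0

    def _kl_lognormal(mu, sr, prior_mu, prior_sd, gmu_key, gsr_key):
        nonlocal kl
        sig = np.exp(sr)
        kl += float(
            np.sum(
                np.log(prior_sd) - sr
                + (sig**2 + (mu - prior_mu) ** 2) / (2 * prior_sd**2)
                - 0.5
            )
        )
        grads[gmu_key] -= (mu - prior_mu) / prior_sd**2
        grads[gsr_key] -= sig**2 / prior_sd**2 - 1.0

    _kl_lognormal(params["em"], params["es_raw"], 0.0,
                  data.efficiency_prior_sd, "em", "es_raw")
    _kl_lognormal(params["sm"], params["ss_raw"], 0.0,
                  data.expression_prior_sd, "sm", "ss_raw")
    _kl_lognormal(params["bm"], params["bs_raw"], data.unspecific_prior_logmean,
                  data.unspecific_prior_sd, "bm", "bs_raw")
    if data.likelihood == "negbin":
        _kl_lognormal(params["phim"], params["phis_raw"],
                      data.overdispersion_prior_logmean,
                      data.overdispersion_prior_sd, "phim", "phis_raw")

    elbo = loglik + data.kappa * bulk_ll - kl

    # ---- backward ----------------------------------------------------------
    g_lam = np.zeros_like(lam)
    g_lam[mask] = dl_dlam
    g_Pb = g_lam * data.n[:, None]                        # grad wrt (P + b)
    g_b = g_Pb.sum(axis=0)
    g_lb = g_b * b
    grads["bm"] += g_lb
    grads["bs_raw"] += g_lb * bs * eps["b"]

    g_R = g_Pb @ data.M                                   # (T, J)
    g_U = g_R * c[None, :]
    g_c = np.einsum("tj,tj->j", g_R, U)

    grads["log_scale"] += float(np.sum(g_c * c))
    g_lec = g_c * c                                        # = g_e * e
    g_le = g_lec - g_lec.mean()
    grads["em"] += g_le
    grads["es_raw"] += g_le * es * eps["e"]

    g_ls = np.bincount(data.locus_idx, weights=g_c * c, minlength=data.n_loci)
    grads["sm"] += g_ls
    grads["ss_raw"] += g_ls * ss * eps["s"]

    g_W = g_U @ data.G + gW_bulk                          # (T, K)
    inner_w = np.einsum("tk,tk->t", g_W, W)
    g_F = W * (g_W - inner_w[:, None])
    g_F_lat = np.delete(g_F, data.normal_idx, axis=1)     # normal field fixed at 0
    g_z = (data.B.T @ g_F_lat).T                          # (K_lat, M)
    grads["zm"] += g_z
    grads["zs_raw"] += g_z * zs * eps["z"]

    if data.likelihood == "negbin":
        g_lphi = dl_dphi * phi
        grads["phim"] += g_lphi
        grads["phis_raw"] += g_lphi * float(phis) * eps["phi"]

    parts = {"loglik": loglik, "bulk": bulk_ll, "kl": kl}
    return float(elbo), grads, parts


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: Params, lr: float = 0.05,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(np.asarray(v, float)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, float)) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        """Ascent step in place (gradients are of the ELBO, to be maximized)."""
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] + self.lr * mhat / (np.sqrt(vhat) + self.eps)
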