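"""Clone-field model: generative mean, ELBO correctness, fitting properties."""

import warnings

import numpy as np
import pytest

import clonemapper as cm
from clonemapper import _svi
from clonemapper.gridding import cell_density, rasterize_spots
from clonemapper.io import ValidationError
from clonemapper.model import build_model_data, elbo, expected_counts


@pytest.fixture(scope="module")
def tiny_fit_data(request):
    """Small half-split tissue (0.8 x 0.8 mm) with counts, density and bulk."""
    tree = cm.CloneTree(parent={"a": None, "b": "a"})
    panel = cm.default_panel(n_loci=4, tree=tree)
    G = cm.build_genotype_matrix(tree, panel)
    sim = cm.SimConfig(
        extent_um=(800.0, 800.0), territory_mode="half_split",
        replicate_count=1, seed=3,
    )
    truth = cm.simulate_territories(sim, seed=3, tree=tree, panel=panel)
    cm.calibrate_signal_scale(sim, G, truth)
    exp = cm.simulate_experiment(truth, G, sim, seed=4)
    counts = rasterize_spots(exp["replicates"][0]["spots"], truth.grid, panel)
    density = cell_density(exp["replicates"][0]["cells"], truth.grid)
    from clonemapper.model import tiles_in_regions

    bulk_tiles = tiles_in_regions(truth.grid, exp["bulk_regions"])
    return {
        "G": G, "counts": counts, "density": density, "bulk": exp["bulk"],
        "bulk_tiles": bulk_tiles, "truth": truth, "panel": panel,
    }


class TestExpectedCounts:
    def _random_state(self, G, K, rng):
        T = 6
        w = rng.dirichlet(np.ones(K), size=T)
        L = len(set(G.locus_of_probe()))
        e = np.exp(rng.normal(0, 0.3, G.n_probes))
        e /= np.exp(np.mean(np.log(e)))
        return cm.LatentState(
            weights=w,
            efficiency=e,
            expression=np.exp(rng.normal(0, 0.3, L)),
            unspecific=rng.uniform(0, 0.01, G.n_probes),
            scale=0.7,
            artefact_value=0.1,
        )

    def test_matches_brute_force_loop(self, toy_tree, toy_panel):
        """λ from the vectorized generative mean equals an explicit loop over
        tiles, observed probes, true probes and clones."""
        G = cm.build_genotype_matrix(toy_tree, toy_panel)
        rng = np.random.default_rng(11)
        K = G.n_clones + 1  # with artefact component
        state = self._random_state(G, K, rng)
        T = state.weights.shape[0]
        n = rng.uniform(0, 30, T)
        density = cm.DensityField(n, cm.make_grid((0, 0, 100 * T, 100), tile_size=100))
        M = cm.hamming_misdecode_matrix(toy_panel, 0.01)

        lam = expected_counts(state, G, density, misdecode=M)

        Gx = np.hstack([G.G, np.full((G.n_probes, 1), state.artefact_value)])
        loci = G.locus_of_probe()
        locus_list = list(dict.fromkeys(loci))
        ref = np.zeros_like(lam)
        for i in range(T):
            for jo in range(G.n_probes):
                acc = 0.0
                for jt in range(G.n_probes):
                    mix = 0.0
                    for k in range(K):
                        mix += state.weights[i, k] * Gx[jt, k]
                    rate = (
                        state.scale
                        * state.efficiency[jt]
                        * state.expression[locus_list.index(loci[jt])]
                        * mix
                    )
                    acc += M[jo, jt] * rate
                ref[i, jo] = n[i] * (acc + state.unspecific[jo])
        np.testing.assert_allclose(lam, ref, rtol=0, atol=1e-12)

    def test_identity_misdecode_equals_none(self, toy_tree, toy_panel):
        G = cm.build_genotype_matrix(toy_tree, toy_panel)
        rng = np.random.default_rng(2)
        state = self._random_state(G, G.n_clones, rng)
        density = cm.DensityField(
            rng.uniform(0, 10, 6), cm.make_grid((0, 0, 600, 100), tile_size=100)
        )
        a = expected_counts(state, G, density)
        b = expected_counts(state, G, density, misdecode=np.eye(G.n_probes))
        np.testing.assert_allclose(a, b, rtol=1e-15)

    def test_scales_linearly_with_density(self, toy_tree, toy_panel):
        G = cm.build_genotype_matrix(toy_tree, toy_panel)
        rng = np.random.default_rng(4)
        state = self._random_state(G, G.n_clones, rng)
        grid = cm.make_grid((0, 0, 600, 100), tile_size=100)
        n = rng.uniform(1, 10, 6)
        a = expected_counts(state, G, cm.DensityField(n, grid))
        b = expected_counts(state, G, cm.DensityField(3 * n, grid))
        np.testing.assert_allclose(b, 3 * a, rtol=1e-12)


class TestMisdecodeMatrix:
    def test_diagonal_and_known_off_diagonal(self, toy_panel):
        f = 0.03
        M = cm.hamming_misdecode_matrix(toy_panel, f)
        np.testing.assert_allclose(np.diag(M), (1 - f) ** 5)
        # AAAAA -> CCCCC is Hamming distance 5
        assert M[1, 0] == pytest.approx((f / 3) ** 5)

    def test_columns_sum_below_one(self, panel):
        M = cm.hamming_misdecode_matrix(panel, 0.03)
        sums = M.sum(axis=0)
        assert (sums <= 1 + 1e-12).all()
        # mass is lost to codes outside the panel
        assert (sums < 1).all()

    def test_zero_error_is_identity(self, panel):
        M = cm.hamming_misdecode_matrix(panel, 0.0)
        np.testing.assert_allclose(M, np.eye(len(panel)))


class TestELBOCorrectness:
    def _data_and_params(self, tiny_fit_data, likelihood="negbin", kappa=1.0):
        cfg = cm.ModelConfig(likelihood=likelihood, kappa=kappa, seed=0)
        data = build_model_data(
            tiny_fit_data["counts"], tiny_fit_data["density"], tiny_fit_data["G"],
            cfg, bulk=tiny_fit_data["bulk"] if kappa > 0 else None,
            bulk_tiles=tiny_fit_data["bulk_tiles"] if kappa > 0 else None,
        )
        rng = np.random.default_rng(0)
        params = _svi.init_params(data, rng)
        # move off the symmetric init so gradients are generic
        opt = _svi.Adam(params, lr=0.05)
        for _ in range(30):
            eps = _svi.draw_noise(data, rng)
            _, grads, _ = _svi.elbo_and_grad(params, data, eps)
            opt.step(params, grads)
        return data, params, rng

    @pytest.mark.parametrize("likelihood,kappa", [("negbin", 1.0), ("poisson", 0.0)])
    def test_gradient_matches_finite_differences(self, tiny_fit_data, likelihood, kappa):
        """Analytic ELBO gradient vs central finite differences, rel err < 1e-4."""
        data, params, rng = self._data_and_params(tiny_fit_data, likelihood, kappa)
        eps = _svi.draw_noise(data, rng)
        _, grads, _ = _svi.elbo_and_grad(params, data, eps)
        h = 1e-6
        worst = 0.0
        for key, val in params.items():
            arr = np.atleast_1d(np.asarray(val, float))
            flat_idx = rng.choice(arr.size, size=min(5, arr.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)

                def eval_at(delta):
                    p2 = {k: np.array(v, dtype=float) for k, v in params.items()}
                    a2 = np.atleast_1d(p2[key])
                    a2[idx] += delta
                    p2[key] = a2.reshape(np.shape(params[key]))
                    v, _, _ = _svi.elbo_and_grad(p2, data, eps)
                    return v

                fd = (eval_at(h) - eval_at(-h)) / (2 * h)
                an = float(np.atleast_1d(grads[key])[idx])
                rel = abs(fd - an) / max(abs(fd), abs(an), 1e-6)
                worst = max(worst, rel)
        assert worst < 1e-4

    def test_kl_zero_at_prior(self, tiny_fit_data):
        """All KL terms vanish when the variational posterior equals the prior."""
        cfg = cm.ModelConfig(likelihood="negbin", kappa=0.0, seed=0)
        data = build_model_data(
            tiny_fit_data["counts"], tiny_fit_data["density"], tiny_fit_data["G"], cfg
        )
        params = _svi.init_params(data, np.random.default_rng(0))
        params["zm"][:] = 0.0
        params["zs_raw"][:] = 0.0  # unit scale: whitened prior is N(0, I)
        params["em"][:] = 0.0
        params["es_raw"][:] = np.log(data.efficiency_prior_sd)
        params["sm"][:] = 0.0
        params["ss_raw"][:] = np.log(data.expression_prior_sd)
        params["bm"][:] = data.unspecific_prior_logmean
        params["bs_raw"][:] = np.log(data.unspecific_prior_sd)
        params["phim"] = np.array(data.overdispersion_prior_logmean)
        params["phis_raw"] = np.array(np.log(data.overdispersion_prior_sd))
        _, _, parts = _svi.elbo_and_grad(params, data, _svi.zero_noise(data))
        assert parts["kl"] == pytest.approx(0.0, abs=1e-10)

    def test_monte_carlo_matches_quadrature(self):
        """On a 1-tile/1-probe Poisson model with only the expression scale
        stochastic, the MC-averaged ELBO matches Gauss–Hermite quadrature."""
        data = _svi.ModelData(
            N=np.array([[3.0]]),
            n=np.array([2.0]),
            B=np.zeros((1, 1)),  # weights pinned at uniform regardless of z
            G=np.array([[1.0, 1.0]]),
            M=np.eye(1),
            locus_idx=np.array([0]),
            n_loci=1,
            normal_idx=0,
            likelihood="poisson",
            efficiency_prior_sd=0.5,
            expression_prior_sd=0.5,
            unspecific_prior_logmean=np.log(1e-3),
            unspecific_prior_sd=1.0,
            overdispersion_prior_logmean=np.log(10.0),
            overdispersion_prior_sd=1.0,
        )
        rng = np.random.default_rng(0)
        params = _svi.init_params(data, rng)
        params["sm"][:] = 0.3
        params["ss_raw"][:] = np.log(0.4)

        def elbo_at(s_eps):
            eps = _svi.zero_noise(data)
            eps["s"] = np.array([s_eps])
            v, _, _ = _svi.elbo_and_grad(params, data, eps)
            return v

        # MC average over the single random coordinate
        draws = rng.standard_normal(4000)
        mc_vals = np.array([elbo_at(d) for d in draws])
        mc = mc_vals.mean()
        sem = mc_vals.std(ddof=1) / np.sqrt(len(draws))
        # probabilists' Gauss–Hermite quadrature of the same expectation
        nodes, weights = np.polynomial.hermite_e.hermegauss(60)
        quad = sum(
            w * elbo_at(x) for x, w in zip(nodes, weights)
        ) / np.sqrt(2 * np.pi)
        assert mc == pytest.approx(quad, abs=max(4 * sem, 1e-6))

    def test_elbo_deterministic_with_zero_noise(self, small_benchmark):
        res = small_benchmark
        counts = rasterize_spots(
            res.experiment["replicates"][0]["spots"], res.truth.grid, res.truth.panel
        )
        density = cell_density(
            res.experiment["replicates"][0]["cells"], res.truth.grid
        )
        cfg = cm.ModelConfig(steps=800, seed=7)
        v1 = elbo(res.state, counts, density, res.truth.G, cfg)
        v2 = elbo(res.state, counts, density, res.truth.G, cfg)
        assert np.isfinite(v1) and v1 == v2

    def test_elbo_requires_params(self, small_benchmark, tiny_fit_data):
        state = cm.LatentState(
            weights=np.array([[1.0]]),
            efficiency=np.ones(1),
            expression=np.ones(1),
            unspecific=np.zeros(1),
        )
        with pytest.raises(ValidationError, match="parameters"):
            elbo(
                state, tiny_fit_data["counts"], tiny_fit_data["density"],
                tiny_fit_data["G"], cm.ModelConfig(),
            )


class TestFitProperties:
    def _fit(self, tiny_fit_data, **cfg_kwargs):
        cfg = cm.ModelConfig(steps=400, **cfg_kwargs)
        return cm.fit_clone_fields(
            tiny_fit_data["counts"], tiny_fit_data["density"], tiny_fit_data["G"],
            bulk=tiny_fit_data["bulk"], config=cfg,
            bulk_tiles=tiny_fit_data["bulk_tiles"],
        )

    def test_deterministic_given_seed(self, tiny_fit_data):
        _, m1 = self._fit(tiny_fit_data, seed=42)
        _, m2 = self._fit(tiny_fit_data, seed=42)
        np.testing.assert_array_equal(m1.w_mean, m2.w_mean)
        np.testing.assert_array_equal(m1.elbo_trace, m2.elbo_trace)

    def test_fraction_field_well_formed(self, small_benchmark):
        m = small_benchmark.clone_map
        assert (m.w_mean >= -1e-12).all() and (m.w_mean <= 1 + 1e-12).all()
        np.testing.assert_allclose(m.w_mean.sum(axis=1), 1.0, atol=1e-9)
        assert (m.w_lo <= m.w_mean + 1e-9).all()
        assert (m.w_hi >= m.w_mean - 1e-9).all()
        assert m.w_mean.shape == (m.grid.n_tiles, len(m.components))

    def test_stable_across_fit_seeds(self, tiny_fit_data):
        """Two optimizations from different random initializations agree on
        the tumour-fraction field (Pearson r > 0.99)."""
        _, m1 = self._fit(tiny_fit_data, seed=1)
        _, m2 = self._fit(tiny_fit_data, seed=2)
        for comp in m1.tumour_components:
            k = m1.components.index(comp)
            r = np.corrcoef(m1.w_mean[:, k], m2.w_mean[:, k])[0, 1]
            assert r > 0.99

    def test_bulk_augmentation_does_not_hurt_recovery(self, tiny_fit_data):
        """Adding the bulk pseudo-likelihood must not degrade recovery of the
        true fraction field."""
        truth = tiny_fit_data["truth"]

        def rmse(m):
            occupied = np.asarray(m.density.n) > 0
            err = []
            for comp in truth.components:
                kt = truth.components.index(comp)
                km = m.components.index(comp)
                err.append(m.w_mean[occupied, km] - truth.w_star[occupied, kt])
            return float(np.sqrt(np.mean(np.square(err))))

        _, with_bulk = self._fit(tiny_fit_data, seed=3, kappa=1.0)
        cfg = cm.ModelConfig(steps=400, seed=3, kappa=0.0)
        _, without = cm.fit_clone_fields(
            tiny_fit_data["counts"], tiny_fit_data["density"], tiny_fit_data["G"],
            config=cfg,
        )
        assert rmse(with_bulk) <= rmse(without) + 0.02

    def test_long_lengthscale_gives_flat_field(self, tiny_fit_data):
        """As the GP lengthscale greatly exceeds the tissue, the field must
        degenerate to a spatially constant mixture."""
        _, m = self._fit(tiny_fit_data, seed=0, lengthscale=1e7)
        spread = m.w_mean.std(axis=0).max()
        assert spread < 0.02

    def test_all_zero_counts_returns_normal_map(self, tiny_fit_data):
        counts = tiny_fit_data["counts"]
        zero = cm.CountTensor(
            np.zeros_like(counts.N), counts.grid, counts.probe_ids
        )
        with pytest.warns(UserWarning, match="all-zero"):
            _, m = cm.fit_clone_fields(
                zero, tiny_fit_data["density"], tiny_fit_data["G"],
                config=cm.ModelConfig(steps=5),
            )
        k = m.components.index(m.normal_component)
        np.testing.assert_allclose(m.w_mean[:, k], 1.0)

    def test_uninformative_component_warns(self, tiny_fit_data):
        tree = cm.CloneTree(parent={"a": None, "b": "a", "c": "b"})
        G = cm.build_genotype_matrix(tree, tiny_fit_data["panel"])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            cm.fit_clone_fields(
                tiny_fit_data["counts"], tiny_fit_data["density"], G,
                config=cm.ModelConfig(steps=5, artefact_component=False),
            )
        assert any("'c'" in str(w.message) for w in rec)

    def test_elbo_trace_improves(self, small_benchmark):
        """Smoothed one-sample ELBO trace ends well above where it starts."""
        trace = small_benchmark.clone_map.elbo_trace
        k = 50
        head = trace[:k].mean()
        tail = trace[-k:].mean()
        assert tail > head

    def test_zero_density_everywhere_rejected(self, tiny_fit_data):
        counts = tiny_fit_data["counts"]
        dens = cm.DensityField(np.zeros(counts.grid.n_tiles), counts.grid)
        with pytest.raises(ValidationError, match="density"):
            cm.fit_clone_fields(counts, dens, tiny_fit_data["G"])


class TestVAFMatrices:
    def test_imputed_beats_raw_on_small_benchmark(self, small_benchmark):
        m = small_benchmark.metrics
        assert m["imputed_vaf_r"] > m["raw_vaf_r"]

    def test_imputed_in_unit_interval(self, small_benchmark):
        v = small_benchmark.imputed.to_numpy()
        v = v[np.isfinite(v)]
        assert ((v >= 0) & (v <= 1)).all()

    def test_empty_region_gives_nan(self, small_benchmark):
        from shapely.geometry import box

        res = small_benchmark
        far = cm.RegionSet([cm.Region("off", "off-tissue", box(-500, -500, -400, -400))])
        imp = cm.impute_vaf(res.clone_map, res.truth.G, res.clone_map.density, far)
        assert imp.loc["off"].isna().all()
        raw = cm.raw_vaf(
            rasterize_spots(
                res.experiment["replicates"][0]["spots"], res.truth.grid,
                res.truth.panel,
            ),
            res.truth.panel, far,
        )
        assert raw.loc["off"].isna().all()


def test_clone_map_roundtrip(tmp_path, small_benchmark):
    m = small_benchmark.clone_map
    path = tmp_path / "map.npz"
    cm.save_clone_map(m, str(path))
    again = cm.load_clone_map(str(path))
    np.testing.assert_array_equal(m.w_mean, again.w_mean)
    np.testing.assert_array_equal(m.w_lo, again.w_lo)
    np.testing.assert_array_equal(m.density.n, again.density.n)
    assert again.components == m.components
    assert again.provenance == m.provenance


def test_clone_map_validates_row_sums(small_benchmark):
    m = small_benchmark.clone_map
    bad = m.w_mean.copy()
    bad[0] *= 2
    with pytest.raises(ValidationError, match="sum to 1"):
        cm.CloneMap(
            grid=m.grid, components=m.components, w_mean=bad, w_lo=m.w_lo,
            w_hi=m.w_hi, density=m.density, Gx=m.Gx, probe_ids=m.probe_ids,
            normal_component=m.normal_component,
        )
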