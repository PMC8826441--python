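"""Genetic-algorithm operators and the compliance-minimization loop."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from latticeimplant import fe_solver, fixtures
from latticeimplant import ga_optimizer as ga

from _oracles import oc_reference_design

CFG = ga.GAConfig()


class TestEncoding:
    def test_bounds_map_to_extreme_genes(self):
        g_lo = ga.encode(0.2, CFG)
        g_hi = ga.encode(0.7, CFG)
        assert not g_lo.any()
        assert g_hi.all()
        assert ga.decode(g_lo, CFG)[0] == 0.2
        assert ga.decode(g_hi, CFG)[0] == 0.7

    def test_quantization_roundtrip_bound(self):
        rng = np.random.default_rng(11)
        rho = rng.uniform(0.2, 0.7, 1000)
        back = ga.decode(ga.encode(rho, CFG), CFG)
        step = CFG.quantization_step
        assert np.abs(back - rho).max() <= step / 2 + 1e-12

    def test_out_of_bounds_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            g = ga.encode(0.9, CFG)
        assert ga.decode(g, CFG)[0] == 0.7

    def test_field_invariants(self):
        fld = ga.DensityField.from_rho([0.25, 0.5, 0.7], CFG)
        assert np.all(fld.rho >= 0.2) and np.all(fld.rho <= 0.7)
        assert np.allclose(ga.decode(fld.genes, CFG), fld.rho)


class TestFitness:
    def test_sums_to_compliance(self, small_cantilever, ref_surrogate):
        mesh, _ = small_cantilever
        st = fe_solver.solve(
            mesh, fe_solver.assemble(mesh, np.full(mesh.n_elements, 0.4), ref_surrogate)
        )
        f = ga.fitness(st)
        assert f.sum() == pytest.approx(st.c, rel=1e-8)
        assert np.all(f >= 0)

    def test_zero_load_zero_fitness(self, small_cantilever, ref_surrogate):
        mesh, _ = small_cantilever
        m = fe_solver.MacroMesh(
            nodes=mesh.nodes, elements=mesh.elements, fixed_dofs=mesh.fixed_dofs
        )
        st = fe_solver.solve(m, fe_solver.assemble(m, np.full(m.n_elements, 0.4), ref_surrogate))
        assert np.all(ga.fitness(st) == 0)

    def test_ranks_brute_force_removal_sensitivity(self, ref_surrogate):
        """Element energies rank the true compliance increase when an
        element's density is dropped to the lower bound (8-element mesh)."""
        mesh, _ = fixtures.make_cantilever(2, 2, 2)
        rho0 = np.full(8, 0.4)
        st = fe_solver.solve(mesh, fe_solver.assemble(mesh, rho0, ref_surrogate))
        deltas = []
        for e in range(8):
            r = rho0.copy()
            r[e] = 0.2
            st2 = fe_solver.solve(mesh, fe_solver.assemble(mesh, r, ref_surrogate))
            deltas.append(st2.c - st.c)
        assert np.all(np.asarray(deltas) > 0)
        rho_corr = spearmanr(st.element_energy, deltas).statistic
        assert rho_corr >= 0.8


class TestSelection:
    def test_all_mass_on_one_element(self):
        rng = np.random.default_rng(0)
        f = np.zeros(10)
        f[3] = 5.0
        father, mother = ga.select_parents(f, rng)
        assert np.all(father == 3) and np.all(mother == 3)

    def test_uniform_fitness_uniform_frequencies(self):
        rng = np.random.default_rng(1)
        n, draws = 8, 100_000
        counts = np.zeros(n)
        for _ in range(draws // n):
            father, _ = ga.select_parents(np.ones(n), rng)
            np.add.at(counts, father, 1)
        p = 1.0 / n
        total = counts.sum()
        sigma = np.sqrt(total * p * (1 - p))
        assert np.abs(counts - total * p).max() <= 3 * sigma

    def test_zero_fitness_uniform_fallback(self):
        rng = np.random.default_rng(2)
        father, mother = ga.select_parents(np.zeros(50), rng)
        assert len(np.unique(father)) > 1

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            ga.select_parents(np.array([1.0, -0.1]), np.random.default_rng(0))


class TestCrossover:
    def test_identical_parents_identical_child(self):
        rng = np.random.default_rng(0)
        g = ga.encode(0.33, CFG)
        child = ga.crossover(g, g, CFG, rng)
        assert np.array_equal(child, g)

    def test_zero_factor_returns_father(self):
        rng = np.random.default_rng(0)
        cfg = ga.GAConfig(crossover_factor=0.0)
        a, b = ga.encode(0.25, cfg), ga.encode(0.65, cfg)
        assert np.array_equal(ga.crossover(a, b, cfg, rng), a)

    def test_bit_fraction_from_mother(self):
        rng = np.random.default_rng(3)
        n_bits = 100_000
        a = np.zeros((1, n_bits), dtype=np.uint8)
        b = np.ones((1, n_bits), dtype=np.uint8)
        child = ga.crossover(a, b, CFG, rng)
        frac = child.mean()
        sigma = np.sqrt(0.3 * 0.7 / n_bits)
        assert abs(frac - 0.3) <= 3 * sigma

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ga.crossover(np.zeros(8, np.uint8), np.zeros(7, np.uint8), CFG, np.random.default_rng(0))


class TestMutation:
    def test_zero_factor_no_change(self):
        cfg = ga.GAConfig(mutation_factor=0.0)
        g = ga.encode(np.full(100, 0.4), cfg)
        out = ga.mutate(g, np.linspace(0, 1, 100), cfg, np.random.default_rng(0))
        assert np.array_equal(out, g)

    def test_top_rank_never_decreases_density(self):
        rng = np.random.default_rng(4)
        rho = rng.uniform(0.2, 0.7, 10_000)
        genes = ga.encode(rho, CFG)
        out = ga.mutate(genes, np.ones(len(rho)), CFG, rng)
        assert np.all(ga.decode(out, CFG) >= ga.decode(genes, CFG) - 1e-12)
        assert (ga.decode(out, CFG) > ga.decode(genes, CFG)).mean() > 0.1

    def test_bottom_rank_never_increases_density(self):
        rng = np.random.default_rng(5)
        rho = rng.uniform(0.2, 0.7, 10_000)
        genes = ga.encode(rho, CFG)
        out = ga.mutate(genes, np.zeros(len(rho)), CFG, rng)
        assert np.all(ga.decode(out, CFG) <= ga.decode(genes, CFG) + 1e-12)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            ga.mutate(ga.encode(0.4, CFG), 1.5, CFG, np.random.default_rng(0))


class TestVolumeEnforcement:
    def test_feasible_field_unchanged(self):
        fld = ga.DensityField.from_rho(np.full(20, 0.35), CFG)
        out = ga.enforce_volume(fld, CFG)
        assert np.array_equal(out.genes, fld.genes)

    def test_saturated_field_scaled_to_constraint(self):
        fld = ga.DensityField.from_rho(np.full(50, 0.7), CFG)
        out = ga.enforce_volume(fld, CFG)
        assert out.mean_density() <= 0.4 + 1e-9
        assert out.mean_density() >= 0.4 - 2 * CFG.quantization_step

    def test_bounds_never_violated(self):
        rng = np.random.default_rng(6)
        fld = ga.DensityField.from_rho(rng.uniform(0.5, 0.7, 100), CFG)
        out = ga.enforce_volume(fld, CFG)
        assert np.all(out.rho >= 0.2 - 1e-12) and np.all(out.rho <= 0.7 + 1e-12)

    def test_infeasible_volume_fraction_rejected(self):
        with pytest.raises(ValueError):
            ga.GAConfig(volume_fraction=0.1)


class TestOptimize:
    def test_zero_load_converges_immediately(self, small_cantilever, ref_surrogate):
        mesh, _ = small_cantilever
        m = fe_solver.MacroMesh(
            nodes=mesh.nodes, elements=mesh.elements, fixed_dofs=mesh.fixed_dofs
        )
        best, hist = ga.optimize(m, None, ref_surrogate, ga.GAConfig(seed=0, max_iters=10))
        assert hist.converged_at == 2
        assert hist.compliance_per_iter[-1] == 0.0

    def test_beats_uniform_baseline(self, small_cantilever, ref_surrogate):
        mesh, _ = small_cantilever
        cfg = ga.GAConfig(seed=3, max_iters=40)
        best, hist = ga.optimize(mesh, None, ref_surrogate, cfg)
        uniform_c = hist.compliance_per_iter[0]
        best_c = min(hist.compliance_per_iter)
        assert best_c <= uniform_c
        asm = fe_solver.assemble(mesh, best.rho, ref_surrogate)
        assert fe_solver.solve(mesh, asm).c == pytest.approx(best_c, rel=1e-9)

    def test_seed_determinism(self, small_cantilever, ref_surrogate):
        mesh, _ = small_cantilever
        cfg = ga.GAConfig(seed=5, max_iters=15)
        b1, h1 = ga.optimize(mesh, None, ref_surrogate, cfg)
        b2, h2 = ga.optimize(mesh, None, ref_surrogate, cfg)
        assert np.array_equal(b1.genes, b2.genes)
        assert h1.compliance_per_iter == h2.compliance_per_iter

    def test_constraints_on_returned_design(self, small_cantilever, ref_surrogate):
        mesh, _ = small_cantilever
        best, hist = ga.optimize(
            mesh, None, ref_surrogate, ga.GAConfig(seed=7, max_iters=30)
        )
        assert best.mean_density() <= 0.4 + CFG.quantization_step
        assert np.all(best.rho >= 0.2) and np.all(best.rho <= 0.7)
        assert np.all(np.asarray(hist.volume_per_iter) <= 0.4 + 1e-6)

    def test_high_fitness_elements_end_denser(self, ref_surrogate):
        mesh, _ = fixtures.make_cantilever(10, 5, 2)
        st0 = fe_solver.solve(
            mesh, fe_solver.assemble(mesh, np.full(mesh.n_elements, 0.4), ref_surrogate)
        )
        best, _ = ga.optimize(mesh, None, ref_surrogate, ga.GAConfig(seed=1, max_iters=50))
        corr = np.corrcoef(st0.element_energy, best.rho)[0, 1]
        assert corr > 0

    def test_bounds_outside_surrogate_domain_rejected(self, small_cantilever, ref_surrogate):
        import dataclasses

        mesh, _ = small_cantilever
        sur = dataclasses.replace(ref_surrogate, rho_domain=(0.3, 0.6))
        with pytest.raises(ValueError, match="domain"):
            ga.optimize(mesh, None, sur, ga.GAConfig(seed=0))

    def test_history_csv(self, small_cantilever, ref_surrogate, tmp_path):
        mesh, _ = small_cantilever
        _, hist = ga.optimize(mesh, None, ref_surrogate, ga.GAConfig(seed=2, max_iters=8))
        hist.to_csv(tmp_path / "hist.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "hist.csv")
        assert list(df.columns) == ["iteration", "compliance_Nmm", "volume_fraction"]
        assert len(df) == len(hist.compliance_per_iter)


class TestAgainstGradientReference:
    """Comparison with an optimality-criteria reference on the extruded
    MBB-like beam at the same volume fraction."""

    @pytest.fixture(scope="class")
    def oc_result(self, mbb_beam, ref_surrogate):
        return oc_reference_design(mbb_beam, ref_surrogate)

    def test_default_operators_within_factor_two(self, mbb_beam, ref_surrogate, oc_result):
        _, c_oc = oc_result
        cfg = ga.GAConfig(seed=1, max_iters=80)
        _, hist = ga.optimize(mbb_beam, None, ref_surrogate, cfg)
        assert min(hist.compliance_per_iter) <= 2.0 * c_oc

    def test_mutation_only_configuration_within_thirty_percent(
        self, mbb_beam, ref_surrogate, oc_result
    ):
        """With crossover disabled the directional mutation alone drives the
        search close to the gradient reference."""
        _, c_oc = oc_result
        cfg = ga.GAConfig(seed=1, max_iters=80, crossover_factor=0.0)
        _, hist = ga.optimize(mbb_beam, None, ref_surrogate, cfg)
        assert min(hist.compliance_per_iter) <= 1.3 * c_oc
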