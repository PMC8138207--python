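import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from graphdock.forcefield import EnergyReport
from graphdock.qga import (
    DeltaThetaSchedule,
    PoseLayout,
    QGAConfig,
    QGAOptimizer,
    QubitChromosome,
    apply_qngo,
    apply_qrgo,
    catastrophe,
    compute_fitness,
    crossover,
    detect_rotatable_bonds,
    initialize_population,
    measure_chromosome,
)


class TestRotatableBonds:
    def test_n_butane_has_exactly_one(self, n_butane):
        assert len(detect_rotatable_bonds(n_butane)) == 1

    def test_benzene_has_none(self, benzene):
        assert detect_rotatable_bonds(benzene) == []

    def test_biphenyl_inter_ring_bond_only(self, biphenyl):
        rot = detect_rotatable_bonds(biphenyl)
        assert len(rot) == 1
        b = biphenyl.bonds[rot[0]]
        assert biphenyl.atoms[b.i].atom_type == "C.ar"
        assert biphenyl.atoms[b.j].atom_type == "C.ar"

    def test_methanol_hydroxyl_is_terminal(self, methanol):
        assert detect_rotatable_bonds(methanol) == []


@pytest.fixture(scope="module")
def layout(coronene_patch, n_butane):
    return PoseLayout(coronene_patch, n_butane, bits_per_variable=16)


class TestEncodeDecode:

    def test_variable_count_is_torsions_plus_seven(self, layout):
        assert layout.n_vars == 1 + 3 + 4
        assert layout.n_bits == 8 * 16

    def test_bound_edges_map_to_all_zero_and_all_one(self, layout):
        lo = layout.bounds[:, 0].copy()
        hi = layout.bounds[:, 1].copy()
        assert layout.encode_values(lo) == "0" * layout.n_bits
        assert layout.encode_values(hi) == "1" * layout.n_bits

    def test_out_of_bounds_variable_rejected(self, layout):
        bad = layout.bounds[:, 1] + 1.0
        with pytest.raises(ValueError):
            layout.encode_values(bad)

    @given(data=st.data())
    def test_round_trip_within_half_step(self, layout, data):
        u = data.draw(
            st.lists(st.floats(0, 1), min_size=layout.n_vars, max_size=layout.n_vars)
        )
        lo, hi = layout.bounds[:, 0], layout.bounds[:, 1]
        vals = lo + np.asarray(u) * (hi - lo)
        back = layout.decode_values(layout.encode_values(vals))
        step = (hi - lo) / (2**16 - 1)
        assert np.all(np.abs(back - vals) <= step / 2 + 1e-12)

    def test_identity_genome_leaves_reference_pose(self, layout, n_butane):
        vals = np.zeros(layout.n_vars)
        vals[-4:] = [0, 0, 0, 1.0]  # identity quaternion
        np.testing.assert_allclose(layout.apply(vals), n_butane.coords, atol=1e-9)

    def test_translation_displaces_centroid_exactly(self, layout, n_butane):
        vals = np.zeros(layout.n_vars)
        vals[-4:] = [0, 0, 0, 1.0]
        vals[1:4] = [2.0, -3.0, 5.0]
        posed = layout.apply(vals)
        np.testing.assert_allclose(
            posed.mean(axis=0) - n_butane.coords.mean(axis=0), [2.0, -3.0, 5.0], atol=1e-9
        )

    def test_zero_quaternion_decodes_to_identity_rotation(self, layout, n_butane):
        vals = np.zeros(layout.n_vars)  # quaternion all zero
        np.testing.assert_allclose(layout.apply(vals), n_butane.coords, atol=1e-9)

    @given(data=st.data())
    def test_bond_lengths_preserved_under_any_pose(self, layout, n_butane, data):
        u = data.draw(
            st.lists(st.floats(0, 1), min_size=layout.n_vars, max_size=layout.n_vars)
        )
        lo, hi = layout.bounds[:, 0], layout.bounds[:, 1]
        posed = layout.apply(lo + np.asarray(u) * (hi - lo))
        ref = n_butane.coords
        for b in n_butane.bonds:
            d_ref = np.linalg.norm(ref[b.i] - ref[b.j])
            d_new = np.linalg.norm(posed[b.i] - posed[b.j])
            assert d_new == pytest.approx(d_ref, abs=1e-9)


class TestQubits:
    def test_fresh_population_is_balanced_superposition(self):
        cfg = QGAConfig(population_size=7, max_generations=1)
        pop = initialize_population(cfg, n_bits=12)
        assert len(pop) == 7
        for ch in pop:
            np.testing.assert_allclose(ch.alpha, math.cos(math.pi / 4))
            np.testing.assert_allclose(ch.beta, math.sin(math.pi / 4))

    def test_measurement_limits(self, rng):
        one = QubitChromosome(np.zeros(64))  # θ=0: α=1
        assert measure_chromosome(one, rng) == "1" * 64
        zero = QubitChromosome(np.full(64, math.pi / 2))  # θ=π/2: β=1
        assert measure_chromosome(zero, rng) == "0" * 64

    def test_measurement_polarity_switch(self, rng):
        one = QubitChromosome(np.zeros(16))
        assert measure_chromosome(one, rng, polarity="alpha_zero") == "0" * 16

    def test_balanced_qubits_measure_half_ones(self):
        rng = np.random.default_rng(3)
        ch = QubitChromosome(np.full(10**5, math.pi / 4))
        freq = measure_chromosome(ch, rng).count("1") / 1e5
        sigma = math.sqrt(0.25 / 1e5)
        assert abs(freq - 0.5) <= 3 * sigma


class TestOperators:
    def test_qrgo_rotation_arithmetic(self, rng):
        # θ = π/4 rotated by Δθ = π/4 gives (α', β') = (0, 1)
        theta = math.pi / 4 + math.pi / 4
        assert math.cos(theta) == pytest.approx(0.0, abs=1e-12)
        assert math.sin(theta) == pytest.approx(1.0, abs=1e-12)

    def test_qrgo_agreeing_bits_leave_chromosome_unchanged(self, rng):
        sched = DeltaThetaSchedule()
        ch = QubitChromosome(np.full(8, 0.3), "10101010", 1.0)
        best = QubitChromosome(np.full(8, math.pi / 4), "10101010", 2.0)
        before = ch.thetas.copy()
        apply_qrgo(ch, best, sched, rng, p_qrgo=1.0)
        np.testing.assert_array_equal(ch.thetas, before)

    def test_qrgo_unitarity_over_random_qubits(self, rng):
        sched = DeltaThetaSchedule()
        thetas = rng.uniform(0, math.pi / 2, 10_000)
        bits = "".join(rng.choice(["0", "1"], 10_000))
        best_bits = "".join(rng.choice(["0", "1"], 10_000))
        ch = QubitChromosome(thetas.copy(), bits, 0.5)
        best = QubitChromosome(np.full(10_000, math.pi / 4), best_bits, 1.0)
        apply_qrgo(ch, best, sched, rng, p_qrgo=1.0)
        np.testing.assert_allclose(ch.alpha**2 + ch.beta**2, 1.0, atol=1e-12)

    def test_qrgo_moves_probability_toward_best_bit(self, rng):
        sched = DeltaThetaSchedule()
        ch = QubitChromosome(np.full(1, math.pi / 4), "0", 0.0)
        best = QubitChromosome(np.full(1, math.pi / 4), "1", 5.0)
        p_before = float(ch.alpha[0] ** 2)
        apply_qrgo(ch, best, sched, rng, p_qrgo=1.0)
        assert float(ch.alpha[0] ** 2) > p_before  # P(bit 1) increased

    def test_qngo_swaps_amplitudes(self, rng):
        theta = math.atan2(0.8, 0.6)  # (α, β) = (0.6, 0.8)
        ch = QubitChromosome(np.array([theta]))
        apply_qngo(ch, rng, p_qngo=1.0)
        assert ch.alpha[0] == pytest.approx(0.8)
        assert ch.beta[0] == pytest.approx(0.6)

    def test_qngo_is_involution_and_fixes_pi_over_4(self, rng):
        thetas = np.array([0.1, math.pi / 4, 1.3])
        ch = QubitChromosome(thetas.copy())
        apply_qngo(ch, rng, p_qngo=1.0)
        assert ch.thetas[1] == pytest.approx(math.pi / 4)
        apply_qngo(ch, rng, p_qngo=1.0)
        np.testing.assert_allclose(ch.thetas, thetas, atol=1e-12)

    def test_crossover_conserves_theta_multiset(self, rng):
        a = QubitChromosome(rng.uniform(0, math.pi / 2, 20))
        b = QubitChromosome(rng.uniform(0, math.pi / 2, 20))
        pooled = sorted(np.concatenate([a.thetas, b.thetas]))
        c, d = crossover(a, b, rng, p_crossover=1.0)
        assert sorted(np.concatenate([c.thetas, d.thetas])) == pytest.approx(pooled)

    def test_crossover_with_itself_is_identity(self, rng):
        a = QubitChromosome(rng.uniform(0, math.pi / 2, 10))
        c, d = crossover(a, a, rng, p_crossover=1.0)
        np.testing.assert_array_equal(c.thetas, a.thetas)
        np.testing.assert_array_equal(d.thetas, a.thetas)

    def test_crossover_length_mismatch_is_error(self, rng):
        with pytest.raises(ValueError):
            crossover(
                QubitChromosome(np.zeros(4)), QubitChromosome(np.zeros(5)), rng, 1.0
            )

    def test_catastrophe_resets_to_fresh_population(self):
        pop = [QubitChromosome(np.random.default_rng(0).uniform(0, 1.5, 16)) for _ in range(5)]
        fresh = catastrophe(pop)
        for ch in fresh:
            np.testing.assert_allclose(ch.thetas, math.pi / 4)

    def test_schedule_missing_entry_is_error(self):
        sched = DeltaThetaSchedule(rows=[{"bit": 0, "best": 0, "better": False, "magnitude": 0, "target": "none"}])
        with pytest.raises(KeyError):
            sched.lookup(1, 0, True)


class TestFitness:
    class _Engine:
        def __init__(self, rep):
            self.rep = rep

        def evaluate(self, pose):
            return self.rep

    def test_potential_mode_negates_total_energy(self):
        eng = self._Engine(EnergyReport(e_gdds=-25.0))
        assert compute_fitness(None, eng, "potential") == pytest.approx(25.0)

    def test_binding_mode_negates_binding_energy(self):
        eng = self._Engine(
            EnergyReport(e_gdds=-100.0, e_g=-60.0, e_lig=-15.0, e_delta=-25.0)
        )
        assert compute_fitness(None, eng, "binding") == pytest.approx(25.0)

    def test_lower_energy_means_higher_fitness(self):
        lo = self._Engine(EnergyReport(e_gdds=-30.0))
        hi = self._Engine(EnergyReport(e_gdds=-10.0))
        assert compute_fitness(None, lo, "potential") > compute_fitness(None, hi, "potential")


def _bitcount_fitness(bits: str) -> float:
    return bits.count("1") / len(bits)


class TestLoop:
    def test_fixed_seed_gives_bit_identical_runs(self):
        cfg = QGAConfig(population_size=10, max_generations=30, seed=42, convergence_enabled=False)
        r1 = QGAOptimizer(24, _bitcount_fitness, cfg).run()
        r2 = QGAOptimizer(24, _bitcount_fitness, cfg).run()
        assert r1.best_bits == r2.best_bits
        assert r1.avg_fitness_trace == r2.avg_fitness_trace

    def test_best_fitness_trace_is_non_decreasing_across_catastrophes(self):
        cfg = QGAConfig(
            population_size=8, max_generations=150, seed=7,
            stagnation_window=20, convergence_enabled=False,
        )
        r = QGAOptimizer(16, _bitcount_fitness, cfg).run()
        assert all(a <= b + 1e-12 for a, b in zip(r.best_fitness_trace, r.best_fitness_trace[1:]))

    def test_trace_length_never_exceeds_max_generations(self):
        cfg = QGAConfig(population_size=6, max_generations=40, seed=1)
        r = QGAOptimizer(12, _bitcount_fitness, cfg).run()
        assert len(r.avg_fitness_trace) <= 40

    def test_rotation_only_dynamics_drift_toward_best(self):
        # with mutation and crossover off and a schedule rotating toward the
        # best bits, the mean Hamming distance to the best string shrinks
        cfg = QGAConfig(
            population_size=20, max_generations=40, seed=5,
            p_qngo=0.0, p_crossover=0.0, p_qrgo=1.0,
            convergence_enabled=False, catastrophe_enabled=False,
        )
        target = "1" * 32

        def fit(bits):
            return -sum(a != b for a, b in zip(bits, target))

        r = QGAOptimizer(32, fit, cfg).run()
        early = np.mean(r.avg_fitness_trace[:5])
        late = np.mean(r.avg_fitness_trace[-5:])
        assert late > early

    def test_catastrophe_fires_at_stagnation_window_plus_one(self):
        cfg = QGAConfig(
            population_size=5, max_generations=120, seed=0,
            stagnation_window=50, convergence_enabled=False,
        )
        r = QGAOptimizer(8, lambda b: 1.0, cfg).run()
        assert r.catastrophe_generations[0] == 51

    def test_convergence_terminates_on_flat_average(self):
        cfg = QGAConfig(
            population_size=5, max_generations=500, seed=0,
            catastrophe_enabled=False, convergence_enabled=True, convergence_window=30,
        )
        r = QGAOptimizer(8, lambda b: 1.0, cfg).run()
        assert r.converged
        assert r.n_generations == 31  # 30 consecutive flat differences
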