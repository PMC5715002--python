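import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from pollinet import (
    MatrixError,
    basic_indices,
    compute_index_report,
    d_prime,
    degree_distribution_fit,
    evenness,
    extreme_specialization,
    f_s_regression,
    h2_prime,
    modularity,
    nestedness_temperature,
)
from pollinet.indices import barber_q, h2_extremes
from pollinet.util import bipartite_from_degrees

from _oracles import (
    binary_matrices_with_margins,
    d_raw_oracle,
    h2_extremes_exact,
    h2_prime_exact,
    shannon,
)
from conftest import im, random_count_matrix


class TestBasicIndices:
    @pytest.mark.parametrize(
        "A,P,I,C,density,ip,ia",
        [
            (76, 26, 153, 0.077, 1.5, 5.88, 2.01),  # visit-survey species network
            (66, 68, 612, 0.136, 4.57, 9.00, 9.27),  # metabarcoding species network
        ],
    )
    def test_published_species_network_arithmetic(self, A, P, I, C, density, ip, ia):
        # realize any binary network with the published dimensions and
        # link count; the arithmetic indices depend only on A, P and I
        plant_deg = [I // P + (1 if k < I % P else 0) for k in range(P)]
        insect_deg = [I // A + (1 if k < I % A else 0) for k in range(A)]
        m = bipartite_from_degrees(plant_deg, insect_deg)
        vals = basic_indices(m)
        assert vals["connectance"] == pytest.approx(C, abs=5e-4)
        assert vals["interaction_density"] == pytest.approx(density, abs=5e-3)
        assert vals["plant_linkage"] == pytest.approx(ip, abs=5e-3)
        assert vals["insect_linkage"] == pytest.approx(ia, abs=5e-3)

    def test_full_matrix_connectance_one(self):
        vals = basic_indices(im(np.ones((3, 5), dtype=int)))
        assert vals["connectance"] == 1.0
        assert vals["n_links"] == 15

    def test_empty_matrix_rejected(self):
        with pytest.raises(MatrixError):
            basic_indices(im(np.zeros((0, 0), dtype=int)))


class TestNestednessTemperature:
    def test_perfectly_nested_staircase_is_cold(self):
        stair = np.tril(np.ones((6, 6), dtype=int))
        res = nestedness_temperature(im(stair))
        assert res["temperature"] < 10
        assert res["nestedness"] > 0.9

    def test_single_row_and_degenerate_fills(self):
        assert nestedness_temperature(im([[1, 0, 1]]))["temperature"] == 0.0
        assert nestedness_temperature(im(np.ones((3, 3), dtype=int)))["temperature"] == 0.0

    def test_score_within_bounds_and_transpose_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_count_matrix(rng)
            res = nestedness_temperature(m)
            assert 0.0 <= res["temperature"] <= 100.0
            assert res["nestedness"] == pytest.approx(
                (100 - res["temperature"]) / 100
            )
            mt = im(m.values.T)
            rest = nestedness_temperature(mt)
            assert rest["temperature"] == pytest.approx(res["temperature"], abs=1e-9)

    def test_checkerboard_is_near_the_maximum_of_its_margin_class(self):
        checker = np.zeros((4, 4), dtype=int)
        checker[::2, ::2] = 1
        checker[1::2, 1::2] = 1
        r, c = checker.sum(axis=1), checker.sum(axis=0)
        temps = [
            nestedness_temperature(im(b))["temperature"]
            for b in binary_matrices_with_margins(r.tolist(), c.tolist())
        ]
        t_checker = nestedness_temperature(im(checker))["temperature"]
        # exhaustive search over the 90 same-margin matrices: the
        # checkerboard sits in the hot part of the class (T = 75.9 of a
        # class maximum of 85.9 under this packing convention) and far
        # from the nested extreme
        assert t_checker >= np.median(temps) - 1e-6
        assert t_checker >= 0.8 * max(temps)
        assert t_checker > 70.0

    def test_staircase_is_the_minimum_of_its_margin_class(self):
        stair = np.array(
            [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]], dtype=int
        )
        r, c = stair.sum(axis=1), stair.sum(axis=0)
        temps = [
            nestedness_temperature(im(b))["temperature"]
            for b in binary_matrices_with_margins(r.tolist(), c.tolist())
        ]
        t_stair = nestedness_temperature(im(stair))["temperature"]
        assert t_stair == pytest.approx(min(temps), abs=1e-9)


class TestModularity:
    def test_two_disjoint_blocks_recovered_with_closed_form_q(self):
        block = np.zeros((4, 4), dtype=int)
        block[:2, :2] = 1
        block[2:, 2:] = 1
        m = im(block)
        res = modularity(m, seed=0)
        # hand computation: within-module cells each contribute
        # (1 - 2*2/8)/8 = 0.0625; eight of them give Q = 0.5
        assert res["modularity"] == pytest.approx(0.5)
        assert res["n_modules"] == 2
        pm, am = res["plant_modules"], res["pollinator_modules"]
        assert pm["P0"] == pm["P1"] == am["A0"] == am["A1"]
        assert pm["P2"] == pm["P3"] == am["A2"] == am["A3"]
        assert pm["P0"] != pm["P2"]

    def test_complete_bipartite_matrix_has_zero_modularity(self):
        res = modularity(im(np.ones((3, 4), dtype=int)), seed=1)
        assert res["modularity"] == pytest.approx(0.0, abs=1e-12)
        assert res["n_modules"] == 1

    def test_reported_q_is_consistent_with_returned_partition(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_count_matrix(rng)
            res = modularity(m, seed=3, n_restarts=5)
            rl = np.array([res["plant_modules"][p] for p in m.plant_labels])
            cl = np.array([res["pollinator_modules"][a] for a in m.pollinator_labels])
            assert barber_q(m, rl, cl) == pytest.approx(res["modularity"])

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        m = random_count_matrix(rng)
        a = modularity(m, seed=9)
        b = modularity(m, seed=9)
        assert a == b


class TestH2Prime:
    def test_perfectly_specialized_diagonal_is_one(self):
        assert h2_prime(im(np.diag([3, 3, 3]))) == pytest.approx(1.0)

    def test_independence_matrix_is_zero(self):
        # cells exactly proportional to the marginal product
        a = np.outer([2, 1], [2, 1])  # margins (6, 3) x (6, 3), F = 9
        assert h2_prime(im(a)) == pytest.approx(0.0, abs=1e-12)

    def test_heuristic_extremes_feasible_and_close_to_exhaustive(self):
        rng = np.random.default_rng(19)
        checked = 0
        while checked < 25:
            shape = (rng.integers(2, 5), rng.integers(2, 5))
            a = rng.integers(0, 3, size=shape)
            if a.sum() == 0 or a.sum() > 8:
                continue
            m = im(a).pruned()
            if m.n_plants < 2 or m.n_pollinators < 2:
                continue
            checked += 1
            r = m.values.sum(axis=1).tolist()
            c = m.values.sum(axis=0).tolist()
            lo_exact, hi_exact = h2_extremes_exact(r, c)
            lo_heur, hi_heur = h2_extremes(m)
            # heuristics produce feasible matrices, so they sit inside
            # the exhaustive envelope ...
            assert lo_heur >= lo_exact - 1e-9
            assert hi_heur <= hi_exact + 1e-9
            # ... and close enough that H2' agrees with the exact value
            assert h2_prime(m) == pytest.approx(h2_prime_exact(m.values), abs=0.1)

    def test_zero_total_rejected(self):
        with pytest.raises(MatrixError):
            h2_prime(im(np.zeros((2, 2), dtype=int)))


class TestDPrime:
    def test_profile_equal_to_availability_is_zero(self):
        # plant P0 uses partners exactly in proportion to availability
        a = np.array([[6, 3], [6, 3]])
        res = d_prime(im(a), "plants")
        assert res["values"]["P0"] == pytest.approx(0.0, abs=1e-12)

    def test_single_partner_on_rarest_partner_is_one(self):
        a = np.array([[0, 5, 0], [3, 0, 0], [0, 0, 1]])
        # P2 holds the only interaction of pollinator A2: q = 1/F
        res = d_prime(im(a), "plants")
        assert res["values"]["P2"] == pytest.approx(1.0)

    def test_matches_direct_kl_summation(self):
        rng = np.random.default_rng(31)
        a = rng.integers(0, 6, size=(4, 4))
        a[a.sum(axis=1) == 0, 0] += 1  # no empty rows
        m = im(a)
        F = a.sum()
        avail = a.sum(axis=0) / F
        res = d_prime(m, "plants")
        for i, lab in enumerate(m.plant_labels):
            d_raw = d_raw_oracle(a[i].astype(float), avail)
            d_max = math.log(F / a[i].sum())
            expected = min(max(d_raw / d_max, 0.0), 1.0)
            assert res["values"][lab] == pytest.approx(expected)

    def test_axis_swap_symmetry(self):
        rng = np.random.default_rng(37)
        m = random_count_matrix(rng)
        mt = im(m.values.T)
        assert d_prime(m, "plants")["mean"] == pytest.approx(
            d_prime(mt, "pollinators")["mean"]
        )


class TestEvenness:
    def test_uniform_full_matrix_is_one(self):
        assert evenness(im(np.full((2, 3), 4))) == pytest.approx(1.0)

    def test_single_cell_is_zero(self):
        a = np.zeros((2, 2), dtype=int)
        a[0, 0] = 7
        assert evenness(im(a)) == 0.0

    def test_hand_computed_two_by_two(self):
        # frequencies (2,1,1,0)/4: H = 1.0397, Hmax = ln 4 -> E2 = 0.75
        a = np.array([[2, 1], [1, 0]])
        assert evenness(im(a)) == pytest.approx(1.0397208 / math.log(4), abs=1e-6)
        assert evenness(im(a)) == pytest.approx(0.75, abs=1e-3)
        assert shannon(a) == pytest.approx(1.0397208, abs=1e-6)


class TestExtremeSpecialization:
    @pytest.mark.parametrize(
        "axis,n_single,n_total,expected",
        [
            ("pollinators", 46, 76, 60.53),  # published insect-side value
            ("plants", 9, 26, 34.6),  # published plant-side value
        ],
    )
    def test_single_partner_percentages(self, axis, n_single, n_total, expected):
        # n_single species with exactly one partner, the rest with two
        B = np.zeros((3, n_total), dtype=int)
        B[0, :n_single] = 1
        B[1:, n_single:] = 1
        m = im(B if axis == "pollinators" else B.T)
        assert extreme_specialization(m, axis) == pytest.approx(expected, abs=0.05)

    def test_no_single_partner_species(self):
        assert extreme_specialization(im(np.ones((3, 3), dtype=int)), "plants") == 0.0


class TestDegreeDistributionFit:
    def test_geometric_degrees_prefer_exponential(self):
        rng = np.random.default_rng(41)
        degrees = rng.geometric(0.25, size=400)
        m = _matrix_with_degrees(degrees)
        res = degree_distribution_fit(m, "pollinators")
        assert res["fit_possible"]
        assert res["best_model"] == "exponential"

    def test_truncated_power_law_recovered(self):
        rng = np.random.default_rng(43)
        s_grid = np.arange(1, 200)
        pmf = s_grid ** -0.7 * np.exp(-s_grid / 30.0)
        pmf /= pmf.sum()
        degrees = rng.choice(s_grid, size=2000, p=pmf)
        m = _matrix_with_degrees(degrees)
        res = degree_distribution_fit(m, "pollinators")
        assert res["best_model"] == "truncated_power_law"

    def test_too_few_distinct_degrees_flagged(self):
        m = im(np.ones((3, 3), dtype=int))
        assert degree_distribution_fit(m, "pollinators")["fit_possible"] is False

    def test_cumulative_distribution_non_increasing(self):
        rng = np.random.default_rng(47)
        m = random_count_matrix(rng)
        B = m.binary
        degrees = B.sum(axis=0)
        s = np.unique(degrees[degrees > 0])
        cum = [(degrees >= v).mean() for v in s]
        assert all(a >= b for a, b in zip(cum, cum[1:]))


def _matrix_with_degrees(degrees) -> "object":
    """Binary matrix whose pollinator degrees equal ``degrees``."""
    degrees = np.asarray(degrees, dtype=int)
    n_plants = int(degrees.max())
    B = np.zeros((n_plants, degrees.size), dtype=int)
    for j, k in enumerate(degrees):
        B[:k, j] = 1
    return im(B)


class TestFSRegression:
    def test_binary_single_visit_data_gives_slope_one(self):
        rng = np.random.default_rng(53)
        B = (rng.random((8, 30)) < 0.3).astype(int)
        B[:, B.sum(axis=0) == 0] = 0
        B[0, B.sum(axis=0) == 0] = 1
        res = f_s_regression(im(B), "pollinators")
        assert res["slope"] == pytest.approx(1.0)

    def test_recovers_planted_square_root_exponent(self):
        rng = np.random.default_rng(59)
        f_vals = np.unique(rng.integers(4, 2000, size=60))
        cols = []
        for f in f_vals:
            s = max(int(round(f**0.5)), 1)
            col = np.zeros(50, dtype=int)
            counts = np.full(s, f // s)
            counts[: f % s] += 1
            col[:s] = counts
            cols.append(col)
        m = im(np.array(cols).T)
        res = f_s_regression(m, "pollinators")
        assert res["slope"] == pytest.approx(0.5, abs=0.05)

    def test_slope_invariant_under_species_relabeling(self):
        rng = np.random.default_rng(61)
        m = random_count_matrix(rng)
        perm = rng.permutation(m.n_pollinators)
        m2 = im(m.values[:, perm])
        assert f_s_regression(m, "pollinators")["slope"] == pytest.approx(
            f_s_regression(m2, "pollinators")["slope"]
        )

    def test_single_species_undefined(self):
        with pytest.raises(MatrixError):
            f_s_regression(im(np.array([[2]])), "pollinators")


class TestReportInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(2, 5), st.integers(2, 5)),
            elements=st.integers(0, 6),
        )
    )
    def test_bounded_indices_stay_in_range(self, a):
        m = im(a).pruned()
        if m.n_plants < 2 or m.n_pollinators < 2 or m.total == 0:
            return
        rep = compute_index_report(m, seed=0, n_restarts=3).as_dict()
        assert 0 < rep["connectance"] <= 1
        assert 0 <= rep["nestedness"] <= 1
        assert 0 <= rep["h2_prime"] <= 1
        assert 0 <= rep["evenness"] <= 1
        assert 0 <= rep["mean_plant_d"] <= 1
        assert 0 <= rep["mean_insect_d"] <= 1
        assert 0 <= rep["extreme_plant_pct"] <= 100
        assert 0 <= rep["extreme_insect_pct"] <= 100
        assert rep["n_links"] == np.count_nonzero(m.values)
        assert rep["interaction_density"] == pytest.approx(
            rep["n_links"] / (rep["n_plants"] + rep["n_pollinators"])
        )

    def test_transpose_symmetry_of_the_full_report(self):
        rng = np.random.default_rng(67)
        m = random_count_matrix(rng)
        mt = im(m.values.T)
        rep = compute_index_report(m, seed=2, n_restarts=10).as_dict()
        rept = compute_index_report(mt, seed=2, n_restarts=10).as_dict()
        assert rep["connectance"] == pytest.approx(rept["connectance"])
        assert rep["nestedness"] == pytest.approx(rept["nestedness"], abs=1e-9)
        assert rep["h2_prime"] == pytest.approx(rept["h2_prime"], abs=1e-9)
        assert rep["evenness"] == pytest.approx(rept["evenness"])
        assert rep["plant_linkage"] == pytest.approx(rept["insect_linkage"])
        assert rep["mean_plant_d"] == pytest.approx(rept["mean_insect_d"])
        assert rep["extreme_plant_pct"] == pytest.approx(rept["extreme_insect_pct"])
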