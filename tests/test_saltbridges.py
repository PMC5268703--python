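"""Contact criterion, contact probabilities and distance pools.

Exhaustive double-loop references are recomputed inline wherever a
vectorized code path is checked, so every oracle stays independent of
the implementation under test.
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import charged_pair_structure, make_structure
from helixbridge import (
    AnalysisConfig,
    Replica,
    ResiduePair,
    TrajectoryEnsemble,
    contact_probability,
    distance_pool,
    is_contact,
    network_total,
    pair_min_distance,
    static_salt_bridges,
)
from helixbridge.errors import (
    EmptyAnalysisError,
    PipelineError,
    UnusableResidueError,
)

PAIR = ResiduePair("A", 1, "A", 2)


def _pair_ensemble(frames_o, frames_n):
    """Ensemble of an ASP/ARG pair with per-frame O and N coordinates."""
    frames_o = [np.atleast_2d(f) for f in frames_o]
    frames_n = [np.atleast_2d(f) for f in frames_n]
    st0 = charged_pair_structure(frames_o[0], frames_n[0])
    coords = np.array(
        [np.vstack([o, n]) for o, n in zip(frames_o, frames_n)]
    )
    times = np.arange(len(coords), dtype=float)
    return TrajectoryEnsemble(st0.topology, [Replica(times, coords)])


class TestPairMinDistance:
    def test_hand_geometry(self):
        st0 = charged_pair_structure(
            [[0, 0, 0], [1, 0, 0]], [[4, 0, 0], [10, 0, 0], [12, 0, 0]]
        )
        assert pair_min_distance(st0.coordinates, PAIR, st0.topology) == pytest.approx(
            3.0
        )

    def test_coincident_atoms(self):
        st0 = charged_pair_structure(
            [[1, 2, 3], [9, 9, 9]], [[1, 2, 3], [8, 8, 8], [7, 7, 7]]
        )
        assert pair_min_distance(st0.coordinates, PAIR, st0.topology) == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            o = rng.uniform(-5, 5, (2, 3))
            n = rng.uniform(-5, 5, (3, 3))
            expected = min(
                float(np.linalg.norm(oi - nj)) for oi in o for nj in n
            )
            st0 = charged_pair_structure(o, n)
            got = pair_min_distance(st0.coordinates, PAIR, st0.topology)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_incomplete_side_chain_rejected(self):
        st0 = charged_pair_structure([[0, 0, 0]], [[3, 0, 0], [4, 0, 0]])  # 1 O, 2 N
        with pytest.raises(UnusableResidueError):
            pair_min_distance(st0.coordinates, PAIR, st0.topology)


class TestIsContact:
    @pytest.mark.parametrize(
        "distance, expected", [(3.0, True), (3.6, False), (3.5, True)]
    )
    def test_cutoff_boundary_inclusive(self, distance, expected):
        assert is_contact(distance, AnalysisConfig()) is expected

    def test_negative_distance_rejected(self):
        with pytest.raises(PipelineError):
            is_contact(-0.1, AnalysisConfig())


class TestContactProbability:
    def _two_frame(self):
        o = [[[0, 0, 0], [1, 0, 0]]] * 2
        n = [
            [[3, 0, 0], [5, 0, 0], [6, 0, 0]],  # min 2.0 -> contact
            [[6, 0, 0], [7, 0, 0], [8, 0, 0]],  # min 5.0 -> no contact
        ]
        return _pair_ensemble(o, n)

    def test_half_contact(self, no_discard):
        result = contact_probability(self._two_frame(), PAIR, no_discard)
        assert (result.n_frames, result.n_contact_frames) == (2, 1)
        assert result.probability == 0.5

    @pytest.mark.parametrize("offset, expected", [(0.0, 1.0), (10.0, 0.0)])
    def test_all_or_none(self, no_discard, offset, expected):
        o = [[[0, 0, 0], [1, 0, 0]]] * 3
        n = [[[2 + offset, 0, 0], [9 + offset, 0, 0], [9, 9, 9]]] * 3
        assert (
            contact_probability(_pair_ensemble(o, n), PAIR, no_discard).probability
            == expected
        )

    def test_pooled_equals_weighted_replica_mean(self, no_discard):
        """Pooled probability = frame-count-weighted mean of per-replica
        probabilities, checked in exact rational arithmetic."""
        rng = np.random.default_rng(7)
        topo = charged_pair_structure(np.zeros((2, 3)), np.zeros((3, 3))).topology
        replicas = []
        for n_frames in (5, 13, 29):
            coords = np.empty((n_frames, 5, 3))
            coords[:, 0] = [0, 0, 0]
            coords[:, 1] = [1, 0, 0]
            coords[:, 2:] = rng.uniform(0, 6, (n_frames, 3, 3))
            replicas.append(Replica(np.arange(n_frames, dtype=float), coords))
        ens = TrajectoryEnsemble(topo, replicas)
        result = contact_probability(ens, PAIR, no_discard)
        weighted = sum(
            Fraction(c, 1) for _, c in result.per_replica
        ) / sum(Fraction(n, 1) for n, _ in result.per_replica)
        assert Fraction(result.n_contact_frames, result.n_frames) == weighted

    def test_probability_monotone_in_cutoff(self, no_discard):
        rng = np.random.default_rng(3)
        o = rng.uniform(0, 4, (30, 2, 3))
        n = rng.uniform(0, 4, (30, 3, 3))
        ens = _pair_ensemble(list(o), list(n))
        probs = [
            contact_probability(ens, PAIR, AnalysisConfig(
                equilibration_ns=0, contact_cutoff=c
            )).probability
            for c in (0.5, 1.5, 2.5, 3.5, 4.5, 8.0)
        ]
        assert probs == sorted(probs)

    def test_two_state_generator_recovery(self, wt_dataset, no_discard):
        """Estimated contact probability lands within 3 Monte-Carlo SE of
        the generator's stationary closed probability."""
        ensemble, manifest, _ = wt_dataset
        model = manifest["saltbridges"][0]
        pair = ResiduePair("S", 1, "S", 2)
        est = contact_probability(ensemble, pair, no_discard).probability
        p = model["stationary_closed"]
        rho = model["lag1_autocorrelation"]
        n = ensemble.n_frames
        se = np.sqrt(p * (1 - p) / n * (1 + rho) / (1 - rho))
        assert abs(est - p) < 3 * se


class TestNetworkTotal:
    @pytest.mark.parametrize(
        "probs, total",
        [
            ([0.60, 0.94, 0.33, 0.21], 2.08),
            ([0.14, 0.90, 0.24, 0.10], 1.38),
        ],
    )
    def test_sum_of_pair_probabilities(self, probs, total):
        assert network_total(probs) == pytest.approx(total)

    def test_empty_rejected(self):
        with pytest.raises(EmptyAnalysisError):
            network_total([])


class TestDistancePool:
    def test_single_frame_pool(self, no_discard):
        # co-located O atoms so each O–N distance appears twice: the pool
        # is {3, 3, 5, 5, ...}, mean 4, half the distances below 4 Å
        o = [[[0, 0, 0], [0, 0, 0]]]
        n = [[[3, 0, 0], [5, 0, 0], [5, 0, 0]]]
        pool = distance_pool(_pair_ensemble(o, n), PAIR, no_discard)
        assert sorted(pool.distances) == pytest.approx([3, 3, 5, 5, 5, 5])
        assert pool.mean == pytest.approx(13 / 3)
        assert pool.fraction_below == pytest.approx(1 / 3)

    def test_duplicate_frames_leave_summaries_unchanged(self, no_discard):
        o1 = [[[0, 0, 0], [1, 1, 1]]]
        n1 = [[[2, 0, 0], [0, 3, 0], [5, 5, 5]]]
        single = distance_pool(_pair_ensemble(o1, n1), PAIR, no_discard)
        double = distance_pool(_pair_ensemble(o1 * 2, n1 * 2), PAIR, no_discard)
        assert len(double.distances) == 2 * len(single.distances)
        assert double.mean == pytest.approx(single.mean)
        assert double.fraction_below == pytest.approx(single.fraction_below)

    def test_pool_matches_exhaustive_double_loop(self, no_discard):
        rng = np.random.default_rng(11)
        o = list(rng.uniform(0, 6, (10, 2, 3)))
        n = list(rng.uniform(0, 6, (10, 3, 3)))
        pool = distance_pool(_pair_ensemble(o, n), PAIR, no_discard)
        expected = [
            float(np.linalg.norm(oi - nj))
            for of, nf in zip(o, n)
            for oi in of
            for nj in nf
        ]
        assert sorted(pool.distances) == pytest.approx(sorted(expected))
        assert len(pool.distances) == 10 * 2 * 3

    def test_mixture_mean_recovered(self):
        """Symmetric two-state pair: pooled mean within 3 SE of the
        mixture mean (0.5·2.8 + 0.5·6.0 = 4.4 Å)."""
        from helixbridge import TwoStateSaltBridgeModel, simulate_saltbridge_series

        model = TwoStateSaltBridgeModel(
            p_stay_closed=0.5,
            p_stay_open=0.5,
            closed_distance=(2.8, 0.2),
            open_distance=(6.0, 1.0),
        )
        _, d = simulate_saltbridge_series(model, 10_000, seed=5)
        mixture_var = 0.5 * (0.2**2 + 2.8**2) + 0.5 * (1.0**2 + 6.0**2) - 4.4**2
        se = np.sqrt(mixture_var / len(d))
        assert abs(np.mean(d) - 4.4) < 3 * se

    def test_histogram_density_normalized(self, no_discard):
        rng = np.random.default_rng(2)
        o = list(rng.uniform(0, 6, (5, 2, 3)))
        n = list(rng.uniform(0, 6, (5, 3, 3)))
        pool = distance_pool(_pair_ensemble(o, n), PAIR, no_discard)
        hist = pool.histogram(0.2)
        assert hist["count"].sum() == len(pool.distances)
        assert (hist["density"] * 0.2).sum() == pytest.approx(1.0)


class TestStaticSaltBridges:
    def test_single_bridge_detected(self):
        st0 = charged_pair_structure(
            [[0, 0, 0], [2.2, 0, 0]], [[0, 2.9, 0], [0, 4, 0], [1, 4, 0]]
        )
        bridges = static_salt_bridges(st0, AnalysisConfig())
        assert len(bridges) == 1
        pair, dist, flag = bridges[0]
        assert dist == pytest.approx(2.9)
        assert flag

    def test_tight_cutoff_excludes(self):
        st0 = charged_pair_structure(
            [[0, 0, 0], [2.2, 0, 0]], [[0, 2.9, 0], [0, 4, 0], [1, 4, 0]]
        )
        bridges = static_salt_bridges(st0, AnalysisConfig(contact_cutoff=2.5))
        assert all(not flag for _, _, flag in bridges)

    def test_matches_brute_force_scan(self):
        """10-residue mixed structure: detected bridges equal an explicit
        all-pairs double loop."""
        rng = np.random.default_rng(19)
        specs, coords = [], []
        atom_sets = {
            "ASP": ["OD1", "OD2"],
            "GLU": ["OE1", "OE2"],
            "ARG": ["NE", "NH1", "NH2"],
            "LYS": ["NZ"],
        }
        resnames = ["ASP", "GLU", "ARG", "LYS", "ASP", "ARG", "GLU", "LYS", "ARG", "ASP"]
        for i, rn in enumerate(resnames):
            center = rng.uniform(0, 12, 3)
            for an in atom_sets[rn]:
                specs.append((an, rn, i + 1, "A"))
                coords.append(center + rng.uniform(-1, 1, 3))
        st0 = make_structure(specs, coords)
        config = AnalysisConfig(contact_cutoff=3.5)
        got = {
            (p.acidic_residue, p.basic_residue): d
            for p, d, flag in static_salt_bridges(st0, config)
            if flag
        }
        # brute force
        expected = {}
        acidic = [(i + 1, rn) for i, rn in enumerate(resnames) if rn in ("ASP", "GLU")]
        basic = [(i + 1, rn) for i, rn in enumerate(resnames) if rn in ("ARG", "LYS")]
        xyz = {
            (ri, an): np.array(c)
            for (an, rn, ri, ch), c in zip(specs, coords)
        }
        for ai, arn in acidic:
            for bi, brn in basic:
                d = min(
                    np.linalg.norm(xyz[(ai, ao)] - xyz[(bi, bo)])
                    for ao in atom_sets[arn]
                    for bo in atom_sets[brn]
                )
                if d <= 3.5:
                    expected[(ai, bi)] = float(d)
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-12)

    def test_no_charged_residues_warns_empty(self):
        st0 = make_structure(
            [("CA", "GLY", 1, "A"), ("CA", "GLY", 2, "A")], np.zeros((2, 3))
        )
        with pytest.warns(UserWarning):
            assert static_salt_bridges(st0, AnalysisConfig()) == []


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    shift=st.floats(min_value=0.0, max_value=10.0),
    cutoff=st.floats(min_value=0.5, max_value=8.0),
)
def test_contact_consistent_with_min_distance(shift, cutoff):
    """is_contact(pair_min_distance) is exactly the frame-contact rule."""
    st0 = charged_pair_structure(
        [[0, 0, 0], [2.2, 0, 0]], [[0, 2 + shift, 0], [0, 3 + shift, 0], [1, 3 + shift, 0]]
    )
    config = AnalysisConfig(contact_cutoff=cutoff)
    d = pair_min_distance(st0.coordinates, PAIR, st0.topology)
    assert is_contact(d, config) == (d <= cutoff)
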