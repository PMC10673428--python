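"""Constraint-network rigidity: interactions, pebble game, unfolding
indexes, ensembles and annotation."""

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from unfoldkit.rigidity import (
    annotate_structure,
    build_network,
    detect_hbonds,
    detect_tethers,
    detect_transition,
    energy_to_temperature,
    fuzzy_ensemble,
    hbond_energy,
    local_indexes,
    pebble_game,
    temperature_to_energy,
    unfold,
)
from unfoldkit.rigidity.network import ConstraintEdge, ConstraintNetwork
from unfoldkit.rigidity.pebble import PebbleGame, RigidDecomposition
from unfoldkit.rigidity.structure import Atom, MolecularStructure


def _atom(name, res, xyz, element=None):
    return Atom(element or name[0], name, res, "ALA", "A", np.asarray(xyz, float))


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

class TestHydrogenBonds:
    def test_distant_pair_is_not_a_bond(self):
        atoms = [
            _atom("N", 1, [0, 0, 0]), _atom("H", 1, [1.0, 0, 0]),
            _atom("C", 5, [6.0, 0, 0]), _atom("O", 5, [5.0, 0, 0]),
        ]
        s = MolecularStructure(atoms, [(0, 1), (2, 3)])
        assert detect_hbonds(s) == []  # donor-acceptor distance 5 A

    def test_energy_monotone_in_distance(self):
        # ideal collinear geometry, sweep donor-acceptor distance downward
        theta, phi = np.pi, np.pi
        distances = np.arange(3.6, 2.79, -0.05)
        energies = [hbond_energy(r, theta, phi) for r in distances]
        assert all(b < a for a, b in zip(energies, energies[1:]))
        assert energies[-1] == pytest.approx(-8.0, rel=1e-6)  # optimum depth

    def test_sorted_weakest_first(self, helix20):
        bonds = detect_hbonds(helix20)
        energies = [hb.energy for hb in bonds]
        assert energies == sorted(energies, reverse=True)


class TestTethers:
    def test_pair_within_cutoff(self):
        atoms = [
            _atom("CB", 1, [0, 0, 0], "C"),
            _atom("CB", 6, [3.9, 0, 0], "C"),
        ]
        s = MolecularStructure(atoms, [])
        assert detect_tethers(s) == [(0, 1)]

    def test_adjacent_residues_excluded(self):
        atoms = [
            _atom("CB", 1, [0, 0, 0], "C"),
            _atom("CB", 2, [3.5, 0, 0], "C"),
        ]
        assert detect_tethers(MolecularStructure(atoms, [])) == []

    def test_extended_chain_has_none(self, extended8):
        assert detect_tethers(extended8) == []


class TestBuildNetwork:
    def test_inclusion_thresholds(self, helix12):
        bonds = detect_hbonds(helix12)
        strongest = max(abs(b.energy) for b in bonds)
        full = build_network(helix12, 0.0, hbonds=bonds)
        bare = build_network(helix12, strongest + 1.0, hbonds=bonds)
        n_hb = sum(e.kind == "hydrogen_bond" for e in full.edges)
        assert n_hb == len(bonds)
        assert sum(e.kind == "hydrogen_bond" for e in bare.edges) == 0
        assert sum(e.kind == "covalent" for e in bare.edges) == len(helix12.bonds)

    def test_edge_count_non_increasing_in_energy(self, helix20):
        bonds = detect_hbonds(helix20)
        counts = [len(build_network(helix20, E, hbonds=bonds).edges)
                  for E in np.arange(0.0, 6.0, 0.25)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        # enumeration oracle: count at E equals bonds at least that strong
        for E, c in zip(np.arange(0.0, 6.0, 0.25), counts):
            expected = sum(abs(b.energy) >= E for b in bonds)
            assert c - len(helix20.bonds) - len(detect_tethers(helix20)) == expected

    def test_negative_energy_rejected(self, helix12):
        with pytest.raises(ValueError):
            build_network(helix12, -0.1)


# ---------------------------------------------------------------------------
# pebble game
# ---------------------------------------------------------------------------

def _rank_oracle_internal_floppy(n, bars, rng):
    """Generic body-bar rigidity matrix nullity (minus trivial motions)."""
    rows = []
    for (u, v) in bars:
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        d = b - a
        row = np.zeros(6 * n)
        row[6 * u:6 * u + 3] = d
        row[6 * u + 3:6 * u + 6] = np.cross(a, d)
        row[6 * v:6 * v + 3] = -d
        row[6 * v + 3:6 * v + 6] = -np.cross(b, d)
        rows.append(row)
    rank = np.linalg.matrix_rank(np.array(rows)) if rows else 0
    return max(6 * n - rank - 6, 0)


class TestPebbleGame:
    def test_single_body(self):
        dec = pebble_game(ConstraintNetwork(1, []))
        assert dec.n_clusters == 1
        assert dec.floppy_modes == 0

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_chain_floppy_modes(self, n):
        # Maxwell count: each 5-bar link leaves one dihedral mode
        edges = [ConstraintEdge(i, i + 1, 5, "covalent") for i in range(n - 1)]
        dec = pebble_game(ConstraintNetwork(n, edges))
        assert dec.floppy_modes == n - 1

    def test_six_bars_make_a_rigid_pair(self):
        game = PebbleGame(2)
        for _ in range(6):
            assert game.add_bar(0, 1)
        assert game.is_rigid_pair(0, 1)
        assert not game.add_bar(0, 1)  # seventh bar is redundant

    def test_five_plus_two_bars_single_cluster(self):
        edges = [ConstraintEdge(0, 1, 5, "covalent"),
                 ConstraintEdge(0, 1, 2, "hydrophobic")]
        dec = pebble_game(ConstraintNetwork(2, edges))
        assert dec.n_clusters == 1
        assert dec.floppy_modes == 0
        assert dec.n_redundant == 1

    def test_matches_rank_oracle_on_random_networks(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 120:
            n = int(rng.integers(2, 13))
            edges, bars = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        mult = int(rng.choice([2, 5]))
                        kind = "covalent" if mult == 5 else "hydrophobic"
                        edges.append(ConstraintEdge(i, j, mult, kind))
                        bars.extend([(i, j)] * mult)
            if not edges:
                continue
            dec = pebble_game(ConstraintNetwork(n, edges))
            assert dec.floppy_modes == _rank_oracle_internal_floppy(n, bars, rng)
            checked += 1

    def test_decomposition_permutation_invariant(self, helix12):
        bonds = detect_hbonds(helix12)
        net = build_network(helix12, 0.0, hbonds=bonds)
        dec = pebble_game(net)
        rng = np.random.default_rng(5)
        perm = rng.permutation(net.n_bodies)
        remapped = ConstraintNetwork(net.n_bodies, [
            replace(e, i=int(perm[e.i]), j=int(perm[e.j])) for e in net.edges
        ])
        dec_p = pebble_game(remapped)
        assert dec_p.floppy_modes == dec.floppy_modes
        # identical partitions after undoing the permutation
        canon = lambda labels: {frozenset(np.flatnonzero(labels == c))
                                for c in range(labels.max() + 1)}
        assert canon(dec_p.labels[perm]) == canon(dec.labels)


# ---------------------------------------------------------------------------
# unfolding sweep and global indexes
# ---------------------------------------------------------------------------

class TestUnfold:
    def test_monotonicity_and_terminal_state(self, helix12):
        trace = unfold(helix12)
        assert np.all(np.diff(trace.phi) >= -1e-12)
        assert np.all(np.diff(trace.pi) <= 1e-12)
        assert np.all(trace.sigma >= -1e-12)
        # beyond the strongest bond: pi at its floor, phi at its ceiling
        bare = pebble_game(build_network(helix12, 1e9))
        n = len(helix12)
        assert trace.phi[-1] == pytest.approx(bare.floppy_modes / (6 * n - 6))
        assert trace.pi[-1] == pytest.approx(1.0 / len(trace.reference_bodies))
        assert trace.sigma[-1] == pytest.approx(0.0, abs=1e-12)

    def test_sigma_boundary_conditions(self):
        from unfoldkit.rigidity.unfolding import _cluster_entropy

        one_cluster = RigidDecomposition(np.zeros(10, dtype=int), 0, 0, 10)
        assert _cluster_entropy(one_cluster) == pytest.approx(0.0, abs=1e-12)
        singletons = RigidDecomposition(np.arange(10), 48, 0, 10)
        assert _cluster_entropy(singletons) == pytest.approx(0.0, abs=1e-12)

    def test_sigma_rises_then_falls_under_graded_strengths(self, helix20_graded):
        structure, graded = helix20_graded
        trace = unfold(structure, hbonds=graded, tethers=[])
        k = int(np.argmax(trace.sigma))
        assert 0 < k < len(trace.sigma) - 1
        assert trace.sigma[k] > trace.sigma[0]
        assert trace.sigma[-1] == pytest.approx(0.0, abs=1e-12)

    def test_sigma_transition_not_after_pi_transition(self, helix20_graded):
        structure, graded = helix20_graded
        trace = unfold(structure, hbonds=graded, tethers=[])
        e_sigma = detect_transition(trace, "sigma")
        e_pi = detect_transition(trace, "pi")
        assert e_sigma is not None and e_pi is not None
        assert e_sigma <= e_pi


class TestEnergyTemperatureMap:
    @pytest.mark.parametrize("E,T_expected", [(0.45, 36.0), (1.83, 63.4), (2.16, 70.2)])
    def test_printed_conversions(self, E, T_expected):
        assert energy_to_temperature(E) == pytest.approx(T_expected, abs=0.3)

    def test_affine_and_invertible(self):
        E = np.array([0.0, 0.7, 2.9])
        T = energy_to_temperature(E)
        assert np.allclose(np.diff(T) / np.diff(E), 20.0)
        assert np.allclose(temperature_to_energy(T), E)
        assert energy_to_temperature(0.0) == pytest.approx(26.85)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            energy_to_temperature(-0.1)


class TestDetectTransition:
    def _trace(self, energies, sigma=None, pi=None):
        n = len(energies)
        return SimpleNamespace(energies=np.asarray(energies, float),
                               sigma=np.asarray(sigma if sigma is not None else np.zeros(n)),
                               pi=np.asarray(pi if pi is not None else np.ones(n)))

    def test_single_step(self):
        e = np.arange(0, 1.01, 0.1)
        pi = np.where(e < 0.5, 1.0, 0.2)
        assert detect_transition(self._trace(e, pi=pi), "pi") == pytest.approx(0.5)
        sigma = np.where(e < 0.7, 0.1, 0.9)
        assert detect_transition(self._trace(e, sigma=sigma), "sigma") == pytest.approx(0.7)

    def test_flat_and_linear_traces_flagged(self):
        e = np.arange(0, 1.01, 0.1)
        assert detect_transition(self._trace(e), "pi") is None
        linear = 1.0 - 0.05 * np.arange(len(e))
        assert detect_transition(self._trace(e, pi=linear), "pi") is None


# ---------------------------------------------------------------------------
# fuzzy ensembles and local indexes
# ---------------------------------------------------------------------------

class TestFuzzyEnsemble:
    def test_zero_sigma_reproduces_single_topology(self, helix12):
        ens = fuzzy_ensemble(helix12, n_topologies=3, sigma_E=0.0, seed=9)
        assert ens.pi_sd == 0.0
        single = detect_transition(unfold(helix12), "pi")
        assert ens.pi_mean == pytest.approx(single)

    def test_same_seed_identical(self, helix12):
        a = fuzzy_ensemble(helix12, n_topologies=5, sigma_E=0.2, seed=4)
        b = fuzzy_ensemble(helix12, n_topologies=5, sigma_E=0.2, seed=4)
        assert np.array_equal(a.pi_transitions, b.pi_transitions)
        assert np.array_equal(a.profile.P, b.profile.P)

    def test_sampling_consistency(self, helix20):
        """Seeded Gaussian perturbation (sd 0.2) spreads the transition
        energies; the ensemble mean stays near the unperturbed value."""
        ens = fuzzy_ensemble(helix20, n_topologies=50, sigma_E=0.2, seed=123)
        assert ens.sigma_sd > 0
        assert ens.pi_sd > 0
        single = detect_transition(unfold(helix20), "pi")
        step = 0.1
        assert abs(ens.pi_mean - single) <= 2 * ens.pi_sd + step
        assert ens.sigma_mean <= ens.pi_mean + step

    def test_mean_converges_with_ensemble_size(self, helix20):
        small = fuzzy_ensemble(helix20, n_topologies=25, sigma_E=0.2, seed=11)
        large = fuzzy_ensemble(helix20, n_topologies=50, sigma_E=0.2, seed=12)
        se = large.pi_sd * np.sqrt(1 / 25 + 1 / 50)
        assert abs(small.pi_mean - large.pi_mean) <= 3 * se + 0.1


class TestLocalIndexes:
    def test_fully_flexible_chain_all_zero(self, extended8):
        profile = local_indexes([unfold(extended8)])
        assert np.allclose(profile.P, 0.0)
        assert np.allclose(profile.R, 0.0)

    def test_termini_less_rigid_than_core(self, helix12):
        profile = local_indexes([unfold(helix12)])
        core = slice(4, 8)
        assert profile.P[0] < profile.P[core].min()
        assert profile.P[-1] < profile.P[core].min()
        assert profile.R[0] < profile.R[core].min()
        assert profile.R[-1] < profile.R[core].min()

    def test_weak_spot_frequencies_normalized(self, helix20):
        ens = fuzzy_ensemble(helix20, n_topologies=25, sigma_E=0.2, seed=2)
        F = ens.profile.F
        assert np.all(F >= 0) and np.all(F <= 1)
        assert F.sum() >= 1.0


class TestAnnotate:
    def test_round_trip_through_pdb(self, helix12, tmp_path):
        from unfoldkit.io import read_structure, write_structure

        profile = local_indexes([unfold(helix12)])
        snapshots = annotate_structure(helix12, profile, [0.0, 2.0], index="P")
        values = {r: v for r, v in zip(profile.residues, profile.P)}
        for E, annotated in snapshots:
            path = tmp_path / f"snap_{E:.1f}.pdb"
            write_structure(annotated, path)
            back = read_structure(path)
            for atom in back.atoms:
                assert atom.bfactor == pytest.approx(values[atom.res_index], abs=0.005)

    def test_native_annotation_below_first_bond_loss(self, helix12):
        profile = local_indexes([unfold(helix12)])
        bonds = detect_hbonds(helix12)
        e_first = min(abs(b.energy) for b in bonds)
        (_, low), = annotate_structure(helix12, profile, [e_first / 2], index="P")
        # values carried in B-factors are the profile itself, unchanged
        for atom in low.atoms:
            assert atom.bfactor == profile.P[list(profile.residues).index(atom.res_index)]

    def test_residue_mismatch_rejected(self, helix12, extended8):
        profile = local_indexes([unfold(extended8)])
        with pytest.raises(ValueError):
            annotate_structure(helix12, profile, [0.0])
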