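"""Simulated thermal unfolding by hydrogen-bond dilution.

The dilution energy E (kcal/mol, positive) is the reaction coordinate:
at each E only hydrogen bonds with |E_HB| >= E remain, so raising E in
0.1 kcal/mol steps removes bonds from the weakest to the strongest.
At each step the network is decomposed with the pebble game and three
global indexes are recorded:

* phi  -- floppy mode density: internal floppy modes / (6 N - 6);
* sigma -- cluster configuration entropy: -sum_s w_s ln w_s with
  w_s = s n_s / N over the rigid-cluster size distribution (zero both
  for a single all-spanning cluster and for all-singleton networks);
* pi   -- rigidity order parameter: the largest fraction of the E = 0
  giant rigid cluster still sharing one rigid cluster.

E maps linearly to temperature, T(K) = 300 + 20 E.  "Fuzzy" ensembles
de-bias the single input topology by Gaussian perturbation of every
hydrogen-bond energy; per-residue indexes P, R, F summarize where the
network loses rigidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..constants import DOF_PER_BODY, E_TO_T_INTERCEPT, E_TO_T_SLOPE, kelvin_to_celsius
from .interactions import HydrogenBond, detect_hbonds, detect_tethers
from .network import build_network
from .pebble import RigidDecomposition, pebble_game
from .structure import MolecularStructure

BACKBONE_NAMES = ("N", "CA", "C", "O", "H")


# ---------------------------------------------------------------------------
# energy <-> temperature map
# ---------------------------------------------------------------------------

def energy_to_temperature(E):
    """Convert dilution energy (kcal/mol, >= 0) to temperature in deg C."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("dilution energy must be non-negative")
    out = kelvin_to_celsius(E_TO_T_INTERCEPT + E_TO_T_SLOPE * E)
    return float(out) if out.ndim == 0 else out


def temperature_to_energy(T_C):
    """Inverse of :func:`energy_to_temperature`."""
    T_C = np.asarray(T_C, dtype=float)
    out = (T_C + 273.15 - E_TO_T_INTERCEPT) / E_TO_T_SLOPE
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# single-topology unfolding
# ---------------------------------------------------------------------------

@dataclass
class UnfoldingTrace:
    """Global indexes and per-step decompositions of one dilution sweep."""

    energies: np.ndarray
    phi: np.ndarray
    sigma: np.ndarray
    pi: np.ndarray
    decompositions: list[RigidDecomposition]
    reference_bodies: np.ndarray       # giant cluster at E = 0
    hbonds: list[HydrogenBond]
    structure: MolecularStructure = field(repr=False)
    step: float = 0.1

    @property
    def temperatures(self) -> np.ndarray:
        return energy_to_temperature(self.energies)

    def giant_label(self, k: int) -> int:
        """Label of the cluster holding most reference bodies at step k."""
        labels = self.decompositions[k].labels[self.reference_bodies]
        return int(np.bincount(labels).argmax())


def _cluster_entropy(decomp: RigidDecomposition) -> float:
    # mass-weighted cluster-size distribution: w_s = s * n_s / N
    sizes = decomp.cluster_sizes()
    uniq, counts = np.unique(sizes, return_counts=True)
    w = uniq * counts / decomp.n_bodies
    w = w[w > 0]
    return float(-(w * np.log(w)).sum())


def unfold(
    structure: MolecularStructure,
    e_max: float | None = None,
    step: float = 0.1,
    hbonds: list[HydrogenBond] | None = None,
    tethers: list[tuple[int, int]] | None = None,
) -> UnfoldingTrace:
    """Dilute hydrogen bonds on an energy grid and track phi, sigma, pi.

    ``e_max`` defaults to one step past the strongest detected hydrogen
    bond, so the final state is fully diluted.  Networks are identical
    between consecutive grid points that remove no bond, and those
    decompositions are reused.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if hbonds is None:
        hbonds = detect_hbonds(structure)
    if tethers is None:
        tethers = detect_tethers(structure)
    strengths = np.array([abs(hb.energy) for hb in hbonds])
    if e_max is None:
        e_max = float(strengths.max()) + step if len(strengths) else step
    energies = np.arange(0.0, e_max + 0.5 * step, step)

    n = len(structure)
    total_internal = max(DOF_PER_BODY * n - DOF_PER_BODY, 1)
    cache: dict[frozenset[int], RigidDecomposition] = {}
    decomps: list[RigidDecomposition] = []
    for E in energies:
        included = frozenset(k for k, s in enumerate(strengths) if s >= E)
        decomp = cache.get(included)
        if decomp is None:
            kept = [hbonds[k] for k in sorted(included)]
            network = build_network(structure, 0.0, hbonds=kept, tethers=tethers)
            decomp = pebble_game(network)
            cache[included] = decomp
        decomps.append(decomp)

    ref_labels = decomps[0].labels
    ref_bodies = np.flatnonzero(ref_labels == decomps[0].giant_cluster_id)

    phi = np.array([d.floppy_modes / total_internal for d in decomps])
    sigma = np.array([_cluster_entropy(d) for d in decomps])
    pi = np.empty(len(decomps))
    for k, d in enumerate(decomps):
        counts = np.bincount(d.labels[ref_bodies])
        pi[k] = counts.max() / len(ref_bodies)
    return UnfoldingTrace(energies, phi, sigma, pi, decomps, ref_bodies,
                          hbonds, structure, step)


def detect_transition(trace: UnfoldingTrace, index: str = "sigma") -> float | None:
    """Energy of the dominant single-step change of a global index.

    For pi this is the largest one-step drop, for sigma the largest
    one-step rise (ties resolved toward the lowest energy).  Returns
    ``None`` when no step stands out from the background drift (flat or
    uniformly changing traces carry no transition).
    """
    if index == "pi":
        steps = -np.diff(trace.pi)
    elif index == "sigma":
        steps = np.diff(trace.sigma)
    else:
        raise ValueError("index must be 'sigma' or 'pi'")
    if steps.size == 0:
        return None
    best = float(steps.max())
    if best <= 0:
        return None
    background = float(np.median(np.abs(steps)))
    if best <= 2.0 * background:
        return None  # uniform drift, not a transition
    k = int(np.argmax(steps))
    return float(trace.energies[k + 1])


# ---------------------------------------------------------------------------
# per-residue indexes
# ---------------------------------------------------------------------------

@dataclass
class ResidueProfile:
    """Per-residue percolation (P), rigidity (R) and weak-spot frequency (F).

    P and R are energies in kcal/mol within the simulated range; F is the
    fraction of ensemble topologies in which the residue hosted the
    weakest hydrogen bond lost at the rigidity-order-parameter transition.
    """

    residues: np.ndarray
    P: np.ndarray
    R: np.ndarray
    F: np.ndarray


def _giant_membership(trace: UnfoldingTrace) -> np.ndarray:
    """Boolean (n_steps, n_bodies): body in the giant cluster at step k."""
    out = np.zeros((len(trace.energies), len(trace.structure)), dtype=bool)
    for k, d in enumerate(trace.decompositions):
        out[k] = d.labels == trace.giant_label(k)
    return out


def _first_false(membership_col: np.ndarray, energies: np.ndarray) -> float:
    """Lowest energy at which membership fails; caps at the top of the range."""
    idx = np.flatnonzero(~membership_col)
    return float(energies[idx[0]]) if idx.size else float(energies[-1])


def local_indexes(traces: list[UnfoldingTrace]) -> ResidueProfile:
    """Ensemble-averaged per-residue flexibility indexes.

    P: lowest E at which the residue's CA leaves the giant rigid cluster.
    R: mean over the residue's backbone covalent edges of the E at which
    the edge's endpoints stop sharing the giant cluster.
    F: fraction of topologies in which the residue donates or accepts the
    weakest hydrogen bond removed at the pi-transition step.
    """
    if not traces:
        raise ValueError("need at least one unfolding run")
    structure = traces[0].structure
    residues = np.array(structure.residues())
    res_pos = {r: i for i, r in enumerate(residues)}

    ca_index = {r: structure.atom_index(r, "CA") for r in residues}
    backbone_edges: dict[int, list[tuple[int, int]]] = {r: [] for r in residues}
    for i, j in structure.bonds:
        ai, aj = structure.atoms[i], structure.atoms[j]
        if ai.name not in BACKBONE_NAMES or aj.name not in BACKBONE_NAMES:
            continue
        for r in {ai.res_index, aj.res_index}:
            backbone_edges[r].append((i, j))

    P_acc = np.zeros(len(residues))
    R_acc = np.zeros(len(residues))
    F_counts = np.zeros(len(residues))
    for trace in traces:
        member = _giant_membership(trace)
        energies = trace.energies
        for r in residues:
            k = res_pos[r]
            ca = ca_index[r]
            P_acc[k] += _first_false(member[:, ca], energies) if ca is not None else 0.0
            edges = backbone_edges[r]
            if edges:
                R_acc[k] += float(np.mean([
                    _first_false(member[:, i] & member[:, j], energies)
                    for i, j in edges
                ]))
        # weak spot: weakest H-bond removed at the pi transition
        e_star = detect_transition(trace, "pi")
        if e_star is not None:
            removed = [hb for hb in trace.hbonds
                       if e_star - trace.step - 1e-9 <= abs(hb.energy) < e_star]
            if removed:
                weakest = min(removed, key=lambda hb: abs(hb.energy))
                hit = {structure.atoms[weakest.donor].res_index,
                       structure.atoms[weakest.acceptor].res_index}
                for r in hit:
                    F_counts[res_pos[r]] += 1

    n = len(traces)
    return ResidueProfile(residues, P_acc / n, R_acc / n, F_counts / n)


# ---------------------------------------------------------------------------
# fuzzy ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Transition statistics and mean residue profile over network topologies."""

    n_topologies: int
    sigma_transitions: np.ndarray       # kcal/mol, one per topology with a transition
    pi_transitions: np.ndarray
    sigma_mean: float
    sigma_sd: float
    pi_mean: float
    pi_sd: float
    profile: ResidueProfile

    @property
    def sigma_temperature(self) -> float:
        return energy_to_temperature(self.sigma_mean)

    @property
    def pi_temperature(self) -> float:
        return energy_to_temperature(self.pi_mean)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1))


def fuzzy_ensemble(
    structure: MolecularStructure,
    n_topologies: int = 500,
    sigma_E: float = 0.2,
    seed: int = 0,
    e_max: float | None = None,
    step: float = 0.1,
) -> EnsembleResult:
    """Unfold an ensemble of perturbed network topologies.

    Each topology perturbs every detected hydrogen-bond energy by
    seeded Gaussian noise of standard deviation ``sigma_E`` (kcal/mol),
    mimicking non-covalent constraints randomly breaking or forming in
    the native state; perturbed bonds whose energy turns unfavorable
    (>= 0) are dropped for that topology.  All topologies share one
    energy grid so transition statistics are comparable.
    """
    if n_topologies < 1:
        raise ValueError("need at least one topology")
    if sigma_E < 0:
        raise ValueError("sigma_E must be non-negative")
    base = detect_hbonds(structure)
    tethers = detect_tethers(structure)
    if e_max is None:
        strongest = max((abs(hb.energy) for hb in base), default=0.0)
        e_max = strongest + 4.0 * sigma_E + step

    rng = np.random.default_rng(seed)
    traces: list[UnfoldingTrace] = []
    sigma_es: list[float] = []
    pi_es: list[float] = []
    for _ in range(n_topologies):
        noise = rng.normal(0.0, sigma_E, size=len(base)) if sigma_E > 0 else np.zeros(len(base))
        perturbed = [
            replace(hb, energy=e_new)
            for hb, e_new in ((hb, hb.energy + dn) for hb, dn in zip(base, noise))
            if e_new < 0
        ]
        trace = unfold(structure, e_max=e_max, step=step,
                       hbonds=perturbed, tethers=tethers)
        traces.append(trace)
        for index, sink in (("sigma", sigma_es), ("pi", pi_es)):
            e_t = detect_transition(trace, index)
            if e_t is not None:
                sink.append(e_t)

    sigma_arr = np.array(sigma_es)
    pi_arr = np.array(pi_es)
    s_mean, s_sd = _mean_sd(sigma_arr)
    p_mean, p_sd = _mean_sd(pi_arr)
    return EnsembleResult(n_topologies, sigma_arr, pi_arr,
                          s_mean, s_sd, p_mean, p_sd, local_indexes(traces))


# ---------------------------------------------------------------------------
# structure annotation
# ---------------------------------------------------------------------------

def annotate_structure(
    structure: MolecularStructure,
    profile: ResidueProfile,
    e_list,
    index: str = "P",
) -> list[tuple[float, MolecularStructure]]:
    """Map a per-residue index onto B-factors, one snapshot per energy.

    Every atom's B-factor carries its residue's index value (unchanged
    across snapshots, preserving any monotone color map); the occupancy
    column marks whether the residue is still part of the giant rigid
    cluster at that energy (index value >= E).
    """
    if index not in ("P", "R", "F"):
        raise ValueError("index must be 'P', 'R' or 'F'")
    if list(profile.residues) != structure.residues():
        raise ValueError("profile residues do not match the structure")
    values = {r: float(v) for r, v in zip(profile.residues, getattr(profile, index))}
    snapshots = []
    for E in np.atleast_1d(np.asarray(e_list, dtype=float)):
        atoms = [
            replace(a, bfactor=values[a.res_index],
                    occupancy=1.0 if values[a.res_index] >= E else 0.0)
            for a in structure.atoms
        ]
        snapshots.append((float(E), MolecularStructure(atoms, list(structure.bonds))))
    return snapshots
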