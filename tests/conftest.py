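import numpy as np
import pytest

from nucleodope.definitions import compile_interaction_sites
from nucleodope.model import DonorAcceptorSet, RingGroup, Topology
from nucleodope.synthetic import ScenarioSpec, synth_interaction_trajectory


@pytest.fixture(scope="session")
def tiny_scenario():
    """A small all-mode scenario with its compiled interaction sites."""
    spec = ScenarioSpec(
        n_alq3=8,
        sequence="TATG",
        fractions={"TypeI": 0.2, "TypeII": 0.2, "HbondOnly": 0.2, "PiOnly": 0.2},
        n_frames=30,
        dt=2.0,
        seed=42,
    )
    traj, truth = synth_interaction_trajectory(spec)
    rings, das = compile_interaction_sites(traj.topology)
    return spec, traj, truth, rings, das


def random_ring_fixture(seed: int, n_base: int = 4, n_quin: int = 6):
    """A <=200-atom random frame with ring groups and donors/acceptors.

    Ring atoms are noisy planar hexagons at random poses so plane fits are
    well defined but contact outcomes are unstructured.
    """
    rng = np.random.default_rng(seed)
    positions, rings = [], []
    names, resnames, resids, molids, elements = [], [], [], [], []
    atom = 0

    def add_ring(kind, mol, rid):
        nonlocal atom
        theta = np.sort(rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, 7)[:6])
        ring_local = 0.14 * np.stack(
            [np.cos(theta), np.sin(theta), np.zeros(6)], axis=1
        )
        ring_local += rng.normal(0, 0.005, ring_local.shape)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        center = rng.uniform(0, 2.5, 3)
        coords = ring_local @ q.T + center
        idx = np.arange(atom, atom + 6)
        for i in range(6):
            positions.append(coords[i])
            names.append(f"R{rid}A{i}")
            resnames.append("RNG")
            resids.append(rid)
            molids.append(mol)
            elements.append("C")
        atom += 6
        rings.append(
            RingGroup(
                molecule_id=mol, ring_id=rid, atom_indices=idx, kind=kind, residue_id=rid
            )
        )

    for b in range(n_base):
        add_ring("base", 1000, b)  # all bases share one molecule
    for q in range(n_quin):
        add_ring("quinoline", q, n_base + q)

    # donors on the base molecule, acceptors on the quinoline molecules
    donors, don_mol, don_res = [], [], []
    for b in range(n_base):
        d = atom
        positions.append(rng.uniform(0, 2.5, 3))
        names.append(f"D{b}")
        resnames.append("RNG")
        resids.append(b)
        molids.append(1000)
        elements.append("N")
        atom += 1
        h = atom
        positions.append(positions[d] + 0.1 * _unit(rng))
        names.append(f"H{b}")
        resnames.append("RNG")
        resids.append(b)
        molids.append(1000)
        elements.append("H")
        atom += 1
        donors.append((d, h))
        don_mol.append(1000)
        don_res.append(b)
    acceptors, acc_mol, acc_res = [], [], []
    for q in range(n_quin):
        a = atom
        positions.append(rng.uniform(0, 2.5, 3))
        names.append(f"A{q}")
        resnames.append("RNG")
        resids.append(n_base + q)
        molids.append(q)
        elements.append("O")
        atom += 1
        acceptors.append(a)
        acc_mol.append(q)
        acc_res.append(n_base + q)

    top = Topology(
        names=names,
        elements=elements,
        residue_names=resnames,
        residue_ids=resids,
        molecule_ids=molids,
    )
    das = DonorAcceptorSet(
        donors=np.asarray(donors),
        donor_molecule_ids=don_mol,
        donor_residue_ids=don_res,
        acceptors=np.asarray(acceptors),
        acceptor_molecule_ids=acc_mol,
        acceptor_residue_ids=acc_res,
    )
    return np.asarray(positions), top, rings, das


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
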