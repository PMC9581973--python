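"""Ring and donor/acceptor definitions keyed by residue name.

The contact analysis only needs to know, per residue type, which atom names
form each aromatic plane, which (D, H) pairs can donate a hydrogen bond and
which atoms can accept one. Shipped defaults cover:

* ``ALQ`` — an idealized tris(8-hydroxyquinolinate)aluminium template with
  three ligands named A/B/C; each ligand's fused bicycle is one 'quinoline'
  ring plane and carries one phenolate-oxygen acceptor.
* ``DA/DT/DG/DC`` — deoxynucleotides with standard PDB atom naming.
* ``SA/ST/SG/SC`` — the synthetic idealized base residues emitted by
  :mod:`nucleodope.synthetic` (hexagonal ring C1..C6, exocyclic donor ND-HD
  and acceptor OA).

Real topologies with other naming conventions override these via a YAML file
(see :func:`load_definitions`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .model import DonorAcceptorSet, RingGroup, Topology

#: residue names treated as nucleotides and merged into one DNA molecule
NUCLEOTIDE_RESNAMES = frozenset(
    {"DA", "DT", "DG", "DC", "SA", "ST", "SG", "SC", "A", "T", "G", "C"}
)


@dataclass(frozen=True)
class ResidueDefinition:
    """Interaction sites of one residue type, by atom name."""

    rings: tuple[tuple[tuple[str, ...], str], ...]  # ((names...), kind)
    donors: tuple[tuple[str, str], ...] = ()
    acceptors: tuple[str, ...] = ()


def _alq_definition() -> ResidueDefinition:
    rings = tuple(
        (tuple(f"{lig}C{i}" for i in range(1, 11)), "quinoline") for lig in "ABC"
    )
    acceptors = tuple(f"{lig}O" for lig in "ABC")
    return ResidueDefinition(rings=rings, donors=(), acceptors=acceptors)


_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
_PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
_SYNTH_RING = ("C1", "C2", "C3", "C4", "C5", "C6")

DEFAULT_DEFINITIONS: dict[str, ResidueDefinition] = {
    "ALQ": _alq_definition(),
    # standard nucleotides (PDB naming)
    "DT": ResidueDefinition(
        rings=((_PYRIMIDINE_RING, "base"),),
        donors=(("N3", "H3"),),
        acceptors=("O2", "O4"),
    ),
    "DC": ResidueDefinition(
        rings=((_PYRIMIDINE_RING, "base"),),
        donors=(("N4", "H41"),),
        acceptors=("O2", "N3"),
    ),
    "DA": ResidueDefinition(
        rings=((_PURINE_RING, "base"),),
        donors=(("N6", "H61"),),
        acceptors=("N1", "N3", "N7"),
    ),
    "DG": ResidueDefinition(
        rings=((_PURINE_RING, "base"),),
        donors=(("N1", "H1"), ("N2", "H21")),
        acceptors=("O6", "N3", "N7"),
    ),
}
# synthetic idealized bases share one layout
for _code in ("SA", "ST", "SG", "SC"):
    DEFAULT_DEFINITIONS[_code] = ResidueDefinition(
        rings=((_SYNTH_RING, "base"),),
        donors=(("ND", "HD"),),
        acceptors=("OA",),
    )


def load_definitions(path) -> dict[str, ResidueDefinition]:
    """Read residue definitions from YAML, overlaid on the shipped defaults.

    Schema per residue name::

        RESNAME:
          rings: [{atoms: [N1, C2, ...], kind: base}, ...]
          donors: [[N3, H3], ...]
          acceptors: [O2, O4]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    defs = dict(DEFAULT_DEFINITIONS)
    for resname, entry in raw.items():
        try:
            rings = tuple(
                (tuple(r["atoms"]), r.get("kind", "base")) for r in entry.get("rings", [])
            )
            donors = tuple((d[0], d[1]) for d in entry.get("donors", []))
            acceptors = tuple(entry.get("acceptors", []))
        except (KeyError, TypeError, IndexError) as exc:
            raise ConfigError(f"bad definition for residue {resname!r}: {exc}") from exc
        defs[resname] = ResidueDefinition(rings=rings, donors=donors, acceptors=acceptors)
    return defs


def compile_interaction_sites(
    topology: Topology,
    definitions: Mapping[str, ResidueDefinition] | None = None,
    strict: bool = False,
) -> tuple[list[RingGroup], DonorAcceptorSet]:
    """Resolve residue definitions against a topology.

    Returns the ring groups (with globally unique ring_ids) and the pooled
    donor/acceptor set. Residues without a definition are skipped unless
    ``strict`` is set.
    """
    defs = dict(definitions) if definitions is not None else DEFAULT_DEFINITIONS
    rings: list[RingGroup] = []
    donors, don_mol, don_res = [], [], []
    acceptors, acc_mol, acc_res = [], [], []
    ring_id = 0
    for rid, idx in topology.residue_atom_indices().items():
        resname = str(topology.residue_names[idx[0]])
        mol = int(topology.molecule_ids[idx[0]])
        rdef = defs.get(resname)
        if rdef is None:
            if strict:
                raise ConfigError(f"no interaction definition for residue {resname!r}")
            continue
        name_to_idx = {str(topology.names[i]): int(i) for i in idx}

        def _resolve(name: str) -> int:
            try:
                return name_to_idx[name]
            except KeyError:
                raise ConfigError(
                    f"residue {resname!r} (id {rid}): atom {name!r} not found"
                ) from None

        for atom_names, kind in rdef.rings:
            rings.append(
                RingGroup(
                    molecule_id=mol,
                    ring_id=ring_id,
                    atom_indices=np.asarray([_resolve(n) for n in atom_names]),
                    kind=kind,
                    residue_id=rid,
                )
            )
            ring_id += 1
        for d_name, h_name in rdef.donors:
            donors.append((_resolve(d_name), _resolve(h_name)))
            don_mol.append(mol)
            don_res.append(rid)
        for a_name in rdef.acceptors:
            acceptors.append(_resolve(a_name))
            acc_mol.append(mol)
            acc_res.append(rid)
    das = DonorAcceptorSet(
        donors=np.asarray(donors, dtype=int).reshape(-1, 2),
        donor_molecule_ids=np.asarray(don_mol, dtype=int),
        donor_residue_ids=np.asarray(don_res, dtype=int),
        acceptors=np.asarray(acceptors, dtype=int),
        acceptor_molecule_ids=np.asarray(acc_mol, dtype=int),
        acceptor_residue_ids=np.asarray(acc_res, dtype=int),
    )
    return rings, das
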