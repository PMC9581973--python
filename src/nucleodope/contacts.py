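"""Per-frame contact detection, base-frame classification, and aggregation.

The counting unit everywhere is the base-frame event: each analysed frame
contributes exactly one label per base, chosen with the fixed priority
TypeI > TypeII > HbondOnly > PiOnly > None, so the four counted categories
partition the events. Occurrence probabilities are each category's count
divided by the total count of non-None events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .geometry import fit_ring_planes_batch, pairwise_stack_geometry
from .model import (
    COUNTED_LABELS,
    AnalysisConfig,
    DonorAcceptorSet,
    Frame,
    InteractionLabel,
    RingGroup,
    Trajectory,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StackContact:
    """One (base ring, quinoline ring) stacking contact in one frame."""

    frame_index: int
    base_residue_id: int
    base_ring_id: int
    alq_molecule_id: int
    quinoline_ring_id: int
    vertical_separation: float
    lateral_offset: float
    interplanar_angle: float


@dataclass(frozen=True)
class HBondContact:
    """One donor...acceptor hydrogen bond in one frame."""

    frame_index: int
    donor_molecule_id: int
    donor_residue_id: int
    donor_atom: int
    hydrogen_atom: int
    acceptor_molecule_id: int
    acceptor_residue_id: int
    acceptor_atom: int
    distance: float
    angle: float


@dataclass
class ContactTable:
    """Per-base-frame labels plus the aggregated occurrence statistics."""

    labels: pd.DataFrame  # frame, base_index, base_residue_id, label, partners
    counts: dict[str, int]
    probabilities: dict[str, float]  # percent; empty when no events
    n_frames: int
    n_bases: int

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "category": lab.value,
                "count": self.counts.get(lab.value, 0),
                "probability_pct": self.probabilities.get(lab.value, float("nan")),
            }
            for lab in COUNTED_LABELS
        ]
        return pd.DataFrame(rows)


@dataclass
class LifetimeSummary:
    """Hydrogen-bond persistence statistics (ps)."""

    mean_lifetime: float
    per_pair: dict[object, float]
    intermittent_tau: float | None
    n_events: int
    any_bond_observed: bool


def _ring_planes(frame: Frame, rings: Sequence[RingGroup]):
    """Centroids and normals for a ring list, batched over equal ring sizes."""
    centroids = np.empty((len(rings), 3))
    normals = np.empty((len(rings), 3))
    sizes: dict[int, list[int]] = {}
    for i, rg in enumerate(rings):
        sizes.setdefault(rg.atom_indices.size, []).append(i)
    for size, idx in sizes.items():
        coords = np.stack([frame.positions[rings[i].atom_indices] for i in idx])
        c, n, _ = fit_ring_planes_batch(coords)
        centroids[idx] = c
        normals[idx] = n
    return centroids, normals


def detect_pi_stacking(
    frame: Frame,
    rings: Sequence[RingGroup],
    config: AnalysisConfig,
    frame_index: int = 0,
) -> list[StackContact]:
    """Base-quinoline ring pairs with vertical separation below the cutoff.

    A pair is a contact iff its vertical separation (along the sign-aligned
    bisector of the two ring normals) is < ``stacking_cutoff`` AND the
    centroid distance is < ``stacking_cutoff + lateral_guard``. The guard
    rejects distant near-coplanar rings that the vertical criterion alone
    would admit; set ``lateral_guard`` large to disable it.
    """
    base_rings = [r for r in rings if r.kind == "base"]
    quin_rings = [r for r in rings if r.kind == "quinoline"]
    if not base_rings or not quin_rings:
        raise ConfigError("need at least one 'base' and one 'quinoline' ring group")
    cb, nb = _ring_planes(frame, base_rings)
    cq, nq = _ring_planes(frame, quin_rings)
    vsep, lat, ang, cdist = pairwise_stack_geometry(cb, nb, cq, nq)
    guard = config.stacking_cutoff + config.lateral_guard
    hits = np.nonzero((vsep < config.stacking_cutoff) & (cdist < guard))
    contacts = []
    for bi, qi in zip(*hits):
        br, qr = base_rings[bi], quin_rings[qi]
        contacts.append(
            StackContact(
                frame_index=frame_index,
                base_residue_id=br.residue_id,
                base_ring_id=br.ring_id,
                alq_molecule_id=qr.molecule_id,
                quinoline_ring_id=qr.ring_id,
                vertical_separation=float(vsep[bi, qi]),
                lateral_offset=float(lat[bi, qi]),
                interplanar_angle=float(ang[bi, qi]),
            )
        )
    return contacts


def detect_hbonds(
    frame: Frame,
    das: DonorAcceptorSet,
    config: AnalysisConfig,
    frame_index: int = 0,
    intermolecular_only: bool = True,
) -> list[HBondContact]:
    """Geometric hydrogen bonds: D-A distance <= cutoff and H-D-A angle <= cutoff.

    Donor hydrogens must be resolved (bonded to D); intramolecular pairs are
    excluded by default since the analysis targets Alq3-DNA bonds.
    """
    if len(das.donors) == 0 or len(das.acceptors) == 0:
        return []
    das.check_donor_hydrogens(frame)
    d_pos = frame.positions[das.donors[:, 0]]
    h_pos = frame.positions[das.donors[:, 1]]
    a_pos = frame.positions[das.acceptors]
    contacts: list[HBondContact] = []
    for i in range(len(das.donors)):
        da = a_pos - d_pos[i]
        dist = np.linalg.norm(da, axis=1)
        ok = dist <= config.hbond_distance_cutoff
        if intermolecular_only:
            ok &= das.acceptor_molecule_ids != das.donor_molecule_ids[i]
        # exclude the degenerate case of D acting as its own acceptor
        ok &= das.acceptors != das.donors[i, 0]
        if not np.any(ok):
            continue
        dh = h_pos[i] - d_pos[i]
        dh_norm = np.linalg.norm(dh)
        if dh_norm < 1e-9:
            raise DataError(f"donor {i}: H coincides with D")
        cosang = (da[ok] @ dh) / (dist[ok] * dh_norm)
        angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        for j, angle in zip(np.nonzero(ok)[0], angles):
            if angle <= config.hbond_angle_cutoff:
                contacts.append(
                    HBondContact(
                        frame_index=frame_index,
                        donor_molecule_id=int(das.donor_molecule_ids[i]),
                        donor_residue_id=int(das.donor_residue_ids[i]),
                        donor_atom=int(das.donors[i, 0]),
                        hydrogen_atom=int(das.donors[i, 1]),
                        acceptor_molecule_id=int(das.acceptor_molecule_ids[j]),
                        acceptor_residue_id=int(das.acceptor_residue_ids[j]),
                        acceptor_atom=int(das.acceptors[j]),
                        distance=float(dist[j]),
                        angle=float(angle),
                    )
                )
    return contacts


def classify_base_frame(
    stacks: Sequence[StackContact],
    hbonds: Sequence[HBondContact],
    base_residue_id: int,
    base_molecule_id: int,
) -> tuple[InteractionLabel, dict[str, int | None]]:
    """Label one base in one frame with fixed priority TypeI > TypeII > HbondOnly > PiOnly.

    TypeI: some Alq3 molecule k both stacks on and hydrogen-bonds to this base.
    TypeII: an H-bond with molecule k and a stack with a different k'.
    Among multiple TypeI partners the smallest vertical separation wins.
    """
    my_stacks = [s for s in stacks if s.base_residue_id == base_residue_id]
    my_hb = []
    for h in hbonds:
        if h.donor_residue_id == base_residue_id and h.donor_molecule_id == base_molecule_id:
            my_hb.append((h, h.acceptor_molecule_id))
        elif h.acceptor_residue_id == base_residue_id and h.acceptor_molecule_id == base_molecule_id:
            my_hb.append((h, h.donor_molecule_id))
    stack_mols = {s.alq_molecule_id for s in my_stacks}
    hb_mols = {m for _, m in my_hb}
    partners: dict[str, int | None] = {"stack_partner": None, "hbond_partner": None}

    both = stack_mols & hb_mols
    if both:
        best = min(
            (s for s in my_stacks if s.alq_molecule_id in both),
            key=lambda s: s.vertical_separation,
        )
        partners["stack_partner"] = best.alq_molecule_id
        partners["hbond_partner"] = best.alq_molecule_id
        return InteractionLabel.TYPE_I, partners
    if hb_mols and stack_mols:
        best = min(my_stacks, key=lambda s: s.vertical_separation)
        partners["stack_partner"] = best.alq_molecule_id
        partners["hbond_partner"] = sorted(hb_mols)[0]
        return InteractionLabel.TYPE_II, partners
    if hb_mols:
        partners["hbond_partner"] = sorted(hb_mols)[0]
        return InteractionLabel.HBOND_ONLY, partners
    if stack_mols:
        best = min(my_stacks, key=lambda s: s.vertical_separation)
        partners["stack_partner"] = best.alq_molecule_id
        return InteractionLabel.PI_ONLY, partners
    return InteractionLabel.NONE, partners


def occurrence_probabilities(counts: Mapping[str, int]) -> dict[str, float]:
    """Category count / total non-None count, in percent.

    This is the probability column of the occurrence table: only the four
    counted categories enter the denominator.
    """
    clean = {}
    for lab in COUNTED_LABELS:
        c = int(counts.get(lab.value, 0))
        if c < 0:
            raise DataError("counts must be non-negative integers")
        clean[lab.value] = c
    total = sum(clean.values())
    if total == 0:
        log.warning("all occurrence counts are zero; probabilities undefined")
        return {}
    return {k: 100.0 * v / total for k, v in clean.items()}


def _base_residues(topology, rings: Sequence[RingGroup]) -> list[tuple[int, int]]:
    """(residue_id, molecule_id) of every base ring residue, in residue order."""
    seen = {}
    for r in rings:
        if r.kind == "base":
            seen[r.residue_id] = r.molecule_id
    return sorted(seen.items())


def aggregate_contacts(
    trajectory: Trajectory,
    rings: Sequence[RingGroup],
    das: DonorAcceptorSet,
    config: AnalysisConfig | None = None,
    apply_window: bool = True,
) -> ContactTable:
    """Detect, classify, and count base-frame events over the analysis window."""
    config = config or AnalysisConfig()
    window = config.window(trajectory) if apply_window else trajectory
    bases = _base_residues(window.topology, rings)
    if not bases:
        raise ConfigError("no base residues with ring definitions in topology")
    rows = []
    for fi, frame in enumerate(window.frames):
        stacks = detect_pi_stacking(frame, rings, config, frame_index=fi)
        hbonds = detect_hbonds(frame, das, config, frame_index=fi)
        for base_index, (rid, mol) in enumerate(bases):
            label, partners = classify_base_frame(stacks, hbonds, rid, mol)
            rows.append(
                {
                    "frame": fi,
                    "time": frame.time,
                    "base_index": base_index,
                    "base_residue_id": rid,
                    "label": label.value,
                    "stack_partner": partners["stack_partner"],
                    "hbond_partner": partners["hbond_partner"],
                }
            )
    labels = pd.DataFrame(rows)
    counts = {
        lab.value: int((labels["label"] == lab.value).sum()) for lab in COUNTED_LABELS
    }
    return ContactTable(
        labels=labels,
        counts=counts,
        probabilities=occurrence_probabilities(counts),
        n_frames=window.n_frames,
        n_bases=len(bases),
    )


def distinct_stacked_bases(
    per_frame_stacks: Sequence[Sequence[StackContact]],
) -> np.ndarray:
    """Per-frame count of distinct bases with at least one stacking contact."""
    if not per_frame_stacks:
        raise DataError("no frames supplied")
    return np.asarray(
        [len({s.base_residue_id for s in stacks}) for stacks in per_frame_stacks],
        dtype=float,
    )


def stacked_base_count(
    trajectory: Trajectory,
    rings: Sequence[RingGroup],
    config: AnalysisConfig | None = None,
    apply_window: bool = False,
) -> tuple[float, float]:
    """Mean +/- population sd of the per-frame count of distinct stacked bases."""
    config = config or AnalysisConfig()
    window = config.window(trajectory) if apply_window else trajectory
    per_frame = [
        detect_pi_stacking(frame, rings, config, frame_index=fi)
        for fi, frame in enumerate(window.frames)
    ]
    counts = distinct_stacked_bases(per_frame)
    return float(counts.mean()), float(counts.std())


def hbond_presence_matrix(
    per_frame_hbonds: Sequence[Sequence[HBondContact]],
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Boolean (pair, frame) presence matrix keyed by (D, H, A) atom indices."""
    keys: list[tuple[int, int, int]] = []
    key_index: dict[tuple[int, int, int], int] = {}
    for frame_hb in per_frame_hbonds:
        for h in frame_hb:
            k = (h.donor_atom, h.hydrogen_atom, h.acceptor_atom)
            if k not in key_index:
                key_index[k] = len(keys)
                keys.append(k)
    presence = np.zeros((len(keys), len(per_frame_hbonds)), dtype=bool)
    for fi, frame_hb in enumerate(per_frame_hbonds):
        for h in frame_hb:
            presence[key_index[(h.donor_atom, h.hydrogen_atom, h.acceptor_atom)], fi] = True
    return presence, keys


def _run_lengths(row: np.ndarray) -> list[int]:
    runs, n = [], 0
    for v in row:
        if v:
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


def hbond_lifetime(
    presence: np.ndarray,
    dt: float,
    keys: Sequence[object] | None = None,
    intermittent: bool = False,
) -> LifetimeSummary:
    """Continuous hydrogen-bond lifetimes from a (pair, frame) presence matrix.

    The continuous lifetime of one event is (run length x dt) over a maximal
    run of consecutive presence; the summary is the mean over all events,
    pooled across pairs. The optional intermittent correlation time is the
    trapezoidal integral of the normalized presence autocorrelation.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.ndim != 2:
        presence = presence.reshape(1, -1)
    if dt <= 0:
        raise DataError("dt must be > 0")
    all_runs: list[int] = []
    per_pair: dict[object, float] = {}
    for i in range(presence.shape[0]):
        runs = _run_lengths(presence[i])
        all_runs.extend(runs)
        key = keys[i] if keys is not None else i
        per_pair[key] = float(np.mean(runs) * dt) if runs else 0.0
    if not all_runs:
        log.warning("no hydrogen bonds ever present; lifetime reported as 0")
        return LifetimeSummary(0.0, per_pair, None, 0, False)
    mean_life = float(np.mean(all_runs) * dt)
    tau = None
    if intermittent:
        h = presence.astype(float)
        n_frames = h.shape[1]
        c0 = float(np.mean(h * h))
        if c0 > 0:
            max_lag = n_frames // 2
            corr = np.empty(max_lag + 1)
            for lag in range(max_lag + 1):
                corr[lag] = np.mean(h[:, : n_frames - lag] * h[:, lag:]) / c0
            tau = float(np.trapezoid(corr, dx=dt))
    return LifetimeSummary(mean_life, per_pair, tau, len(all_runs), True)
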