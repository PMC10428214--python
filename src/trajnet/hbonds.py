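"""Hydrogen-bond detection, occupancies, and occupancy-difference fingerprints.

A hydrogen bond is recorded between a donor heavy atom D (N or O carrying
at least one covalent hydrogen) and an acceptor heavy atom A (N or O of a
different residue) when

* the D–A heavy-atom distance is at most ``max_da_distance`` (default
  3.2 Å), and
* for at least one hydrogen on the donor, the D–H···A angle deviates from
  linearity (180°) by at most ``max_angle_deviation`` (default 20°).

The alternative convention — angle between the D→H and D→A vectors at the
donor ≤ cutoff — is available via ``angle_convention="donor"``.

Occupancy is the fraction of analyzed frames in which a bond is present.
The fingerprint stage compares two occupancy tables and selects bonds whose
occupancy change is large (≥ 20 points by default), significant (> 3σ of
all changes) and stable across trajectory chunks (chunk SD < 2σ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import SpecError, TopologyError
from .structures_io import Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondKey",
    "OccupancyTable",
    "FingerprintConfig",
    "FingerprintEntry",
    "detect_hbonds_frame",
    "occupancy_table",
    "residue_contact_barcode",
    "occupancy_fingerprint",
    "occupancy_table_tsv",
    "fingerprint_tsv",
]

_H_COVALENT_CUTOFF = 1.2  # Å, H assigned to the nearest N/O within this


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.2          # Å
    max_angle_deviation: float = 20.0     # degrees
    equilibration_discard_ns: float = 10.0
    angle_convention: str = "dha"         # "dha" | "donor"

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise SpecError("max_da_distance must be > 0")
        if not (0 < self.max_angle_deviation <= 90):
            raise SpecError("max_angle_deviation must lie in (0, 90]")
        if self.angle_convention not in ("dha", "donor"):
            raise SpecError("angle_convention must be 'dha' or 'donor'")


class HBondKey(NamedTuple):
    donor: tuple[str, str]     # (residue id, atom name)
    acceptor: tuple[str, str]


@dataclass
class OccupancyTable:
    entries: dict[HBondKey, float]
    chunk_occupancies: dict[HBondKey, list[float]]
    n_frames: int
    n_chunks: int


@dataclass(frozen=True)
class FingerprintConfig:
    min_abs_difference: float = 20.0   # percentage points
    sigma_multiplier_select: float = 3.0
    sigma_multiplier_stability: float = 2.0
    n_chunks: int = 5

    def __post_init__(self) -> None:
        if min(self.min_abs_difference, self.sigma_multiplier_select,
               self.sigma_multiplier_stability) <= 0:
            raise SpecError("fingerprint thresholds must be > 0")


class FingerprintEntry(NamedTuple):
    key: HBondKey
    delta: float          # percentage points, alternate − reference
    chunk_sd: float       # SD of per-chunk deltas, points
    selected: bool
    direction: str        # "increase" | "decrease" | "none"


# ---------------------------------------------------------------------------
# donor / acceptor election
# ---------------------------------------------------------------------------

def _heavy_and_hydrogen_indices(structure: Structure):
    heavy_no, hydrogens = [], []
    for i, a in enumerate(structure.atoms):
        el = a.element_guess
        if el in ("N", "O"):
            heavy_no.append(i)
        elif el == "H":
            hydrogens.append(i)
    return heavy_no, hydrogens


def _assign_donors(
    structure: Structure, coords: np.ndarray
) -> tuple[dict[int, list[int]], list[int]]:
    """Map donor heavy-atom index -> hydrogen indices; plus acceptor list.

    A hydrogen is covalently assigned to the nearest N/O of its own residue
    within 1.2 Å. Raises if the topology carries no hydrogens at all.
    """
    heavy_no, hydrogens = _heavy_and_hydrogen_indices(structure)
    if not hydrogens:
        raise TopologyError(
            "topology contains no hydrogen atoms; inferred-hydrogen mode is "
            "not supported — provide a structure with explicit hydrogens"
        )
    donors: dict[int, list[int]] = {}
    heavy_arr = np.asarray(heavy_no, dtype=int)
    if heavy_arr.size:
        heavy_xyz = coords[heavy_arr]
        for h in hydrogens:
            d = np.linalg.norm(heavy_xyz - coords[h], axis=1)
            j = int(np.argmin(d))
            if d[j] <= _H_COVALENT_CUTOFF:
                donors.setdefault(int(heavy_arr[j]), []).append(h)
    return donors, heavy_no


def detect_hbonds_frame(
    coords: np.ndarray, topology: Structure, criteria: HBondCriteria
) -> set[HBondKey]:
    """All hydrogen bonds satisfying the geometric criteria in one frame."""
    coords = np.asarray(coords, dtype=float)
    donors, acceptors = _assign_donors(topology, coords)
    if not donors or not acceptors:
        return set()

    atoms = topology.atoms
    found: set[HBondKey] = set()
    acc_arr = np.asarray(acceptors, dtype=int)
    acc_xyz = coords[acc_arr]
    cos_cut = math.cos(math.radians(criteria.max_angle_deviation))
    for d_idx, h_list in donors.items():
        d_xyz = coords[d_idx]
        dist = np.linalg.norm(acc_xyz - d_xyz, axis=1)
        close = acc_arr[(dist <= criteria.max_da_distance) & (acc_arr != d_idx)]
        for a_idx in close:
            a_idx = int(a_idx)
            if atoms[a_idx].residue_id == atoms[d_idx].residue_id:
                continue
            a_xyz = coords[a_idx]
            ok = False
            for h in h_list:
                h_xyz = coords[h]
                if criteria.angle_convention == "dha":
                    v1, v2 = d_xyz - h_xyz, a_xyz - h_xyz
                else:  # donor-vertex convention: D->H vs D->A
                    v1, v2 = h_xyz - d_xyz, a_xyz - d_xyz
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 == 0 or n2 == 0:
                    continue
                cos_t = float(np.dot(v1, v2) / (n1 * n2))
                if criteria.angle_convention == "dha":
                    # deviation from 180° at H: angle(D,H,A) >= 180 - cutoff
                    ok = cos_t <= -cos_cut
                else:
                    ok = cos_t >= cos_cut
                if ok:
                    break
            if ok:
                found.add(HBondKey(
                    donor=(atoms[d_idx].residue_id, atoms[d_idx].name),
                    acceptor=(atoms[a_idx].residue_id, atoms[a_idx].name),
                ))
    return found


# ---------------------------------------------------------------------------
# occupancies
# ---------------------------------------------------------------------------

def _analyzed_frame_indices(traj: Trajectory, criteria: HBondCriteria) -> list[int]:
    if traj.frame_times is None:
        return list(range(traj.n_frames))
    t0 = traj.frame_times[0] + criteria.equilibration_discard_ns
    return [i for i, t in enumerate(traj.frame_times) if t >= t0]


def _chunk_slices(n: int, n_chunks: int) -> list[slice]:
    """Contiguous equal-size chunks; remainder frames go to the last chunk."""
    size = n // n_chunks
    bounds = [i * size for i in range(n_chunks)] + [n]
    return [slice(bounds[i], bounds[i + 1]) for i in range(n_chunks)]


def occupancy_table(
    traj: Trajectory,
    criteria: HBondCriteria | None = None,
    n_chunks: int = 5,
) -> OccupancyTable:
    """Per-bond occupancies over the analyzed frames, whole and per chunk."""
    criteria = criteria or HBondCriteria()
    frames = _analyzed_frame_indices(traj, criteria)
    if len(frames) < n_chunks:
        raise SpecError(
            f"only {len(frames)} analyzed frames for {n_chunks} chunks"
        )
    per_frame: list[set[HBondKey]] = [
        detect_hbonds_frame(traj.frames[i], traj.topology, criteria)
        for i in frames
    ]
    keys = sorted({k for s in per_frame for k in s})
    n = len(per_frame)
    chunks = _chunk_slices(n, n_chunks)

    entries: dict[HBondKey, float] = {}
    chunk_occ: dict[HBondKey, list[float]] = {}
    for key in keys:
        present = np.fromiter((key in s for s in per_frame), dtype=bool, count=n)
        entries[key] = float(present.mean())
        chunk_occ[key] = [float(present[c].mean()) for c in chunks]
    return OccupancyTable(entries, chunk_occ, n_frames=n, n_chunks=n_chunks)


def residue_contact_barcode(
    traj: Trajectory,
    residue_id: str,
    partner_id: str,
    criteria: HBondCriteria | None = None,
) -> np.ndarray:
    """0/1 per analyzed frame: any hydrogen bond between the two residues.

    Multiple simultaneous bonds in a frame still score 1.
    """
    criteria = criteria or HBondCriteria()
    residue_ids = {a.residue_id for a in traj.topology.atoms}
    for rid in (residue_id, partner_id):
        if rid not in residue_ids:
            raise SpecError(f"unknown residue id {rid!r}")
    frames = _analyzed_frame_indices(traj, criteria)
    pair = {residue_id, partner_id}
    out = np.zeros(len(frames), dtype=int)
    for j, i in enumerate(frames):
        bonds = detect_hbonds_frame(traj.frames[i], traj.topology, criteria)
        if any({k.donor[0], k.acceptor[0]} == pair for k in bonds):
            out[j] = 1
    return out


# ---------------------------------------------------------------------------
# fingerprint
# ---------------------------------------------------------------------------

def occupancy_fingerprint(
    reference: OccupancyTable,
    alternate: OccupancyTable,
    config: FingerprintConfig | None = None,
) -> tuple[list[FingerprintEntry], float]:
    """Occupancy-difference fingerprint between two systems.

    Δ = (alternate − reference)·100 percentage points per bond, bonds
    absent from one table counting as occupancy 0 there. σ is the standard
    deviation of all Δ values. A bond is selected when |Δ| ≥ the absolute
    threshold, |Δ| > select-multiplier·σ, and the SD of its per-chunk Δ
    estimates stays below the stability-multiplier·σ.

    Returns (entries sorted by |Δ| descending, ties by key; σ).
    """
    config = config or FingerprintConfig()
    if reference.n_chunks != alternate.n_chunks:
        raise SpecError(
            f"chunk-count mismatch: {reference.n_chunks} vs {alternate.n_chunks}"
        )
    n_chunks = reference.n_chunks
    keys = sorted(set(reference.entries) | set(alternate.entries))
    deltas = np.array([
        (alternate.entries.get(k, 0.0) - reference.entries.get(k, 0.0)) * 100.0
        for k in keys
    ])
    sigma = float(np.std(deltas)) if keys else 0.0

    zero_chunks = [0.0] * n_chunks
    entries: list[FingerprintEntry] = []
    for k, delta in zip(keys, deltas):
        ref_c = reference.chunk_occupancies.get(k, zero_chunks)
        alt_c = alternate.chunk_occupancies.get(k, zero_chunks)
        chunk_deltas = (np.asarray(alt_c) - np.asarray(ref_c)) * 100.0
        chunk_sd = float(np.std(chunk_deltas, ddof=1)) if n_chunks > 1 else 0.0
        selected = (
            abs(delta) >= config.min_abs_difference
            and abs(delta) > config.sigma_multiplier_select * sigma
            and chunk_sd < config.sigma_multiplier_stability * sigma
        )
        direction = "none"
        if selected:
            direction = "increase" if delta > 0 else "decrease"
        entries.append(FingerprintEntry(k, float(delta), chunk_sd, selected,
                                        direction))
    entries.sort(key=lambda e: (-abs(e.delta), e.key))
    return entries, sigma


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def _key_str(key: HBondKey) -> tuple[str, str]:
    return (f"{key.donor[0]}/{key.donor[1]}",
            f"{key.acceptor[0]}/{key.acceptor[1]}")


def occupancy_table_tsv(table: OccupancyTable) -> str:
    chunk_cols = "\t".join(f"chunk{i}" for i in range(table.n_chunks))
    lines = [f"donor\tacceptor\toccupancy\t{chunk_cols}"]
    for key in sorted(table.entries):
        d, a = _key_str(key)
        chunks = "\t".join(f"{c:.6f}" for c in table.chunk_occupancies[key])
        lines.append(f"{d}\t{a}\t{table.entries[key]:.6f}\t{chunks}")
    return "\n".join(lines) + "\n"


def fingerprint_tsv(entries: list[FingerprintEntry], sigma: float) -> str:
    lines = [f"# sigma_points\t{sigma:.6f}",
             "donor\tacceptor\tdelta_points\tchunk_sd_points\tselected\tdirection"]
    for e in entries:
        d, a = _key_str(e.key)
        lines.append(
            f"{d}\t{a}\t{e.delta:.4f}\t{e.chunk_sd:.4f}"
            f"\t{int(e.selected)}\t{e.direction}"
        )
    return "\n".join(lines) + "\n"
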