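"""Ground-truth synthetic trajectory and sample generators.

Every downstream stage of the pipeline is exercised against data built
here: bead polymers with planted community structure, donor–H–acceptor
triplets switching between bonded and broken geometry via a two-state
Markov chain, mode-driven correlated displacements, and Gaussian
forward/backward work distributions with an analytically known ΔF.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .free_energy import R_KCAL, FEPSamples, FEPWindow
from .structures_io import Atom, Structure, Trajectory

__all__ = [
    "PlantedCommunitySpec",
    "HBondSeriesSpec",
    "GaussianWorkSpec",
    "make_planted_community_trajectory",
    "make_hbond_trajectory",
    "make_correlated_trajectory",
    "make_fep_samples",
    "make_fep_ladder",
    "ground_truth_tsv",
]


def _bead(serial: int, resseq: int, name: str = "CB", resname: str = "ALA",
          element: str = "C", coord=(0.0, 0.0, 0.0), chain: str = "A",
          hetatm: bool = False) -> Atom:
    return Atom(serial=serial, name=name, residue_name=resname, chain=chain,
                residue_seq=resseq, element=element, coord=tuple(coord),
                is_hetatm=hetatm)


# ---------------------------------------------------------------------------
# planted community structure
# ---------------------------------------------------------------------------

@dataclass
class PlantedCommunitySpec:
    """Bead-polymer blocks linked only through designated bridge pairs.

    Each block is a dense zig-zag column of beads; consecutive blocks are
    separated along x by ``inter_block_separation`` and joined by
    ``n_bridges`` bead pairs sitting in the gap at ``bridge_distance``
    from each other, each within contact range of its own block only.
    """

    n_blocks: int = 3
    block_sizes: list[int] = field(default_factory=lambda: [8, 8, 8])
    intra_contact_distance: float = 5.0
    inter_block_separation: float = 15.0
    bridge_distance: float = 6.0
    n_bridges: int = 1
    jitter_sd: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks != len(self.block_sizes):
            raise SpecError("n_blocks must equal len(block_sizes)")
        if any(s < 3 for s in self.block_sizes):
            raise SpecError("every block needs >= 3 beads")
        if self.jitter_sd < 0:
            raise SpecError("jitter_sd must be >= 0")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if not (self.bridge_distance < self.inter_block_separation):
            raise SpecError(
                "bridge_distance must be smaller than inter_block_separation"
            )
        if self.n_bridges < 0:
            raise SpecError("n_bridges must be >= 0")
        if self.n_bridges and min(self.block_sizes) <= 2 * (self.n_bridges - 1):
            raise SpecError(
                "blocks too small to anchor the requested number of bridges"
            )


def make_planted_community_trajectory(
    spec: PlantedCommunitySpec,
) -> tuple[Trajectory, np.ndarray]:
    """Build the bead trajectory and its ground-truth block labels.

    In the jitter-free geometry, beads of one block form a connected
    contact graph at any cutoff above ~0.67×intra_contact_distance, and
    the only inter-block pairs within plausible cutoffs are the bridge
    pairs (at ``bridge_distance``). Returns (trajectory, labels) with one
    integer label per bead in atom order.
    """
    dy = 0.5 * spec.intra_contact_distance
    dz = 0.44 * spec.intra_contact_distance
    gap_pad = 0.5 * (spec.inter_block_separation - spec.bridge_distance)

    coords: list[tuple[float, float, float]] = []
    labels: list[int] = []
    for k, size in enumerate(spec.block_sizes):
        x_k = k * spec.inter_block_separation
        for j in range(size):
            coords.append((x_k, j * dy, (j % 2) * dz))
            labels.append(k)
    # bridge pairs between consecutive blocks, anchored at even-index beads
    for k in range(spec.n_blocks - 1):
        x_k = k * spec.inter_block_separation
        for b in range(spec.n_bridges):
            y_b, z_b = (2 * b) * dy, 0.0
            coords.append((x_k + gap_pad, y_b, z_b))
            labels.append(k)
            coords.append((x_k + gap_pad + spec.bridge_distance, y_b, z_b))
            labels.append(k + 1)

    atoms = [
        _bead(serial=i + 1, resseq=i + 1, coord=c) for i, c in enumerate(coords)
    ]
    base = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(spec.seed)
    frames = base[None, :, :] + rng.normal(
        0.0, spec.jitter_sd, size=(spec.n_frames, len(atoms), 3)
    ) if spec.jitter_sd > 0 else np.repeat(base[None, :, :], spec.n_frames, axis=0)
    return Trajectory(Structure(atoms), frames), np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# two-state hydrogen-bond series
# ---------------------------------------------------------------------------

@dataclass
class HBondSeriesSpec:
    """Donor–H–acceptor triplets toggling between planted geometries.

    Each triplet occupies two pseudo-residues (donor N+H; acceptor O) and
    flips between a bonded pose (collinear, D–A = ``bonded_distance``) and
    a broken pose (D–A = ``broken_distance``) following a two-state Markov
    chain whose stationary bonded probability is the target occupancy and
    whose mean bonded dwell is ``mean_dwell_frames``.
    """

    occupancies: list[float] = field(default_factory=lambda: [0.5])
    mean_dwell_frames: float = 5.0
    bonded_distance: float = 2.9
    broken_distance: float = 4.5
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= p <= 1.0) for p in self.occupancies):
            raise SpecError("occupancies must lie in [0, 1]")
        if not (self.bonded_distance < 3.2 < self.broken_distance):
            raise SpecError("need bonded_distance < 3.2 < broken_distance")
        if self.mean_dwell_frames < 1:
            raise SpecError("mean dwell must be >= 1 frame")
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")

    @property
    def n_triplets(self) -> int:
        return len(self.occupancies)


def _markov_states(
    p: float, dwell: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary series with stationary P(1)=p and mean dwell in state 1."""
    if p <= 0.0:
        return np.zeros(n, dtype=int)
    if p >= 1.0:
        return np.ones(n, dtype=int)
    k_off = 1.0 / dwell                 # P(1 -> 0) per frame
    k_on = k_off * p / (1.0 - p)        # detailed balance at occupancy p
    if k_on > 1.0:
        raise SpecError(
            f"mean dwell {dwell} too short for occupancy {p}: "
            f"implied on-rate {k_on:.3f} exceeds 1/frame"
        )
    states = np.empty(n, dtype=int)
    states[0] = 1 if rng.random() < p else 0
    u = rng.random(n - 1)
    for t in range(1, n):
        if states[t - 1] == 1:
            states[t] = 0 if u[t - 1] < k_off else 1
        else:
            states[t] = 1 if u[t - 1] < k_on else 0
    return states


def make_hbond_trajectory(
    spec: HBondSeriesSpec,
) -> tuple[Trajectory, list[float], np.ndarray]:
    """Generate the triplet trajectory plus its planted truth.

    Returns (trajectory, target occupancies, states) where ``states`` is a
    (n_triplets, n_frames) 0/1 array of the planted bonded state.
    """
    rng = np.random.default_rng(spec.seed)
    states = np.stack([
        _markov_states(p, spec.mean_dwell_frames, spec.n_frames, rng)
        for p in spec.occupancies
    ])

    atoms: list[Atom] = []
    serial = 1
    for i in range(spec.n_triplets):
        origin = 25.0 * i
        donor_res, acceptor_res = 2 * i + 1, 2 * i + 2
        atoms.append(_bead(serial, donor_res, name="N", resname="DON",
                           element="N", coord=(origin, 0.0, 0.0)))
        atoms.append(_bead(serial + 1, donor_res, name="H", resname="DON",
                           element="H", coord=(origin + 1.0, 0.0, 0.0)))
        atoms.append(_bead(serial + 2, acceptor_res, name="O", resname="ACC",
                           element="O", coord=(origin + 2.9, 0.0, 0.0)))
        serial += 3

    frames = np.empty((spec.n_frames, len(atoms), 3))
    for t in range(spec.n_frames):
        for i in range(spec.n_triplets):
            origin = 25.0 * i
            da = spec.bonded_distance if states[i, t] else spec.broken_distance
            frames[t, 3 * i] = (origin, 0.0, 0.0)
            frames[t, 3 * i + 1] = (origin + 1.0, 0.0, 0.0)
            frames[t, 3 * i + 2] = (origin + da, 0.0, 0.0)

    traj = Trajectory(Structure(atoms), frames)
    return traj, list(spec.occupancies), states


def markov_occupancy_bound(p: float, dwell: float, n_frames: int,
                           n_sigma: float = 3.0) -> float:
    """Sampling bound on the empirical occupancy of the two-state chain.

    Uses the effective sample size n_eff = n(1−ρ)/(1+ρ) with lag-1
    autocorrelation ρ = 1 − k_on − k_off of the chain.
    """
    if p <= 0.0 or p >= 1.0:
        return 0.0
    k_off = 1.0 / dwell
    k_on = k_off * p / (1.0 - p)
    rho = max(min(1.0 - k_on - k_off, 0.999), -0.999)
    n_eff = n_frames * (1.0 - rho) / (1.0 + rho)
    return n_sigma * np.sqrt(p * (1.0 - p) / n_eff)


# ---------------------------------------------------------------------------
# correlated displacements
# ---------------------------------------------------------------------------

def make_correlated_trajectory(
    covariance: np.ndarray,
    modes: np.ndarray,
    n_frames: int,
    seed: int = 0,
    base_coords: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory whose displacements are mode combinations with MVN amplitudes.

    Parameters
    ----------
    covariance
        (k, k) symmetric positive-semidefinite amplitude covariance (Å²).
    modes
        (k, n_atoms, 3) displacement direction per mode and atom.
    base_coords
        optional (n_atoms, 3) rest coordinates; defaults to a 20 Å-spaced
        line of ALA CB beads.
    """
    cov = np.asarray(covariance, dtype=float)
    modes = np.asarray(modes, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise SpecError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise SpecError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
        raise SpecError("covariance must be positive semidefinite")
    if modes.ndim != 3 or modes.shape[0] != cov.shape[0] or modes.shape[2] != 3:
        raise SpecError("modes must have shape (k, n_atoms, 3)")

    n_atoms = modes.shape[1]
    if base_coords is None:
        base_coords = np.column_stack([
            20.0 * np.arange(n_atoms), np.zeros(n_atoms), np.zeros(n_atoms)
        ])
    base_coords = np.asarray(base_coords, dtype=float)

    rng = np.random.default_rng(seed)
    # eigendecomposition handles semidefinite covariances exactly
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    amplitudes = rng.standard_normal((n_frames, cov.shape[0])) @ (
        v * np.sqrt(w)
    ).T
    frames = base_coords[None, :, :] + np.einsum(
        "fk,kaj->faj", amplitudes, modes
    )
    atoms = [
        _bead(serial=i + 1, resseq=i + 1, coord=tuple(base_coords[i]))
        for i in range(n_atoms)
    ]
    return Trajectory(Structure(atoms), frames)


# ---------------------------------------------------------------------------
# Crooks-consistent Gaussian work samples
# ---------------------------------------------------------------------------

@dataclass
class GaussianWorkSpec:
    """Gaussian forward/backward ΔU distributions with known ΔF.

    Construction satisfies the Crooks relation: forward samples are
    N(ΔF + σ²/2RT, σ²) and backward samples N(−ΔF + σ²/2RT, σ²), so every
    estimator (Zwanzig, BAR, MBAR) targets exactly ``true_df``.
    """

    true_df: float = -3.0
    work_sd: float = 1.0
    temperature: float = 300.0
    n_forward: int = 1000
    n_backward: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.work_sd <= 0:
            raise SpecError("work_sd must be > 0")
        if self.n_forward < 2 or self.n_backward < 2:
            raise SpecError("need >= 2 samples in each direction")


def make_fep_samples(spec: GaussianWorkSpec) -> FEPSamples:
    """Single-window Crooks-consistent Gaussian ΔU samples."""
    rng = np.random.default_rng(spec.seed)
    rt = R_KCAL * spec.temperature
    shift = spec.work_sd**2 / (2.0 * rt)
    forward = rng.normal(spec.true_df + shift, spec.work_sd, spec.n_forward)
    backward = rng.normal(-spec.true_df + shift, spec.work_sd, spec.n_backward)
    return FEPSamples(
        windows=[FEPWindow(forward, backward)], temperature=spec.temperature
    )


def make_fep_ladder(spec: GaussianWorkSpec, n_windows: int) -> FEPSamples:
    """Split ``true_df`` evenly over ``n_windows`` Crooks-consistent windows."""
    if n_windows < 1:
        raise SpecError("n_windows must be >= 1")
    rng = np.random.default_rng(spec.seed)
    rt = R_KCAL * spec.temperature
    per_df = spec.true_df / n_windows
    shift = spec.work_sd**2 / (2.0 * rt)
    windows = []
    for _ in range(n_windows):
        fwd = rng.normal(per_df + shift, spec.work_sd, spec.n_forward)
        bwd = rng.normal(-per_df + shift, spec.work_sd, spec.n_backward)
        windows.append(FEPWindow(fwd, bwd))
    return FEPSamples(windows=windows, temperature=spec.temperature)


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------

def ground_truth_tsv(kind: str, ids, values) -> str:
    """Sidecar table (entity id, true value) for a generated dataset."""
    lines = [f"entity\ttrue_{kind}"]
    lines.extend(f"{i}\t{v}" for i, v in zip(ids, values))
    return "\n".join(lines) + "\n"
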