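"""Synthetic fixtures with known ground truth.

Stands in for the external inputs of the real pipeline: a two-chain toy
complex with a constructed buried interface, docked-pose ensembles with a
known best pose, affinity corpora with a linear ground truth over triad
features, idealized helices for hydrogen-bond logic, and harmonic/hopping
trajectories with per-residue amplitudes.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .design import AA_ALPHABET, validate_sequence
from .energetics import PoseEnsemble
from .errors import DataError
from .screening import AffinityRecord, conjoint_triad, N_BINS
from .structure import Atom, Residue, ResidueKey, Structure, assign_radii
from .traj import Trajectory

# backbone atom offsets relative to CA (element, name, dx, dy, dz)
_BACKBONE_OFFSETS = (
    ("N", "N", 0.00, 0.80, -1.20),
    ("C", "C", 0.00, 0.80, 1.20),
    ("O", "O", 0.00, 1.90, 1.40),
    ("C", "CB", 0.00, -1.00, 0.00),
)

CA_SPACING = 3.8


@dataclass(frozen=True)
class ToyComplexSpec:
    n_residues: int = 12
    contact_patch: tuple[int, ...] = (4, 5, 6)  # 0-based indices
    inter_chain_gap: float = 4.0     # CA-CA gap at the patch, A
    far_gap: float = 16.0            # CA-CA gap away from the patch, A
    seed: int = 0

    def __post_init__(self):
        if self.inter_chain_gap <= 0:
            raise DataError("inter_chain_gap must be > 0")
        if any(not 0 <= i < self.n_residues for i in self.contact_patch):
            raise DataError("contact_patch indices out of range")


@dataclass
class ToyComplex:
    structure: Structure          # chains A (receptor) and B (ligand)
    interface: list[ResidueKey]   # ground-truth chain-A contact residues
    receptor_chain: str = "A"
    ligand_chain: str = "B"
    suggested_cutoff: float = 20.0  # per-residue delta-SASA, A^2


@dataclass(frozen=True)
class AffinityCorpusSpec:
    n_records: int = 100
    parent: str = "YIDPKHGGTGSNNEDLR"
    true_weights: Optional[tuple[float, ...]] = None  # len 343; random if None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 10:
            raise DataError("n_records must be >= 10")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        validate_sequence(self.parent)


@dataclass
class AffinityCorpus:
    records: list[AffinityRecord]
    true_affinities: np.ndarray       # noiseless values, record order
    true_ranking: list[int]           # record indices, best (lowest) first
    target_seq: str
    weights: np.ndarray


@dataclass(frozen=True)
class TrajectorySpec:
    n_frames: int = 100
    dt: float = 0.01  # ns
    per_residue_amplitudes: tuple[float, ...] = ()  # per-coordinate sd, A
    n_states: int = 0  # 0 -> harmonic mode; >=2 -> hopping mode
    state_displacement: float = 4.0  # A, hopping mode
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise DataError("n_frames must be >= 2")
        if any(a < 0 for a in self.per_residue_amplitudes):
            raise DataError("amplitudes must be >= 0")


def _make_residue(chain_id: str, resseq: int, ca: np.ndarray, serial0: int,
                  flip_y: bool = False, name: str = "ALA") -> Residue:
    sign = -1.0 if flip_y else 1.0
    atoms = [Atom(serial=serial0, name="CA", element="C", coords=ca.copy())]
    for i, (el, aname, dx, dy, dz) in enumerate(_BACKBONE_OFFSETS, start=1):
        atoms.append(Atom(serial=serial0 + i, name=aname, element=el,
                          coords=ca + np.array([dx, sign * dy, dz])))
    return Residue(ResidueKey(chain_id, resseq), name, atoms)


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ToyComplex:
    """Two poly-alanine-like chains; chain-B patch residues sit within the
    stated gap of the designated chain-A residues, all other chain-B
    residues are far away.  The constructed chain-A contact list is returned
    as ground truth."""
    rng = np.random.default_rng(spec.seed)
    patch = set(spec.contact_patch)
    serial = 1
    chain_a, chain_b = [], []
    jitter = rng.normal(0.0, 0.03, size=(2 * spec.n_residues, 3))
    for i in range(spec.n_residues):
        ca = np.array([CA_SPACING * i, 0.0, 0.0]) + jitter[i]
        res = _make_residue("A", i + 1, ca, serial)
        serial += 5
        chain_a.append(res)
    for i in range(spec.n_residues):
        gap = spec.inter_chain_gap if i in patch else spec.far_gap
        ca = np.array([CA_SPACING * i, gap, 0.0]) + jitter[spec.n_residues + i]
        res = _make_residue("B", i + 1, ca, serial, flip_y=True)
        serial += 5
        chain_b.append(res)
    structure = Structure([(1, {"A": chain_a, "B": chain_b})])
    assign_radii(structure)
    truth = [ResidueKey("A", i + 1) for i in sorted(patch)]
    return ToyComplex(structure=structure, interface=truth)


def make_pose_ensemble(receptor: Structure, ligand: Structure,
                       site: Sequence[ResidueKey], n_poses: int = 10,
                       displacement_step: float = 2.0,
                       seed: int = 0) -> PoseEnsemble:
    """Pose 0 is the original ligand placement; pose k is rigidly displaced
    by k*step along a seeded random unit vector oriented away from the
    receptor, so the ground-truth best pose is model 0."""
    if n_poses < 1:
        raise DataError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    away = (ligand.coordinates().mean(axis=0)
            - receptor.coordinates().mean(axis=0))
    norm = np.linalg.norm(away)
    away = away / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
    # random direction with a solid outward component
    while True:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if np.dot(v, away) >= 0.5:
            break
    poses = []
    for k in range(n_poses):
        moved = ligand.copy()
        moved.set_coordinates(moved.coordinates()
                              + k * displacement_step * v)
        poses.append((k, moved))
    return PoseEnsemble(receptor=receptor, poses=poses, site=list(site))


def default_triad_weights(seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0, N_BINS)


def _random_target(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def make_affinity_corpus(spec: AffinityCorpusSpec = AffinityCorpusSpec()
                         ) -> AffinityCorpus:
    """Random single/double mutants of the parent, with affinity equal to a
    fixed linear functional of the peptide triad vector plus Gaussian
    noise.  The noiseless ranking accompanies the records."""
    rng = np.random.default_rng(spec.seed)
    if spec.true_weights is None:
        weights = rng.normal(0.0, 1.0, N_BINS)
    else:
        weights = np.asarray(spec.true_weights, dtype=float)
        if weights.shape != (N_BINS,):
            raise DataError(f"true_weights must have length {N_BINS}")
    target = _random_target(rng)
    L = len(spec.parent)
    alphabet = list(AA_ALPHABET)
    seqs = []
    for _ in range(spec.n_records):
        seq = list(spec.parent)
        n_mut = int(rng.integers(1, 3))  # 1 or 2 point mutations
        positions = rng.choice(L, size=n_mut, replace=False)
        for p in positions:
            choices = [a for a in alphabet if a != seq[p]]
            seq[p] = choices[int(rng.integers(len(choices)))]
        seqs.append("".join(seq))
    true_vals = np.array([float(weights @ conjoint_triad(s)) for s in seqs])
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_records)
    records = [AffinityRecord(s, target, float(v + e))
               for s, v, e in zip(seqs, true_vals, noise)]
    ranking = list(np.argsort(true_vals, kind="stable"))
    return AffinityCorpus(records=records, true_affinities=true_vals,
                          true_ranking=[int(i) for i in ranking],
                          target_seq=target, weights=weights)


# ideal-helix cylindrical parameters per backbone atom:
# (radius A, phase offset deg, z offset A); 100 deg twist, 1.5 A rise
_HELIX_PARAMS = {
    "N": (1.56, -28.3, -0.70),
    "CA": (2.27, 0.0, 0.00),
    "C": (1.99, 26.3, 0.55),
    "O": (2.30, 38.0, 2.85),
}


def make_helix(n_residues: int = 12, chain_id: str = "A") -> Structure:
    """Idealized poly-alanine alpha-helical backbone (N, CA, C, O) whose
    O(i)...N(i+4) distances fall in hydrogen-bond range."""
    residues = []
    serial = 1
    for i in range(n_residues):
        base = math.radians(100.0 * i)
        atoms = []
        for name in ("N", "CA", "C", "O"):
            r, dphi, dz = _HELIX_PARAMS[name]
            phi = base + math.radians(dphi)
            coords = np.array([r * math.cos(phi), r * math.sin(phi),
                               1.5 * i + dz])
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              coords=coords))
            serial += 1
        residues.append(Residue(ResidueKey(chain_id, i + 1), "ALA", atoms))
    s = Structure([(1, {chain_id: residues})])
    assign_radii(s)
    return s


def make_trajectory(topology: Structure,
                    spec: TrajectorySpec = TrajectorySpec()) -> Trajectory:
    """Synthetic trajectory about the topology's coordinates.

    Harmonic mode (n_states == 0): each frame displaces every atom by an
    isotropic Gaussian whose per-coordinate sd is its residue's amplitude.
    Hopping mode (n_states >= 2): n_states displaced reference conformers
    are visited in contiguous blocks with small within-state noise.
    """
    rng = np.random.default_rng(spec.seed)
    ref = topology.coordinates()
    n_atoms = len(ref)
    residues = list(topology.residues())
    atoms_per_res = [len(r.atoms) for r in residues]
    if spec.per_residue_amplitudes:
        if len(spec.per_residue_amplitudes) != len(residues):
            raise DataError(
                f"need one amplitude per residue ({len(residues)}), got "
                f"{len(spec.per_residue_amplitudes)}"
            )
        amp = np.repeat(np.asarray(spec.per_residue_amplitudes, dtype=float),
                        atoms_per_res)
    else:
        amp = np.full(n_atoms, 0.5)
    times = np.arange(spec.n_frames) * spec.dt

    if spec.n_states >= 2:
        centers = [ref]
        for _ in range(spec.n_states - 1):
            offset = rng.normal(0.0, 1.0, size=(n_atoms, 3))
            offset *= spec.state_displacement / np.linalg.norm(offset, axis=1).mean()
            centers.append(ref + offset)
        state_of_frame = np.repeat(
            np.arange(spec.n_states),
            int(math.ceil(spec.n_frames / spec.n_states)))[: spec.n_frames]
        frames = np.array([
            centers[s] + rng.normal(0.0, 0.2, size=(n_atoms, 3))
            for s in state_of_frame
        ])
    else:
        noise = rng.normal(0.0, 1.0, size=(spec.n_frames, n_atoms, 3))
        frames = ref[None, :, :] + noise * amp[None, :, None]
    return Trajectory(topology=topology, frames=frames, times=times)


def write_multimodel_pdb(structures: Sequence[Structure], path) -> None:
    """Write a list of single-model structures as one multi-model PDB."""
    from .structure import Structure as S, write_pdb

    models = []
    for i, s in enumerate(structures, start=1):
        models.append((i, s.models[0][1]))
    write_pdb(S(models), path)
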