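"""Trajectory post-analysis.

Kabsch superposition, RMSD/RMSF series, radius of gyration, per-frame SASA
and hydrogen-bond series, Cartesian PCA, and Boltzmann-inversion free-energy
landscapes.  Internal math is in Angstrom; reported series follow the
conventional figure units (nm, nm^2, kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import DataError
from .sasa import SASAParams, compute_sasa, detect_hbonds
from .structure import ResidueKey, Structure, atom_mass

#: Boltzmann constant, kcal/(mol*K)
KB_KCAL = 0.0019872041

Selection = Union[None, str, Sequence[int]]


@dataclass
class Trajectory:
    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray   # ns, strictly increasing

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n_atoms = self.topology.n_atoms
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n_atoms, 3):
            raise DataError(
                f"frames shape {self.frames.shape} does not match "
                f"{n_atoms} topology atoms"
            )
        if len(self.times) != len(self.frames):
            raise DataError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DataError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray   # 3x3, proper
    translation: np.ndarray
    rmsd: float            # Angstrom


@dataclass
class FELGrid:
    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    free_energy: np.ndarray  # kcal/mol; occupied minimum is 0
    temperature: float
    cap: float


def _atom_info(topology: Structure):
    names, masses, reskeys = [], [], []
    for res in topology.residues():
        for a in res.atoms:
            names.append(a.name)
            masses.append(atom_mass(a.element))
            reskeys.append(res.key)
    return names, np.array(masses), reskeys


def resolve_selection(topology: Structure, selection: Selection) -> np.ndarray:
    """Atom indices for a selection: None = all atoms, a string = atoms of
    that name (e.g. "CA"), or an explicit index sequence."""
    names, _, _ = _atom_info(topology)
    if selection is None:
        return np.arange(len(names))
    if isinstance(selection, str):
        idx = np.array([i for i, n in enumerate(names) if n == selection])
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise DataError("empty atom selection")
    return idx


def kabsch_superpose(ref: np.ndarray, mobile: np.ndarray,
                     weights: Optional[np.ndarray] = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns the proper rotation (determinant +1, enforced by sign
    correction), translation, and the post-fit RMSD in Angstrom.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n,3); got {ref.shape} "
                         f"vs {mobile.shape}")
    if len(ref) < 3:
        raise ValueError("need at least 3 points to superpose")
    if weights is None:
        w = np.ones(len(ref))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    H = (w[:, None] * mob_c).T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if S[1] < 1e-12:
        import warnings
        warnings.warn("degenerate (collinear) point set; superposition is "
                      "best-effort")
    rotated = mob_c @ R.T
    rmsd = float(np.sqrt((w * np.sum((rotated - ref_c) ** 2, axis=1)).sum()))
    translation = (w[:, None] * ref).sum(axis=0) - R @ (w[:, None] * mobile).sum(axis=0)
    return SuperpositionResult(rotation=R, translation=translation, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, sup: SuperpositionResult) -> np.ndarray:
    return coords @ sup.rotation.T + sup.translation


def rmsd_series(t: Trajectory, selection: Selection = "CA",
                ref_frame: int = 0):
    """Per-frame superposed RMSD vs a reference frame, in (time ns, rmsd nm)."""
    if not 0 <= ref_frame < t.n_frames:
        raise ValueError(f"reference frame {ref_frame} out of range")
    idx = resolve_selection(t.topology, selection)
    ref = t.frames[ref_frame][idx]
    values = np.array([kabsch_superpose(ref, frame[idx]).rmsd
                       for frame in t.frames])
    return t.times.copy(), values / 10.0  # A -> nm


def _superpose_to_mean(coords: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Superpose every frame onto the evolving mean structure."""
    out = coords.copy()
    for _ in range(iterations):
        mean = out.mean(axis=0)
        out = np.array([apply_superposition(f, kabsch_superpose(mean, f))
                        for f in out])
    return out


def rmsf(t: Trajectory, selection: Selection = None) -> dict[ResidueKey, float]:
    """Per-residue RMSF (nm): frames are superposed to the mean structure,
    per-atom fluctuations are mass-weight averaged within each residue."""
    if t.n_frames < 2:
        raise DataError("need at least 2 frames for RMSF")
    idx = resolve_selection(t.topology, selection)
    _, masses, reskeys = _atom_info(t.topology)
    coords = _superpose_to_mean(t.frames[:, idx, :])
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    out: dict[ResidueKey, list] = {}
    for local_i, atom_i in enumerate(idx):
        out.setdefault(reskeys[atom_i], []).append(
            (masses[atom_i], per_atom[local_i]))
    result = {}
    for key, pairs in out.items():
        m = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        result[key] = float((m * v).sum() / m.sum()) / 10.0  # A -> nm
    return result


def radius_of_gyration(coords: np.ndarray,
                       masses: Optional[np.ndarray] = None) -> float:
    """Mass-weighted radius of gyration of one frame, reported in nm."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n,3) array")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    rg2 = (masses * np.sum((coords - com) ** 2, axis=1)).sum() / total
    return float(np.sqrt(rg2)) / 10.0  # A -> nm


def rg_series(t: Trajectory, selection: Selection = None):
    idx = resolve_selection(t.topology, selection)
    _, masses, _ = _atom_info(t.topology)
    values = np.array([radius_of_gyration(frame[idx], masses[idx])
                       for frame in t.frames])
    return t.times.copy(), values


def sasa_series(t: Trajectory, params: SASAParams = SASAParams(),
                selection: Selection = None, algorithm: str = "shrake"):
    """Per-frame total SASA of the selection, in nm^2."""
    idx = np.sort(resolve_selection(t.topology, selection))
    idx_set = set(int(i) for i in idx)
    # working sub-topology with only the selected atoms, empty residues dropped
    from .structure import Residue

    counter = 0
    new_chains: dict = {}
    for cid, residues in t.topology.copy().chains.items():
        kept_res = []
        for res in residues:
            kept_atoms = []
            for a in res.atoms:
                if counter in idx_set:
                    kept_atoms.append(a)
                counter += 1
            if kept_atoms:
                kept_res.append(Residue(res.key, res.name, kept_atoms))
        if kept_res:
            new_chains[cid] = kept_res
    sub = Structure([(1, new_chains)])
    values = []
    for frame in t.frames:
        sub.set_coordinates(frame[idx])
        values.append(compute_sasa(sub, params, algorithm).total / 100.0)
    return t.times.copy(), np.array(values)


def hbond_series(t: Trajectory, donors_from: Iterable[str],
                 acceptors_from: Iterable[str], d_max: float = 3.5,
                 angle_min: float = 120.0):
    """Per-frame hydrogen-bond count between two chain selections."""
    donors_from = list(donors_from)
    acceptors_from = list(acceptors_from)
    work = t.topology.copy()
    counts = []
    for frame in t.frames:
        work.set_coordinates(frame)
        counts.append(len(detect_hbonds(work, donors_from, acceptors_from,
                                        d_max=d_max, angle_min=angle_min)))
    return t.times.copy(), np.array(counts, dtype=int)


def pca(t: Trajectory, selection: Selection = "CA", n_components: int = 2):
    """Cartesian PCA of superposed frames.

    Returns (eigenvalues descending, per-frame projections on the top
    ``n_components`` components).  Each eigenvector's largest-magnitude
    entry is made positive so signs are reproducible.
    """
    if t.n_frames < 2:
        raise DataError("need at least 2 frames for PCA")
    idx = resolve_selection(t.topology, selection)
    coords = _superpose_to_mean(t.frames[:, idx, :])
    X = coords.reshape(t.n_frames, -1)
    X = X - X.mean(axis=0)
    cov = X.T @ X / (t.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    projections = X @ evecs[:, :n_components]
    return evals, projections


def free_energy_landscape(proj: np.ndarray, temperature: float = 300.0,
                          bins: int = 32) -> FELGrid:
    """Boltzmann inversion of the 2-D projection histogram.

    F = -kB*T*ln(P/P_max), so the modal bin is exactly 0; empty bins are
    set to the cap (max occupied value + kB*T) to keep the grid finite.
    """
    proj = np.asarray(proj, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2 or len(proj) == 0:
        raise ValueError("proj must be a non-empty (n,>=2) array")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    H, xedges, yedges = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins)
    kt = KB_KCAL * temperature
    occupied = H > 0
    F = np.full_like(H, np.nan)
    F[occupied] = -kt * np.log(H[occupied] / H.max())
    cap = float(np.nanmax(F) + kt)
    F[~occupied] = cap
    return FELGrid(pc1_edges=xedges, pc2_edges=yedges, free_energy=F,
                   temperature=temperature, cap=cap)
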