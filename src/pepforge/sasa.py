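"""Solvent-accessible surface area and interface analysis.

Two independent SASA algorithms (test-point quadrature on expanded spheres,
and accessible-arc integration over z-slices), per-residue aggregation,
bound/unbound delta-SASA at a binding site, interface-residue detection and
hydrogen-bond detection.

All areas are reported in A^2; probe and radii in A.  Both algorithms are
fully deterministic for fixed parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, SelectionError
from .structure import Atom, Residue, ResidueKey, Structure, select

__all__ = [
    "SASAParams", "SASAResult", "DeltaSASAReport", "HBond",
    "sasa_shrake_rupley", "sasa_lee_richards", "compute_sasa",
    "aggregate_per_residue", "delta_sasa", "detect_interface",
    "detect_hbonds", "fibonacci_sphere",
]


@dataclass(frozen=True)
class SASAParams:
    """Quadrature parameters for the SASA algorithms."""

    probe_radius: float = 1.4
    n_test_points: int = 100
    slice_width: float = 0.25
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_test_points < 12:
            raise ValueError("n_test_points must be >= 12")
        if self.slice_width <= 0:
            raise ValueError("slice_width must be > 0")


@dataclass
class SASAResult:
    per_atom: list[float]
    atom_keys: list[tuple[ResidueKey, str]]
    params: SASAParams
    per_residue: dict[ResidueKey, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.per_atom))


@dataclass
class DeltaSASAReport:
    site_residues: list[ResidueKey]
    unbound_site_sasa: float
    bound_site_sasa: float
    delta_sasa: float
    per_residue_delta: dict[ResidueKey, float]


@dataclass(frozen=True)
class HBond:
    donor: tuple[ResidueKey, str]
    acceptor: tuple[ResidueKey, str]
    distance: float
    angle: Optional[float] = None


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle
    lattice), shape (n, 3)."""
    k = np.arange(n, dtype=float) + 0.5
    cos_theta = 1.0 - 2.0 * k / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta)
    )


def _collect_atoms(s: Structure, params: SASAParams, model: int = 0):
    atoms: list[Atom] = []
    keys: list[tuple[ResidueKey, str]] = []
    for res in s.residues(model):
        for a in res.atoms:
            if not params.include_hydrogens and a.element.upper() == "H":
                continue
            atoms.append(a)
            keys.append((res.key, a.name))
    if not atoms:
        raise EmptyStructureError("no atoms left after hydrogen filtering")
    for a in atoms:
        if a.vdw_radius is None or a.vdw_radius <= 0:
            raise ValueError(
                f"atom {a.name} has no vdW radius; call assign_radii first"
            )
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    return atoms, keys, coords, radii


def sasa_shrake_rupley(s: Structure, params: SASAParams = SASAParams(),
                       model: int = 0) -> SASAResult:
    """Test-point SASA: for each atom, points on the probe-expanded sphere
    not buried inside any other expanded sphere are accessible."""
    _, keys, coords, radii = _collect_atoms(s, params, model)
    expanded = radii + params.probe_radius
    unit = fibonacci_sphere(params.n_test_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        ri = expanded[i]
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + max_r)
                if j != i]
        pts = coords[i] + ri * unit
        accessible = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * math.pi * ri**2
    result = SASAResult(per_atom=areas.tolist(), atom_keys=keys, params=params)
    return aggregate_per_residue(result)


def _merge_arcs(intervals: list[tuple[float, float]]) -> float:
    """Total length of the union of angular intervals on [0, 2pi)."""
    segs = []
    two_pi = 2.0 * math.pi
    for a, b in intervals:
        width = b - a
        if width >= two_pi:
            return two_pi
        a %= two_pi
        b = a + width
        if b <= two_pi:
            segs.append((a, b))
        else:  # wraps around
            segs.append((a, two_pi))
            segs.append((0.0, b - two_pi))
    segs.sort()
    covered = 0.0
    cur_a, cur_b = None, None
    for a, b in segs:
        if cur_a is None:
            cur_a, cur_b = a, b
        elif a <= cur_b:
            cur_b = max(cur_b, b)
        else:
            covered += cur_b - cur_a
            cur_a, cur_b = a, b
    if cur_a is not None:
        covered += cur_b - cur_a
    return min(covered, two_pi)


def sasa_lee_richards(s: Structure, params: SASAParams = SASAParams(),
                      model: int = 0) -> SASAResult:
    """Slice SASA: integrate accessible arc length over z-slices.

    For a sphere of radius R the lateral area between z and z+dz is
    2*pi*R*dz, so each slice contributes (accessible angle) * R * dz.
    """
    _, keys, coords, radii = _collect_atoms(s, params, model)
    expanded = radii + params.probe_radius
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        ri_sphere = expanded[i]
        zi = coords[i][2]
        nbrs = []
        for j in tree.query_ball_point(coords[i], ri_sphere + max_r):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < ri_sphere + expanded[j]:
                nbrs.append(j)
        n_slices = max(1, int(math.ceil(2.0 * ri_sphere / params.slice_width)))
        dz = 2.0 * ri_sphere / n_slices
        area = 0.0
        for k in range(n_slices):
            z = zi - ri_sphere + (k + 0.5) * dz
            rc2 = ri_sphere**2 - (z - zi) ** 2
            if rc2 <= 0:
                continue
            rc = math.sqrt(rc2)
            intervals = []
            buried = False
            for j in nbrs:
                dzj = z - coords[j][2]
                rj_sphere = expanded[j]
                if abs(dzj) >= rj_sphere:
                    continue
                rj = math.sqrt(rj_sphere**2 - dzj**2)
                dx = coords[j][0] - coords[i][0]
                dy = coords[j][1] - coords[i][1]
                d = math.hypot(dx, dy)
                if d >= rc + rj:
                    continue
                if d + rc <= rj:
                    buried = True
                    break
                if d + rj <= rc:
                    continue
                alpha = math.acos(
                    max(-1.0, min(1.0, (d * d + rc * rc - rj * rj) / (2.0 * d * rc)))
                )
                beta = math.atan2(dy, dx)
                intervals.append((beta - alpha, beta + alpha))
            if buried:
                continue
            accessible = 2.0 * math.pi - _merge_arcs(intervals)
            area += accessible * ri_sphere * dz
        areas[i] = area
    result = SASAResult(per_atom=areas.tolist(), atom_keys=keys, params=params)
    return aggregate_per_residue(result)


_ALGORITHMS = {"shrake": sasa_shrake_rupley, "lee": sasa_lee_richards}


def compute_sasa(s: Structure, params: SASAParams = SASAParams(),
                 algorithm: str = "shrake", model: int = 0) -> SASAResult:
    try:
        fn = _ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(f"unknown SASA algorithm '{algorithm}'") from None
    return fn(s, params, model=model)


def aggregate_per_residue(result: SASAResult) -> SASAResult:
    """Fill ``per_residue`` by summing member-atom areas."""
    per_res: dict[ResidueKey, float] = {}
    for (key, _), area in zip(result.atom_keys, result.per_atom):
        per_res[key] = per_res.get(key, 0.0) + area
    result.per_residue = per_res
    return result


def delta_sasa(
    complex_structure: Structure,
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    site: Sequence[ResidueKey],
    params: SASAParams = SASAParams(),
    algorithm: str = "shrake",
) -> DeltaSASAReport:
    """Buried surface at ``site``: receptor-alone SASA minus in-complex SASA.

    ``site`` residues must belong to the receptor chains.
    """
    receptor_chains = sorted(set(receptor_chains))
    ligand_chains = sorted(set(ligand_chains))
    overlap = set(receptor_chains) & set(ligand_chains)
    if overlap:
        raise SelectionError(
            f"receptor and ligand chain sets overlap: {sorted(overlap)}"
        )
    receptor = select(complex_structure, receptor_chains)
    receptor_keys = {r.key for r in receptor.residues()}
    bad = [k for k in site if k not in receptor_keys]
    if bad:
        raise SelectionError(f"site residue {bad[0]} not in receptor chains")
    site = list(site)
    if not site:
        warnings.warn("empty binding site: delta-SASA report is all zeros")
        return DeltaSASAReport(site_residues=[], unbound_site_sasa=0.0,
                               bound_site_sasa=0.0, delta_sasa=0.0,
                               per_residue_delta={})

    both = select(complex_structure, receptor_chains + ligand_chains)
    unbound = compute_sasa(receptor, params, algorithm)
    bound = compute_sasa(both, params, algorithm)
    per_delta = {
        k: unbound.per_residue.get(k, 0.0) - bound.per_residue.get(k, 0.0)
        for k in site
    }
    unbound_site = sum(unbound.per_residue.get(k, 0.0) for k in site)
    bound_site = sum(bound.per_residue.get(k, 0.0) for k in site)
    return DeltaSASAReport(
        site_residues=site,
        unbound_site_sasa=unbound_site,
        bound_site_sasa=bound_site,
        delta_sasa=unbound_site - bound_site,
        per_residue_delta=per_delta,
    )


def detect_interface(report: DeltaSASAReport,
                     per_residue_cutoff: float = 1.0) -> list[ResidueKey]:
    """Residues whose per-residue buried area meets the cutoff, in key order."""
    hits = [k for k, d in report.per_residue_delta.items()
            if d >= per_residue_cutoff]
    return sorted(hits)


# ---------------------------------------------------------------------------
# hydrogen bonds

#: side-chain donor heavy atoms (backbone N is a donor for all but PRO)
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"},
}
#: side-chain acceptor heavy atoms (backbone O/OXT accept for all)
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}


def _donor_atoms(res: Residue):
    names = set(_SIDECHAIN_DONORS.get(res.name, ()))
    if res.name != "PRO":
        names.add("N")
    return [a for a in res.atoms if a.name in names]


def _acceptor_atoms(res: Residue):
    names = set(_SIDECHAIN_ACCEPTORS.get(res.name, ())) | {"O", "OXT"}
    return [a for a in res.atoms if a.name in names]


def _attached_hydrogens(res: Residue, donor: Atom, max_bond: float = 1.25):
    return [a for a in res.atoms
            if a.element.upper() == "H"
            and np.linalg.norm(a.coords - donor.coords) <= max_bond]


def detect_hbonds(
    s: Structure,
    donors_from: Iterable[str],
    acceptors_from: Iterable[str],
    d_max: float = 3.5,
    angle_min: float = 120.0,
    min_sequence_separation: int = 2,
    model: int = 0,
) -> list[HBond]:
    """Geometric hydrogen bonds between two chain selections.

    Donor N/O heavy atoms (residue-template tables) within ``d_max`` of an
    acceptor N/O; when explicit hydrogens are attached to the donor the
    D-H...A angle (at H) must reach ``angle_min`` degrees, otherwise the
    distance criterion alone applies.  Same-chain pairs closer in sequence
    than ``min_sequence_separation`` (covalently linked neighbors) are
    skipped.
    """
    donors_from = set(donors_from)
    acceptors_from = set(acceptors_from)
    chains = s.models[model][1]
    for cid in donors_from | acceptors_from:
        if cid not in chains:
            raise SelectionError(f"chain '{cid}' not present")

    donors = []
    for cid in sorted(donors_from):
        for res in chains[cid]:
            for a in _donor_atoms(res):
                donors.append((res, a))
    acceptors = []
    for cid in sorted(acceptors_from):
        for res in chains[cid]:
            for a in _acceptor_atoms(res):
                acceptors.append((res, a))

    bonds = []
    for dres, datom in donors:
        hydrogens = _attached_hydrogens(dres, datom)
        for ares, aatom in acceptors:
            if ares.key.chain_id == dres.key.chain_id and \
                    abs(ares.key.resseq - dres.key.resseq) < min_sequence_separation:
                continue
            dist = float(np.linalg.norm(datom.coords - aatom.coords))
            if dist > d_max:
                continue
            angle = None
            if hydrogens:
                best = -1.0
                for h in hydrogens:
                    v1 = datom.coords - h.coords
                    v2 = aatom.coords - h.coords
                    cosang = float(np.dot(v1, v2) /
                                   (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    best = max(best, math.degrees(math.acos(
                        max(-1.0, min(1.0, cosang)))))
                if best < angle_min:
                    continue
                angle = best
            bonds.append(HBond(donor=(dres.key, datom.name),
                               acceptor=(ares.key, aatom.name),
                               distance=dist, angle=angle))
    bonds.sort(key=lambda b: (b.donor[0], b.donor[1], b.acceptor[0], b.acceptor[1]))
    return bonds
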