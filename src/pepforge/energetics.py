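"""Docked-pose rescoring by interface burial and the MM-GBSA ledger.

Scores each pose of an ensemble by the buried binding-site surface
(unbound minus bound SASA), selects the largest-burial pose, and keeps the
energy-decomposition bookkeeping: gas-phase total = electrostatic + van der
Waals, solvation total = polar (GB) + non-polar (gamma * SASA), enthalpy =
gas + solvation, binding free energy = enthalpy - entropy term.  The force
field and GB terms themselves are consumed from external tables, not
computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .sasa import SASAParams, compute_sasa
from .structure import ResidueKey, Structure, merge

#: default nonpolar surface coefficient, kcal/(mol*A^2)
DEFAULT_GAMMA = 0.0072


@dataclass
class PoseEnsemble:
    receptor: Structure
    poses: list[tuple[int, Structure]]  # (model_id, ligand placement)
    site: list[ResidueKey]

    def __post_init__(self):
        ids = [mid for mid, _ in self.poses]
        if len(ids) != len(set(ids)):
            raise DataError("pose model_ids must be unique")


@dataclass
class PoseScore:
    model_id: int
    unbound_sasa: float
    bound_sasa: float

    @property
    def delta_sasa(self) -> float:
        return self.unbound_sasa - self.bound_sasa


@dataclass
class EnergyComponents:
    EEL: float = 0.0
    VDWAALS: float = 0.0
    EGB: float = 0.0
    ESURF: float = 0.0
    entropy_term_TdS: float = 0.0

    def __post_init__(self):
        vals = (self.EEL, self.VDWAALS, self.EGB, self.ESURF,
                self.entropy_term_TdS)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("energy components must be finite")


@dataclass
class EnergyDecomposition:
    components: EnergyComponents
    GGAS: float
    GSOLV: float
    enthalpy_dH: float
    dG_binding: float
    gamma: float = DEFAULT_GAMMA
    #: optional raw totals (G_complex, G_receptor, G_ligand); when set,
    #: their difference is an alternative route to dG
    raw_totals: Optional[tuple[float, float, float]] = None

    @property
    def dG_from_totals(self) -> Optional[float]:
        if self.raw_totals is None:
            return None
        g_complex, g_receptor, g_ligand = self.raw_totals
        return g_complex - (g_receptor + g_ligand)


def score_poses(ensemble: PoseEnsemble, params: SASAParams = SASAParams(),
                algorithm: str = "shrake") -> list[PoseScore]:
    """One buried-surface score per pose.

    The unbound (receptor-alone) site SASA is computed once and shared by
    every pose of the ensemble.
    """
    if not ensemble.poses:
        raise DataError("pose ensemble is empty")
    if not ensemble.site:
        raise DataError("binding site is empty")
    receptor_keys = {r.key for r in ensemble.receptor.residues()}
    bad = [k for k in ensemble.site if k not in receptor_keys]
    if bad:
        raise DataError(f"site residue {bad[0]} not in receptor")
    unbound_res = compute_sasa(ensemble.receptor, params, algorithm).per_residue
    unbound = sum(unbound_res.get(k, 0.0) for k in ensemble.site)
    scores = []
    for mid, ligand in ensemble.poses:
        complex_structure = merge(ensemble.receptor, ligand)
        bound_res = compute_sasa(complex_structure, params, algorithm).per_residue
        bound = sum(bound_res.get(k, 0.0) for k in ensemble.site)
        scores.append(PoseScore(model_id=mid, unbound_sasa=unbound,
                                bound_sasa=bound))
    return scores


def select_best_pose(scores: Sequence[PoseScore]) -> PoseScore:
    """Pose with maximal buried surface; ties go to the lowest model_id."""
    if not scores:
        raise DataError("no pose scores to select from")
    return max(scores, key=lambda s: (s.delta_sasa, -s.model_id))


def esurf_from_sasa(sasa: float, gamma: float = DEFAULT_GAMMA) -> float:
    """Non-polar solvation term: gamma * SASA (kcal/mol)."""
    if sasa < 0:
        raise ValueError(f"SASA must be >= 0, got {sasa}")
    return gamma * sasa


def decompose(c: EnergyComponents, entropy_term_TdS: Optional[float] = None,
              gamma: float = DEFAULT_GAMMA,
              raw_totals: Optional[tuple[float, float, float]] = None,
              ) -> EnergyDecomposition:
    """Close the decomposition ledger over the given components.

    GGAS = EEL + VDWAALS; GSOLV = EGB + ESURF; dH = GGAS + GSOLV;
    dG = dH - entropy term (defaults to the component's value, itself 0
    unless supplied).
    """
    tds = c.entropy_term_TdS if entropy_term_TdS is None else entropy_term_TdS
    ggas = c.EEL + c.VDWAALS
    gsolv = c.EGB + c.ESURF
    dh = ggas + gsolv
    return EnergyDecomposition(
        components=EnergyComponents(c.EEL, c.VDWAALS, c.EGB, c.ESURF, tds),
        GGAS=ggas, GSOLV=gsolv, enthalpy_dH=dh, dG_binding=dh - tds,
        gamma=gamma, raw_totals=raw_totals,
    )


_REQUIRED_COLUMNS = ("EEL", "VDWAALS", "EGB", "ESURF")


def read_energy_table(path) -> list[tuple[int, EnergyComponents]]:
    """Parse a whitespace- or comma-delimited per-frame component table.

    The header must name EEL, VDWAALS, EGB and ESURF (any order, case
    insensitive); a FRAME column is honored when present, otherwise frames
    are numbered from 0.  Unknown columns are ignored with a warning.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [str(c).strip().upper() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"energy table missing required column '{missing[0]}'")
    known = set(_REQUIRED_COLUMNS) | {"FRAME"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring unknown energy-table column(s): {extra}")
    frames = (df["FRAME"].astype(int).tolist() if "FRAME" in df.columns
              else list(range(len(df))))
    out = []
    for i, row in zip(frames, df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        out.append((i, EnergyComponents(
            EEL=float(rowd["EEL"]), VDWAALS=float(rowd["VDWAALS"]),
            EGB=float(rowd["EGB"]), ESURF=float(rowd["ESURF"]))))
    return out


def read_pose_ensemble(receptor: Structure, poses_path,
                       site: Sequence[ResidueKey]) -> PoseEnsemble:
    """Load a multi-model PDB of ligand placements as a pose ensemble."""
    from .structure import read_pdb

    multi = read_pdb(poses_path)
    poses = [(mid, Structure([(mid, chains)])) for mid, chains in multi.models]
    return PoseEnsemble(receptor=receptor, poses=poses, site=list(site))
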