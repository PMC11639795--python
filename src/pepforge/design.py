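"""Interface-derived peptide assembly and saturation mutagenesis.

Extracts contiguous binding segments from an interface residue list, sizes
a flexible Gly-Ser linker from the inter-segment gap, concatenates segments
into a designed peptide, and enumerates the exhaustive single-point mutant
library (19 substitutions per position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import SelectionError, SequenceError
from .structure import STANDARD_AA, ResidueKey, Structure

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard letters, alphabetical

#: extended-chain CA-CA step used to size linkers, Angstrom
CA_STEP = 3.8


def validate_sequence(seq: str) -> str:
    if not seq:
        raise SequenceError("sequence is empty")
    bad = sorted(set(seq) - STANDARD_AA)
    if bad:
        raise SequenceError(f"non-standard residue letter(s): {bad}")
    return seq


@dataclass
class BindingSegment:
    chain_id: str
    start: ResidueKey
    end: ResidueKey
    sequence: str


@dataclass
class DesignedPeptide:
    segments: list[BindingSegment]
    linker: str
    sequence: str
    provenance: list[str]  # per-position: 'segment<i>' or 'linker'


@dataclass(frozen=True)
class Variant:
    position: int  # 1-based
    original: str
    substituted: str
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.original}{self.position}{self.substituted}"


@dataclass
class MutantLibrary:
    parent: str
    variants: list[Variant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def extract_segments(
    interface: Iterable[ResidueKey],
    s: Structure,
    min_len: int = 1,
) -> list[BindingSegment]:
    """Maximal runs of chain-consecutive interface residues of length
    >= ``min_len``, ordered by chain then start key.

    Consecutive means adjacent in the chain's ResidueKey order, so
    insertion-code residues (53A between 53 and 54) stay inside a run.
    """
    interface = set(interface)
    if not interface:
        return []
    res_keys = {r.key for r in s.residues()}
    missing = sorted(k for k in interface if k not in res_keys)
    if missing:
        raise SelectionError(f"interface residue {missing[0]} not in structure")

    segments: list[BindingSegment] = []
    for cid in sorted(s.chains):
        residues = s.chains[cid]
        run: list = []
        for idx, res in enumerate(residues):
            if res.key in interface:
                if run and run[-1][0] != idx - 1:
                    _close_run(run, cid, segments, min_len)
                    run = []
                run.append((idx, res))
            elif run:
                _close_run(run, cid, segments, min_len)
                run = []
        if run:
            _close_run(run, cid, segments, min_len)
    return segments


def _close_run(run, cid, segments, min_len):
    if len(run) >= min_len:
        residues = [r for _, r in run]
        segments.append(BindingSegment(
            chain_id=cid,
            start=residues[0].key,
            end=residues[-1].key,
            sequence="".join(r.one_letter for r in residues),
        ))


def choose_linker(gap: float) -> str:
    """Flexible linker spanning ``gap`` Angstrom: n = ceil(gap / 3.8)
    residues (minimum 1), taken from the repeating pattern "GS"."""
    if gap <= 0:
        raise ValueError(f"gap must be > 0, got {gap}")
    n = max(1, math.ceil(gap / CA_STEP))
    pattern = "GS"
    return (pattern * (n // 2 + 1))[:n]


def segment_gap(a: BindingSegment, b: BindingSegment, s: Structure) -> float:
    """Distance between the nearest terminal CA atoms of two segments."""
    res_map = s.residue_map()

    def _ca(key):
        res = res_map.get(key)
        atom = res.atom("CA") if res else None
        if atom is None:
            raise SelectionError(f"no CA atom for residue {key}")
        return atom.coords

    ends_a = [_ca(a.start), _ca(a.end)]
    ends_b = [_ca(b.start), _ca(b.end)]
    return float(min(np.linalg.norm(p - q) for p in ends_a for q in ends_b))


def assemble(segments: Sequence[BindingSegment], linker: str) -> DesignedPeptide:
    """Join segments with ``linker`` between consecutive segments."""
    if not segments:
        raise ValueError("need at least one segment")
    for seg in segments:
        validate_sequence(seg.sequence)
    if linker:
        validate_sequence(linker)
    parts: list[str] = []
    provenance: list[str] = []
    for i, seg in enumerate(segments):
        if i > 0 and linker:
            parts.append(linker)
            provenance.extend(["linker"] * len(linker))
        parts.append(seg.sequence)
        provenance.extend([f"segment{i}"] * len(seg.sequence))
    sequence = "".join(parts)
    return DesignedPeptide(segments=list(segments), linker=linker,
                           sequence=sequence, provenance=provenance)


def saturation_mutagenesis(parent: str) -> MutantLibrary:
    """Exhaustive single-point mutants: 19 substitutions per position,
    ordered by position then substituted letter (alphabetical)."""
    validate_sequence(parent)
    variants = []
    for pos, orig in enumerate(parent, start=1):
        for sub in AA_ALPHABET:
            if sub == orig:
                continue
            seq = parent[: pos - 1] + sub + parent[pos:]
            variants.append(Variant(position=pos, original=orig,
                                    substituted=sub, sequence=seq))
    return MutantLibrary(parent=parent, variants=variants)


def library_to_fasta(lib: MutantLibrary, path) -> None:
    with open(path, "w") as fh:
        for v in lib.variants:
            fh.write(f">{v.name}\n{v.sequence}\n")


def library_to_csv(lib: MutantLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("name,position,original,substituted,sequence\n")
        for v in lib.variants:
            fh.write(f"{v.name},{v.position},{v.original},{v.substituted},{v.sequence}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (header, sequence) pairs."""
    entries: list[tuple[str, str]] = []
    header: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, "".join(chunks)))
                header = line[1:].strip()
                chunks = []
            else:
                chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries
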