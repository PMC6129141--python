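"""Binding-site sequence-conservation scanning of ε-subunit alignments.

Workflow: read an aligned FASTA or Clustal multiple sequence alignment of
ε subunits, drop redundant sequences (≥ 95% pairwise identity by default,
greedy first-come clustering), map alignment columns onto the *Bacillus* PS3
residue numbering via the PS3 reference row, and classify each sequence's
binding-site positions.

The ligand-binding set is E83, R92, R99, R122, R126 (PS3 numbering);
positions 103 and 115 are the affinity-modulating pair.  A sequence with the
binding set fully conserved but a substitution at 103 and/or 115 is
hypothesised to bind ATP with increased affinity (the behaviour demonstrated
by the R103A/R115A mutant); a substitution at 103/115 co-occurring with any
binding-set substitution is indeterminate; everything else is baseline.
Conservation means exact residue identity — no similarity groups.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import AlignIO

__all__ = [
    "Alignment",
    "PositionMap",
    "BindingSiteProfile",
    "BINDING_SET_POSITIONS",
    "MODULATOR_POSITIONS",
    "PS3_BINDING_RESIDUES",
    "read_alignment",
    "remove_redundant",
    "pairwise_identity",
    "build_position_map",
    "profile_binding_sites",
]

# PS3-numbered positions: the conserved ligand-binding set and the two
# affinity-modulating positions.
BINDING_SET_POSITIONS = (83, 92, 99, 122, 126)
MODULATOR_POSITIONS = (103, 115)
ALL_POSITIONS = tuple(sorted(BINDING_SET_POSITIONS + MODULATOR_POSITIONS))
PS3_BINDING_RESIDUES: Mapping[int, str] = {83: "E", 92: "R", 99: "R",
                                           103: "R", 115: "R", 122: "R", 126: "R"}


@dataclass(frozen=True)
class Alignment:
    """Uniform-length gapped records with unique ids, in file order."""

    ids: tuple[str, ...]
    descriptions: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment record ids must be unique")
        if self.sequences:
            length = len(self.sequences[0])
            for rid, seq in zip(self.ids, self.sequences):
                if len(seq) != length:
                    raise ValueError(f"ragged alignment: record {rid!r} has "
                                     f"length {len(seq)} != {length}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def record(self, rid: str) -> str:
        try:
            return self.sequences[self.ids.index(rid)]
        except ValueError as exc:
            raise KeyError(f"record {rid!r} not in alignment") from exc


def read_alignment(path: str, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA (``"fasta"``) or Clustal (``"clustal"``) file.

    Clustal consensus lines are ignored by the parser.  Ragged alignments
    raise, naming the offending record.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"format must be 'fasta' or 'clustal', got {fmt!r}")
    msa = AlignIO.read(path, fmt)
    return Alignment(
        ids=tuple(rec.id for rec in msa),
        descriptions=tuple(rec.description for rec in msa),
        sequences=tuple(str(rec.seq).upper() for rec in msa),
    )


def pairwise_identity(seq_a: str, seq_b: str,
                      denominator: str = "mutual") -> float:
    """Fractional identity between two gapped rows of equal length.

    With ``denominator="mutual"`` (default) identity = matches / columns where
    both rows are non-gap, 0 when no such column exists; ``"length"`` divides
    by the full alignment length instead.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    matches = 0
    mutual = 0
    for a, b in zip(seq_a, seq_b):
        if a != "-" and b != "-":
            mutual += 1
            if a == b:
                matches += 1
    if denominator == "mutual":
        return matches / mutual if mutual else 0.0
    if denominator == "length":
        return matches / len(seq_a) if seq_a else 0.0
    raise ValueError("denominator must be 'mutual' or 'length'")


def remove_redundant(aln: Alignment, threshold: float = 0.95,
                     denominator: str = "mutual") -> Alignment:
    """Greedy redundancy filter in input order.

    A record is kept iff its identity to every already-kept record is below
    ``threshold``; the first representative of each cluster survives.
    Idempotent.
    """
    if len(aln) < 1:
        raise ValueError("alignment must have >= 1 record")
    kept: list[int] = []
    for i, seq in enumerate(aln.sequences):
        if all(pairwise_identity(seq, aln.sequences[j], denominator) < threshold
               for j in kept):
            kept.append(i)
    return Alignment(
        ids=tuple(aln.ids[i] for i in kept),
        descriptions=tuple(aln.descriptions[i] for i in kept),
        sequences=tuple(aln.sequences[i] for i in kept),
    )


@dataclass(frozen=True)
class PositionMap:
    """Bijection between PS3 residue numbers and alignment columns (1-based)."""

    reference_id: str
    position_to_column: Mapping[int, int]
    column_to_position: Mapping[int, int]


def build_position_map(aln: Alignment, reference_id: str,
                       offset: int = 0) -> PositionMap:
    """Map PS3 residue numbers onto alignment columns via the reference row.

    The k-th non-gap column of the reference corresponds to PS3 position
    ``k + offset`` (offset 0 for a reference starting at residue 1).  Both
    directions are strictly increasing and mutually inverse.
    """
    ref = aln.record(reference_id)
    pos_to_col: dict[int, int] = {}
    col_to_pos: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(ref, start=1):
        if ch != "-":
            k += 1
            pos = k + offset
            pos_to_col[pos] = col
            col_to_pos[col] = pos
    if not pos_to_col:
        raise ValueError(f"reference {reference_id!r} is all gaps")
    return PositionMap(reference_id=reference_id,
                       position_to_column=pos_to_col,
                       column_to_position=col_to_pos)


@dataclass(frozen=True)
class BindingSiteProfile:
    """Residues of one sequence at the PS3 binding-site positions, with flags."""

    sequence_id: str
    residues: Mapping[int, str]  # PS3 position -> residue (or '-')
    binding_set_conserved: bool
    pos103_substituted: bool
    pos115_substituted: bool
    confound: bool  # any binding-set substitution
    hypothesis: str  # increased-affinity | baseline | indeterminate
    caveats: tuple[str, ...] = ()


def profile_binding_sites(aln: Alignment, pmap: PositionMap,
                          positions: Sequence[int] = ALL_POSITIONS,
                          reference_residues: Mapping[int, str] = PS3_BINDING_RESIDUES,
                          ) -> list[BindingSiteProfile]:
    """Classify each sequence's binding-site positions.

    A gap at any scored position counts as a substitution.  The hypothesis is
    total: exactly one of ``increased-affinity`` (substitution at 103/115 with
    the binding set fully conserved), ``indeterminate`` (103/115 substitution
    confounded by a binding-set substitution) or ``baseline``.
    """
    for pos in positions:
        if pos not in pmap.position_to_column:
            raise ValueError(f"PS3 position {pos} not covered by the position map")
    profiles = []
    for rid, seq in zip(aln.ids, aln.sequences):
        residues = {pos: seq[pmap.position_to_column[pos] - 1] for pos in positions}
        set_conserved = all(
            residues.get(pos, "-") == reference_residues[pos]
            for pos in BINDING_SET_POSITIONS if pos in positions
        )
        sub103 = residues.get(103, reference_residues[103]) != reference_residues[103]
        sub115 = residues.get(115, reference_residues[115]) != reference_residues[115]
        confound = not set_conserved
        caveats: list[str] = []
        if sub103 or sub115:
            if set_conserved:
                hypothesis = "increased-affinity"
                if residues.get(103) == "H":
                    caveats.append(
                        "histidine at 103: the imidazole ring is titratable near "
                        "neutral pH, so the effect may be pH-dependent"
                    )
            else:
                hypothesis = "indeterminate"
                changed = [f"{reference_residues[p]}{p}{residues[p]}"
                           for p in BINDING_SET_POSITIONS
                           if p in positions and residues[p] != reference_residues[p]]
                caveats.append(
                    f"binding-set substitution(s) {', '.join(changed)} confound "
                    f"the 103/115 effect"
                )
        else:
            hypothesis = "baseline"
        profiles.append(BindingSiteProfile(
            sequence_id=rid, residues=residues,
            binding_set_conserved=set_conserved,
            pos103_substituted=sub103, pos115_substituted=sub115,
            confound=confound, hypothesis=hypothesis, caveats=tuple(caveats),
        ))
    return profiles
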