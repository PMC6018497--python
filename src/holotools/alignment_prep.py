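"""Gap-column filtering, per-group residue frequency profiles and consensus.

These are the shared substrate of the plant-like-site scan and the
ancestral-sequence deduction: profiles are computed per functional group
(plant BAS, plant CAS, animal LAS) or per animal clade, always on the
gap-filtered alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_io import (
    AMINO_ACIDS,
    GroupAssignment,
    ProteinAlignment,
)

#: residue -> row index in profile count matrices
RESIDUE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_MAX_GAP_FRAC = Fraction(2, 3)


def as_fraction(x) -> Fraction:
    """Exact rational for a threshold given as Fraction, int, or decimal float.

    Floats are snapped to the nearest simple rational (denominator <= 1e6),
    so 0.2 means exactly 1/5 and float(2/3) means exactly 2/3; boundary
    comparisons against count ratios are then exact.
    """
    if isinstance(x, Fraction):
        return x
    return Fraction(x).limit_denominator(1_000_000)


@dataclass(frozen=True)
class ColumnMap:
    """Original 0-based column indices surviving the gap filter."""

    kept_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        cols = self.kept_columns
        if any(a >= b for a, b in zip(cols, cols[1:])):
            raise ValueError("kept_columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.kept_columns)

    def to_original(self, filtered_col: int) -> int:
        return self.kept_columns[filtered_col]


def filter_gap_columns(
    aln: ProteinAlignment,
    max_gap_frac: Fraction | float = DEFAULT_MAX_GAP_FRAC,
) -> tuple[ProteinAlignment, ColumnMap]:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_frac``.

    The gap fraction of a column is (#'-' + #'X') / #rows: 'X' carries no
    residue identity so it counts as missing. Comparison is exact rational
    arithmetic, so a 3-row column with exactly 2 gaps (fraction 2/3) is
    retained under the default threshold.
    """
    threshold = as_fraction(max_gap_frac)
    if not 0 < threshold <= 1:
        raise ValueError(f"max_gap_frac must be in (0, 1], got {threshold}")
    n_rows = aln.n_sequences
    kept = []
    for col in range(aln.length):
        gaps = sum(1 for row in aln.rows if row[col] in "-X")
        if Fraction(gaps, n_rows) <= threshold:
            kept.append(col)
    if not kept:
        raise ValueError("gap filter removed every column")
    rows = tuple("".join(row[c] for c in kept) for row in aln.rows)
    return ProteinAlignment(ids=aln.ids, rows=rows), ColumnMap(tuple(kept))


@dataclass(frozen=True)
class PositionProfile:
    """Per-column residue counts for one group of sequences.

    ``counts`` is a (n_columns, 20) integer matrix; ``n_effective`` counts
    the non-gap, non-'X' residues per column. Frequencies are
    counts / n_effective — gaps and 'X' are excluded from numerator and
    denominator alike — so per column they sum to 1 (or are all 0 when the
    column is entirely missing in the group).
    """

    group: str
    counts: np.ndarray
    n_effective: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (self.n_effective.size, 20):
            raise ValueError("counts must be (n_columns, 20)")
        if np.any(self.counts.sum(axis=1) != self.n_effective):
            raise ValueError("n_effective must equal per-column count sums")

    @property
    def n_columns(self) -> int:
        return int(self.n_effective.size)

    def frequency(self, col: int, residue: str) -> float:
        n = int(self.n_effective[col])
        if n == 0:
            return 0.0
        return int(self.counts[col, RESIDUE_INDEX[residue]]) / n

    def frequency_exact(self, col: int, residue: str) -> Fraction:
        n = int(self.n_effective[col])
        if n == 0:
            return Fraction(0)
        return Fraction(int(self.counts[col, RESIDUE_INDEX[residue]]), n)

    def frequencies(self, col: int) -> dict[str, float]:
        n = int(self.n_effective[col])
        if n == 0:
            return {aa: 0.0 for aa in AMINO_ACIDS}
        return {aa: int(self.counts[col, i]) / n for aa, i in RESIDUE_INDEX.items()}

    def modal_residue(self, col: int) -> str | None:
        """Strict mode of the column, or None on tie / empty column."""
        if self.n_effective[col] == 0:
            return None
        row = self.counts[col]
        best = int(row.max())
        winners = np.flatnonzero(row == best)
        if winners.size != 1:
            return None
        return AMINO_ACIDS[int(winners[0])]


def group_profile(
    aln: ProteinAlignment,
    groups: GroupAssignment,
    functional_group: str | None = None,
    animal_clade: str | None = None,
) -> PositionProfile:
    """Residue-count profile over the members of one group or clade."""
    if (functional_group is None) == (animal_clade is None):
        raise ValueError("select exactly one of functional_group / animal_clade")
    if functional_group is not None:
        member_ids = groups.ids_in_group(functional_group)
        label = functional_group
    else:
        member_ids = groups.ids_in_clade(animal_clade)
        label = animal_clade
    member_ids = tuple(i for i in member_ids if i in aln.ids)
    if not member_ids:
        raise ValueError(f"no alignment sequences in group {label!r}")
    counts = np.zeros((aln.length, 20), dtype=np.int64)
    for sid in member_ids:
        row = aln.row(sid)
        for col, ch in enumerate(row):
            idx = RESIDUE_INDEX.get(ch)
            if idx is not None:
                counts[col, idx] += 1
    return PositionProfile(
        group=label, counts=counts, n_effective=counts.sum(axis=1)
    )


@dataclass(frozen=True)
class ConsensusSequence:
    """Majority-residue string; 'X' where the majority is tied or undefined."""

    group: str
    residues: str


def consensus_sequence(profile: PositionProfile) -> ConsensusSequence:
    """Per column, the unique most frequent residue; 'X' on ties or empty columns."""
    residues = []
    for col in range(profile.n_columns):
        modal = profile.modal_residue(col)
        residues.append(modal if modal is not None else "X")
    return ConsensusSequence(group=profile.group, residues="".join(residues))


def write_profile_tsv(
    profiles: Sequence[PositionProfile],
    column_map: ColumnMap,
    path: str | Path,
) -> None:
    """Export profiles as TSV: column, group, residue, frequency, n_effective."""
    with open(path, "w") as fh:
        fh.write("original_column\tfiltered_column\tgroup\tresidue\tfrequency\tn_effective\n")
        for profile in profiles:
            for col in range(profile.n_columns):
                n = int(profile.n_effective[col])
                for aa, i in RESIDUE_INDEX.items():
                    c = int(profile.counts[col, i])
                    if c == 0:
                        continue
                    fh.write(
                        f"{column_map.to_original(col)}\t{col}\t{profile.group}\t"
                        f"{aa}\t{c / n:.6g}\t{n}\n"
                    )
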