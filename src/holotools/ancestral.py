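"""Ancestral animal LAS deduction and Poisson-corrected divergence.

The ancestral sequence is deduced column-wise by a two-of-three clade
majority: a residue is assigned when it is the strict modal residue within
at least two of the three animal clades (non-bilaterian, protostome,
deuterostome); otherwise the column is undetermined ('X'). Divergence of
each animal sequence from this ancestor is the Poisson-corrected distance
d = -ln(1 - p) on the proportion p of differing sites under pairwise
deletion, with a site-resampling bootstrap standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_prep import PositionProfile
from .seq_io import AMINO_ACIDS, GroupAssignment, ProteinAlignment

CLADE_ORDER = ("non_bilaterian", "protostome", "deuterostome")
DEFAULT_BOOTSTRAP_REPLICATES = 1000


@dataclass(frozen=True)
class AncestralSequence:
    """Deduced ancestral residues with per-column clade support.

    ``support[col]`` lists the clades whose modal residue matched the
    assigned residue; it is empty exactly where the residue is 'X'.
    """

    residues: str
    support: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.support):
            raise ValueError("support and residues differ in length")
        for ch, sup in zip(self.residues, self.support):
            if (ch == "X") != (len(sup) == 0):
                raise ValueError("support must be empty exactly at 'X' columns")

    @property
    def n_determined(self) -> int:
        return sum(1 for ch in self.residues if ch != "X")


def deduce_ancestral(
    clade_profiles: Mapping[str, PositionProfile]
) -> AncestralSequence:
    """Two-of-three clade majority over strict within-clade modal residues.

    A clade that is tied or entirely missing at a column contributes no
    vote; a clade with no sequences at all is an error.
    """
    missing = [c for c in CLADE_ORDER if c not in clade_profiles]
    if missing:
        raise ValueError(f"missing clade profiles: {missing}")
    n_cols = clade_profiles[CLADE_ORDER[0]].n_columns
    for clade in CLADE_ORDER:
        if clade_profiles[clade].n_columns != n_cols:
            raise ValueError("clade profiles computed on different column sets")

    residues: list[str] = []
    support: list[tuple[str, ...]] = []
    for col in range(n_cols):
        votes: dict[str, list[str]] = {}
        for clade in CLADE_ORDER:
            modal = clade_profiles[clade].modal_residue(col)
            if modal is not None:
                votes.setdefault(modal, []).append(clade)
        winner = next(
            (res for res, clades in votes.items() if len(clades) >= 2), None
        )
        if winner is None:
            residues.append("X")
            support.append(())
        else:
            residues.append(winner)
            support.append(tuple(votes[winner]))
    return AncestralSequence(residues="".join(residues), support=tuple(support))


def _valid_columns(seq_a: str, seq_b: str) -> list[int]:
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    return [
        i
        for i, (a, b) in enumerate(zip(seq_a, seq_b))
        if a in AMINO_ACIDS and b in AMINO_ACIDS
    ]


def p_distance_pairwise_deletion(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Proportion of differing sites, excluding columns with '-' or 'X'.

    Returns ``(p, n_valid)``; raises when no column is comparable.
    """
    valid = _valid_columns(seq_a, seq_b)
    if not valid:
        raise ValueError("no comparable sites after pairwise deletion")
    diffs = sum(1 for i in valid if seq_a[i] != seq_b[i])
    return diffs / len(valid), len(valid)


def poisson_distance(p: float) -> float:
    """Multiple-hit corrected distance d = -ln(1 - p), defined for 0 <= p < 1."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"Poisson distance undefined for p = {p}")
    return -math.log1p(-p)


def bootstrap_se(
    seq_a: str,
    seq_b: str,
    n_replicates: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of the Poisson distance.

    Comparable columns (after pairwise deletion) are resampled with
    replacement ``n_replicates`` times and d recomputed per replicate; the
    SE is the standard deviation of the replicate values. Replicates with
    p = 1 (saturated, d undefined) are dropped with a warning.
    """
    valid = _valid_columns(seq_a, seq_b)
    if not valid:
        raise ValueError("no comparable sites after pairwise deletion")
    diff = np.array([seq_a[i] != seq_b[i] for i in valid], dtype=np.int8)
    n = diff.size
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(n_replicates, n))
    p_rep = diff[draws].mean(axis=1)
    saturated = p_rep >= 1.0
    n_dropped = int(saturated.sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} of {n_replicates} bootstrap replicates saturated "
            "(p = 1) and were dropped"
        )
        p_rep = p_rep[~saturated]
    if p_rep.size < 2:
        raise ValueError("too few usable bootstrap replicates")
    d_rep = -np.log1p(-p_rep)
    return float(np.std(d_rep, ddof=1))


@dataclass(frozen=True)
class DistanceEstimate:
    """Poisson-corrected divergence of one sequence from the ancestor."""

    seq_id: str
    p: float
    n_valid: int
    d: float
    se: float
    n_replicates: int
    seed: int | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError("p must be in [0, 1)")
        if self.d < self.p - 1e-12:
            raise ValueError("Poisson distance cannot be below p")
        if self.n_valid <= 0:
            raise ValueError("n_valid must be positive")
        if self.se < 0:
            raise ValueError("se must be non-negative")


def divergence_table(
    aln: ProteinAlignment,
    groups: GroupAssignment,
    ancestral: AncestralSequence,
    n_replicates: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-species divergence from the deduced ancestor, sorted descending.

    One row per animal LAS sequence: id, p, n_valid, d, se, plus the
    fraction of ancestral columns left undetermined (excluded by pairwise
    deletion). ``aln`` must be the gap-filtered alignment the ancestor was
    deduced on. Per-sequence bootstrap seeds are derived from ``seed``.
    """
    if len(ancestral.residues) != aln.length:
        raise ValueError("ancestral sequence length does not match alignment")
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    las_ids = groups.ids_in_group("animal_LAS")
    child_seeds = seed_seq.spawn(len(las_ids))
    undetermined_frac = 1.0 - ancestral.n_determined / len(ancestral.residues)
    for sid, child in zip(las_ids, child_seeds):
        seq = aln.row(sid)
        p, n_valid = p_distance_pairwise_deletion(seq, ancestral.residues)
        d = poisson_distance(p)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        se = (
            0.0
            if p == 0.0
            else bootstrap_se(seq, ancestral.residues, n_replicates, sub_seed)
        )
        rows.append(
            {
                "id": sid,
                "clade": groups.animal_clade(sid),
                "p": p,
                "n_valid": n_valid,
                "d": d,
                "se": se,
                "n_replicates": n_replicates,
                "ancestral_undetermined_frac": undetermined_frac,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("d", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
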