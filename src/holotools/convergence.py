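"""Plant-like site calling by lineage contrast, site counting, motif grouping.

A column is a plant-like site for a focal animal sequence when the focal
residue is rare among animal lanosterol synthases (frequency strictly below
``animal_max``, default 20%) yet common in plant beta-amyrin synthases or
plant cycloartenol synthases (frequency strictly above ``plant_min``,
default 55%, in either plant group). Both inequalities are strict, and
comparisons are exact on count ratios so the boundaries are not subject to
floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .alignment_prep import ColumnMap, PositionProfile, as_fraction
from .seq_io import AMINO_ACIDS, ProteinAlignment

DEFAULT_ANIMAL_MAX = 0.20
DEFAULT_PLANT_MIN = 0.55


@dataclass(frozen=True)
class PlantLikeSiteCall:
    """Threshold evaluation of one focal residue at one filtered column."""

    filtered_column: int
    original_column: int
    focal_residue: str
    freq_animal_las: float
    freq_plant_bas: float
    freq_plant_cas: float
    is_plant_like: bool


@dataclass(frozen=True)
class PlantLikeMotif:
    """Run of nearby plant-like calls, in filtered and original coordinates."""

    calls: tuple[PlantLikeSiteCall, ...]
    start_original: int
    end_original: int

    @property
    def length(self) -> int:
        return len(self.calls)


def call_plant_like_sites(
    focal_id: str,
    aln: ProteinAlignment,
    column_map: ColumnMap,
    profile_animal_las: PositionProfile,
    profile_plant_bas: PositionProfile,
    profile_plant_cas: PositionProfile,
    animal_max: float = DEFAULT_ANIMAL_MAX,
    plant_min: float = DEFAULT_PLANT_MIN,
) -> list[PlantLikeSiteCall]:
    """Evaluate every informative column of the focal sequence.

    ``aln`` must be the gap-filtered alignment on which the three profiles
    were computed; the focal sequence is a member of the animal LAS group
    and is included in the animal frequency denominator. Columns where the
    focal sequence has '-' or 'X' are skipped, not reported.
    """
    n_cols = aln.length
    for profile in (profile_animal_las, profile_plant_bas, profile_plant_cas):
        if profile.n_columns != n_cols:
            raise ValueError(
                f"profile {profile.group!r} has {profile.n_columns} columns, "
                f"alignment has {n_cols}"
            )
    if len(column_map) != n_cols:
        raise ValueError("column map does not match the filtered alignment")
    focal_row = aln.row(focal_id)  # raises KeyError on unknown id
    animal_max_f = as_fraction(animal_max)
    plant_min_f = as_fraction(plant_min)

    calls = []
    for col in range(n_cols):
        residue = focal_row[col]
        if residue not in AMINO_ACIDS:
            continue
        f_animal = profile_animal_las.frequency_exact(col, residue)
        f_bas = profile_plant_bas.frequency_exact(col, residue)
        f_cas = profile_plant_cas.frequency_exact(col, residue)
        plant_like = f_animal < animal_max_f and (
            f_bas > plant_min_f or f_cas > plant_min_f
        )
        calls.append(
            PlantLikeSiteCall(
                filtered_column=col,
                original_column=column_map.to_original(col),
                focal_residue=residue,
                freq_animal_las=float(f_animal),
                freq_plant_bas=float(f_bas),
                freq_plant_cas=float(f_cas),
                is_plant_like=plant_like,
            )
        )
    return calls


def count_plant_like_sites(calls: Sequence[PlantLikeSiteCall]) -> int:
    """Number of columns called plant-like for one focal sequence."""
    return sum(1 for c in calls if c.is_plant_like)


def group_motifs(
    calls: Sequence[PlantLikeSiteCall],
    min_run: int = 2,
    max_spacing: int = 3,
) -> list[PlantLikeMotif]:
    """Group plant-like calls into motifs.

    Maximal runs in which consecutive plant-like columns are at most
    ``max_spacing`` filtered columns apart; runs shorter than ``min_run``
    are discarded. The grouping rule is a reporting convention — raw site
    calls should always be reported alongside motifs.
    """
    hits = sorted(
        (c for c in calls if c.is_plant_like), key=lambda c: c.filtered_column
    )
    motifs: list[PlantLikeMotif] = []
    run: list[PlantLikeSiteCall] = []

    def flush() -> None:
        if len(run) >= min_run:
            motifs.append(
                PlantLikeMotif(
                    calls=tuple(run),
                    start_original=run[0].original_column,
                    end_original=run[-1].original_column,
                )
            )

    for call in hits:
        if run and call.filtered_column - run[-1].filtered_column > max_spacing:
            flush()
            run = []
        run.append(call)
    if run:
        flush()
    return motifs


def write_site_report(
    focal_id: str, calls: Sequence[PlantLikeSiteCall], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "focal_id\toriginal_column\tfiltered_column\tfocal_residue\t"
            "freq_animal_LAS\tfreq_plant_BAS\tfreq_plant_CAS\tis_plant_like\n"
        )
        for c in calls:
            fh.write(
                f"{focal_id}\t{c.original_column}\t{c.filtered_column}\t"
                f"{c.focal_residue}\t{c.freq_animal_las:.6g}\t"
                f"{c.freq_plant_bas:.6g}\t{c.freq_plant_cas:.6g}\t"
                f"{int(c.is_plant_like)}\n"
            )


def write_motif_report(
    focal_id: str, motifs: Sequence[PlantLikeMotif], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "focal_id\tstart_original\tend_original\tn_sites\t"
            "filtered_columns\tresidues\n"
        )
        for m in motifs:
            cols = ",".join(str(c.filtered_column) for c in m.calls)
            residues = "".join(c.focal_residue for c in m.calls)
            fh.write(
                f"{focal_id}\t{m.start_original}\t{m.end_original}\t"
                f"{m.length}\t{cols}\t{residues}\n"
            )
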