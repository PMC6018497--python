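"""Readers, writers and validated in-memory containers for every external format.

All internal coordinates are 0-based half-open. Conversions happen only at
I/O boundaries: VCF and GFF3 positions (1-based) are shifted on import,
BED coordinates pass through unchanged, and exported BED equals internal
coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues + missing ('X') + gap ('-')
ALIGNMENT_ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}

FUNCTIONAL_GROUPS = ("plant_BAS", "plant_CAS", "animal_LAS")
ANIMAL_CLADES = ("non_bilaterian", "protostome", "deuterostome")


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, illegal characters...)."""


class GroupTableError(ValueError):
    """Malformed or incomplete sequence-to-group assignment."""


class CoordinateError(ValueError):
    """Genomic coordinate outside the declared chromosome bounds."""


# ---------------------------------------------------------------------------
# protein alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinAlignment:
    """Equal-length gapped amino-acid sequences with stable identifiers.

    Rows are strings over the 20 amino acids plus ``X`` (unknown residue)
    and ``-`` (gap).
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence identifiers: {dupes}")
        if not self.rows:
            raise AlignmentError("empty alignment")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {width}"
                )
            for pos, ch in enumerate(row):
                if ch not in ALIGNMENT_ALPHABET:
                    raise AlignmentError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {pos}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def subset(self, keep_ids: Sequence[str]) -> "ProteinAlignment":
        return ProteinAlignment(
            ids=tuple(keep_ids), rows=tuple(self.row(i) for i in keep_ids)
        )

    def column(self, col: int) -> str:
        return "".join(row[col] for row in self.rows)


def read_alignment(path: str | Path) -> ProteinAlignment:
    """Read a FASTA alignment; residues are upper-cased, ``.`` becomes ``-``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: alignment needs >=2 sequences, got {len(records)}")
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper().replace(".", "-") for r in records)
    return ProteinAlignment(ids=ids, rows=rows)


def write_alignment(aln: ProteinAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# group assignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupAssignment:
    """Maps each sequence id to its functional group and animal clade.

    ``animal_clade`` is ``"none"`` exactly for the plant groups.
    """

    assignment: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for sid, (group, clade) in self.assignment.items():
            if group not in FUNCTIONAL_GROUPS:
                raise GroupTableError(
                    f"unknown functional group {group!r} for {sid!r}; "
                    f"expected one of {FUNCTIONAL_GROUPS}"
                )
            if group == "animal_LAS":
                if clade not in ANIMAL_CLADES:
                    raise GroupTableError(
                        f"animal_LAS sequence {sid!r} needs a clade in "
                        f"{ANIMAL_CLADES}, got {clade!r}"
                    )
            elif clade != "none":
                raise GroupTableError(
                    f"plant sequence {sid!r} must have clade 'none', got {clade!r}"
                )

    def functional_group(self, sid: str) -> str:
        return self.assignment[sid][0]

    def animal_clade(self, sid: str) -> str:
        return self.assignment[sid][1]

    def ids_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, (g, _) in self.assignment.items() if g == group)

    def ids_in_clade(self, clade: str) -> tuple[str, ...]:
        return tuple(s for s, (_, c) in self.assignment.items() if c == clade)

    def require_cover(self, aln: ProteinAlignment) -> None:
        missing = [i for i in aln.ids if i not in self.assignment]
        if missing:
            raise GroupTableError(f"alignment ids missing from group table: {missing}")


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a TSV of ``id<TAB>functional_group<TAB>animal_clade``.

    A header line is recognised (and skipped) when its first field is
    ``id``; duplicate ids with conflicting assignments are rejected.
    """
    mapping: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "id":
                continue
            if len(fields) != 3:
                raise GroupTableError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            sid, group, clade = fields
            if sid in mapping and mapping[sid] != (group, clade):
                raise GroupTableError(
                    f"{path}:{lineno}: conflicting duplicate assignment for {sid!r}"
                )
            mapping[sid] = (group, clade)
    return GroupAssignment(assignment=mapping)


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tfunctional_group\tanimal_clade\n")
        for sid, (group, clade) in groups.assignment.items():
            fh.write(f"{sid}\t{group}\t{clade}\n")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpTable:
    """Sorted, deduplicated SNP positions per chromosome (0-based).

    The table stores positions only: the scan counts polymorphic *sites*,
    so duplicate records at one position collapse to a single site.
    """

    positions: Mapping[str, np.ndarray]
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if chrom not in self.chrom_lengths:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            length = self.chrom_lengths[chrom]
            if pos.size and (pos[0] < 0 or pos[-1] >= length):
                bad = pos[0] if pos[0] < 0 else pos[-1]
                raise CoordinateError(
                    f"position {bad} outside [0, {length}) on {chrom!r}"
                )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int]],
        chrom_lengths: Mapping[str, int],
    ) -> "SnpTable":
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in records:
            by_chrom.setdefault(chrom, []).append(pos)
        positions = {
            chrom: np.unique(np.asarray(pos_list, dtype=np.int64))
            for chrom, pos_list in by_chrom.items()
        }
        return cls(positions=positions, chrom_lengths=dict(chrom_lengths))

    @property
    def n_snps(self) -> int:
        return sum(int(p.size) for p in self.positions.values())

    def chrom_count(self, chrom: str) -> int:
        return int(self.positions.get(chrom, np.empty(0)).size)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of SNP sites with ``start <= pos < end``."""
        pos = self.positions.get(chrom)
        if pos is None or pos.size == 0:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


def _read_snps_vcf(path: str | Path, chrom_lengths: Mapping[str, int]) -> SnpTable:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            chrom = rec.chrom
            if chrom not in chrom_lengths:
                raise CoordinateError(f"{path}: unknown chromosome {chrom!r}")
            # pysam exposes POS already 0-based via rec.start
            if rec.pos < 1:
                raise CoordinateError(
                    f"{path}: invalid 1-based VCF position {rec.pos} on {chrom}"
                )
            if rec.start >= chrom_lengths[chrom]:
                raise CoordinateError(
                    f"{path}: position {rec.pos} beyond {chrom} length "
                    f"{chrom_lengths[chrom]}"
                )
            records.append((chrom, rec.start))
    return SnpTable.from_records(records, chrom_lengths)


def _read_snps_tsv(path: str | Path, chrom_lengths: Mapping[str, int]) -> SnpTable:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise CoordinateError(f"{path}:{lineno}: expected chrom<TAB>pos")
            chrom, pos_s = fields[0], fields[1]
            try:
                pos = int(pos_s)  # 1-based by dialect
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise CoordinateError(
                    f"{path}:{lineno}: non-numeric position {pos_s!r}"
                ) from None
            if chrom not in chrom_lengths:
                raise CoordinateError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if pos < 1 or pos > chrom_lengths[chrom]:
                raise CoordinateError(
                    f"{path}:{lineno}: 1-based position {pos} outside "
                    f"[1, {chrom_lengths[chrom]}] on {chrom}"
                )
            records.append((chrom, pos - 1))
    return SnpTable.from_records(records, chrom_lengths)


def read_snps(path: str | Path, chrom_lengths: Mapping[str, int]) -> SnpTable:
    """Read SNP positions from VCF (v4.x; CHROM/POS only) or a 1-based TSV."""
    path = Path(path)
    if path.suffix in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_snps_vcf(path, chrom_lengths)
    return _read_snps_tsv(path, chrom_lengths)


def write_snps_tsv(snps: SnpTable, path: str | Path) -> None:
    """Write SNPs as ``chrom<TAB>pos`` with 1-based positions (declared in header)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos (1-based)\n")
        for chrom in sorted(snps.positions):
            for pos in snps.positions[chrom]:
                fh.write(f"{chrom}\t{pos + 1}\n")


def write_snps_vcf(snps: SnpTable, path: str | Path) -> None:
    """Write a minimal sites-only VCF (placeholder alleles) via pysam."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in sorted(snps.chrom_lengths):
        header.contigs.add(chrom, length=snps.chrom_lengths[chrom])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom in sorted(snps.positions):
            for pos in snps.positions[chrom]:
                rec = out.new_record(
                    contig=chrom, start=int(pos), stop=int(pos) + 1,
                    alleles=("N", "<SNP>"),
                )
                out.write(rec)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """CDS intervals of one gene, 0-based half-open, disjoint, on one chromosome."""

    gene_id: str
    chrom: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.cds_intervals:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty interval [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: intervals overlap or unsorted")
            prev_end = end
        if self.cds_length_bp <= 0:
            raise ValueError(f"{self.gene_id}: zero CDS length")

    @property
    def cds_length_bp(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> tuple[tuple[tuple[int, int], ...], bool]:
    """Sort and union half-open intervals; flags whether any overlap was merged."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    overlapped = False
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            if start < merged[-1][1]:
                overlapped = True
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged), overlapped


def _build_gene(gene_id: str, chrom: str, raw: list[tuple[int, int]]) -> GeneModel | None:
    raw = [(s, e) for s, e in raw if e > s]
    if not raw:
        warnings.warn(f"gene {gene_id!r}: zero CDS length, skipped")
        return None
    merged, overlapped = merge_intervals(raw)
    if overlapped:
        warnings.warn(f"gene {gene_id!r}: overlapping CDS intervals merged")
    return GeneModel(gene_id=gene_id, chrom=chrom, cds_intervals=merged)


def _gff3_attribute(attrs: str, *keys: str) -> str | None:
    for item in attrs.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            if key.strip() in keys:
                return value.split(",")[0].strip()
    return None


def _read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    by_gene: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start_s, end_s, _, _, _, attrs = fields[:9]
            if ftype != "CDS":
                continue
            gene_id = _gff3_attribute(attrs, "Parent", "ID", "gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: CDS without Parent/ID attribute")
            # GFF3 is 1-based closed -> 0-based half-open
            start, end = int(start_s) - 1, int(end_s)
            entry = by_gene.setdefault(gene_id, (chrom, []))
            if entry[0] != chrom:
                raise ValueError(f"{path}: gene {gene_id!r} spans chromosomes")
            entry[1].append((start, end))
    genes = [_build_gene(gid, chrom, ivs) for gid, (chrom, ivs) in by_gene.items()]
    return [g for g in genes if g is not None]


def _read_gene_models_bed(path: str | Path) -> list[GeneModel]:
    by_gene: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >=4 columns (name required)")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if len(fields) >= 12:  # BED12: expand blocks
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                ivs = [(start + s, start + s + size) for s, size in zip(starts, sizes)]
            else:
                ivs = [(start, end)]
            entry = by_gene.setdefault(name, (chrom, []))
            if entry[0] != chrom:
                raise ValueError(f"{path}: gene {name!r} spans chromosomes")
            entry[1].extend(ivs)
    genes = [_build_gene(gid, chrom, ivs) for gid, (chrom, ivs) in by_gene.items()]
    return [g for g in genes if g is not None]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene CDS intervals from GFF3 (1-based closed) or BED (0-based)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gene_models_gff3(path)
    return _read_gene_models_bed(path)


def write_gene_models_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene CDS intervals as BED6 rows (one row per CDS interval)."""
    with open(path, "w") as fh:
        for gene in genes:
            for start, end in gene.cds_intervals:
                fh.write(f"{gene.chrom}\t{start}\t{end}\t{gene.gene_id}\t0\t+\n")


# ---------------------------------------------------------------------------
# BED export of scored regions
# ---------------------------------------------------------------------------

_SCORE_CAP = 300.0


def bed_score(p_value: float) -> float:
    """-log10(p), capped at 300 (handles p = 0)."""
    if p_value <= 0.0:
        return _SCORE_CAP
    return min(_SCORE_CAP, -math.log10(p_value))


def write_bed(
    regions: Sequence,
    path: str | Path,
    track_name: str = "regions",
) -> None:
    """Write regions (objects with chrom/start/end and a p-value) as BED.

    The score column carries ``-log10(p)`` capped at 300.
    """
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for i, region in enumerate(regions):
            p = getattr(region, "min_p_value", None)
            if p is None:
                p = getattr(region, "p_value", 1.0)
            name = getattr(region, "name", f"{track_name}_{i + 1}")
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{name}\t"
                f"{bed_score(p):.6g}\n"
            )


# ---------------------------------------------------------------------------
# chromosome length tables
# ---------------------------------------------------------------------------


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a ``chrom<TAB>length`` table (samtools .fai style: extra columns ignored)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
            lengths[fields[0]] = int(fields[1])
    if not lengths:
        raise ValueError(f"{path}: no chromosome lengths found")
    return lengths


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")


# ---------------------------------------------------------------------------
# k-mer histograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmerHistogram:
    """Depth -> count table of k-mer occurrences (jellyfish ``histo`` dialect)."""

    depths: np.ndarray
    counts: np.ndarray
    k: int = 19

    def __post_init__(self) -> None:
        d, c = self.depths, self.counts
        if d.size == 0:
            raise ValueError("empty k-mer histogram")
        if d.size != c.size:
            raise ValueError("depths and counts differ in length")
        if np.any(d[:-1] >= d[1:]):
            raise ValueError("depths must be strictly increasing")
        if d[0] < 1:
            raise ValueError("depths must be positive")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if self.total_mass() <= 0:
            raise ValueError("total k-mer mass must be positive")

    def total_mass(self, min_depth: int | None = None) -> int:
        """Total number of k-mers, sum(depth * count), optionally from min_depth."""
        mask = slice(None) if min_depth is None else self.depths >= min_depth
        return int(np.sum(self.depths[mask].astype(object) * self.counts[mask]))


def read_kmer_histogram(path: str | Path, k: int = 19) -> KmerHistogram:
    data = np.loadtxt(path, dtype=np.int64, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (depth, count)")
    return KmerHistogram(depths=data[:, 0], counts=data[:, 1], k=k)


def write_kmer_histogram(hist: KmerHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        for depth, count in zip(hist.depths, hist.counts):
            fh.write(f"{depth} {count}\n")
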