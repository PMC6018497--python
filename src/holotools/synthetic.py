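"""Synthetic inputs with planted, machine-readable ground truth.

Three generators emulate the statistical structure of the three analysis
tracks so each can be exercised and validated end to end:

* :func:`simulate_osc_msa` — a grouped protein alignment (plant BAS, plant
  CAS, animal LAS split into three clades) evolved from a known root
  sequence, with planted convergent ("plant-like") columns in one focal
  animal lineage.
* :func:`simulate_snp_landscape` — a Bernoulli SNP landscape over one or
  more chromosomes with planted high-density hotspot intervals and planted
  high-density CDS genes.
* :func:`simulate_kmer_histogram` — a k-mer depth histogram constructed to
  invert the peak genome-size formula exactly, with an optional low-depth
  error component.

Substitution model
------------------
Sequences evolve under a 20-state uniform-replacement model: on a branch of
expected length ``d`` substitutions/site, each column substitutes with
probability ``1 - exp(-d)``, to a residue drawn uniformly from the other
19. Every substitution event is therefore observable against the parent,
so the expected p-distance to the parent is exactly ``1 - exp(-d)`` and the
Poisson correction ``-ln(1 - p)`` recovers ``d`` without bias — which is
what makes parameter-recovery checks of the divergence estimator possible.

All generators are pure functions of their scenario plus the seed; no
global random state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seq_io import (
    AMINO_ACIDS,
    GeneModel,
    GroupAssignment,
    KmerHistogram,
    ProteinAlignment,
    SnpTable,
    merge_intervals,
)

# ---------------------------------------------------------------------------
# protein alignment scenario
# ---------------------------------------------------------------------------


def expected_p_distance(d: float) -> float:
    """Expected p-distance to the parent after a branch of length d."""
    return 1.0 - math.exp(-d)


def _evolve(parent: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of the uniform-replacement model on residue indices."""
    child = parent.copy()
    mask = rng.random(parent.size) < expected_p_distance(d)
    n_sub = int(mask.sum())
    if n_sub:
        offsets = rng.integers(1, 20, size=n_sub)
        child[mask] = (child[mask] + offsets) % 20
    return child


def evolve_sequence(ancestor: str, d: float, rng: np.random.Generator) -> str:
    """Evolve a residue string one branch of expected length d subst/site."""
    idx = np.array([AMINO_ACIDS.index(ch) for ch in ancestor])
    return "".join(AMINO_ACIDS[i] for i in _evolve(idx, d, rng))


@dataclass(frozen=True)
class MsaScenario:
    """Study conditions for the grouped OSC-like alignment.

    Defaults: 10 plant BAS + 10 plant CAS + 12 animal LAS sequences (three
    clades of four), 700 columns, 30 planted plant-like columns in one
    focal deuterostome lineage, every branch (members and plant stems) at
    0.1 substitutions/site, and a 2% per-cell gap rate. A faster focal
    lineage (``focal_rate_multiplier``) emulates the elevated rate of the
    sea-cucumber lanosterol synthases when divergence ranking is studied.
    """

    n_plant_bas: int = 10
    n_plant_cas: int = 10
    n_per_clade: tuple[int, int, int] = (4, 4, 4)
    length: int = 700
    n_planted: int = 30
    d_within: float = 0.1
    d_plant_stem: float = 0.1
    focal_rate_multiplier: float = 1.0
    gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_within", "d_plant_stem", "gap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")
        if not 0 <= self.n_planted <= self.length:
            raise ValueError("n_planted must be within [0, length]")
        if min(self.n_per_clade) < 1 or self.n_plant_bas < 1 or self.n_plant_cas < 1:
            raise ValueError("every group needs at least one member")
        # one focal carrier among the animals must stay below the 20% threshold
        if sum(self.n_per_clade) <= 5:
            raise ValueError(
                "need >5 animal LAS sequences so a single planted residue "
                "stays below the rare-in-animals threshold"
            )

    @property
    def n_animals(self) -> int:
        return sum(self.n_per_clade)

    @property
    def focal_id(self) -> str:
        return "deuterostome_1"


@dataclass(frozen=True)
class MsaTruth:
    """Ground truth emitted with a simulated alignment."""

    ancestral: str
    planted_columns: tuple[int, ...]
    planted_residues: str
    focal_id: str
    realized_p: Mapping[str, float]  # p-distance to the root, pre-gap
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_columns"] = list(self.planted_columns)
        payload["realized_p"] = dict(self.realized_p)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MsaTruth":
        payload = json.loads(Path(path).read_text())
        payload["planted_columns"] = tuple(payload["planted_columns"])
        return cls(**payload)


def simulate_osc_msa(
    scenario: MsaScenario = MsaScenario(),
) -> tuple[ProteinAlignment, GroupAssignment, MsaTruth]:
    """Simulate the grouped alignment with planted convergent columns.

    Tree shape: a single animal root; the three animal clades descend from
    it directly and each member evolves one branch of ``d_within`` (the
    focal lineage at ``d_within * focal_rate_multiplier``); the two plant
    groups descend through stem branches of ``d_plant_stem`` and then
    member branches of ``d_within``.

    At each planted column, every plant sequence carries one shared residue
    that differs from the root, the focal animal carries that same residue,
    and every other animal is forced off it — so the planted contrast
    satisfies the default plant-like thresholds with margin. Planted
    columns are kept gap-free so the planted truth is exact; all other
    cells gap independently at ``gap_rate``.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    L = sc.length
    root = rng.integers(0, 20, size=L)

    ids: list[str] = []
    seqs: list[np.ndarray] = []
    assignment: dict[str, tuple[str, str]] = {}

    bas_anc = _evolve(root, sc.d_plant_stem, rng)
    cas_anc = _evolve(root, sc.d_plant_stem, rng)
    for i in range(sc.n_plant_bas):
        sid = f"bas_{i + 1}"
        ids.append(sid)
        seqs.append(_evolve(bas_anc, sc.d_within, rng))
        assignment[sid] = ("plant_BAS", "none")
    for i in range(sc.n_plant_cas):
        sid = f"cas_{i + 1}"
        ids.append(sid)
        seqs.append(_evolve(cas_anc, sc.d_within, rng))
        assignment[sid] = ("plant_CAS", "none")

    clade_names = ("non_bilaterian", "protostome", "deuterostome")
    clade_prefix = {"non_bilaterian": "nonbil", "protostome": "proto", "deuterostome": "deuterostome"}
    animal_rows: dict[str, int] = {}
    for clade, n_members in zip(clade_names, sc.n_per_clade):
        for i in range(n_members):
            sid = f"{clade_prefix[clade]}_{i + 1}"
            branch = sc.d_within
            if sid == sc.focal_id:
                branch *= sc.focal_rate_multiplier
            ids.append(sid)
            animal_rows[sid] = len(seqs)
            seqs.append(_evolve(root, branch, rng))
            assignment[sid] = ("animal_LAS", clade)

    # plant the convergent columns
    planted = np.sort(rng.choice(L, size=sc.n_planted, replace=False))
    planted_residues = []
    plant_row_ids = [i for i, sid in enumerate(ids) if assignment[sid][0] != "animal_LAS"]
    focal_row = animal_rows[sc.focal_id]
    for col in planted:
        alt = (int(root[col]) + int(rng.integers(1, 20))) % 20
        planted_residues.append(AMINO_ACIDS[alt])
        for row in plant_row_ids:
            seqs[row][col] = alt
        for sid, row in animal_rows.items():
            if row == focal_row:
                seqs[row][col] = alt
            elif seqs[row][col] == alt:
                seqs[row][col] = int(root[col])

    realized_p = {
        sid: float(np.mean(seqs[i] != root))
        for i, sid in enumerate(ids)
        if assignment[sid][0] == "animal_LAS"
    }

    # per-cell gaps, keeping planted columns intact
    gap_mask = rng.random((len(seqs), L)) < sc.gap_rate
    gap_mask[:, planted] = False
    rows = []
    for i, seq in enumerate(seqs):
        chars = [AMINO_ACIDS[r] for r in seq]
        for col in np.flatnonzero(gap_mask[i]):
            chars[col] = "-"
        rows.append("".join(chars))

    aln = ProteinAlignment(ids=tuple(ids), rows=tuple(rows))
    groups = GroupAssignment(assignment=assignment)
    truth = MsaTruth(
        ancestral="".join(AMINO_ACIDS[r] for r in root),
        planted_columns=tuple(int(c) for c in planted),
        planted_residues="".join(planted_residues),
        focal_id=sc.focal_id,
        realized_p=realized_p,
        seed=sc.seed,
    )
    return aln, groups, truth


# ---------------------------------------------------------------------------
# SNP landscape scenario
# ---------------------------------------------------------------------------

_DEFAULT_HOTSPOTS = (
    ("chr1", 2_000_000, 3_000_000),
    ("chr1", 5_500_000, 6_500_000),
    ("chr1", 9_000_000, 10_000_000),
    ("chr1", 12_500_000, 13_500_000),
    ("chr1", 16_000_000, 17_000_000),
)


@dataclass(frozen=True)
class SnpScenario:
    """Study conditions for the polymorphism landscape.

    Defaults: one 20-Mb chromosome, background SNP rate 0.001/bp, five
    planted 1-Mb hotspots at 5x the background rate, genes tiled every
    20 kb outside the hotspots (two 1.5-kb CDS exons each), and three
    planted genes whose CDS carries 10x the background rate.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000}
    )
    background_rate: float = 0.001
    hotspots: tuple[tuple[str, int, int], ...] = _DEFAULT_HOTSPOTS
    hotspot_multiplier: float = 5.0
    n_hpg: int = 3
    hpg_multiplier: float = 10.0
    gene_spacing: int = 20_000
    exon_length: int = 1_500
    n_exons: int = 2
    intron_length: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")
        top = self.background_rate * max(self.hotspot_multiplier, self.hpg_multiplier)
        if top >= 1:
            raise ValueError("multiplied SNP rate must stay below 1 per bp")
        for chrom, start, end in self.hotspots:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"hotspot on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ValueError(f"hotspot [{start}, {end}) outside {chrom}")

    @property
    def gene_span(self) -> int:
        return self.n_exons * self.exon_length + (self.n_exons - 1) * self.intron_length


@dataclass(frozen=True)
class SnpTruth:
    """Planted features of a simulated SNP landscape."""

    hotspots: tuple[tuple[str, int, int], ...]
    hpg_gene_ids: tuple[str, ...]
    background_rate: float
    hotspot_multiplier: float
    hpg_multiplier: float
    seed: int

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write('track name="planted_hotspots"\n')
            for chrom, start, end in self.hotspots:
                fh.write(f"{chrom}\t{start}\t{end}\thotspot\n")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["hotspots"] = [list(h) for h in self.hotspots]
        payload["hpg_gene_ids"] = list(self.hpg_gene_ids)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SnpTruth":
        payload = json.loads(Path(path).read_text())
        payload["hotspots"] = tuple(tuple(h) for h in payload["hotspots"])
        payload["hpg_gene_ids"] = tuple(payload["hpg_gene_ids"])
        return cls(**payload)


def _bernoulli_positions(
    rng: np.random.Generator,
    start: int,
    end: int,
    rate: float,
    chunk: int = 4_000_000,
) -> np.ndarray:
    """Positions of independent per-base successes on [start, end)."""
    if rate <= 0 or end <= start:
        return np.empty(0, dtype=np.int64)
    parts = []
    for s in range(start, end, chunk):
        n = min(chunk, end - s)
        hits = np.flatnonzero(rng.random(n) < rate)
        if hits.size:
            parts.append(hits.astype(np.int64) + s)
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def _tile_genes(sc: SnpScenario) -> list[GeneModel]:
    """Genes tiled along each chromosome, skipping planted hotspot spans.

    Keeping gene models off the hotspots keeps the two planted truth
    tracks (hotspot intervals, high-density genes) disjoint, so each can
    be recovered and scored independently.
    """
    genes = []
    counter = 0
    for chrom in sorted(sc.chrom_lengths):
        length = sc.chrom_lengths[chrom]
        hot = [(s, e) for c, s, e in sc.hotspots if c == chrom]
        start = 0
        while start + sc.gene_span <= length:
            end = start + sc.gene_span
            if not any(s < end and start < e for s, e in hot):
                counter += 1
                exons = tuple(
                    (
                        start + i * (sc.exon_length + sc.intron_length),
                        start + i * (sc.exon_length + sc.intron_length) + sc.exon_length,
                    )
                    for i in range(sc.n_exons)
                )
                genes.append(
                    GeneModel(
                        gene_id=f"gene_{counter:04d}", chrom=chrom, cds_intervals=exons
                    )
                )
            start += sc.gene_spacing
    return genes


def simulate_snp_landscape(
    scenario: SnpScenario = SnpScenario(),
) -> tuple[SnpTable, SnpTruth, list[GeneModel]]:
    """Simulate the SNP landscape with planted hotspots and planted HPGs.

    SNP presence at each base is an independent Bernoulli draw: at the
    background rate genome-wide, at ``hotspot_multiplier`` times that rate
    inside planted hotspot intervals, and at ``hpg_multiplier`` times the
    background inside the CDS of the planted genes. Overlapping planted
    hotspot intervals are merged with a warning.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    hotspot_by_chrom: dict[str, tuple[tuple[int, int], ...]] = {}
    merged_hotspots: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in sc.hotspots}):
        merged, overlapped = merge_intervals(
            (s, e) for c, s, e in sc.hotspots if c == chrom
        )
        if overlapped:
            import warnings

            warnings.warn(f"overlapping planted hotspots on {chrom} were merged")
        hotspot_by_chrom[chrom] = merged
        merged_hotspots.extend((chrom, s, e) for s, e in merged)

    genes = _tile_genes(sc)
    if sc.n_hpg > len(genes):
        raise ValueError("more planted HPGs requested than tiled genes")
    hpg_idx = rng.choice(len(genes), size=sc.n_hpg, replace=False)
    hpg_ids = tuple(sorted(genes[int(i)].gene_id for i in hpg_idx))
    hpg_genes = {genes[int(i)].gene_id: genes[int(i)] for i in hpg_idx}

    lam0 = sc.background_rate
    records: list[tuple[str, int]] = []
    for chrom in sorted(sc.chrom_lengths):
        length = sc.chrom_lengths[chrom]
        pos = [_bernoulli_positions(rng, 0, length, lam0)]
        # layer extra draws on top of the background so the combined
        # per-base rate is exactly multiplier * background
        for s, e in hotspot_by_chrom.get(chrom, ()):
            target = lam0 * sc.hotspot_multiplier
            extra = 1.0 - (1.0 - target) / (1.0 - lam0)
            pos.append(_bernoulli_positions(rng, s, e, extra))
        for gene in hpg_genes.values():
            if gene.chrom != chrom:
                continue
            target = lam0 * sc.hpg_multiplier
            extra = 1.0 - (1.0 - target) / (1.0 - lam0)
            for s, e in gene.cds_intervals:
                pos.append(_bernoulli_positions(rng, s, e, extra))
        merged_pos = np.unique(np.concatenate(pos)) if pos else np.empty(0)
        records.extend((chrom, int(p)) for p in merged_pos)

    snps = SnpTable.from_records(records, sc.chrom_lengths)
    truth = SnpTruth(
        hotspots=tuple(merged_hotspots),
        hpg_gene_ids=hpg_ids,
        background_rate=lam0,
        hotspot_multiplier=sc.hotspot_multiplier,
        hpg_multiplier=sc.hpg_multiplier,
        seed=sc.seed,
    )
    return snps, truth, genes


# ---------------------------------------------------------------------------
# k-mer histogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmerTruth:
    genome_size: int
    peak_depth: int
    error_mass: int


def simulate_kmer_histogram(
    genome_size: int = 1_000_000,
    peak_depth: int = 30,
    error_mass: int = 0,
) -> tuple[KmerHistogram, KmerTruth]:
    """Construct a histogram whose peak formula inverts to ``genome_size``.

    The main component is a discretised bell of counts symmetric about
    ``peak_depth`` whose counts sum to exactly ``genome_size``; by
    symmetry its k-mer mass is exactly ``genome_size * peak_depth``, so
    the estimator recovers the genome size without error. The optional
    error component places ``error_mass`` k-mers at depths 1-2, separated
    from the main component by an explicit zero-count valley so the
    automatic error cutoff isolates it exactly. The construction is fully
    deterministic.
    """
    G, c, e = int(genome_size), int(peak_depth), int(error_mass)
    if G <= 0 or c <= 0:
        raise ValueError("genome_size and peak_depth must be positive")
    if e < 0:
        raise ValueError("error_mass must be non-negative")
    if e > 0 and c <= 3:
        raise ValueError(
            "error and coverage components are indistinguishable at "
            f"peak_depth={c} (need >= 4)"
        )

    min_main_depth = 4 if e > 0 else 1
    half_width = min(10, c - min_main_depth)
    sigma = max(half_width / 3.0, 0.5)
    weights = np.exp(-np.arange(half_width + 1) ** 2 / (2 * sigma**2))
    total_weight = weights[0] + 2 * weights[1:].sum()
    side = [int(G * w / total_weight) for w in weights[1:]]
    center = G - 2 * sum(side)
    depths = list(range(c - half_width, c + half_width + 1))
    counts = side[::-1] + [center] + side

    if e > 0:
        if e < 8:
            err_depths, err_counts = [1], [e]
        else:
            c2 = e // 4
            err_depths, err_counts = [1, 2], [e - 2 * c2, c2]
        valley_depth = err_depths[-1] + 1
        depths = err_depths + [valley_depth] + depths
        counts = err_counts + [0] + counts

    hist = KmerHistogram(
        depths=np.asarray(depths, dtype=np.int64),
        counts=np.asarray(counts, dtype=np.int64),
    )
    return hist, KmerTruth(genome_size=G, peak_depth=c, error_mass=e)
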