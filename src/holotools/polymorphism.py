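"""Sliding-window SNP-density scan, hotspot regions, highly polymorphic genes.

SNP density is the number of SNP sites per unit region, computed in 1-Mb
sliding windows with a 50-kb step (the defaults). Each window (and each
gene's CDS) is tested for enrichment against the rest of its chromosome by
a one-sided Fisher's exact test with base pairs as trials — a site either
carries a SNP or it does not — and a fixed significance cutoff of 1e-4.
Significant windows merge into hotspot regions (reported at >= 500 kb);
region edges may optionally be refined to step resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import GeneModel, SnpTable

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 50_000
DEFAULT_ALPHA = 1e-4
DEFAULT_MIN_REGION = 500_000


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    snp_count: int
    p_value: float | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def density_per_kb(self) -> float:
        return self.snp_count / (self.length_bp / 1000)


@dataclass(frozen=True)
class HotspotRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    min_p_value: float

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HPGCall:
    """Per-gene CDS SNP density and enrichment against the chromosome."""

    gene_id: str
    chrom: str
    cds_snp_count: int
    cds_length_bp: int
    p_value: float
    significant: bool

    @property
    def density_per_kb(self) -> float:
        return self.cds_snp_count / (self.cds_length_bp / 1000)


def window_densities(
    snps: SnpTable,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[Window]:
    """Sliding windows starting at 0, step, 2*step, ... per chromosome.

    The terminal window is truncated at the chromosome end; a chromosome
    shorter than the step still yields one truncated window. Every SNP is
    counted in every window containing it (half-open membership).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    out = []
    for chrom in sorted(snps.chrom_lengths):
        length = snps.chrom_lengths[chrom]
        start = 0
        while start < length:
            end = min(start + window, length)
            out.append(
                Window(
                    chrom=chrom,
                    start=start,
                    end=end,
                    snp_count=snps.count_in(chrom, start, end),
                )
            )
            start += step
    return out


def fisher_enrichment_p(
    snp_count: int,
    length_bp: int,
    chrom_snp_count: int,
    chrom_length_bp: int,
) -> float:
    """One-sided (enrichment) Fisher's exact p of a window vs its chromosome.

    The 2x2 table uses base pairs as trials and excludes the window from
    the background side, so the cells are disjoint:

        [[snp_count,             length_bp - snp_count],
         [rest_snp_count,        rest_length - rest_snp_count]]
    """
    rest_len = chrom_length_bp - length_bp
    rest_snps = chrom_snp_count - snp_count
    if rest_len <= 0:
        warnings.warn(
            "window covers the whole chromosome: no background, p = 1"
        )
        return 1.0
    if rest_snps < 0:
        raise ValueError("window SNP count exceeds chromosome total")
    table = [
        [snp_count, length_bp - snp_count],
        [rest_snps, rest_len - rest_snps],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def scan_windows(
    snps: SnpTable,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[Window]:
    """Window densities with enrichment p-values attached."""
    windows = window_densities(snps, window=window, step=step)
    out = []
    for win in windows:
        p = fisher_enrichment_p(
            win.snp_count,
            win.length_bp,
            snps.chrom_count(win.chrom),
            snps.chrom_lengths[win.chrom],
        )
        out.append(replace(win, p_value=p))
    return out


def call_hotspot_regions(
    windows: Sequence[Window],
    alpha: float = DEFAULT_ALPHA,
    min_region: int = DEFAULT_MIN_REGION,
) -> list[HotspotRegion]:
    """Merge significant windows (p < alpha) into regions of >= min_region bp.

    Overlapping or exactly bookended significant windows merge; gapped
    ones do not. Merged spans shorter than ``min_region`` are discarded.
    """
    sig = sorted(
        (w for w in windows if w.p_value is not None and w.p_value < alpha),
        key=lambda w: (w.chrom, w.start),
    )
    regions: list[HotspotRegion] = []
    current: list[Window] = []

    def flush() -> None:
        if not current:
            return
        start = current[0].start
        end = max(w.end for w in current)
        if end - start >= min_region:
            regions.append(
                HotspotRegion(
                    chrom=current[0].chrom,
                    start=start,
                    end=end,
                    n_windows=len(current),
                    min_p_value=min(w.p_value for w in current),
                )
            )

    for win in sig:
        if current and (
            win.chrom != current[0].chrom or win.start > max(w.end for w in current)
        ):
            flush()
            current = []
        current.append(win)
    flush()
    return regions


def refine_region_boundaries(
    regions: Sequence[HotspotRegion],
    snps: SnpTable,
    step: int = DEFAULT_STEP,
    min_region: int = DEFAULT_MIN_REGION,
) -> list[HotspotRegion]:
    """Trim merged regions to step-resolution density boundaries.

    A 1-Mb sliding window turns significant long before it fully enters a
    dense tract, so plain window-union regions overshoot each true edge by
    up to a window length. This optional refinement re-examines each
    merged region at step (bin) resolution: bin SNP counts are classified
    against the midpoint between the chromosomal background rate (measured
    outside all candidate regions) and the region's own peak-bin rate, and
    the region is trimmed to the maximal run of dense bins around the
    densest bin. Regions falling below ``min_region`` after trimming are
    dropped.
    """
    by_chrom: dict[str, list[HotspotRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.chrom, []).append(region)

    refined: list[HotspotRegion] = []
    for chrom, chrom_regions in sorted(by_chrom.items()):
        chrom_len = snps.chrom_lengths[chrom]
        covered = sum(r.length_bp for r in chrom_regions)
        in_regions = sum(snps.count_in(chrom, r.start, r.end) for r in chrom_regions)
        outside_len = chrom_len - covered
        if outside_len <= 0:
            refined.extend(chrom_regions)  # no background to contrast against
            continue
        bg_rate = (snps.chrom_count(chrom) - in_regions) / outside_len
        for region in chrom_regions:
            edges = np.arange(region.start, region.end + step, step)
            edges[-1] = min(edges[-1], region.end)
            if edges.size < 2:
                continue
            counts = np.array(
                [
                    snps.count_in(chrom, int(a), int(b))
                    for a, b in zip(edges[:-1], edges[1:])
                ],
                dtype=float,
            )
            widths = np.diff(edges).astype(float)
            dens = counts / widths
            seed = int(np.argmax(dens))
            threshold = (bg_rate + dens[seed]) / 2.0
            lo = seed
            while lo > 0 and dens[lo - 1] >= threshold:
                lo -= 1
            hi = seed
            while hi + 1 < dens.size and dens[hi + 1] >= threshold:
                hi += 1
            start, end = int(edges[lo]), int(edges[hi + 1])
            if end - start >= min_region:
                refined.append(replace(region, start=start, end=end))
    return refined


def cds_snp_density(gene: GeneModel, snps: SnpTable) -> float:
    """SNP sites per kb of CDS; intronic and intergenic SNPs do not count."""
    count = sum(snps.count_in(gene.chrom, s, e) for s, e in gene.cds_intervals)
    return count / (gene.cds_length_bp / 1000)


def call_hpgs(
    genes: Sequence[GeneModel],
    snps: SnpTable,
    alpha: float = DEFAULT_ALPHA,
) -> list[HPGCall]:
    """Highly-polymorphic-gene calls: CDS enrichment vs chromosomal background.

    Per gene the 2x2 table contrasts CDS base pairs against the rest of
    the chromosome (CDS excluded), one-sided towards enrichment. A gene is
    significant when its raw p-value is below ``alpha``.
    """
    calls = []
    for gene in genes:
        if gene.chrom not in snps.chrom_lengths:
            raise ValueError(f"gene {gene.gene_id!r}: unknown chromosome {gene.chrom!r}")
        count = sum(snps.count_in(gene.chrom, s, e) for s, e in gene.cds_intervals)
        p = fisher_enrichment_p(
            count,
            gene.cds_length_bp,
            snps.chrom_count(gene.chrom),
            snps.chrom_lengths[gene.chrom],
        )
        calls.append(
            HPGCall(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                cds_snp_count=count,
                cds_length_bp=gene.cds_length_bp,
                p_value=p,
                significant=p < alpha,
            )
        )
    return calls


def windows_to_frame(windows: Sequence[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "snp_count": [w.snp_count for w in windows],
            "density_per_kb": [w.density_per_kb for w in windows],
            "p_value": [w.p_value for w in windows],
        }
    )


def hpgs_to_frame(calls: Sequence[HPGCall]) -> pd.DataFrame:
    """HPG calls as a table; adds a Benjamini-Hochberg column for reference.

    Significance of the calls themselves uses the raw fixed cutoff; the
    q-values are informational only.
    """
    frame = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "chrom": [c.chrom for c in calls],
            "cds_snp_count": [c.cds_snp_count for c in calls],
            "cds_length_bp": [c.cds_length_bp for c in calls],
            "density_per_kb": [c.density_per_kb for c in calls],
            "p_value": [c.p_value for c in calls],
            "significant": [c.significant for c in calls],
        }
    )
    if len(frame):
        frame["q_value_bh"] = stats.false_discovery_control(
            frame["p_value"].to_numpy(), method="bh"
        )
    return frame
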