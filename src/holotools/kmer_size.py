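"""Genome-size estimation from a k-mer depth histogram.

The estimator is the classical peak formula:

    genome size = (total number of k-mers) / (depth of the coverage peak)

The coverage peak is the modal depth of the histogram after the low-depth
error component (sequencing-error k-mers) has been excluded; by default the
error component is everything below the first local minimum of the counts,
and its mass is also excluded from the k-mer total (flag-controlled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import KmerHistogram


class NoCoveragePeakError(ValueError):
    """Histogram has no interior mode to interpret as the coverage peak."""


def find_error_cutoff(hist: KmerHistogram) -> int:
    """Depth of the first local minimum of the counts.

    Counts below this depth are attributed to sequencing-error k-mers. For
    a histogram that rises from its very first depth, the cutoff is that
    first depth (no error component).
    """
    counts = hist.counts
    rises = np.flatnonzero(counts[1:] > counts[:-1])
    if rises.size == 0:
        raise NoCoveragePeakError(
            "no coverage peak: histogram counts never increase with depth"
        )
    return int(hist.depths[rises[0]])


def find_coverage_peak(hist: KmerHistogram, min_depth: int | None = None) -> int:
    """Depth of the maximal count at or above ``min_depth``.

    ``min_depth=None`` applies the automatic error-component rule (first
    local minimum of the counts).
    """
    if min_depth is None:
        min_depth = find_error_cutoff(hist)
    mask = hist.depths >= min_depth
    if not mask.any():
        raise NoCoveragePeakError(f"no histogram entries at depth >= {min_depth}")
    counts = hist.counts[mask]
    depths = hist.depths[mask]
    return int(depths[int(np.argmax(counts))])


@dataclass(frozen=True)
class GenomeSizeEstimate:
    peak_depth: int
    n_kmers: int
    genome_size: float
    error_cutoff: int | None  # None when error k-mers were kept in the total


def estimate_genome_size(
    hist: KmerHistogram,
    peak_depth: int | None = None,
    exclude_error: bool = True,
) -> GenomeSizeEstimate:
    """Apply the peak formula G = N / m.

    ``peak_depth=None`` locates the peak automatically. With
    ``exclude_error`` (the default) the k-mer total N also omits the
    low-depth error component; with it off, N is the full histogram mass.
    """
    cutoff = find_error_cutoff(hist) if (peak_depth is None or exclude_error) else None
    m = peak_depth if peak_depth is not None else find_coverage_peak(hist, cutoff)
    if m <= 0:
        raise ValueError("peak depth must be positive")
    if exclude_error:
        n_kmers = hist.total_mass(min_depth=cutoff)
    else:
        n_kmers = hist.total_mass()
    return GenomeSizeEstimate(
        peak_depth=m,
        n_kmers=n_kmers,
        genome_size=n_kmers / m,
        error_cutoff=cutoff if exclude_error else None,
    )
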