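"""Transposable-element overlap calls, per-family enrichment, and
fixed-width window density tables."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, TEFeature, TranscriptModel


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 Fisher's-exact comparison of TE-family overlap between two groups."""

    family: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: A, B; cols: with, without
    odds_ratio: float
    p_value: float


def te_overlaps(
    transcripts: Iterable[TranscriptModel],
    tes: Sequence[TEFeature],
    min_overlap_bp: int = 10,
    use_span: bool = False,
) -> dict[str, set[str]]:
    """Map each transcript id to the set of TE families overlapping it.

    A TE counts iff its intersection with the transcript's exonic bases
    (or span, when ``use_span``) totals at least ``min_overlap_bp``;
    strand-ignorant.
    """
    by_chrom: dict[str, list[TEFeature]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    out: dict[str, set[str]] = {}
    for t in transcripts:
        families: set[str] = set()
        regions = (t.interval,) if use_span else t.exons
        for te in by_chrom.get(t.chrom, ()):
            iv = te.interval
            bp = sum(
                max(0, min(r.end, iv.end) - max(r.start, iv.start))
                for r in regions
            )
            if bp >= min_overlap_bp:
                families.add(te.family)
        out[t.transcript_id] = families
    return out


def family_enrichment(
    group_a: Iterable[str],
    group_b: Iterable[str],
    overlaps: Mapping[str, set[str]],
    family: str,
) -> EnrichmentResult:
    """Fisher's exact test of family overlap between two disjoint id groups.

    Odds ratio is the plain cross-product; a 0.5 Haldane correction is added
    to every cell only when some cell is zero (which is also the only way a
    margin can be zero).
    """
    a_ids, b_ids = set(group_a), set(group_b)
    if not a_ids or not b_ids:
        raise ValueError("both groups must be non-empty")
    if a_ids & b_ids:
        raise ValueError("groups must be disjoint")
    a_with = sum(1 for i in a_ids if family in overlaps.get(i, set()))
    b_with = sum(1 for i in b_ids if family in overlaps.get(i, set()))
    table = ((a_with, len(a_ids) - a_with), (b_with, len(b_ids) - b_with))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    cells = [table[0][0], table[0][1], table[1][0], table[1][1]]
    if 0 in cells:
        cells = [c + 0.5 for c in cells]
    odds = (
        math.inf
        if cells[1] * cells[2] == 0
        else (cells[0] * cells[3]) / (cells[1] * cells[2])
    )
    return EnrichmentResult(family, table, odds, float(p))


def window_density(
    features: Iterable[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 500_000,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Count features per fixed-width window on each chromosome.

    Windows tile ``[k*step, k*step + window)``; with the default
    ``step = window`` this is non-overlapping tiling (the usual Circos-track
    usage) and each feature lands in exactly the window containing its start,
    so per-chromosome counts conserve totals.  The last partial window is
    included.  Features on chromosomes absent from ``chrom_lengths`` raise.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step = window_bp if step_bp is None else step_bp
    if step <= 0:
        raise ValueError("step_bp must be positive")
    starts: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for f in features:
        if f.chrom not in chrom_lengths:
            raise ValueError(f"feature on unknown chromosome {f.chrom!r}")
        if f.end > chrom_lengths[f.chrom]:
            raise ValueError(
                f"feature {f.chrom}:{f.start}-{f.end} exceeds chromosome length"
            )
        starts[f.chrom].append(f.start)
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_windows = max(1, -(-length // step))  # ceil; last partial included
        pos = sorted(starts[chrom])
        for k in range(n_windows):
            w_start = k * step
            w_end = min(w_start + window_bp, length)
            count = sum(1 for s in pos if w_start <= s < w_end)
            rows.append((chrom, w_start, w_end, count))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end", "count"])
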