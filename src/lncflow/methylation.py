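"""Per-cytosine methylation levels, strand-oriented TSS metaprofiles per
context, and up-/down-regulated group comparisons.

The site-level percent is 100 * meth / (meth + unmeth); zero-coverage sites
are undefined and excluded from averages, never counted as 0.  TSS profiles
are transcript-oriented: negative offsets are 5' (upstream) of the TSS,
which for a - strand transcript is its rightmost transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import METH_CONTEXTS, MethylationRecord, TranscriptModel


@dataclass(frozen=True)
class TssProfile:
    """Binned mean methylation percent around the TSS for one context."""

    context: str
    bins: tuple[tuple[int, int], ...]  # (offset_start, offset_end), 5'->3'
    mean_pct: tuple[float, ...]  # NaN where no covered site
    n_sites: tuple[int, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "context": self.context,
                "bin_start": [b[0] for b in self.bins],
                "bin_end": [b[1] for b in self.bins],
                "mean_pct": self.mean_pct,
                "n_sites": self.n_sites,
            }
        )


@dataclass(frozen=True)
class RegulationGroups:
    up: frozenset[str]
    down: frozenset[str]
    log2fc: "pd.Series"


def site_percent(meth_count: int, unmeth_count: int) -> float:
    """100 * meth / (meth + unmeth); NaN (undefined) when coverage is zero."""
    if meth_count < 0 or unmeth_count < 0:
        raise ValueError("counts must be non-negative")
    total = meth_count + unmeth_count
    if total == 0:
        return float("nan")
    return 100.0 * meth_count / total


def tss_position(t: TranscriptModel) -> int:
    """0-based TSS: span start on +, span end - 1 on -."""
    if t.strand == "+":
        return t.interval.start
    if t.strand == "-":
        return t.interval.end - 1
    raise ValueError(f"{t.transcript_id}: unstranded transcript has no TSS")


def tss_profile(
    transcripts: Iterable[TranscriptModel],
    records: Sequence[MethylationRecord],
    context: str,
    flank_bp: int = 1000,
    bin_bp: int = 50,
    min_coverage: int = 1,
) -> TssProfile:
    """Strand-oriented metaprofile of site percents in [-flank, +flank).

    A site at genomic position p contributes to the bin containing its
    oriented offset (p - tss on +, tss - p on -) when its coverage is at
    least ``min_coverage``.  Bin means are unweighted over contributing
    sites (each cytosine equal weight).
    """
    if context not in METH_CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chrom_groups: dict[str, list[MethylationRecord]] = {}
    for r in records:
        if r.context == context and r.coverage >= min_coverage:
            chrom_groups.setdefault(r.chrom, []).append(r)
    for chrom, recs in chrom_groups.items():
        recs.sort(key=lambda r: r.pos)
        pos = np.array([r.pos for r in recs])
        pct = np.array([site_percent(r.meth_count, r.unmeth_count) for r in recs])
        by_chrom[chrom] = (pos, pct)

    for t in transcripts:
        if t.chrom not in by_chrom:
            continue
        tss = tss_position(t)
        pos, pct = by_chrom[t.chrom]
        lo = np.searchsorted(pos, tss - flank_bp)
        hi = np.searchsorted(pos, tss + flank_bp + 1)
        for p, v in zip(pos[lo:hi], pct[lo:hi]):
            offset = p - tss if t.strand == "+" else tss - p
            if not (-flank_bp <= offset < flank_bp):
                continue
            b = (offset + flank_bp) // bin_bp
            sums[b] += v
            counts[b] += 1

    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = tuple(
        (-flank_bp + k * bin_bp, -flank_bp + (k + 1) * bin_bp)
        for k in range(n_bins)
    )
    return TssProfile(context, bins, tuple(means), tuple(int(c) for c in counts))


def regulation_groups(
    early_means: pd.Series,
    late_means: pd.Series,
    pseudocount: float = 1.0,
    fc_threshold: float = 1.0,
) -> RegulationGroups:
    """Partition transcripts into up/down groups by late-vs-early log2FC."""
    common = early_means.index.intersection(late_means.index)
    if len(common) < len(early_means.index) or len(common) < len(late_means.index):
        raise ValueError("early and late matrices must cover the same transcripts")
    log2fc = np.log2(
        (late_means[common] + pseudocount) / (early_means[common] + pseudocount)
    )
    up = frozenset(log2fc.index[log2fc > fc_threshold])
    down = frozenset(log2fc.index[log2fc < -fc_threshold])
    return RegulationGroups(up, down, log2fc)


def upstream_mean_levels(
    transcripts: Iterable[TranscriptModel],
    records: Sequence[MethylationRecord],
    context: str = "CG",
    flank_bp: int = 1000,
    min_coverage: int = 1,
) -> pd.Series:
    """Per-transcript mean site percent over [-flank, 0) upstream of the TSS.

    Transcripts with no covered upstream site are omitted.
    """
    by_chrom: dict[str, list[MethylationRecord]] = {}
    for r in records:
        if r.context == context and r.coverage >= min_coverage:
            by_chrom.setdefault(r.chrom, []).append(r)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: r.pos)
    out: dict[str, float] = {}
    for t in transcripts:
        recs = by_chrom.get(t.chrom, [])
        tss = tss_position(t)
        vals = []
        for r in recs:
            offset = r.pos - tss if t.strand == "+" else tss - r.pos
            if -flank_bp <= offset < 0:
                vals.append(site_percent(r.meth_count, r.unmeth_count))
        if vals:
            out[t.transcript_id] = float(np.mean(vals))
    return pd.Series(out, dtype=float)


def compare_methylation(
    group_a_levels: Sequence[float], group_b_levels: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test on methylation levels."""
    a = np.asarray(group_a_levels, dtype=float)
    b = np.asarray(group_b_levels, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
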