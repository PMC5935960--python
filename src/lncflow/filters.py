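"""The five-stage filter cascade that turns classified transcripts into the
final lncRNA set, with an auditable per-stage report.

Stage order (category rules happen in :mod:`lncflow.classify`):

1. category — drop transcripts labelled ``discarded``;
2. length — drop transcripts shorter than 200 bp;
3. homology — drop transcripts with a qualifying EST or ncRNA database hit;
4. protein/coding — drop transcripts with a qualifying protein hit or a
   positive coding-potential score;
5. expression — keep transcripts with FPKM > 1 in at least one sample.

All printed inequalities are applied literally: strict ``>`` for coverage,
identity, alignment length and FPKM; E-value cutoffs are ``<=``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .classify import ClassifiedTranscript
from .genomic_io import HomologyHit, TranscriptModel

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class EstThresholds:
    max_e: float = 1e-10
    min_coverage_pct: float = 80.0
    min_identity_pct: float = 80.0


@dataclass(frozen=True)
class NcrnaThresholds:
    max_e: float = 1e-10
    min_identity_pct: float = 90.0
    min_alignment_bp: int = 22


@dataclass(frozen=True)
class ProteinThresholds:
    max_e: float = 1e-10
    min_alignment: int = 50


@dataclass(frozen=True)
class FilterThresholds:
    """Defaults equal the published cutoffs."""

    min_length_bp: int = 200
    est: EstThresholds = field(default_factory=EstThresholds)
    ncrna: NcrnaThresholds = field(default_factory=NcrnaThresholds)
    protein: ProteinThresholds = field(default_factory=ProteinThresholds)
    coding_score_cut: float = 0.0
    min_fpkm: float = 1.0
    min_samples_over_fpkm: int = 1


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterReport:
    """Per-stage survivor counts plus per-transcript removal reasons."""

    stages: list[FilterStage] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append(FilterStage(name, n_in, n_in - n_out, n_out))

    def validate(self) -> None:
        for s in self.stages:
            assert s.n_out == s.n_in - s.n_removed
        for a, b in zip(self.stages, self.stages[1:]):
            assert b.n_in == a.n_out, "stage chaining broken"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_removed, s.n_out) for s in self.stages],
            columns=["stage", "input", "removed", "surviving"],
        )


def hit_is_disqualifying(hit: HomologyHit, thresholds: FilterThresholds) -> bool:
    """True when a single hit meets all of its database's removal criteria."""
    if hit.database == "EST":
        t = thresholds.est
        return (
            hit.e_value <= t.max_e
            and hit.query_coverage_pct > t.min_coverage_pct
            and hit.identity_pct > t.min_identity_pct
        )
    if hit.database == "ncRNA":
        t = thresholds.ncrna
        return (
            hit.e_value <= t.max_e
            and hit.identity_pct > t.min_identity_pct
            and hit.alignment_length > t.min_alignment_bp
        )
    if hit.database == "protein":
        t = thresholds.protein
        return hit.e_value <= t.max_e and hit.alignment_length > t.min_alignment
    raise ValueError(f"unknown database {hit.database!r}")


def filter_length(
    transcripts: Sequence[ClassifiedTranscript], min_length_bp: int = 200
) -> tuple[list[ClassifiedTranscript], dict[str, str]]:
    """Keep transcripts with summed exon length >= ``min_length_bp``."""
    kept, removed = [], {}
    for c in transcripts:
        if c.transcript.length >= min_length_bp:
            kept.append(c)
        else:
            removed[c.transcript_id] = (
                f"length {c.transcript.length} < {min_length_bp}"
            )
    return kept, removed


def filter_homology(
    transcripts: Sequence[ClassifiedTranscript],
    hits: Iterable[HomologyHit],
    thresholds: FilterThresholds,
    databases: Sequence[str] = ("EST", "ncRNA", "protein"),
) -> tuple[list[ClassifiedTranscript], dict[str, str]]:
    """Remove transcripts with any single disqualifying hit (any-hit rule)."""
    known = {c.transcript_id for c in transcripts}
    flagged: dict[str, str] = {}
    for hit in hits:
        if hit.database not in databases:
            continue
        if hit.query_id not in known:
            warnings.warn(
                f"hit for unknown transcript {hit.query_id!r} ignored",
                stacklevel=2,
            )
            continue
        if hit.query_id not in flagged and hit_is_disqualifying(hit, thresholds):
            flagged[hit.query_id] = f"{hit.database} hit (e={hit.e_value:g})"
    kept = [c for c in transcripts if c.transcript_id not in flagged]
    return kept, flagged


def longest_orf_nt(sequence: str) -> int:
    """Length in nt of the longest forward-strand ORF (ATG..stop inclusive).

    All three forward frames are scanned; an ATG with no downstream in-frame
    stop does not count as an ORF.
    """
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def coding_potential_score(sequence: str) -> float:
    """Heuristic coding-potential score; > 0 flags a transcript as coding.

    score = max(orf_aa / 100, orf_coverage / 0.5) - 1, where orf_aa is the
    longest-ORF length in codons and orf_coverage its fraction of the
    transcript.  This is a documented stand-in for an SVM coding classifier
    with the same decision boundary semantics; externally computed scores can
    be supplied to :func:`run_cascade` instead.
    """
    if not sequence:
        raise ValueError("empty sequence")
    orf_nt = longest_orf_nt(sequence)
    orf_aa = orf_nt / 3.0
    coverage = orf_nt / len(sequence)
    return max(orf_aa / 100.0, coverage / 0.5) - 1.0


def filter_coding_potential(
    transcripts: Sequence[ClassifiedTranscript],
    sequences: Mapping[str, str],
    coding_score_cut: float = 0.0,
    scores: Mapping[str, float] | None = None,
    scorer: Callable[[str], float] = coding_potential_score,
) -> tuple[list[ClassifiedTranscript], dict[str, str]]:
    """Remove transcripts whose coding score exceeds the cut.

    Precomputed ``scores`` take precedence over ``sequences``; transcripts
    with neither are kept with a warning.
    """
    kept, removed = [], {}
    for c in transcripts:
        tid = c.transcript_id
        if scores is not None and tid in scores:
            score = scores[tid]
        elif tid in sequences:
            score = scorer(sequences[tid])
        else:
            warnings.warn(f"no sequence or score for {tid}; kept", stacklevel=2)
            kept.append(c)
            continue
        if score > coding_score_cut:
            removed[tid] = f"coding score {score:.3f} > {coding_score_cut:g}"
        else:
            kept.append(c)
    return kept, removed


def filter_expression(
    transcripts: Sequence[ClassifiedTranscript],
    matrix: pd.DataFrame,
    min_fpkm: float = 1.0,
    min_samples: int = 1,
) -> tuple[list[ClassifiedTranscript], dict[str, str]]:
    """Keep transcripts with FPKM > min_fpkm in >= min_samples samples.

    Transcripts absent from the matrix are treated as all-zero (and removed
    when min_samples >= 1).
    """
    kept, removed = [], {}
    for c in transcripts:
        tid = c.transcript_id
        if tid in matrix.index:
            n_over = int((matrix.loc[tid] > min_fpkm).sum())
        else:
            n_over = 0
        if n_over >= min_samples:
            kept.append(c)
        else:
            removed[tid] = (
                f"FPKM > {min_fpkm:g} in {n_over} sample(s), need {min_samples}"
            )
    return kept, removed


def run_cascade(
    classified: Sequence[ClassifiedTranscript],
    hits: Sequence[HomologyHit],
    sequences: Mapping[str, str],
    matrix: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    scores: Mapping[str, float] | None = None,
) -> tuple[list[ClassifiedTranscript], FilterReport]:
    """Run the full cascade and return survivors plus the audit report."""
    th = thresholds or FilterThresholds()
    report = FilterReport()

    current = [c for c in classified if c.label != "discarded"]
    for c in classified:
        if c.label == "discarded":
            report.reasons[c.transcript_id] = "category: reference match"
    report.add("category", len(classified), len(current))

    survivors, removed = filter_length(current, th.min_length_bp)
    report.reasons.update({k: f"length: {v}" for k, v in removed.items()})
    report.add("length", len(current), len(survivors))
    current = survivors

    survivors, removed = filter_homology(current, hits, th, ("EST", "ncRNA"))
    report.reasons.update({k: f"homology: {v}" for k, v in removed.items()})
    report.add("homology_est_ncrna", len(current), len(survivors))
    current = survivors

    survivors, removed = filter_homology(current, hits, th, ("protein",))
    reasons = {k: f"protein: {v}" for k, v in removed.items()}
    survivors, removed = filter_coding_potential(
        survivors, sequences, th.coding_score_cut, scores
    )
    reasons.update({k: f"coding: {v}" for k, v in removed.items()})
    report.reasons.update(reasons)
    report.add("protein_coding", len(current), len(survivors))
    current = survivors

    survivors, removed = filter_expression(
        current, matrix, th.min_fpkm, th.min_samples_over_fpkm
    )
    report.reasons.update({k: f"expression: {v}" for k, v in removed.items()})
    report.add("expression", len(current), len(survivors))

    report.validate()
    return survivors, report


def category_counts(classified: Iterable[ClassifiedTranscript]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in classified:
        counts[c.label] = counts.get(c.label, 0) + 1
    return counts


def category_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages of each category, rounded half-up to one decimal.

    ``category_percentages({"lincRNA": 70635, "ancRNA": 8085, "slncRNA": 602})``
    gives 89.0 / 10.2 / 0.8.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no transcripts to report")
    out = {}
    for label, n in counts.items():
        pct = Decimal(100 * n) / Decimal(total)
        out[label] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out
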