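"""Positional classification of novel transcripts against a coding reference.

Each stranded novel transcript receives exactly one label:

* ``slncRNA``   — partial same-strand exon overlap with a coding transcript
                  (generic exonic-overlap semantics, i.e. assembler class
                  code 'o'); same-strand overlap that amounts to a reference
                  match (identical intron chain, or full containment within
                  reference exons) is ``discarded`` instead;
* ``ancRNA``    — exon overlap with a coding transcript on the opposite
                  strand only;
* ``intronic``  — span entirely inside one reference intron;
* ``lincRNA``   — none of the above.

Precedence is slncRNA/discarded -> ancRNA -> intronic -> lincRNA: sense
exonic evidence is the strongest claim of relation to a gene, and the
labels partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genomic_io import TranscriptModel

LABELS = ("lincRNA", "ancRNA", "slncRNA", "intronic", "discarded")


@dataclass(frozen=True)
class ClassifiedTranscript:
    transcript: TranscriptModel
    label: str
    evidence: tuple[tuple[str, int], ...] = ()  # (reference id, overlap bp)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def exon_overlap_bp(
    a: TranscriptModel, b: TranscriptModel, same_strand: bool
) -> int:
    """Total exonic overlap in bases between two transcripts.

    Sums intersection lengths over exon pairs (exons within a transcript are
    non-overlapping, so each genomic base is counted once).  Returns 0 when
    the strand condition is not met or the transcripts are on different
    chromosomes (by contract, not an error).
    """
    if a.chrom != b.chrom:
        return 0
    strands_equal = a.strand == b.strand
    if same_strand != strands_equal:
        return 0
    total = 0
    for ea in a.exons:
        if ea.start >= b.interval.end or ea.end <= b.interval.start:
            continue
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def is_reference_match(novel: TranscriptModel, ref: TranscriptModel) -> bool:
    """True when same-strand overlap amounts to a reference match.

    Either the intron chains are identical (non-empty), or every novel exon
    lies fully within the reference's exonic bases.
    """
    if novel.chrom != ref.chrom or novel.strand != ref.strand:
        return False
    n_introns, r_introns = novel.introns, ref.introns
    if n_introns and n_introns == r_introns:
        return True
    # full containment of novel exons inside reference exons
    for e in novel.exons:
        if not any(r.contains(e) for r in ref.exons):
            return False
    return True


class ReferenceIndex:
    """Per-chromosome index of reference coding transcripts."""

    def __init__(self, reference: Iterable[TranscriptModel]) -> None:
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in reference:
            self._by_chrom.setdefault(t.chrom, []).append(t)
        for ts in self._by_chrom.values():
            ts.sort(key=lambda t: (t.interval.start, t.transcript_id))

    def on_chrom(self, chrom: str) -> Sequence[TranscriptModel]:
        return self._by_chrom.get(chrom, ())


def classify_transcript(
    t: TranscriptModel, index: ReferenceIndex
) -> ClassifiedTranscript:
    """Assign the positional category for one stranded novel transcript."""
    if t.unstranded:
        raise ValueError(
            f"{t.transcript_id} is unstranded; exclude unstranded transcripts "
            "before classification"
        )
    refs = index.on_chrom(t.chrom)

    sense: list[tuple[str, int]] = []
    matched = False
    for ref in refs:
        bp = exon_overlap_bp(t, ref, same_strand=True)
        if bp > 0:
            sense.append((ref.transcript_id, bp))
            if is_reference_match(t, ref):
                matched = True
    if sense:
        label = "discarded" if matched else "slncRNA"
        return ClassifiedTranscript(t, label, tuple(sorted(sense)))

    antisense = []
    for ref in refs:
        bp = exon_overlap_bp(t, ref, same_strand=False)
        if bp > 0:
            antisense.append((ref.transcript_id, bp))
    if antisense:
        return ClassifiedTranscript(t, "ancRNA", tuple(sorted(antisense)))

    for ref in refs:
        for intron in ref.introns:
            if intron.contains(t.interval):
                return ClassifiedTranscript(
                    t, "intronic", ((ref.transcript_id, 0),)
                )

    return ClassifiedTranscript(t, "lincRNA", ())


def classify_all(
    novel: Iterable[TranscriptModel],
    reference: Iterable[TranscriptModel],
    skip_unstranded: bool = True,
) -> list[ClassifiedTranscript]:
    """Classify every stranded novel transcript against the reference."""
    index = ReferenceIndex(reference)
    out = []
    for t in novel:
        if t.unstranded:
            if skip_unstranded:
                continue
            raise ValueError(f"{t.transcript_id} is unstranded")
        out.append(classify_transcript(t, index))
    return out


def classification_table(classified: Iterable[ClassifiedTranscript]) -> pd.DataFrame:
    rows = []
    for c in classified:
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "label": c.label,
                "evidence_ids": ",".join(e[0] for e in c.evidence),
                "overlap_bp": sum(e[1] for e in c.evidence),
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "label", "evidence_ids", "overlap_bp"]
    )
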