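"""Toy-scale simulator with planted ground truth.

Generates a reference coding annotation, novel transcripts of every planted
positional class, TE tracks, homology-hit tables, transcript sequences,
expression matrices with planted specificity/DE structure, and per-cytosine
methylation reports — everything the downstream stages read — plus a
machine-readable truth table.  All outputs are deterministic given the seed,
and every noise knob can be turned to zero so planted values are recovered
exactly.

Geometry: each coding gene occupies a fixed-width slot on its chromosome
(two 1 kb exons around a 1 kb intron).  Planted classes attach to slots:

* ancRNA      — single exon overlapping exon 1 on the opposite strand;
* slncRNA     — single exon partially overlapping exon 1 on the same strand,
                running into the intron (so it is neither contained in
                reference exons nor intron-chain identical);
* intronic    — single exon entirely inside the intron;
* lincRNA     — single exon in the intergenic zone of the slot;
* decoy_coding — intergenic like a lincRNA, but its emitted sequence carries
                a long ORF and its hit-table rows qualify for removal; this
                is how the database filter stages are exercised without
                running an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    GenomicInterval,
    HomologyHit,
    MethylationRecord,
    TEFeature,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_hits,
    write_methylation_report,
    write_reference_gff3,
    write_table,
    write_te_bed,
)

DEFAULT_TISSUES = (
    "leaf", "root", "seed", "peel", "flesh", "embryo", "anther", "bud",
    "hypocotyl", "flower", "stem", "pericarp", "septum", "locule",
    "placenta", "sepal", "petiole", "meristem",
)
DEFAULT_TE_FAMILIES = (
    "LTR/Gypsy", "LTR/Copia", "LINE/L1", "DNA/hAT",
    "Low_complexity", "Simple_repeat",
)
STAGES = ("MG", "BR", "BR+7")

# stage-mean FPKM patterns cycled over planted transcripts (MG, BR, BR+7)
STAGE_PATTERNS = (
    (2.0, 2.0, 2.0),     # flat low
    (40.0, 40.0, 40.0),  # flat high
    (10.0, 40.0, 40.0),  # up at BR, stays up
    (40.0, 10.0, 10.0),  # down at BR, stays down
    (15.0, 15.0, 40.0),  # up late
)

_SLOT = 12_000
_GENE_OFFSET = 1_000  # gene occupies [slot+1000, slot+4000)


@dataclass(frozen=True)
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_coding_genes: int = 30
    n_lincrna: int = 10
    n_ancrna: int = 8
    n_slncrna: int = 8
    n_intronic: int = 4
    n_decoy_coding: int = 6
    tissues: Sequence[str] = DEFAULT_TISSUES
    tissue_reps: int = 2
    stage_reps: int = 3
    seed: int = 0
    fpkm_dispersion: float = 0.0  # sigma of multiplicative lognormal noise
    meth_concentration: float | None = None  # None = no noise (limit)
    meth_depth: int = 20
    meth_flank_bp: int = 1000
    meth_bin_bp: int = 50
    meth_site_spacing: int = 20
    n_te: int = 120
    te_families: Sequence[str] = DEFAULT_TE_FAMILIES

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "n_coding_genes", "tissue_reps",
            "stage_reps", "meth_depth", "meth_flank_bp", "meth_bin_bp",
            "meth_site_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_lincrna", "n_ancrna", "n_slncrna", "n_intronic",
                     "n_decoy_coding", "n_te"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fpkm_dispersion < 0:
            raise ValueError("fpkm_dispersion must be >= 0")
        genes_per_chrom = -(-self.n_coding_genes // self.n_chroms)
        needed = genes_per_chrom * _SLOT + _GENE_OFFSET
        if needed > self.chrom_length:
            raise ValueError(
                f"cannot place {self.n_coding_genes} genes on {self.n_chroms} "
                f"chromosome(s) of {self.chrom_length} bp; increase "
                f"chrom_length to at least {needed}"
            )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: list[TranscriptModel]
    novel: list[TranscriptModel]
    tes: list[TEFeature]
    hits: list[HomologyHit]
    sequences: dict[str, str]
    chrom_sizes: dict[str, int]
    truth: pd.DataFrame  # indexed by transcript_id
    expression: pd.DataFrame | None = None
    design: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact as plain text; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"seed={self.config.seed}"
        paths = {
            "reference": outdir / "reference.gff3",
            "novel": outdir / "novel.gtf",
            "te": outdir / "te.bed",
            "hits": outdir / "hits.tsv",
            "fasta": outdir / "transcripts.fa",
            "chrom_sizes": outdir / "chrom.sizes",
            "truth": outdir / "truth.tsv",
        }
        write_reference_gff3(self.reference, paths["reference"], header=[tag])
        write_gtf(self.novel, paths["novel"], header=[tag])
        write_te_bed(self.tes, paths["te"], header=[tag])
        write_hits(self.hits, paths["hits"], header=[tag])
        write_fasta(self.sequences, paths["fasta"])
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        write_table(
            self.truth.reset_index(names="transcript_id"),
            paths["truth"], header=[tag],
        )
        if self.expression is not None:
            paths["expression"] = outdir / "fpkm.tsv"
            paths["design"] = outdir / "design.tsv"
            write_table(
                self.expression.reset_index(names="transcript_id"),
                paths["expression"], header=[tag],
            )
            write_table(self.design, paths["design"], header=[tag])
        return paths


def _random_seq(rng: np.random.Generator, length: int,
                alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _noncoding_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence with a non-positive coding score (rejection-sampled)."""
    from .filters import coding_potential_score

    for _ in range(50):
        seq = _random_seq(rng, length)
        if coding_potential_score(seq) <= 0:
            return seq
    return _random_seq(rng, length, alphabet="CGT")  # no ATG possible


def _decoy_seq(rng: np.random.Generator, length: int = 600) -> str:
    """Sequence with a 450-nt ORF (150 codons, 75% coverage): score 0.5."""
    non_stop = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    orf = "ATG" + "".join(rng.choice(non_stop, size=148)) + "TAA"
    pad = length - len(orf) - 50
    return _random_seq(rng, 50, "CGT") + orf + _random_seq(rng, pad, "CGT")


def simulate_genome(config: SimulationConfig) -> SimulatedDataset:
    """Generate the annotation, novel transcripts, TEs, hits and sequences."""
    rng = np.random.default_rng([config.seed, 1])
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    chroms = list(chrom_sizes)

    reference: list[TranscriptModel] = []
    slots: list[tuple[str, int, str]] = []  # (chrom, slot_start, gene_strand)
    for g in range(config.n_coding_genes):
        chrom = chroms[g % config.n_chroms]
        slot = (g // config.n_chroms) * _SLOT
        strand = "+" if rng.random() < 0.5 else "-"
        s = slot + _GENE_OFFSET
        exons = [
            GenomicInterval(chrom, s, s + 1000, strand),
            GenomicInterval(chrom, s + 2000, s + 3000, strand),
        ]
        reference.append(
            TranscriptModel.from_exons(
                f"mRNA{g:03d}", f"gene{g:03d}", exons, biotype="coding"
            )
        )
        slots.append((chrom, slot, strand))

    novel: list[TranscriptModel] = []
    truth_rows: list[dict] = []

    def add(tid: str, cls: str, chrom: str, start: int, end: int,
            strand: str) -> None:
        exon = GenomicInterval(chrom, start, end, strand)
        novel.append(TranscriptModel.from_exons(tid, tid, [exon], "novel"))
        truth_rows.append({"transcript_id": tid, "class": cls})

    def slot_for(i: int) -> tuple[str, int, str]:
        if not slots:
            raise ValueError("no coding genes to attach planted transcripts to")
        return slots[i % len(slots)]

    counter = 0
    for i in range(config.n_ancrna):
        chrom, slot, strand = slot_for(counter); counter += 1
        opp = "-" if strand == "+" else "+"
        s = slot + _GENE_OFFSET
        add(f"ANC{i:03d}", "ancRNA", chrom, s + 500, s + 1300, opp)
    for i in range(config.n_slncrna):
        chrom, slot, strand = slot_for(counter); counter += 1
        s = slot + _GENE_OFFSET
        add(f"SLNC{i:03d}", "slncRNA", chrom, s + 700, s + 1500, strand)
    for i in range(config.n_intronic):
        chrom, slot, strand = slot_for(counter); counter += 1
        s = slot + _GENE_OFFSET
        intron_strand = "+" if rng.random() < 0.5 else "-"
        add(f"INTR{i:03d}", "intronic", chrom, s + 1200, s + 1700, intron_strand)
    for i in range(config.n_lincrna):
        chrom, slot, _ = slot_for(counter); counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(400, 801))
        start = slot + 6000
        add(f"LINC{i:03d}", "lincRNA", chrom, start, start + length, strand)
    for i in range(config.n_decoy_coding):
        chrom, slot, _ = slot_for(counter); counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        add(f"DECOY{i:03d}", "decoy_coding", chrom, slot + 8000, slot + 8600, strand)

    # TE track: uniform random placement, random family
    tes = []
    for _ in range(config.n_te):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(100, 1501))
        start = int(rng.integers(0, config.chrom_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        family = str(rng.choice(list(config.te_families)))
        tes.append(TEFeature(GenomicInterval(chrom, start, start + length, strand),
                             family))

    # sequences and hit tables
    sequences: dict[str, str] = {}
    hits: list[HomologyHit] = []
    decoy_hit_cycle = ("EST", "ncRNA", "protein")
    n_decoy_seen = 0
    for t in novel:
        cls = truth_rows[[r["transcript_id"] for r in truth_rows].index(
            t.transcript_id)]["class"]
        if cls == "decoy_coding":
            sequences[t.transcript_id] = _decoy_seq(rng, max(600, t.length))
            db = decoy_hit_cycle[n_decoy_seen % 3]
            n_decoy_seen += 1
            if db == "EST":
                hits.append(HomologyHit(t.transcript_id, "EST", 1e-12, 92.0,
                                        300, 90.0))
            elif db == "ncRNA":
                hits.append(HomologyHit(t.transcript_id, "ncRNA", 1e-15, 95.0,
                                        80, 60.0))
            else:
                hits.append(HomologyHit(t.transcript_id, "protein", 1e-20, 70.0,
                                        100, 50.0))
        else:
            sequences[t.transcript_id] = _noncoding_seq(rng, t.length)
            if rng.random() < 0.3:  # weak, non-qualifying hit
                hits.append(HomologyHit(t.transcript_id, "EST", 1e-4, 60.0,
                                        40, 30.0))

    # brute-force distance to nearest coding gene span
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    dists = []
    for t in novel:
        best = None
        for m in reference:
            if m.chrom != t.chrom:
                continue
            gap = max(0, m.interval.start - t.interval.end,
                      t.interval.start - m.interval.end)
            best = gap if best is None else min(best, gap)
        dists.append(best if best is not None else -1)
    truth["distance_to_nearest_mrna"] = dists

    return SimulatedDataset(
        config=config,
        reference=reference,
        novel=novel,
        tes=tes,
        hits=hits,
        sequences=sequences,
        chrom_sizes=chrom_sizes,
        truth=truth,
    )


def simulate_expression(sim: SimulatedDataset) -> None:
    """Attach an FPKM matrix + design with planted specificity/DE structure.

    Tissue block: every transcript gets a planted specificity category
    (cycled specific / uniform / heterogeneous); "specific" puts all
    expression in one tissue (entropy 0), "uniform" equal means everywhere
    (entropy log2 t), "heterogeneous" equal means in 4 tissues (entropy 2).
    Stage block: stage-mean patterns are cycled from STAGE_PATTERNS; each
    coding gene inherits the pattern of the planted transcript occupying its
    slot (so DE lncRNAs have a correlated DE mRNA nearby).  Replicate noise
    is multiplicative lognormal with ``fpkm_dispersion``; zeros stay exact.
    """
    config = sim.config
    rng = np.random.default_rng([config.seed, 2])
    tissues = list(config.tissues)
    n_t = len(tissues)

    samples, tissue_col, stage_col = [], [], []
    for tis in tissues:
        for r in range(config.tissue_reps):
            samples.append(f"{tis}_r{r + 1}")
            tissue_col.append(tis)
            stage_col.append(".")
    for st in STAGES:
        for r in range(config.stage_reps):
            samples.append(f"{st}_r{r + 1}")
            tissue_col.append(".")
            stage_col.append(st)
    design = pd.DataFrame(
        {"sample": samples, "tissue": tissue_col, "stage": stage_col}
    )

    spec_cats = ("tissue-specific", "uniform", "heterogeneous")
    all_tx = sim.novel + sim.reference
    tissue_means = {}
    stage_means = {}
    spec_of = {}
    gene_pattern: dict[str, int] = {}

    for i, t in enumerate(sim.novel):
        cat = spec_cats[i % 3]
        spec_of[t.transcript_id] = cat
        means = np.zeros(n_t)
        if cat == "tissue-specific":
            means[i % n_t] = 50.0
        elif cat == "uniform":
            means[:] = 20.0
        else:  # 4 equal tissues -> entropy exactly 2 bits
            means[[(i + k) % n_t for k in range(4)]] = 25.0
        tissue_means[t.transcript_id] = means
        pattern = i % len(STAGE_PATTERNS)
        stage_means[t.transcript_id] = STAGE_PATTERNS[pattern]
        # the coding gene of this transcript's slot mirrors its stage pattern
        host = i % len(sim.reference) if sim.reference else None
        if host is not None:
            gene_pattern.setdefault(sim.reference[host].transcript_id, pattern)

    for j, m in enumerate(sim.reference):
        spec_of[m.transcript_id] = "uniform"
        tissue_means[m.transcript_id] = np.full(n_t, 30.0)
        pattern = gene_pattern.get(m.transcript_id, 1)
        stage_means[m.transcript_id] = STAGE_PATTERNS[pattern]

    sigma = config.fpkm_dispersion
    rows = []
    for t in all_tx:
        tid = t.transcript_id
        vals = []
        for tis in tissues:
            mu = tissue_means[tid][tissues.index(tis)]
            for _ in range(config.tissue_reps):
                noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                vals.append(mu * noise if mu > 0 else 0.0)
        for k, st in enumerate(STAGES):
            mu = stage_means[tid][k]
            for _ in range(config.stage_reps):
                noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                vals.append(mu * noise if mu > 0 else 0.0)
        rows.append(vals)
    matrix = pd.DataFrame(rows, index=[t.transcript_id for t in all_tx],
                          columns=samples)
    matrix.index.name = "transcript_id"

    # planted truth columns from the noise-free means (pseudocount 1)
    truth = sim.truth
    truth["specificity_category"] = [
        spec_of[tid] for tid in truth.index
    ]
    for a, b in (("MG", "BR"), ("MG", "BR+7"), ("BR", "BR+7")):
        ia, ib = STAGES.index(a), STAGES.index(b)
        flags = []
        for tid in truth.index:
            mA, mB = stage_means[tid][ia], stage_means[tid][ib]
            flags.append(abs(np.log2((mA + 1) / (mB + 1))) > 1)
        truth[f"de_{a}-vs-{b}"] = flags
    reg = []
    for tid in truth.index:
        fc = np.log2((stage_means[tid][2] + 1) / (stage_means[tid][0] + 1))
        reg.append("up" if fc > 1 else ("down" if fc < -1 else "flat"))
    truth["regulation"] = reg
    for k, st in enumerate(STAGES):
        truth[f"high_{st}"] = [stage_means[tid][k] > 10 for tid in truth.index]

    sim.expression = matrix
    sim.design = design


# --- methylation ----------------------------------------------------------

_BASE_LEVELS = {
    # (class, context): (upstream_pct, downstream_pct); multiples of 5 so the
    # no-noise limit with depth 20 reproduces them exactly
    ("mRNA", "CG"): (45, 70),
    ("mRNA", "CHG"): (40, 10),
    ("mRNA", "CHH"): (30, 5),
    ("lincRNA", "CG"): (80, 60),
    ("lincRNA", "CHG"): (45, 40),
    ("lincRNA", "CHH"): (35, 30),
}
_CONTEXT_SHIFT = {"CG": 0, "CHG": 7, "CHH": 13}


def planted_profile(feature_class: str, context: str, config: SimulationConfig,
                    delta: int = 0) -> np.ndarray:
    """Planted mean methylation percent per TSS bin (length 2*flank/bin)."""
    n_bins = 2 * config.meth_flank_bp // config.meth_bin_bp
    up, down = _BASE_LEVELS[(feature_class, context)]
    prof = np.empty(n_bins)
    prof[: n_bins // 2] = up
    prof[n_bins // 2 :] = down
    prof = np.clip(prof - delta, 0, 100)
    return prof


def simulate_methylation(
    sim: SimulatedDataset, delta: int = 0
) -> list[MethylationRecord]:
    """Per-cytosine records around the TSS of mRNAs and planted lincRNAs.

    Counts follow the planted strand-oriented bin profile; with
    ``meth_concentration=None`` (the no-noise limit) meth counts equal
    round(mu * depth) exactly.  ``delta`` shifts all planted levels down
    (use it to emit a hypomethylated "late stage" report).
    """
    from .methylation import tss_position

    config = sim.config
    rng = np.random.default_rng([config.seed, 3, delta])
    flank, spacing = config.meth_flank_bp, config.meth_site_spacing
    depth, conc = config.meth_depth, config.meth_concentration

    targets = [(m, "mRNA") for m in sim.reference]
    linc_ids = set(sim.truth.index[sim.truth["class"] == "lincRNA"])
    targets += [(t, "lincRNA") for t in sim.novel
                if t.transcript_id in linc_ids]

    records = []
    for t, cls in targets:
        tss = tss_position(t)
        for context in ("CG", "CHG", "CHH"):
            prof = planted_profile(cls, context, config, delta)
            shift = _CONTEXT_SHIFT[context]
            for offset in range(-flank + shift, flank, spacing):
                pos = tss + offset if t.strand == "+" else tss - offset
                if not (0 <= pos < sim.chrom_sizes[t.chrom]):
                    continue
                b = (offset + flank) // config.meth_bin_bp
                mu = prof[b] / 100.0
                if conc is None:
                    meth = int(round(mu * depth))
                else:
                    p = mu
                    if 0 < mu < 1:
                        p = rng.beta(conc * mu, conc * (1 - mu))
                    meth = int(rng.binomial(depth, p))
                records.append(
                    MethylationRecord(
                        chrom=t.chrom,
                        pos=pos,
                        strand=t.strand,
                        meth_count=meth,
                        unmeth_count=depth - meth,
                        context=context,
                    )
                )
    return records


def simulate_null_matrix(
    n_transcripts: int = 1000,
    reps: int = 3,
    mean_fpkm: float = 20.0,
    dispersion: float = 0.3,
    seed: int = 0,
    stages: Sequence[str] = STAGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A no-DE expression matrix (every transcript has equal stage means).

    Used to measure the empirical false-positive rate of the DE stage.
    """
    rng = np.random.default_rng(seed)
    samples, stage_col = [], []
    for st in stages:
        for r in range(reps):
            samples.append(f"{st}_r{r + 1}")
            stage_col.append(st)
    values = mean_fpkm * np.exp(
        rng.normal(0.0, dispersion, size=(n_transcripts, len(samples)))
    )
    matrix = pd.DataFrame(
        values,
        index=[f"NULL{i:05d}" for i in range(n_transcripts)],
        columns=samples,
    )
    matrix.index.name = "transcript_id"
    design = pd.DataFrame(
        {"sample": samples, "tissue": ["."] * len(samples), "stage": stage_col}
    )
    return matrix, design
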