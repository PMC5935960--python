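"""Ripening-stage analysis: expressed sets, differential expression with
BH-FDR, Venn partitioning of contrasts, nearest-mRNA pairing and pair
correlation.

The default DE test is an exact replicate-label permutation test on
log2(FPKM + pseudocount) — assumption-light and exactly enumerable at small
replicate numbers.  Note its granularity: with nA + nB total replicates the
smallest achievable two-sided p is bounded below by 2/C(nA+nB, nA), so with
3 vs 3 replicates p >= 0.1.  A Welch t-test route (``method="ttest"``) and a
hook for externally computed p-values are provided for designs where that
floor matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import TranscriptModel

STAGES = ("MG", "BR", "BR+7")
CONTRASTS = (("MG", "BR"), ("MG", "BR+7"), ("BR", "BR+7"))


@dataclass(frozen=True)
class LncMrnaPair:
    lnc_id: str
    mrna_id: str
    distance_bp: int
    pearson_r: float  # NaN when undefined (zero-variance vector)


def _stage_samples(design: pd.DataFrame, stage: str) -> list[str]:
    samples = design.loc[design["stage"] == stage, "sample"].tolist()
    if not samples:
        raise ValueError(f"stage {stage!r} not present in design")
    return samples


def expressed_set(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    min_mean_fpkm: float = 10.0,
) -> set[str]:
    """Transcripts with mean FPKM strictly above the floor in one stage."""
    samples = _stage_samples(design, stage)
    means = matrix[samples].mean(axis=1)
    return set(means.index[means > min_mean_fpkm])


def _permutation_pvalues(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Two-sided label-permutation p-values on rows of a (n_tx, nA) and
    b (n_tx, nB); exact enumeration when the assignment count is small."""
    n_a, n_b = a.shape[1], b.shape[1]
    x = np.hstack([a, b])
    n = n_a + n_b
    obs = a.mean(axis=1) - b.mean(axis=1)
    combos = list(combinations(range(n), n_a))
    if len(combos) <= max(n_perm, 1000):  # exact enumeration
        count = np.zeros(x.shape[0], dtype=int)
        for idx_a in combos:
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            stat = x[:, mask].mean(axis=1) - x[:, ~mask].mean(axis=1)
            count += np.abs(stat) >= np.abs(obs) - 1e-12
        return count / len(combos)
    count = np.zeros(x.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = x[:, perm[:n_a]].mean(axis=1) - x[:, perm[n_a:]].mean(axis=1)
        count += np.abs(stat) >= np.abs(obs) - 1e-12
    return (count + 1) / (n_perm + 1)


def de_test(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
    method: str = "permutation",
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    external_p: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Differential expression for one stage contrast.

    Returns a table with columns transcript_id, contrast, log2fc, p, q,
    significant; q is Benjamini–Hochberg over all tested transcripts and
    significant <=> |log2fc| > fc_threshold and q < q_threshold.
    """
    stage_a, stage_b = contrast
    samples_a = _stage_samples(design, stage_a)
    samples_b = _stage_samples(design, stage_b)
    mean_a = matrix[samples_a].mean(axis=1).values
    mean_b = matrix[samples_b].mean(axis=1).values
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    if external_p is not None:
        p = np.array([external_p[t] for t in matrix.index], dtype=float)
    else:
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError(
                "need >= 2 replicates per stage (or supply external_p)"
            )
        la = np.log2(matrix[samples_a].values + pseudocount)
        lb = np.log2(matrix[samples_b].values + pseudocount)
        if method == "permutation":
            rng = np.random.default_rng(seed)
            p = _permutation_pvalues(la, lb, n_perm, rng)
        elif method == "ttest":
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
            p = np.where(np.isnan(p), 1.0, p)  # zero variance both groups
        else:
            raise ValueError(f"unknown method {method!r}")

    _, q, _, _ = multipletests(p, method="fdr_bh")
    significant = (np.abs(log2fc) > fc_threshold) & (q < q_threshold)
    return pd.DataFrame(
        {
            "transcript_id": matrix.index,
            "contrast": f"{stage_a}-vs-{stage_b}",
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": significant,
        }
    ).reset_index(drop=True)


def venn_partition(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }


def nearest_mrna(
    lnc: TranscriptModel, mrnas: Sequence[TranscriptModel]
) -> tuple[str | None, int | None]:
    """Nearest same-chromosome mRNA by span gap (0 if overlapping/adjacent).

    Strand-ignorant; ties broken by lexicographically smallest mRNA id.
    Returns (None, None) when no same-chromosome candidate exists.
    """
    best: tuple[int, str] | None = None
    for m in mrnas:
        if m.chrom != lnc.chrom:
            continue
        gap = max(
            0,
            m.interval.start - lnc.interval.end,
            lnc.interval.start - m.interval.end,
        )
        key = (gap, m.transcript_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[1], best[0]


def pair_and_correlate(
    de_lnc_ids: Iterable[str],
    de_mrna_ids: Iterable[str],
    lnc_models: Mapping[str, TranscriptModel],
    mrna_models: Mapping[str, TranscriptModel],
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    max_distance: int = 10_000,
    proximity_bp: int = 30_000,
    pseudocount: float = 1.0,
    stages: Sequence[str] = STAGES,
) -> tuple[list[LncMrnaPair], float]:
    """Pair each DE lncRNA with its nearest DE mRNA within ``max_distance``.

    Pearson r is computed across all samples of the given stages on
    log2(FPKM + pseudocount); zero-variance vectors yield NaN (pair kept).
    Also returns the fraction of DE lncRNAs whose nearest DE mRNA lies
    within ``proximity_bp``.
    """
    candidates = [mrna_models[m] for m in de_mrna_ids if m in mrna_models]
    samples = [
        s for st in stages for s in design.loc[design["stage"] == st, "sample"]
    ]
    if not samples:
        raise ValueError("no stage samples in design")
    pairs: list[LncMrnaPair] = []
    distances: list[int] = []
    for lnc_id in sorted(set(de_lnc_ids)):
        lnc = lnc_models.get(lnc_id)
        if lnc is None:
            continue
        mrna_id, dist = nearest_mrna(lnc, candidates)
        if mrna_id is None:
            continue
        distances.append(dist)
        if dist >= max_distance:
            continue
        x = np.log2(matrix.loc[lnc_id, samples].values.astype(float) + pseudocount)
        y = np.log2(matrix.loc[mrna_id, samples].values.astype(float) + pseudocount)
        if np.std(x) == 0 or np.std(y) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(x, y).statistic)
        pairs.append(LncMrnaPair(lnc_id, mrna_id, dist, r))
    frac_close = (
        sum(1 for d in distances if d < proximity_bp) / len(distances)
        if distances
        else float("nan")
    )
    return pairs, frac_close
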