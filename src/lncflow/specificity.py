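"""Shannon-entropy tissue-specificity scoring.

For transcript i with per-tissue mean FPKM v_ij, relative frequencies are
p_ij = v_ij / sum_j v_ij and the score is H_i = -sum_j p_ij * log2(p_ij)
with the 0*log(0) = 0 convention.  H ranges from 0 (expressed in a single
tissue) to log2(t) (uniform over t tissues); all-zero rows are undefined
rather than 0, since 0 means maximal specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("tissue-specific", "heterogeneous", "uniform", "undefined")
DEFAULT_SPECIFIC_MAX = 1.0
DEFAULT_UNIFORM_MIN = 3.0


@dataclass(frozen=True)
class EntropyResult:
    transcript_id: str
    H: float  # NaN when undefined
    category: str
    n_tissues: int


def tissue_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean FPKM per transcript per tissue (arithmetic mean over replicates).

    Samples with tissue "." in the design (e.g. pure stage samples) are
    ignored.  Raises if a matrix sample is missing from the design or a
    selected tissue ends up with zero samples.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    tissue_of = design["tissue"]
    cols = [s for s in matrix.columns if tissue_of[s] != "."]
    if not cols:
        raise ValueError("no tissue-annotated samples in matrix")
    groups = matrix[cols].T.groupby(tissue_of[cols])
    if any(n == 0 for n in groups.size()):
        raise ValueError("tissue with zero samples")
    return groups.mean().T


def entropy(values) -> float:
    """Shannon entropy in bits of one transcript's per-tissue means.

    Returns NaN for an all-zero row (undefined).  Negative values raise.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D row over >= 2 tissues")
    if (v < 0).any():
        raise ValueError("negative expression value")
    total = v.sum()
    if total == 0:
        return float("nan")
    p = v / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) + 0.0  # normalize -0.0


def categorize(
    H: float,
    specific_max: float = DEFAULT_SPECIFIC_MAX,
    uniform_min: float = DEFAULT_UNIFORM_MIN,
) -> str:
    """H < specific_max -> tissue-specific; H > uniform_min -> uniform;
    otherwise heterogeneous.  NaN -> undefined."""
    if math.isnan(H):
        return "undefined"
    if H < specific_max:
        return "tissue-specific"
    if H > uniform_min:
        return "uniform"
    return "heterogeneous"


def entropy_table(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    specific_max: float = DEFAULT_SPECIFIC_MAX,
    uniform_min: float = DEFAULT_UNIFORM_MIN,
) -> pd.DataFrame:
    """Per-transcript entropy scores and categories as a tidy table."""
    means = tissue_means(matrix, design)
    t = means.shape[1]
    rows = []
    for tid, row in means.iterrows():
        h = entropy(row.values)
        rows.append((tid, h, categorize(h, specific_max, uniform_min), t))
    return pd.DataFrame(rows, columns=["transcript_id", "H", "category", "t"])
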