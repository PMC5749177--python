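"""Per-individual inter-individual variability of a molecular phenotype.

For a phenotype matrix of N individuals by L loci, the statistic for
individual n is the average squared relative distance from the per-locus
mean, with the unbiased-variance correction:

    V_n = N / (L (N - 1)) * sum_l (x_nl - xbar_l)^2 / xbar_l^2

V_n is invariant to rescaling the whole matrix and is reported on a log2
scale (V_n = 0 maps to -inf).  Loci with zero mean are dropped (and counted)
before L is determined.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("orbweaver")


class VariabilityError(ValueError):
    pass


def variability(
    matrix: pd.DataFrame | np.ndarray, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """V_n and log2(V_n) per individual.

    ``matrix`` is individuals x loci (a DataFrame indexed by sample id, or a
    plain array with ``sample_ids``).  Returns a DataFrame with columns
    ``sample``, ``v_n``, ``log2_vn``.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        ids = [str(s) for s in matrix.index]
    else:
        values = np.asarray(matrix, dtype=float)
        ids = sample_ids or [f"sample_{i}" for i in range(values.shape[0])]
    if values.ndim != 2:
        raise VariabilityError("phenotype matrix must be 2-D (individuals x loci)")
    n, total_loci = values.shape
    if n < 2:
        raise VariabilityError("need at least 2 individuals")
    if not np.all(np.isfinite(values)):
        raise VariabilityError("phenotype matrix contains non-finite values")

    means = values.mean(axis=0)
    keep = means != 0.0
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d loci with zero mean", dropped)
    if not keep.any():
        raise VariabilityError("all loci have zero mean")
    values, means = values[:, keep], means[keep]
    L = values.shape[1]

    rel_sq = ((values - means) / means) ** 2
    v = n / (L * (n - 1)) * rel_sq.sum(axis=1)
    with np.errstate(divide="ignore"):
        log2_v = np.log2(v)
    return pd.DataFrame({"sample": ids, "v_n": v, "log2_vn": log2_v})


def read_matrix_tsv(path: str) -> pd.DataFrame:
    """Loci x individuals TSV (header row of sample ids) -> individuals x loci."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def compare_variability(v_a: np.ndarray, v_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Mann-Whitney rank test between two groups' V_n values."""
    stat, p = stats.mannwhitneyu(v_a, v_b, alternative="two-sided")
    return float(stat), float(p)
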