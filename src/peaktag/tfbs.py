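"""Binarized transcription-factor binding-site matrices and pioneer regressions.

A TF "binds" an ATAC peak when any of its ChIP-seq (or motif) intervals
overlaps the peak (half-open semantics), and binds a gene when an interval
overlaps the gene's promoter (TSS±1kb, clipped at the chromosome start). The
number of TFs shared by a pair of elements is the dot product of their binary
TFBS rows. Pioneer TFs — factors able to open closed chromatin — are flagged
from a user-supplied list; the bivariate regression of a score (e.g.
co-accessibility) on the pioneer and non-pioneer binding counts compares
their per-TF effects with a Wald test on the coefficient difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._intervals import any_overlap
from .core import GeneSet, PeakSet

PROMOTER_HALF_WIDTH = 1_000  # promoter window: TSS +/- 1kb


@dataclass
class TFBSMatrix:
    """Elements x TFs binary matrix with pioneer flags."""

    matrix: np.ndarray
    element_ids: np.ndarray
    tf_names: list
    pioneer: np.ndarray  # bool per TF

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("TFBS matrix entries must be 0/1")
        self.pioneer = np.asarray(self.pioneer, dtype=bool)
        if self.matrix.shape != (len(self.element_ids), len(self.tf_names)):
            raise ValueError("TFBS matrix shape inconsistent with names")
        if len(self.pioneer) != len(self.tf_names):
            raise ValueError("pioneer flags must match TF names")

    def tf_counts(self) -> np.ndarray:
        """Number of TFs bound per element (row sums)."""
        return self.matrix.sum(axis=1)

    def pioneer_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(pioneer, non-pioneer) binding counts per element."""
        return self.matrix[:, self.pioneer].sum(axis=1), self.matrix[:, ~self.pioneer].sum(axis=1)


def build_tfbs(
    peaks: PeakSet,
    genes: GeneSet,
    chip_intervals: dict[str, pd.DataFrame],
    pioneer_list=(),
) -> tuple[TFBSMatrix, TFBSMatrix]:
    """Binarized TFBS matrices for peaks and for gene promoters (TSS±1kb).

    ``chip_intervals`` maps TF name -> DataFrame(chrom, start, end) of binding
    intervals (narrowPeak-style; only the first three columns are used). A TF
    with no intervals yields an all-zero column with a warning.
    """
    pioneer_set = set(pioneer_list)
    tf_names = list(chip_intervals)
    pioneer = np.array([t in pioneer_set for t in tf_names], dtype=bool)

    prom_start = np.maximum(genes.tss - PROMOTER_HALF_WIDTH, 0)
    prom_end = genes.tss + PROMOTER_HALF_WIDTH
    prom_df = pd.DataFrame({"chrom": genes.chroms, "start": prom_start, "end": prom_end})
    peak_df = peaks.df

    peak_mat = np.zeros((len(peaks), len(tf_names)), dtype=np.int8)
    prom_mat = np.zeros((len(genes), len(tf_names)), dtype=np.int8)
    for t, name in enumerate(tf_names):
        iv = chip_intervals[name]
        if iv is None or len(iv) == 0:
            warnings.warn(f"TF {name!r} has no intervals; all-zero column", stacklevel=2)
            continue
        for target_df, mat in ((peak_df, peak_mat), (prom_df, prom_mat)):
            for chrom, sub in iv.groupby("chrom", sort=False):
                on = np.flatnonzero((target_df["chrom"] == chrom).to_numpy())
                if on.size == 0:
                    continue
                hit = any_overlap(
                    target_df["start"].to_numpy()[on],
                    target_df["end"].to_numpy()[on],
                    sub["start"].to_numpy(),
                    sub["end"].to_numpy(),
                )
                mat[on[hit], t] = 1
    return (
        TFBSMatrix(peak_mat, peaks.ids, tf_names, pioneer),
        TFBSMatrix(prom_mat, genes.ids, tf_names, pioneer),
    )


def tf_counts(matrix_a: TFBSMatrix, matrix_b: TFBSMatrix | None = None, pairs=None):
    """Per-element TF counts, or shared-TF counts for element pairs.

    Without ``pairs``: row sums of ``matrix_a``. With ``pairs`` (index_a,
    index_b): dot products of binary rows of ``matrix_a`` and ``matrix_b``
    (``matrix_a`` again if omitted) — e.g. peak row x promoter row for a
    peak-gene pair.
    """
    if pairs is None:
        return matrix_a.tf_counts()
    B = matrix_a if matrix_b is None else matrix_b
    ia = np.asarray([p[0] for p in pairs], dtype=np.intp)
    ib = np.asarray([p[1] for p in pairs], dtype=np.intp)
    A = matrix_a.matrix.astype(np.int64)
    Bm = B.matrix.astype(np.int64)
    return np.einsum("ij,ij->i", A[ia], Bm[ib])


@dataclass
class BivariateEffect:
    """Pioneer vs non-pioneer per-TF effects from a bivariate regression."""

    effect_pioneer: float
    se_pioneer: float
    effect_nonpioneer: float
    se_nonpioneer: float
    p_difference: float
    n_obs: int

    def summary(self) -> str:
        return (
            f"per-pioneer-TF effect {self.effect_pioneer:.4g} (se {self.se_pioneer:.3g}); "
            f"per-non-pioneer-TF effect {self.effect_nonpioneer:.4g} (se {self.se_nonpioneer:.3g}); "
            f"p(difference) = {self.p_difference:.3g}  [n={self.n_obs}]"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": ["pioneer", "nonpioneer"],
                "enrichment": [self.effect_pioneer, self.effect_nonpioneer],
                "se": [self.se_pioneer, self.se_nonpioneer],
            }
        )


def pioneer_regression(response, pioneer_count, nonpioneer_count, extra_covariates=None) -> BivariateEffect:
    """OLS of a score on pioneer and non-pioneer TF binding counts.

    The difference p-value is a Wald test of (effect_pioneer -
    effect_nonpioneer) = 0 using the coefficient covariance. Optional extra
    covariates (e.g. quartile bins of average TF binding/expression) enter the
    design additively.
    """
    y = np.asarray(response, dtype=float)
    xp = np.asarray(pioneer_count, dtype=float)
    xn = np.asarray(nonpioneer_count, dtype=float)
    if len(y) < 10:
        raise ValueError(f"need >= 10 observations, got {len(y)}")
    if xp.std() == 0 or xn.std() == 0:
        raise ValueError("zero variance in a predictor; coefficient undefined")
    cols = [xp, xn]
    if extra_covariates is not None:
        E = np.asarray(extra_covariates, dtype=float)
        if E.ndim == 1:
            E = E[:, None]
        cols.extend(E.T)
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X).fit()
    b = fit.params
    cov = fit.cov_params()
    diff = b[1] - b[2]
    se_diff = float(np.sqrt(cov[1, 1] + cov[2, 2] - 2 * cov[1, 2]))
    from scipy import stats

    p = float(2 * stats.norm.sf(abs(diff) / se_diff)) if se_diff > 0 else (0.0 if diff != 0 else 1.0)
    return BivariateEffect(
        effect_pioneer=float(b[1]),
        se_pioneer=float(np.sqrt(cov[1, 1])),
        effect_nonpioneer=float(b[2]),
        se_nonpioneer=float(np.sqrt(cov[2, 2])),
        p_difference=p,
        n_obs=len(y),
    )


def binding_bins(tfbs: TFBSMatrix, expression=None, n_bins: int = 4) -> np.ndarray:
    """Per-element covariates binning bound TFs by average binding (and expression).

    Default quartile bins of the TFs' column sums: for each element, the count
    of bound TFs falling in each bin (the first bin is dropped to avoid
    collinearity with the total).
    """
    col_sums = tfbs.matrix.sum(axis=0).astype(float)
    ranks = pd.qcut(col_sums, q=n_bins, labels=False, duplicates="drop")
    n_eff = int(np.nanmax(ranks)) + 1 if len(col_sums) else 0
    out = np.zeros((tfbs.matrix.shape[0], n_eff))
    for b in range(n_eff):
        out[:, b] = tfbs.matrix[:, ranks == b].sum(axis=1)
    return out[:, 1:]
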