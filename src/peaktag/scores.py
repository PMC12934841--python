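"""Co-accessibility, co-activity, co-expression and gene co-activity scores.

Each score is a per-element sum of bias-corrected squared Pearson correlations
with nearby partners, computed across units (metacells or cells):

* peak co-accessibility  ``x_j = sum_{k in K_j} (r_jk^2 - b_x)`` over cis peaks
  centered <1Mb from peak j's center, including peak j itself;
* peak co-activity       ``y_j = sum_{g in G_j} (r_jg^2 - b_y)`` over genes with
  TSS <1Mb from peak j's center (no self term);
* gene co-expression     ``x_i = sum_{g in G_i} (r_ig^2 - b_e)`` over genes with
  TSS <1Mb from gene i's TSS, including gene i itself;
* gene co-activity       ``y_i = sum_{k in K_i} (r_ik^2 - b_y)`` over peaks
  centered <1Mb from gene i's TSS.

``b_x``/``b_y``/``b_e`` estimate the finite-sample upward bias of r^2 (an
independent pair has E[r^2] = 1/(n-1), not 0) by comparing mean r^2 on all
units with mean r^2 on a random half of the units. The co-accessibility score
is the single-cell analogue of a SNP's LD score; the co-activity score is the
analogue of the sum of squared marginal GWAS associations.

Genome-wide variants drop the <1Mb restriction. Promoter-overlapping peaks
(within 1kb of any TSS) are expected to have been removed from the dataset
before scoring (``MultiomeDataset.without_promoter_peaks``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_CIS_WINDOW, MultiomeDataset

logger = logging.getLogger(__name__)

BIAS_DEFAULT_N_PAIRS = 100_000


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------


def standardize_columns(matrix, covariates=None, warn_constant=True):
    """Column-standardize (mean 0, unit L2 norm) so r = dot product.

    If ``covariates`` is given, each column is first residualized on them
    (intercept included), turning subsequent correlations into partial
    correlations. Constant (or fully covariate-explained) columns become all
    zeros, so any correlation involving them is 0 by convention.
    """
    X = np.asarray(matrix, dtype=float)
    if covariates is not None:
        C = np.column_stack([np.ones(X.shape[0]), np.asarray(covariates, dtype=float)])
        beta, *_ = np.linalg.lstsq(C, X, rcond=None)
        X = X - C @ beta
    else:
        X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    const = norms < 1e-12 * max(1.0, np.abs(X).max())
    if const.any() and warn_constant:
        warnings.warn(f"{int(const.sum())} constant column(s); correlations set to 0", stacklevel=2)
    norms[const] = 1.0
    Z = X / norms
    Z[:, const] = 0.0
    return Z


def pairwise_r2(matrix_a, matrix_b=None, pairs=None, covariates=None) -> pd.DataFrame:
    """Pearson r and r^2 across units for requested column pairs.

    ``pairs`` is an iterable of (index_a, index_b); with ``matrix_b=None`` both
    indices refer to ``matrix_a``. With ``covariates`` (units x q), partial
    correlations conditional on the covariates are returned.
    """
    A = np.asarray(matrix_a, dtype=float)
    if A.shape[0] < 3:
        raise ValueError(f"need >= 3 units, got {A.shape[0]}")
    Za = standardize_columns(A, covariates)
    Zb = Za if matrix_b is None else standardize_columns(np.asarray(matrix_b, dtype=float), covariates)
    if pairs is None:
        raise ValueError("pairs must be provided")
    pairs = list(pairs)
    ia = np.asarray([p[0] for p in pairs], dtype=np.intp)
    ib = np.asarray([p[1] for p in pairs], dtype=np.intp)
    r = np.einsum("ij,ij->j", Za[:, ia], Zb[:, ib])
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame({"a": ia, "b": ib, "r": r, "r2": r * r})


# ---------------------------------------------------------------------------
# finite-sample bias
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasEstimate:
    """Expected upward bias of r^2 due to finite sample size (b_x, b_y or b_e)."""

    value: float
    n_pairs_sampled: int
    seed: int


def _sample_pairs(rng, p_a, p_b, n_pairs, within):
    """Uniform sample of column pairs without replacement.

    ``within=True`` samples unordered pairs i<j from a p_a x p_a square;
    otherwise all p_a x p_b cross pairs.
    """
    total = p_a * (p_a - 1) // 2 if within else p_a * p_b
    n = min(n_pairs, total)
    if total <= 4 * n:
        flat = rng.choice(total, size=n, replace=False)
    else:
        # rejection sampling avoids materializing a permutation of `total`
        seen = set()
        flat = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.integers(0, total, size=2 * (n - filled))
            for v in draw:
                if v not in seen:
                    seen.add(v)
                    flat[filled] = v
                    filled += 1
                    if filled == n:
                        break
    if within:
        # map linear index of upper triangle (i<j) back to (i, j)
        i = (p_a - 2 - np.floor(np.sqrt(-8 * flat + 4 * p_a * (p_a - 1) - 7) / 2.0 - 0.5)).astype(np.int64)
        j = (flat + i + 1 - i * (2 * p_a - i - 1) // 2).astype(np.int64)
        return i, j
    return flat // p_b, flat % p_b


def estimate_bias(matrix_a, matrix_b=None, n_pairs=BIAS_DEFAULT_N_PAIRS, seed=0) -> BiasEstimate:
    """Estimate the finite-sample r^2 bias by 50% unit downsampling.

    Samples pairs of columns (within ``matrix_a``, or across the two matrices
    for ATAC-RNA), computes the mean r^2 across all units and across a random
    half of the units, and returns their difference: halving the sample size
    doubles the noise bias, so the difference estimates the full-sample bias.
    """
    A = np.asarray(matrix_a, dtype=float)
    n_units = A.shape[0]
    if n_units < 6:
        raise ValueError(f"need >= 6 units to downsample, got {n_units}")
    rng = np.random.default_rng(seed)
    within = matrix_b is None
    p_a = A.shape[1]
    p_b = p_a if within else np.asarray(matrix_b).shape[1]
    ia, ib = _sample_pairs(rng, p_a, p_b, n_pairs, within)

    half = rng.choice(n_units, size=n_units // 2, replace=False)

    Za = standardize_columns(A, warn_constant=False)
    Zb = Za if within else standardize_columns(np.asarray(matrix_b, dtype=float), warn_constant=False)
    r_full = np.einsum("ij,ij->j", Za[:, ia], Zb[:, ib])

    Za_h = standardize_columns(A[half], warn_constant=False)
    Zb_h = Za_h if within else standardize_columns(np.asarray(matrix_b, dtype=float)[half], warn_constant=False)
    r_half = np.einsum("ij,ij->j", Za_h[:, ia], Zb_h[:, ib])

    b = float(np.mean(r_half**2) - np.mean(r_full**2))
    return BiasEstimate(value=b, n_pairs_sampled=len(ia), seed=seed)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


def _cis_sum_r2(Z_focal, focal_chroms, focal_pos, Z_partner, partner_chroms, partner_pos, max_dist):
    """Per focal column: sum of r^2 against cis partner columns and partner count."""
    n_focal = Z_focal.shape[1]
    sums = np.zeros(n_focal)
    counts = np.zeros(n_focal, dtype=np.int64)
    focal_chroms = np.asarray(focal_chroms)
    partner_chroms = np.asarray(partner_chroms)
    for chrom in pd.unique(focal_chroms):
        f_idx = np.flatnonzero(focal_chroms == chrom)
        p_idx = np.flatnonzero(partner_chroms == chrom)
        if p_idx.size == 0:
            continue
        order = np.argsort(partner_pos[p_idx], kind="stable")
        p_idx = p_idx[order]
        pos = np.asarray(partner_pos[p_idx], dtype=np.int64)
        Zp = Z_partner[:, p_idx]
        for f in f_idx:
            c = int(focal_pos[f])
            lo = np.searchsorted(pos, c - max_dist, side="right")
            hi = np.searchsorted(pos, c + max_dist, side="left")
            if hi <= lo:
                continue
            r = Z_focal[:, f] @ Zp[:, lo:hi]
            sums[f] = float(np.sum(np.clip(r, -1, 1) ** 2))
            counts[f] = hi - lo
    return sums, counts


def _genomewide_sum_r2(Z_focal, Z_partner, chunk=512):
    """Per focal column: sum of r^2 against all partner columns."""
    n_focal = Z_focal.shape[1]
    sums = np.empty(n_focal)
    for lo in range(0, n_focal, chunk):
        hi = min(lo + chunk, n_focal)
        R = Z_focal[:, lo:hi].T @ Z_partner
        np.clip(R, -1, 1, out=R)
        sums[lo:hi] = np.sum(R * R, axis=1)
    return sums


def _count_in_window(focal_chroms, focal_pos, other_chroms, other_pos, max_dist):
    counts = np.zeros(len(focal_pos), dtype=np.int64)
    focal_chroms = np.asarray(focal_chroms)
    other_chroms = np.asarray(other_chroms)
    for chrom in pd.unique(focal_chroms):
        f_idx = np.flatnonzero(focal_chroms == chrom)
        o_idx = np.flatnonzero(other_chroms == chrom)
        pos = np.sort(np.asarray(other_pos[o_idx], dtype=np.int64))
        for f in f_idx:
            c = int(focal_pos[f])
            lo = np.searchsorted(pos, c - max_dist, side="right")
            hi = np.searchsorted(pos, c + max_dist, side="left")
            counts[f] = hi - lo
    return counts


def _score_frame(ids, chroms, score, n_partners, covariate, genome_wide):
    return pd.DataFrame(
        {
            "element_id": ids,
            "chrom": chroms,
            "score": score,
            "n_cis_partners": n_partners,
            "covariate": covariate,
            "genome_wide": genome_wide,
        }
    )


def co_accessibility_scores(
    dataset: MultiomeDataset,
    bias: BiasEstimate | float = 0.0,
    genome_wide: bool = False,
    max_dist: int = DEFAULT_CIS_WINDOW,
    conditional: bool = False,
) -> pd.DataFrame:
    """Peak co-accessibility scores x_j with the gene-count covariate G_j.

    The focal peak's self term (r^2 = 1) is included and bias-corrected like
    every other term. With ``conditional=True``, correlations are partial
    correlations conditioning on ``dataset.unit_covariates``.
    """
    b = bias.value if isinstance(bias, BiasEstimate) else float(bias)
    cov = dataset.unit_covariates if conditional else None
    Z = standardize_columns(dataset.atac, cov)
    chroms = dataset.peaks.chroms
    centers = dataset.peaks.centers
    if genome_wide:
        sums = _genomewide_sum_r2(Z, Z)
        counts = np.full(len(chroms), Z.shape[1], dtype=np.int64)
    else:
        sums, counts = _cis_sum_r2(Z, chroms, centers, Z, chroms, centers, max_dist)
    score = sums - b * counts
    g_j = _count_in_window(chroms, centers, dataset.genes.chroms, dataset.genes.tss, max_dist)
    return _score_frame(dataset.peaks.ids, chroms, score, counts, g_j, genome_wide)


def co_activity_scores(
    dataset: MultiomeDataset,
    bias: BiasEstimate | float = 0.0,
    genome_wide: bool = False,
    max_dist: int = DEFAULT_CIS_WINDOW,
    conditional: bool = False,
) -> pd.DataFrame:
    """Peak co-activity scores y_j (peak-gene r^2 sums); no self term."""
    b = bias.value if isinstance(bias, BiasEstimate) else float(bias)
    cov = dataset.unit_covariates if conditional else None
    Zp = standardize_columns(dataset.atac, cov)
    Zg = standardize_columns(dataset.rna, cov)
    chroms = dataset.peaks.chroms
    centers = dataset.peaks.centers
    if genome_wide:
        sums = _genomewide_sum_r2(Zp, Zg)
        counts = np.full(len(chroms), Zg.shape[1], dtype=np.int64)
    else:
        sums, counts = _cis_sum_r2(Zp, chroms, centers, Zg, dataset.genes.chroms, dataset.genes.tss, max_dist)
    score = sums - b * counts
    g_j = _count_in_window(chroms, centers, dataset.genes.chroms, dataset.genes.tss, max_dist)
    return _score_frame(dataset.peaks.ids, chroms, score, counts, g_j, genome_wide)


def gene_scores(
    dataset: MultiomeDataset,
    bias_e: BiasEstimate | float = 0.0,
    bias_y: BiasEstimate | float = 0.0,
    genome_wide: bool = False,
    max_dist: int = DEFAULT_CIS_WINDOW,
    conditional: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene co-expression scores x_i and gene co-activity scores y_i.

    Mirrors of the peak scores with roles swapped: co-expression sums gene-gene
    r^2 over genes with TSS <1Mb (self term included, bias b_e); gene
    co-activity sums gene-peak r^2 over (non-promoter) peaks centered <1Mb
    from the TSS (bias b_y, shared with peak co-activity). Both carry the
    peak-count covariate K_i.
    """
    be = bias_e.value if isinstance(bias_e, BiasEstimate) else float(bias_e)
    by = bias_y.value if isinstance(bias_y, BiasEstimate) else float(bias_y)
    cov = dataset.unit_covariates if conditional else None
    Zg = standardize_columns(dataset.rna, cov)
    Zp = standardize_columns(dataset.atac, cov)
    gchrom, gtss = dataset.genes.chroms, dataset.genes.tss
    pchrom, pcen = dataset.peaks.chroms, dataset.peaks.centers
    if genome_wide:
        sums_e = _genomewide_sum_r2(Zg, Zg)
        counts_e = np.full(len(gchrom), Zg.shape[1], dtype=np.int64)
        sums_y = _genomewide_sum_r2(Zg, Zp)
        counts_y = np.full(len(gchrom), Zp.shape[1], dtype=np.int64)
    else:
        sums_e, counts_e = _cis_sum_r2(Zg, gchrom, gtss, Zg, gchrom, gtss, max_dist)
        sums_y, counts_y = _cis_sum_r2(Zg, gchrom, gtss, Zp, pchrom, pcen, max_dist)
    k_i = _count_in_window(gchrom, gtss, pchrom, pcen, max_dist)
    co_expression = _score_frame(dataset.genes.ids, gchrom, sums_e - be * counts_e, counts_e, k_i, genome_wide)
    gene_co_activity = _score_frame(dataset.genes.ids, gchrom, sums_y - by * counts_y, counts_y, k_i, genome_wide)
    return co_expression, gene_co_activity


def score_correlation(score_a: pd.DataFrame, score_b: pd.DataFrame, condition_on=None):
    """Pearson r between two score tables, plus the partial r given covariates.

    Tables are aligned on ``element_id``. ``condition_on`` names covariate
    columns (looked up in ``score_a``, e.g. ``["covariate"]`` for the
    gene-count conditioning) or is an array of per-element covariates.
    """
    merged = score_a.merge(score_b, on="element_id", suffixes=("_a", "_b"))
    a = merged["score_a"].to_numpy(dtype=float)
    b = merged["score_b"].to_numpy(dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    if condition_on is None:
        return r, r
    if isinstance(condition_on, (list, tuple)) and all(isinstance(c, str) for c in condition_on):
        C = merged[[c + "_a" if c + "_a" in merged else c for c in condition_on]].to_numpy(dtype=float)
    else:
        C = np.asarray(condition_on, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    D = np.column_stack([np.ones(len(a)), C])
    ra = a - D @ np.linalg.lstsq(D, a, rcond=None)[0]
    rb = b - D @ np.linalg.lstsq(D, b, rcond=None)[0]
    cond_r = float(np.corrcoef(ra, rb)[0, 1])
    return r, cond_r


def write_score_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)
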