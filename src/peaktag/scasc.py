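"""Stratified co-accessibility score regression (S-CASC) and its gene mirror.

The model: a peak's co-activity score is, in expectation, linear in its
co-accessibility scores stratified by functional peak category,

    E[y_j] = tau_0 + sum_C tau_C x_{j,C} + gamma G_j,

where ``x_{j,C} = sum_{k in K_j} (I_Ck r_jk^2 - b_x)`` sums squared peak-peak
correlations over cis partners weighted by category membership I_Ck in [0,1],
and G_j counts genes with TSS <1Mb. tau_C is interpreted as the per-peak
contribution of category C to causal peak-gene effect-size variance (the
analogue of stratified LD score regression's per-SNP heritability
coefficients). From fitted tau the per-peak causal effect-size variance is
Var(beta_j) = sum_C I_Cj tau_C, the category total is v_C = sum_k I_Ck
Var(beta_k), and the enrichment of category C is

    E_C = (v_C / v_all) / (M_C / M_all),      M_C = sum_j I_Cj.

E_C > 1 means causal peak-gene effect variance concentrates in category C
beyond its share of peaks; the "all" category has E_all = 1 by construction.
Standard errors come from a delete-one-block jackknife (blocks = chromosomes,
or k-means blocks on the accessibility matrix), propagated through the whole
tau -> Var -> v -> E pipeline. Estimates are pooled across datasets by
DerSimonian-Laird random-effects meta-analysis.

The gene-side mirror (S-CESC) regresses gene co-activity scores on stratified
gene co-expression scores with the peak-count covariate K_i; both levels share
this module's machinery.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import any_overlap, covered_fraction
from .core import DEFAULT_CIS_WINDOW, GeneSet, MultiomeDataset, PeakSet
from .scores import (
    BiasEstimate,
    _cis_sum_r2,
    _count_in_window,
    co_activity_scores,
    gene_scores,
    standardize_columns,
)

logger = logging.getLogger(__name__)

DEFAULT_KMEANS_BLOCKS = 200


class CategoryAnnotation:
    """Per-element membership values I_C in [0, 1] for named categories.

    Carries an always-1 "all" category (added if absent) and a per-element
    block label (chromosome by default) used for jackknifing.
    """

    ALL = "all"

    def __init__(self, element_ids, membership: pd.DataFrame, blocks=None):
        element_ids = np.asarray(element_ids, dtype=object)
        m = membership.copy()
        m.index = element_ids
        vals = m.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("category membership contains NaN")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("category membership values must lie in [0, 1]")
        if self.ALL not in m.columns:
            m.insert(0, self.ALL, 1.0)
        elif not np.allclose(m[self.ALL], 1.0):
            raise ValueError('"all" category must equal 1 for every element')
        self.membership = m
        self.blocks = None if blocks is None else np.asarray(blocks, dtype=object)
        if self.blocks is not None and len(self.blocks) != len(m):
            raise ValueError("block labels must match number of elements")

    @property
    def element_ids(self) -> np.ndarray:
        return self.membership.index.to_numpy()

    @property
    def category_names(self) -> list:
        return list(self.membership.columns)

    def values_for(self, element_ids) -> np.ndarray:
        """Membership matrix rows for the given elements; missing ids are fatal."""
        idx = self.membership.index.get_indexer(element_ids)
        if (idx < 0).any():
            missing = np.asarray(element_ids)[idx < 0][:10]
            raise ValueError(f"elements missing from category annotation: {list(missing)}")
        return self.membership.to_numpy(dtype=float)[idx]

    def blocks_for(self, element_ids) -> np.ndarray | None:
        if self.blocks is None:
            return None
        idx = self.membership.index.get_indexer(element_ids)
        if (idx < 0).any():
            missing = np.asarray(element_ids)[idx < 0][:10]
            raise ValueError(f"elements missing from category annotation: {list(missing)}")
        return self.blocks[idx]


# ---------------------------------------------------------------------------
# stratified scores
# ---------------------------------------------------------------------------


def stratified_scores(
    dataset: MultiomeDataset,
    categories: CategoryAnnotation,
    bias_x: BiasEstimate | float = 0.0,
    bias_y: BiasEstimate | float = 0.0,
    level: str = "peak",
    max_dist: int = DEFAULT_CIS_WINDOW,
    partition_consistent: bool = False,
    genome_wide: bool = False,
    allow_genome_wide: bool = False,
    conditional: bool = False,
) -> pd.DataFrame:
    """Per-element stratified scores x_{j,C}, response y, and covariate.

    ``level="peak"`` stratifies peak co-accessibility (response: co-activity);
    ``level="gene"`` stratifies gene co-expression (response: gene
    co-activity). The printed formula subtracts the bias once per partner
    within every category, so summing x_{j,C} over a partition of categories
    over-subtracts relative to x_j; ``partition_consistent=True`` instead
    subtracts the bias once per pair (``I_Ck * (r^2 - b)``).

    Genome-wide stratified scores are refused unless ``allow_genome_wide``:
    without the cis restriction the per-category scores become nearly
    collinear and the regression uninformative.
    """
    if genome_wide and not allow_genome_wide:
        raise ValueError(
            "genome-wide stratified scores are disabled by default (severe "
            "multicollinearity across categories); pass allow_genome_wide=True to override"
        )
    bx = bias_x.value if isinstance(bias_x, BiasEstimate) else float(bias_x)
    cov = dataset.unit_covariates if conditional else None

    if level == "peak":
        ids = dataset.peaks.ids
        chroms = dataset.peaks.chroms
        positions = dataset.peaks.centers
        Z = standardize_columns(dataset.atac, cov)
        response = co_activity_scores(dataset, bias_y, max_dist=max_dist, conditional=conditional)
        covariate = _count_in_window(chroms, positions, dataset.genes.chroms, dataset.genes.tss, max_dist)
    elif level == "gene":
        ids = dataset.genes.ids
        chroms = dataset.genes.chroms
        positions = dataset.genes.tss
        Z = standardize_columns(dataset.rna, cov)
        _, response = gene_scores(dataset, bias_e=bias_x, bias_y=bias_y, max_dist=max_dist, conditional=conditional)
        covariate = _count_in_window(chroms, positions, dataset.peaks.chroms, dataset.peaks.centers, max_dist)
    else:
        raise ValueError(f"level must be 'peak' or 'gene', got {level!r}")

    member = categories.values_for(ids)  # elements x categories
    cat_names = categories.category_names
    n_elem = len(ids)
    X = np.zeros((n_elem, len(cat_names)))

    chroms_arr = np.asarray(chroms)
    pos_arr = np.asarray(positions, dtype=np.int64)
    for chrom in pd.unique(chroms_arr):
        e_idx = np.flatnonzero(chroms_arr == chrom)
        order = np.argsort(pos_arr[e_idx], kind="stable")
        p_idx = e_idx[order]
        pos = pos_arr[p_idx]
        Zc = Z[:, p_idx]
        Mc = member[p_idx]
        for f in e_idx:
            c = int(pos_arr[f])
            if genome_wide:
                r = Z[:, f] @ Z
                r2 = np.clip(r, -1, 1) ** 2
                I = member
            else:
                lo = np.searchsorted(pos, c - max_dist, side="right")
                hi = np.searchsorted(pos, c + max_dist, side="left")
                if hi <= lo:
                    continue
                r = Z[:, f] @ Zc[:, lo:hi]
                r2 = np.clip(r, -1, 1) ** 2
                I = Mc[lo:hi]
            if partition_consistent:
                X[f] = I.T @ (r2 - bx)
            else:
                X[f] = I.T @ r2 - bx * I.shape[0]

    table = pd.DataFrame(X, columns=[f"x::{c}" for c in cat_names])
    table.insert(0, "element_id", ids)
    table["y"] = response["score"].to_numpy()
    table["covariate"] = covariate
    blocks = categories.blocks_for(ids)
    table["block"] = blocks if blocks is not None else chroms_arr
    return table


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class StratifiedScoreRegression:
    """OLS of co-activity scores on category-stratified co-accessibility scores.

    Parameters
    ----------
    response : array (n,)
        Co-activity score per element (y_j or y_i).
    stratified : array (n, C)
        Stratified scores x_{j,C}, one column per category (first column
        conventionally the "all" category).
    membership : array (n, C)
        Category membership I_Cj used to convert tau into per-element
        variances and enrichments.
    category_names : sequence of str
    covariate : array (n,), optional
        Gene count G_j (peak level) or peak count K_i (gene level).
    blocks : array (n,), optional
        Jackknife block label per element (chromosome or k-means block).
    """

    def __init__(self, response, stratified, membership, category_names, covariate=None, blocks=None):
        self.y = np.asarray(response, dtype=float)
        self.X = np.asarray(stratified, dtype=float)
        self.membership = np.asarray(membership, dtype=float)
        self.category_names = list(category_names)
        self.covariate = None if covariate is None else np.asarray(covariate, dtype=float)
        self.blocks = None if blocks is None else np.asarray(blocks, dtype=object)
        n, C = self.X.shape
        if len(self.category_names) != C or self.membership.shape != (n, C):
            raise ValueError("inconsistent shapes between scores, membership and names")
        if n < C + 3:
            raise ValueError(f"need at least n_categories + 3 = {C + 3} elements, got {n}")

    @classmethod
    def from_dataset(
        cls,
        dataset: MultiomeDataset,
        categories: CategoryAnnotation,
        bias_x=0.0,
        bias_y=0.0,
        level: str = "peak",
        max_dist: int = DEFAULT_CIS_WINDOW,
        partition_consistent: bool = False,
        conditional: bool = False,
    ) -> "StratifiedScoreRegression":
        table = stratified_scores(
            dataset,
            categories,
            bias_x=bias_x,
            bias_y=bias_y,
            level=level,
            max_dist=max_dist,
            partition_consistent=partition_consistent,
            conditional=conditional,
        )
        ids = table["element_id"].to_numpy()
        member = categories.values_for(ids)
        xcols = [c for c in table.columns if c.startswith("x::")]
        return cls(
            response=table["y"].to_numpy(),
            stratified=table[xcols].to_numpy(),
            membership=member,
            category_names=[c[3:] for c in xcols],
            covariate=table["covariate"].to_numpy(),
            blocks=table["block"].to_numpy(),
        )

    # -- fitting ---------------------------------------------------------

    def _design(self, rows=slice(None)):
        cols = [np.ones(len(self.y))[rows], *(self.X[rows, c] for c in range(self.X.shape[1]))]
        if self.covariate is not None:
            cols.append(self.covariate[rows])
        return np.column_stack(cols)

    def _check_rank(self):
        D = self._design()
        # normalize column scales so rank reflects collinearity, not units
        Dn = D / np.maximum(np.linalg.norm(D, axis=0), 1e-300)
        rank = np.linalg.matrix_rank(Dn, tol=1e-8)
        if rank < D.shape[1]:
            # locate offending category columns via pivoted QR
            from scipy.linalg import qr

            _, _, piv = qr(Dn, pivoting=True, mode="economic")
            dropped = sorted(piv[rank:])
            names = []
            for d in dropped:
                if d == 0:
                    names.append("<intercept>")
                elif d <= len(self.category_names):
                    names.append(self.category_names[d - 1])
                else:
                    names.append("<covariate>")
            raise np.linalg.LinAlgError(
                f"rank-deficient design: collinear columns {names}; "
                "merge or drop the offending categories"
            )

    def _estimate(self, rows=slice(None)):
        """tau-hat and derived quantities on a subset of elements."""
        D = self._design(rows)
        beta, *_ = np.linalg.lstsq(D, self.y[rows], rcond=None)
        C = self.X.shape[1]
        tau0 = beta[0]
        tau = beta[1 : 1 + C]
        gamma = beta[1 + C] if self.covariate is not None else np.nan
        member = self.membership[rows]
        var_beta = member @ tau
        v_c = member.T @ var_beta
        m_c = member.sum(axis=0)
        m_all = member.shape[0]
        v_all = float(var_beta.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            enrich = (v_c / v_all) / (m_c / m_all)
        return {
            "tau0": float(tau0),
            "tau": tau,
            "gamma": float(gamma),
            "var_beta": var_beta,
            "v_c": v_c,
            "m_c": m_c,
            "enrichment": enrich,
        }

    def fit(self) -> "StratifiedScoreRegressionResults":
        self._check_rank()
        est = self._estimate()
        return StratifiedScoreRegressionResults(self, est)


class StratifiedScoreRegressionResults:
    """Fitted S-CASC / S-CESC estimates with jackknife uncertainties."""

    def __init__(self, model: StratifiedScoreRegression, est: dict):
        self.model = model
        self.category_names = model.category_names
        self.tau0 = est["tau0"]
        self.tau = pd.Series(est["tau"], index=self.category_names, name="tau")
        self.gamma = est["gamma"]
        self.var_beta = est["var_beta"]
        self.v_c = pd.Series(est["v_c"], index=self.category_names, name="v_C")
        self.m_c = pd.Series(est["m_c"], index=self.category_names, name="M_C")
        self.enrichment = pd.Series(est["enrichment"], index=self.category_names, name="enrichment")
        self._jack = None

    @property
    def n_elements(self) -> int:
        return len(self.model.y)

    def jackknife(self, blocks=None) -> pd.DataFrame:
        """Delete-one-block jackknife SEs and p-values for every enrichment.

        Re-runs the full pipeline (tau -> Var -> v -> E) leaving out each block
        in turn, then applies the delete-m_j jackknife for unequal block sizes
        (Busing et al. 1999). The two-sided p tests H0: E_C = 1 under a normal
        approximation. A category fully contained in one block is flagged
        unstable (its leave-out enrichment is undefined).
        """
        blocks = self.model.blocks if blocks is None else np.asarray(blocks, dtype=object)
        if blocks is None:
            raise ValueError("no jackknife blocks available")
        labels, counts = np.unique(blocks, return_counts=True)
        if len(labels) < 2:
            raise ValueError("jackknife requires >= 2 non-empty blocks")
        n = len(blocks)
        B = len(labels)
        theta_full = self.enrichment.to_numpy()
        theta_del = np.empty((B, len(self.category_names)))
        for b, lab in enumerate(labels):
            rows = np.flatnonzero(blocks != lab)
            theta_del[b] = self.model._estimate(rows)["enrichment"]
        h = n / counts.astype(float)  # h_b = n / m_b
        unstable = ~np.isfinite(theta_del).all(axis=0)
        with np.errstate(invalid="ignore"):
            theta_j = B * theta_full - ((1.0 - 1.0 / h)[:, None] * theta_del).sum(axis=0)
            pseudo = h[:, None] * theta_full[None, :] - (h - 1.0)[:, None] * theta_del
            var = np.mean((pseudo - theta_j[None, :]) ** 2 / (h - 1.0)[:, None], axis=0)
        se = np.sqrt(var)
        se[unstable] = np.nan
        if unstable.any():
            bad = [self.category_names[i] for i in np.flatnonzero(unstable)]
            warnings.warn(f"unstable jackknife SE for categories {bad}", stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (theta_full - 1.0) / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        # "all" has zero variance by construction
        out = pd.DataFrame(
            {
                "category": self.category_names,
                "tau": self.tau.to_numpy(),
                "enrichment": theta_full,
                "se": se,
                "p": p,
                "n_elements": n,
                "M_C": self.m_c.to_numpy(),
                "unstable": unstable,
            }
        )
        self._jack = out
        return out

    def summary(self) -> str:
        """Plain-text summary table (enrichments with jackknife SEs if computed)."""
        lines = [
            "Stratified score regression",
            f"  elements: {self.n_elements}   categories: {len(self.category_names)}",
            f"  intercept tau0 = {self.tau0:.4g}   covariate gamma = {self.gamma:.4g}",
            "",
            f"  {'category':<24}{'tau':>12}{'M_C':>10}{'enrichment':>12}{'se':>10}{'p':>12}",
        ]
        jack = self._jack
        for i, name in enumerate(self.category_names):
            se = p = ""
            if jack is not None:
                se_v, p_v = jack["se"].iloc[i], jack["p"].iloc[i]
                se = f"{se_v:.3g}" if np.isfinite(se_v) else "unstable"
                p = f"{p_v:.3g}" if np.isfinite(p_v) else ""
                stars = "***" if p_v < 0.001 else "**" if p_v < 0.01 else "*" if p_v < 0.05 else ""
                p = p + stars
            lines.append(
                f"  {name:<24}{self.tau.iloc[i]:>12.4g}{self.m_c.iloc[i]:>10.1f}"
                f"{self.enrichment.iloc[i]:>12.4g}{se:>10}{p:>12}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        if self._jack is not None:
            return self._jack.copy()
        return pd.DataFrame(
            {
                "category": self.category_names,
                "tau": self.tau.to_numpy(),
                "enrichment": self.enrichment.to_numpy(),
                "M_C": self.m_c.to_numpy(),
                "n_elements": self.n_elements,
            }
        )


def fit_stratified_regression(table: pd.DataFrame, categories: CategoryAnnotation) -> StratifiedScoreRegressionResults:
    """Functional wrapper: fit the regression from a `stratified_scores` table."""
    ids = table["element_id"].to_numpy()
    member = categories.values_for(ids)
    xcols = [c for c in table.columns if c.startswith("x::")]
    model = StratifiedScoreRegression(
        response=table["y"].to_numpy(),
        stratified=table[xcols].to_numpy(),
        membership=member,
        category_names=[c[3:] for c in xcols],
        covariate=table["covariate"].to_numpy() if "covariate" in table else None,
        blocks=table["block"].to_numpy() if "block" in table else None,
    )
    return model.fit()


def jackknife_enrichment(table: pd.DataFrame, categories: CategoryAnnotation, blocks=None) -> pd.DataFrame:
    """Functional wrapper: fit + jackknife in one step."""
    res = fit_stratified_regression(table, categories)
    return res.jackknife(blocks)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------


def meta_analyze(results: list[pd.DataFrame]) -> pd.DataFrame:
    """DerSimonian-Laird random-effects pooling of enrichments across datasets.

    Each input frame needs columns (category, enrichment, se). The
    between-dataset variance tau2_meta is truncated at zero; pooled p-values
    test H0: E_C = 1. A single input is passed through with a warning.
    """
    if len(results) == 0:
        raise ValueError("no results to meta-analyze")
    if len(results) == 1:
        warnings.warn("meta_analyze called with a single input; passing through", stacklevel=2)
        out = results[0][["category", "enrichment", "se"]].copy()
        out["tau2_meta"] = 0.0
        out["p"] = 2.0 * stats.norm.sf(np.abs((out["enrichment"] - 1.0) / out["se"]))
        out["n_datasets"] = 1
        return out

    cats = list(results[0]["category"])
    for r in results[1:]:
        if list(r["category"]) != cats:
            raise ValueError("all inputs must share the same category names (in order)")
    est = np.column_stack([r["enrichment"].to_numpy(dtype=float) for r in results])
    se = np.column_stack([r["se"].to_numpy(dtype=float) for r in results])
    k = est.shape[1]

    rows = []
    for i, cat in enumerate(cats):
        th, s = est[i], se[i]
        ok = np.isfinite(th) & np.isfinite(s) & (s >= 0)
        th, s = th[ok], s[ok]
        if len(th) == 0 or np.all(s == 0) and len(np.unique(th)) > 1:
            rows.append((cat, np.nan, np.nan, np.nan, np.nan, int(len(th))))
            continue
        s_eff = np.where(s == 0, 1e-12, s)
        w = 1.0 / s_eff**2
        fixed = float(np.sum(w * th) / np.sum(w))
        q = float(np.sum(w * (th - fixed) ** 2))
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (len(th) - 1)) / c) if c > 0 else 0.0
        w_star = 1.0 / (s_eff**2 + tau2)
        pooled = float(np.sum(w_star * th) / np.sum(w_star))
        pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
        p = float(2.0 * stats.norm.sf(abs(pooled - 1.0) / pooled_se)) if pooled_se > 0 else 1.0
        rows.append((cat, pooled, pooled_se, tau2, p, int(len(th))))
    return pd.DataFrame(rows, columns=["category", "enrichment", "se", "tau2_meta", "p", "n_datasets"])


# ---------------------------------------------------------------------------
# built-in categories and jackknife blocks
# ---------------------------------------------------------------------------


def builtin_categories(
    peaks: PeakSet,
    genes: GeneSet,
    feature_intervals: dict | None = None,
    constraint_intervals: pd.DataFrame | None = None,
    level: str = "peak",
    tss_windows=(10_000, 100_000),
    blocks=None,
) -> CategoryAnnotation:
    """Construct the standard functional categories for peaks or genes.

    Peak level: one binary category per supplied interval set (any overlap,
    half-open), "TSS+/-10kb" and "TSS+/-100kb" windows around gene TSSs,
    "Closest to TSS" (for each gene, the single peak whose center is nearest
    its TSS), and a probabilistic "Constraint" category (fraction of peak bases
    covered by constrained regions) when constraint intervals are supplied.

    Gene level: binary categories from interval sets overlapping the TSS,
    "Peak+/-10kb" (TSS within 10kb of any peak) and "Closest to peak" (for
    each peak, the gene with nearest TSS).

    ``feature_intervals`` maps category name -> DataFrame(chrom, start, end).
    Empty categories are kept with a warning. Blocks default to chromosomes.
    """
    feature_intervals = feature_intervals or {}
    if level == "peak":
        ids = peaks.ids
        chroms = peaks.chroms
        cols = {}
        for name, iv in feature_intervals.items():
            cols[name] = _overlap_category(peaks.df, iv)
        for w in tss_windows:
            win = pd.DataFrame(
                {
                    "chrom": genes.chroms,
                    "start": np.maximum(genes.tss - w, 0),
                    "end": genes.tss + w,
                }
            )
            cols[f"TSS±{w // 1000}kb"] = _overlap_category(peaks.df, win)
        cols["Closest to TSS"] = _closest_category(
            focal_chroms=genes.chroms, focal_pos=genes.tss,
            cand_chroms=chroms, cand_pos=peaks.centers, n_cand=len(peaks),
        )
        if constraint_intervals is not None:
            cols["Constraint"] = _constraint_category(peaks.df, constraint_intervals)
    elif level == "gene":
        ids = genes.ids
        chroms = genes.chroms
        gdf = pd.DataFrame({"chrom": genes.chroms, "start": genes.tss, "end": genes.tss + 1})
        cols = {}
        for name, iv in feature_intervals.items():
            cols[name] = _overlap_category(gdf, iv)
        w = 10_000
        peak_win = pd.DataFrame(
            {
                "chrom": peaks.chroms,
                "start": np.maximum(peaks.centers - w, 0),
                "end": peaks.centers + w,
            }
        )
        cols["Peak±10kb"] = _overlap_category(gdf, peak_win)
        cols["Closest to peak"] = _closest_category(
            focal_chroms=peaks.chroms, focal_pos=peaks.centers,
            cand_chroms=chroms, cand_pos=genes.tss, n_cand=len(genes),
        )
    else:
        raise ValueError(f"level must be 'peak' or 'gene', got {level!r}")

    for name, vals in cols.items():
        if np.sum(vals) == 0:
            warnings.warn(f"category {name!r} is empty; kept", stacklevel=2)
    membership = pd.DataFrame(cols, index=ids, dtype=float)
    return CategoryAnnotation(ids, membership, blocks=blocks if blocks is not None else chroms)


def _overlap_category(elem_df: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(elem_df), dtype=float)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        on = np.flatnonzero((elem_df["chrom"] == chrom).to_numpy())
        if on.size == 0:
            continue
        hit = any_overlap(
            elem_df["start"].to_numpy()[on],
            elem_df["end"].to_numpy()[on],
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
        )
        out[on] = hit.astype(float)
    return out


def _constraint_category(elem_df: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(elem_df), dtype=float)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        on = np.flatnonzero((elem_df["chrom"] == chrom).to_numpy())
        if on.size == 0:
            continue
        out[on] = covered_fraction(
            elem_df["start"].to_numpy()[on],
            elem_df["end"].to_numpy()[on],
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
        )
    return out


def _closest_category(focal_chroms, focal_pos, cand_chroms, cand_pos, n_cand) -> np.ndarray:
    """Mark, per focal element, the nearest candidate (ties -> lowest index)."""
    out = np.zeros(n_cand, dtype=float)
    focal_chroms = np.asarray(focal_chroms)
    cand_chroms = np.asarray(cand_chroms)
    focal_pos = np.asarray(focal_pos, dtype=np.int64)
    cand_pos = np.asarray(cand_pos, dtype=np.int64)
    for chrom in pd.unique(focal_chroms):
        c_idx = np.flatnonzero(cand_chroms == chrom)
        if c_idx.size == 0:
            continue
        f_idx = np.flatnonzero(focal_chroms == chrom)
        dists = np.abs(cand_pos[c_idx][None, :] - focal_pos[f_idx][:, None])
        nearest = np.argmin(dists, axis=1)  # argmin takes the first (lowest index) on ties
        out[c_idx[nearest]] = 1.0
    return out


def read_categories(path: str) -> CategoryAnnotation:
    """Wide TSV: element_id column, optional block column, one column per category."""
    df = pd.read_csv(path, sep="\t")
    if "element_id" not in df.columns:
        raise ValueError("category table needs an 'element_id' column")
    blocks = df.pop("block").to_numpy(dtype=object) if "block" in df.columns else None
    ids = df.pop("element_id").to_numpy(dtype=object)
    return CategoryAnnotation(ids, df.astype(float), blocks=blocks)


def write_categories(categories: CategoryAnnotation, path: str) -> None:
    out = categories.membership.copy()
    out.insert(0, "element_id", categories.element_ids)
    if categories.blocks is not None:
        out["block"] = categories.blocks
    out.to_csv(path, sep="\t", index=False)


def kmeans_blocks(atac: np.ndarray, n_blocks: int = DEFAULT_KMEANS_BLOCKS, seed: int = 0) -> np.ndarray:
    """Jackknife block labels from k-means on the peak x unit accessibility matrix."""
    from sklearn.cluster import KMeans

    X = np.asarray(atac, dtype=float).T  # peaks as observations
    n_blocks = min(n_blocks, X.shape[0])
    km = KMeans(n_clusters=n_blocks, random_state=seed, n_init=3)
    return km.fit_predict(X).astype(object)
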