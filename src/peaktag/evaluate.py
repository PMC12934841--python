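"""Enrichment-recall evaluation of peak-gene linking methods.

Candidate links are scored peak-gene pairs (peak-TSS distance <1Mb; for
CRISPR-style sets additionally restricted to experimentally tested pairs) for
genes with at least one "true" link. Sweeping a threshold c over the unique
linking scores, with predicted = links scoring >= c:

    enrichment(c) = (|pred ∩ true| / |true|) / (|pred| / |universe|)
    recall(c)     = |pred ∩ true| / |true|

The scalar summary *average enrichment across recall values* truncates every
method's curve at the common maximum recall R and averages
``enrichment_i * (1 - recall_i)`` over the curve points at which the i-th true
link is first recovered (i = 1..n_R), up-weighting precision at stringent
thresholds. Uncertainties and between-method differences come from
bootstrapping genes (all links of a resampled gene enter together).

``tagging_diagnostics`` reproduces the CRISPR tagging check: for genes with a
validated causal peak that the correlation method identifies, each
experimentally negative peak's correlation with the causal peak is compared
with its correlation with the gene — a high correlation across such pairs is
the signature of tagging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EvaluationLinkSet, MultiomeDataset
from .scores import standardize_columns

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1_000
DEFAULT_TAGGING_R = 0.45


@dataclass
class EnrichmentCurve:
    """Enrichment-recall curve plus the universe it was computed on."""

    points: pd.DataFrame  # threshold, n_pred, n_true_pred, recall, enrichment
    n_true: int
    n_universe: int

    @property
    def max_recall(self) -> float:
        return float(self.points["recall"].max())

    def at_true_link_points(self) -> pd.DataFrame:
        """One curve point per true link: the first threshold recovering the i-th.

        These are the points averaged by Eq-style average enrichment; ties in
        score can recover several true links at the same threshold, in which
        case that point is repeated.
        """
        rec = self.points["recall"].to_numpy()
        rows = []
        for i in range(1, self.n_true + 1):
            target = i / self.n_true
            hit = np.flatnonzero(rec >= target - 1e-12)
            if hit.size == 0:
                break
            rows.append(self.points.iloc[hit[0]])
        return pd.DataFrame(rows).reset_index(drop=True)


def _restrict_universe(scores: pd.DataFrame, links: EvaluationLinkSet, restrict_to_tested: bool) -> pd.DataFrame:
    lab = links.table.set_index(["peak_id", "gene_id"])["label"]
    key = pd.MultiIndex.from_frame(scores[["peak_id", "gene_id"]])
    labels = lab.reindex(key).to_numpy(dtype=object)
    labels = np.where(pd.isna(labels), "untested", labels)
    uni = scores.copy()
    uni["label"] = labels
    if restrict_to_tested:
        uni = uni[uni["label"] != "untested"]
    true_genes = set(uni.loc[uni["label"] == "true", "gene_id"])
    uni = uni[uni["gene_id"].isin(true_genes)]
    return uni.reset_index(drop=True)


def enrichment_recall(
    scores: pd.DataFrame,
    links: EvaluationLinkSet,
    score_col: str = "score",
    restrict_to_tested: bool = False,
) -> EnrichmentCurve:
    """Enrichment and recall at every unique linking score threshold.

    ``scores`` has one row per candidate link: (peak_id, gene_id, score_col).
    """
    uni = _restrict_universe(scores, links, restrict_to_tested)
    n_universe = len(uni)
    is_true = (uni["label"] == "true").to_numpy()
    n_true = int(is_true.sum())
    if n_true == 0:
        raise ValueError("no true links in the evaluation universe")
    s = uni[score_col].to_numpy(dtype=float)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    true_sorted = is_true[order]
    # positions where a new (lower) unique score begins; pred set = all rows before
    cum_true = np.cumsum(true_sorted)
    uniq_last = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)  # last index of each unique score
    n_pred = uniq_last + 1
    n_true_pred = cum_true[uniq_last]
    recall = n_true_pred / n_true
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = (n_true_pred / n_true) / (n_pred / n_universe)
    points = pd.DataFrame(
        {
            "threshold": s_sorted[uniq_last],
            "n_pred": n_pred,
            "n_true_pred": n_true_pred,
            "recall": recall,
            "enrichment": enrich,
        }
    )
    return EnrichmentCurve(points=points, n_true=n_true, n_universe=n_universe)


def average_enrichment(curves: dict[str, EnrichmentCurve]) -> pd.DataFrame:
    """(1 - recall)-weighted mean enrichment, truncated at the common max recall.

    R is the minimum over methods of each curve's maximum recall; for each
    method the mean of ``enrichment_i * (1 - recall_i)`` runs over the curve
    points recovering the first n_R true links, n_R = floor(R * n_true).
    """
    if not curves:
        raise ValueError("no curves supplied")
    R = min(c.max_recall for c in curves.values())
    if R <= 0:
        raise ValueError("common maximum recall is zero")
    rows = []
    for name, curve in curves.items():
        pts = curve.at_true_link_points()
        n_r = int(np.floor(R * curve.n_true + 1e-9))
        use = pts.iloc[:n_r]
        val = float(np.mean(use["enrichment"].to_numpy() * (1.0 - use["recall"].to_numpy())))
        rows.append((name, val, n_r, R))
    return pd.DataFrame(rows, columns=["method", "average_enrichment", "n_R", "common_recall"])


# ---------------------------------------------------------------------------
# gene bootstrap
# ---------------------------------------------------------------------------


def _average_enrichment_once(tables: dict[str, pd.DataFrame], score_col: str) -> dict[str, float] | None:
    """Average enrichment per method on pre-restricted universe tables."""
    curves = {}
    for name, uni in tables.items():
        is_true = (uni["label"] == "true").to_numpy()
        if not is_true.any():
            return None
        s = uni[score_col].to_numpy(dtype=float)
        order = np.argsort(-s, kind="stable")
        s_sorted, true_sorted = s[order], is_true[order]
        cum_true = np.cumsum(true_sorted)
        uniq_last = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
        n_true = int(is_true.sum())
        points = pd.DataFrame(
            {
                "threshold": s_sorted[uniq_last],
                "n_pred": uniq_last + 1,
                "n_true_pred": cum_true[uniq_last],
                "recall": cum_true[uniq_last] / n_true,
                "enrichment": (cum_true[uniq_last] / n_true) / ((uniq_last + 1) / len(uni)),
            }
        )
        curves[name] = EnrichmentCurve(points=points, n_true=n_true, n_universe=len(uni))
    av = average_enrichment(curves)
    return dict(zip(av["method"], av["average_enrichment"]))


def bootstrap_compare(
    scores_by_method: dict[str, pd.DataFrame],
    links: EvaluationLinkSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    score_col: str = "score",
    restrict_to_tested: bool = False,
) -> dict:
    """Gene-bootstrap SEs on average enrichment and p-values for differences.

    Genes are resampled with replacement; every link of a resampled gene
    enters the replicate (repeated genes contribute repeatedly), and the
    common-recall truncation is re-applied within each replicate. The p-value
    on a difference is the two-sided bootstrap tail fraction with a +1
    continuity correction.
    """
    rng = np.random.default_rng(seed)
    restricted = {
        name: _restrict_universe(tab, links, restrict_to_tested) for name, tab in scores_by_method.items()
    }
    methods = list(restricted)
    genes = sorted(set.intersection(*(set(t["gene_id"]) for t in restricted.values())))
    restricted = {n: t[t["gene_id"].isin(genes)].reset_index(drop=True) for n, t in restricted.items()}
    by_gene = {n: {g: sub for g, sub in t.groupby("gene_id", sort=False)} for n, t in restricted.items()}

    point = _average_enrichment_once(restricted, score_col)
    if point is None:
        raise ValueError("no true links in the evaluation universe")

    boot = {n: np.empty(n_boot) for n in methods}
    for b in range(n_boot):
        draw = rng.choice(len(genes), size=len(genes), replace=True)
        tables = {
            n: pd.concat([by_gene[n][genes[g]] for g in draw], ignore_index=True) for n in methods
        }
        vals = _average_enrichment_once(tables, score_col)
        if vals is None:  # replicate without true links: redraw deterministic-ly
            for n in methods:
                boot[n][b] = np.nan
            continue
        for n in methods:
            boot[n][b] = vals[n]

    per_method = pd.DataFrame(
        {
            "method": methods,
            "average_enrichment": [point[n] for n in methods],
            "se": [float(np.nanstd(boot[n], ddof=1)) for n in methods],
        }
    )
    rows = []
    for i, a in enumerate(methods):
        for bname in methods[i + 1 :]:
            d = boot[a] - boot[bname]
            d = d[np.isfinite(d)]
            diff = point[a] - point[bname]
            se = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
            if len(d) == 0 or np.allclose(d, d[0]):
                p = 1.0
            else:
                lo = (np.sum(d <= 0) + 1) / (len(d) + 1)
                hi = (np.sum(d >= 0) + 1) / (len(d) + 1)
                p = float(min(1.0, 2.0 * min(lo, hi)))
            rows.append((a, bname, diff, se, p))
    pairwise = pd.DataFrame(rows, columns=["method_a", "method_b", "difference", "se", "p"])
    return {"per_method": per_method, "pairwise": pairwise, "n_boot": n_boot, "seed": seed}


# ---------------------------------------------------------------------------
# CRISPR tagging diagnostics
# ---------------------------------------------------------------------------


def tagging_diagnostics(
    dataset: MultiomeDataset,
    links: EvaluationLinkSet,
    r_threshold: float = DEFAULT_TAGGING_R,
    level: str = "gene",
) -> pd.DataFrame:
    """Correlations of experimentally negative elements with the causal element.

    ``level="gene"``: for each gene with a validated causal (true) peak whose
    peak-gene correlation exceeds ``r_threshold`` and at least one tested
    non-causal (false) peak, report each negative peak's correlation with the
    causal peak and with the gene. ``level="peak"`` is the mirror across
    target genes of a focal peak. If several causal elements qualify, the one
    most correlated with the focal element is used.
    """
    Zp = standardize_columns(dataset.atac, warn_constant=False)
    Zg = standardize_columns(dataset.rna, warn_constant=False)
    peak_idx = pd.Index(dataset.peaks.ids)
    gene_idx = pd.Index(dataset.genes.ids)
    t = links.table
    rows = []
    if level == "gene":
        for gid, sub in t.groupby("gene_id", sort=False):
            g = gene_idx.get_indexer([gid])[0]
            if g < 0:
                continue
            pos = peak_idx.get_indexer(sub.loc[sub["label"] == "true", "peak_id"])
            neg = peak_idx.get_indexer(sub.loc[sub["label"] == "false", "peak_id"])
            pos, neg = pos[pos >= 0], neg[neg >= 0]
            if pos.size == 0 or neg.size == 0:
                continue
            r_pos = Zp[:, pos].T @ Zg[:, g]
            best = np.argmax(r_pos)
            if r_pos[best] <= r_threshold:
                continue
            p_best = pos[best]
            for nidx in neg:
                rows.append(
                    (
                        gid,
                        dataset.peaks.ids[p_best],
                        dataset.peaks.ids[nidx],
                        float(Zp[:, nidx] @ Zp[:, p_best]),
                        float(Zp[:, nidx] @ Zg[:, g]),
                    )
                )
        cols = ["gene_id", "positive_peak", "negative_peak", "r_with_positive", "r_with_focal"]
    elif level == "peak":
        for pid, sub in t.groupby("peak_id", sort=False):
            p = peak_idx.get_indexer([pid])[0]
            if p < 0:
                continue
            pos = gene_idx.get_indexer(sub.loc[sub["label"] == "true", "gene_id"])
            neg = gene_idx.get_indexer(sub.loc[sub["label"] == "false", "gene_id"])
            pos, neg = pos[pos >= 0], neg[neg >= 0]
            if pos.size == 0 or neg.size == 0:
                continue
            r_pos = Zg[:, pos].T @ Zp[:, p]
            best = np.argmax(r_pos)
            if r_pos[best] <= r_threshold:
                continue
            g_best = pos[best]
            for nidx in neg:
                rows.append(
                    (
                        pid,
                        dataset.genes.ids[g_best],
                        dataset.genes.ids[nidx],
                        float(Zg[:, nidx] @ Zg[:, g_best]),
                        float(Zg[:, nidx] @ Zp[:, p]),
                    )
                )
        cols = ["peak_id", "positive_gene", "negative_gene", "r_with_positive", "r_with_focal"]
    else:
        raise ValueError(f"level must be 'gene' or 'peak', got {level!r}")
    if not rows:
        logger.warning("tagging_diagnostics: no qualifying focal elements")
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def diagnostic_correlation(pairs: pd.DataFrame) -> float:
    """Correlation across (negative, causal) pairs between the two r columns."""
    if len(pairs) < 3:
        return float("nan")
    return float(np.corrcoef(pairs["r_with_positive"], pairs["r_with_focal"])[0, 1])


def plot_enrichment_recall(curves: dict[str, EnrichmentCurve], path: str | None = None):
    """Optional enrichment-recall plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.step(curve.points["recall"], curve.points["enrichment"], where="post", label=name)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("recall")
    ax.set_ylabel("enrichment")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
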