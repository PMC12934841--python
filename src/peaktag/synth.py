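"""Synthetic multiome generator with TF-factor-driven tagging structure.

The generator emulates the mechanism by which non-causal ("tagging")
peak-gene links arise in single-cell multiome data:

* latent per-unit TF activities drive peak accessibility through factor
  loadings — ordinary factors load on local (cis) blocks of peaks, while a
  small number of *pioneer* factors load on peaks genome-wide, producing both
  cis-like and trans-like co-accessibility;
* each gene receives sparse causal effects from a few cis peaks, with effect
  variance that can differ by functional peak category (enrichment ground
  truth), plus a small direct "leakage" of TF-factor activity into expression
  (trans TF effects on transcription);
* observed matrices apply an exponential link and multiplicative lognormal
  measurement noise (continuous, metacell-like values; an optional Poisson
  layer produces cell-like counts).

Everything downstream — scores, stratified regression, fine-mapping,
evaluation — can be validated against the exported ground truth
(:class:`SynthTruth`, true links, category membership, TF loadings).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import EvaluationLinkSet, GeneSet, MultiomeDataset, PeakSet
from .scasc import CategoryAnnotation
from .tfbs import TFBSMatrix


@dataclass
class SynthConfig:
    """Study conditions for the synthetic multiome.

    Defaults are the scaled-down conditions used throughout the test-suite:
    500 metacell-like units, 400 peaks spaced ~25kb over 4 chromosomes (so a
    1Mb window holds ~40 cis neighbours) and 80 genes, with two pioneer
    factors among ten TF factors.
    """

    n_units: int = 500
    n_peaks: int = 400
    n_genes: int = 80
    n_chroms: int = 4

    peak_spacing: int = 25_000
    peak_jitter: int = 5_000
    peak_width: int = 500

    n_tf_factors: int = 10
    n_pioneer_factors: int = 2
    local_block: int = 25  # peaks per ordinary (cis) factor
    local_loading: float = 1.0
    pioneer_loading: float = 0.8
    pioneer_fraction: float = 0.3  # fraction of all peaks a pioneer factor touches
    loading_heterogeneity: float = 0.6  # spread of per-peak overall loading scale
    unique_sd: float = 0.6  # peak-specific (non-shared) signal

    causal_peaks_per_gene: int = 2
    causal_effect_sd: float = 1.0
    enriched_category_fraction: float = 0.25
    enriched_effect_multiplier: float = 1.0  # >1 concentrates causal variance in the category
    leakage_sd: float = 0.45  # direct factor -> expression leakage
    expr_unique_sd: float = 0.8

    noise_sd: float = 0.3  # multiplicative lognormal measurement noise (ATAC)
    expr_noise_sd: float = 0.3
    dropout: float = 0.0
    counts: bool = False  # optional Poisson count layer (cell-level)

    shuffle_loadings: bool = False  # no-tagging control: break cross-peak correlation

    seed: int = 0

    def __post_init__(self):
        for name in ("pioneer_fraction", "enriched_category_fraction", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("local_loading", "pioneer_loading", "unique_sd", "noise_sd", "leakage_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pioneer_factors > self.n_tf_factors:
            raise ValueError("n_pioneer_factors cannot exceed n_tf_factors")


@dataclass
class SynthTruth:
    """Ground truth exported alongside a generated dataset."""

    causal_links: pd.DataFrame  # peak_id, gene_id, beta
    loadings: np.ndarray  # peaks x factors
    pioneer_factors: np.ndarray  # factor indices
    tagging_intensity: np.ndarray  # per peak: total squared shared-factor loading
    factor_activities: np.ndarray  # units x factors


def _genome_layout(cfg: SynthConfig, rng) -> tuple[PeakSet, GeneSet]:
    peaks_per_chrom = cfg.n_peaks // cfg.n_chroms
    genes_per_chrom = cfg.n_genes // cfg.n_chroms
    if peaks_per_chrom < cfg.causal_peaks_per_gene:
        raise ValueError(
            f"infeasible geometry: {peaks_per_chrom} peaks per chromosome but "
            f"{cfg.causal_peaks_per_gene} causal peaks per gene requested"
        )
    p_ids, p_chroms, p_starts, p_ends = [], [], [], []
    g_ids, g_chroms, g_tss, g_strand = [], [], [], []
    k = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        extra = cfg.n_peaks - peaks_per_chrom * cfg.n_chroms if c == 0 else 0
        n_p = peaks_per_chrom + extra
        centers = (np.arange(n_p) + 1) * cfg.peak_spacing + rng.integers(
            -cfg.peak_jitter, cfg.peak_jitter + 1, size=n_p
        )
        centers = np.sort(np.maximum(centers, cfg.peak_width))
        for pos in centers:
            p_ids.append(f"peak_{k}")
            p_chroms.append(chrom)
            p_starts.append(int(pos - cfg.peak_width // 2))
            p_ends.append(int(pos + cfg.peak_width // 2))
            k += 1
        extra_g = cfg.n_genes - genes_per_chrom * cfg.n_chroms if c == 0 else 0
        host = rng.choice(n_p, size=genes_per_chrom + extra_g, replace=False)
        for i, h in enumerate(np.sort(host)):
            # TSS midway between adjacent peaks: in cis but never promoter-overlapping
            g_ids.append(f"gene_{len(g_ids)}")
            g_chroms.append(chrom)
            g_tss.append(int(centers[h] + cfg.peak_spacing // 2))
            g_strand.append("+" if i % 2 == 0 else "-")
    return PeakSet(p_ids, p_chroms, p_starts, p_ends), GeneSet(g_ids, g_chroms, g_tss, g_strand)


def _factor_loadings(cfg: SynthConfig, peaks: PeakSet, rng) -> tuple[np.ndarray, np.ndarray]:
    n_p = len(peaks)
    L = np.zeros((n_p, cfg.n_tf_factors))
    pioneer = np.arange(cfg.n_pioneer_factors)
    # per-peak overall scale: the tagging-intensity heterogeneity
    scale = np.exp(cfg.loading_heterogeneity * rng.normal(size=n_p))
    chrom_idx = {c: np.flatnonzero(peaks.chroms == c) for c in pd.unique(peaks.chroms)}
    chrom_list = list(chrom_idx)
    for f in range(cfg.n_tf_factors):
        if f < cfg.n_pioneer_factors:
            members = np.flatnonzero(rng.random(n_p) < cfg.pioneer_fraction)
            L[members, f] = cfg.pioneer_loading * rng.uniform(0.5, 1.5, size=members.size)
        else:
            chrom = chrom_list[(f - cfg.n_pioneer_factors) % len(chrom_list)]
            idx = chrom_idx[chrom]
            if len(idx) <= cfg.local_block:
                block = idx
            else:
                start = rng.integers(0, len(idx) - cfg.local_block + 1)
                block = idx[start : start + cfg.local_block]
            L[block, f] = cfg.local_loading * rng.uniform(0.5, 1.5, size=block.size)
    return L * scale[:, None], pioneer


def generate(config: SynthConfig):
    """Generate a synthetic multiome with full ground truth.

    Returns ``(dataset, truth, categories, tfbs, links)``; deterministic given
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    peaks, genes = _genome_layout(cfg, rng)
    loadings, pioneer = _factor_loadings(cfg, peaks, rng)

    A = rng.normal(size=(cfg.n_units, cfg.n_tf_factors))  # factor activities
    S = A @ loadings.T + cfg.unique_sd * rng.normal(size=(cfg.n_units, len(peaks)))
    S = (S - S.mean(axis=0)) / np.maximum(S.std(axis=0), 1e-12)
    if cfg.shuffle_loadings:
        # no-tagging control: permute units independently within each peak
        # column, destroying every cross-peak correlation while preserving
        # each peak's marginal distribution
        for j in range(S.shape[1]):
            S[:, j] = S[rng.permutation(cfg.n_units), j]

    # functional categories: an enriched category plus an overlapping decoy
    # (no complement category: a partition would be collinear with "all")
    enriched = rng.random(len(peaks)) < cfg.enriched_category_fraction
    decoy = rng.random(len(peaks)) < 0.5
    membership = pd.DataFrame(
        {"enriched": enriched.astype(float), "decoy": decoy.astype(float)},
        index=peaks.ids,
    )
    categories = CategoryAnnotation(peaks.ids, membership, blocks=peaks.chroms)

    # sparse causal peak -> gene effects, variance scaled by category
    effect_sd = np.where(
        enriched, cfg.causal_effect_sd * np.sqrt(cfg.enriched_effect_multiplier), cfg.causal_effect_sd
    )
    leak_w = rng.normal(size=(cfg.n_tf_factors, cfg.n_genes))
    leak_w[pioneer] *= 3.0  # pioneer activity leaks more strongly into expression
    leak_w /= np.linalg.norm(leak_w, axis=0, keepdims=True)
    causal_rows = []
    E = np.zeros((cfg.n_units, cfg.n_genes))
    pcen, pchrom = peaks.centers, peaks.chroms
    for g in range(cfg.n_genes):
        cis = np.flatnonzero((pchrom == genes.chroms[g]) & (np.abs(pcen - genes.tss[g]) < 1_000_000))
        k = min(cfg.causal_peaks_per_gene, cis.size)
        chosen = rng.choice(cis, size=k, replace=False)
        betas = rng.normal(scale=effect_sd[chosen])
        E[:, g] = S[:, chosen] @ betas
        for pj, b in zip(chosen, betas):
            causal_rows.append((peaks.ids[pj], genes.ids[g], float(b)))
    E = E + cfg.leakage_sd * (A @ leak_w)
    E = E + cfg.expr_unique_sd * rng.normal(size=E.shape)
    E = (E - E.mean(axis=0)) / np.maximum(E.std(axis=0), 1e-12)

    # observation layer: exp link + multiplicative lognormal noise
    atac_base = rng.normal(scale=0.3, size=len(peaks))
    rna_base = rng.normal(scale=0.3, size=cfg.n_genes)
    atac = np.exp(atac_base + 0.5 * S) * np.exp(cfg.noise_sd * rng.normal(size=S.shape))
    rna = np.exp(rna_base + 0.5 * E) * np.exp(cfg.expr_noise_sd * rng.normal(size=E.shape))
    if cfg.dropout > 0:
        atac *= rng.random(atac.shape) >= cfg.dropout
        rna *= rng.random(rna.shape) >= cfg.dropout
    unit_kind = "metacell"
    if cfg.counts:
        atac = rng.poisson(atac).astype(float)
        rna = rng.poisson(rna).astype(float)
        unit_kind = "cell"

    dataset = MultiomeDataset(atac=atac, rna=rna, peaks=peaks, genes=genes, unit_kind=unit_kind)
    truth = SynthTruth(
        causal_links=pd.DataFrame(causal_rows, columns=["peak_id", "gene_id", "beta"]),
        loadings=loadings,
        pioneer_factors=pioneer,
        tagging_intensity=(loadings**2).sum(axis=1),
        factor_activities=A,
    )
    tfbs = TFBSMatrix(
        matrix=(loadings > 0).astype(np.int8),
        element_ids=peaks.ids,
        tf_names=[f"TF{f}" for f in range(cfg.n_tf_factors)],
        pioneer=np.isin(np.arange(cfg.n_tf_factors), pioneer),
    )
    links = _link_set(peaks, genes, truth.causal_links)
    return dataset, truth, categories, tfbs, links


def _link_set(peaks: PeakSet, genes: GeneSet, causal: pd.DataFrame) -> EvaluationLinkSet:
    """All cis pairs labelled: causal -> true, other cis -> false."""
    truth_pairs = set(zip(causal["peak_id"], causal["gene_id"]))
    rows = []
    pcen, pchrom, pids = peaks.centers, peaks.chroms, peaks.ids
    for g in range(len(genes)):
        cis = np.flatnonzero((pchrom == genes.chroms[g]) & (np.abs(pcen - genes.tss[g]) < 1_000_000))
        gid = genes.ids[g]
        for pj in cis:
            pid = pids[pj]
            rows.append((pid, gid, "true" if (pid, gid) in truth_pairs else "false"))
    return EvaluationLinkSet(pd.DataFrame(rows, columns=["peak_id", "gene_id", "label"]))


def inject_noise(dataset: MultiomeDataset, element_subset, noise_sd: float, seed: int = 0, modality: str = "atac") -> MultiomeDataset:
    """Multiply selected columns by iid lognormal noise (artificial measurement noise)."""
    rng = np.random.default_rng(seed)
    idx = np.asarray(element_subset, dtype=np.intp)
    if modality == "atac":
        atac = dataset.atac.copy()
        if noise_sd > 0:
            atac[:, idx] *= np.exp(noise_sd * rng.normal(size=(dataset.n_units, idx.size)))
        return replace(dataset, atac=atac)
    if modality == "rna":
        rna = dataset.rna.copy()
        if noise_sd > 0:
            rna[:, idx] *= np.exp(noise_sd * rng.normal(size=(dataset.n_units, idx.size)))
        return replace(dataset, rna=rna)
    raise ValueError(f"modality must be 'atac' or 'rna', got {modality!r}")


# ---------------------------------------------------------------------------
# score-level simulation under the stratified regression model
# ---------------------------------------------------------------------------


def stratified_model_sim(
    n_elements: int = 20_000,
    n_blocks: int = 20,
    category_fraction: float = 0.25,
    tau_all: float = 0.0,
    tau_category: float = 0.4,
    tau0: float = 0.1,
    gamma: float = 0.02,
    mean_partners: float = 40.0,
    mean_r2: float = 0.05,
    bias: float = 0.001,
    noise_sd: float = 0.15,
    seed: int = 0,
):
    """Simulate stratified scores and responses directly under the regression model.

    Each element gets a Poisson number of cis partners with exponential r^2
    values plus the self term; partners fall into the focal category with
    probability ``category_fraction``. The response is the linear model
    ``y = tau0 + tau_all x_all + tau_cat x_cat + gamma G + noise``, so the
    implied per-element causal variance is ``tau_all + I_C tau_category`` and
    the category enrichment has the closed form
    ``(tau_all + tau_category) / (tau_all + f tau_category)`` (equal to 1/f
    when the category carries all causal variance). Used to validate
    estimation and jackknife calibration at scales where simulating a full
    multiome would be wasteful.

    Returns ``(table, membership, expected_enrichment)`` where ``table`` has
    the layout of :func:`peaktag.scasc.stratified_scores`.
    """
    rng = np.random.default_rng(seed)
    in_cat = rng.random(n_elements) < category_fraction
    m = rng.poisson(mean_partners, size=n_elements) + 1
    total = int(m.sum())
    r2 = np.clip(rng.exponential(mean_r2, size=total), 0, 1)
    cat = rng.random(total) < category_fraction
    offsets = np.concatenate([[0], np.cumsum(m)[:-1]])
    # self term: r^2 = 1, membership = own membership
    x_all = np.add.reduceat(r2, offsets) + 1.0 - bias * (m + 1)
    x_cat = np.add.reduceat(r2 * cat, offsets) + in_cat.astype(float) - bias * (m + 1)
    g = rng.poisson(8.0, size=n_elements).astype(float)
    y = tau0 + tau_all * x_all + tau_category * x_cat + gamma * g + noise_sd * rng.normal(size=n_elements)
    blocks = rng.integers(0, n_blocks, size=n_elements)
    table = pd.DataFrame(
        {
            "element_id": [f"e{j}" for j in range(n_elements)],
            "x::all": x_all,
            "x::category": x_cat,
            "y": y,
            "covariate": g,
            "block": [f"block{b}" for b in blocks],
        }
    )
    membership = pd.DataFrame(
        {"all": np.ones(n_elements), "category": in_cat.astype(float)},
        index=table["element_id"],
    )
    f = in_cat.mean()
    denom = tau_all + f * tau_category
    expected = (tau_all + tau_category) / denom if denom > 0 else np.nan
    return table, membership, float(expected)


# ---------------------------------------------------------------------------
# focused fine-mapping scenario
# ---------------------------------------------------------------------------


def tagging_scenario(
    n_units: int = 400,
    n_taggers: int = 20,
    tagging_r: float = 0.7,
    causal_r2: float = 0.3,
    tagger_cor: float = 0.97,
    leakage_var: float = 0.30,
    seed: int = 0,
):
    """One focal gene with a single causal peak among correlated tagging peaks.

    A latent TF activity ``f`` drives a tight cluster of tagging peaks
    (pairwise correlation ``tagger_cor``) and, more weakly, the causal peak,
    calibrated so that corr(causal, tagger) = ``tagging_r``. Expression is

        y = sqrt(causal_r2) * causal + sqrt(leakage_var) * f + noise,

    i.e. a direct causal effect plus trans leakage of the TF activity into
    transcription. The leakage makes single tagging peaks near-ties with the
    causal peak marginally, while conditioning on the tagger cluster (which
    proxies f) exposes the causal peak — the regime where fine-mapping helps.

    Returns ``(y, X, causal_index)`` with the causal peak in column 0.
    """
    rho_c = tagging_r**2 / tagger_cor
    if not 0 < rho_c <= 1:
        raise ValueError("tagging_r^2 must not exceed tagger_cor")
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n_units)
    causal = np.sqrt(rho_c) * f + np.sqrt(1 - rho_c) * rng.normal(size=n_units)
    taggers = np.sqrt(tagger_cor) * f[:, None] + np.sqrt(1 - tagger_cor) * rng.normal(size=(n_units, n_taggers))
    noise_var = max(1.0 - causal_r2 - leakage_var, 0.05)
    y = (
        np.sqrt(causal_r2) * causal
        + np.sqrt(leakage_var) * f
        + np.sqrt(noise_var) * rng.normal(size=n_units)
    )
    X = np.column_stack([causal, taggers])
    return y, X, 0
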