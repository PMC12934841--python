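"""Sum-of-single-effects (SuSiE) fine-mapping of peak-gene links.

For a focal gene, the standardized expression vector y is modelled as
``y = X b + e`` where X holds standardized accessibility of candidate peaks
within 1Mb of the TSS and b is a sum of L "single effects", each having
exactly one nonzero coordinate. The iterative Bayesian stepwise selection
(IBSS) algorithm fits each single-effect regression (SER) in turn on the
residual left by the others; each SER yields a posterior distribution alpha_l
over which candidate carries the effect. The per-candidate posterior inclusion
probability is ``PIP_j = 1 - prod_l (1 - alpha_lj)``.

Four configurations mirror common usage: a single causal peak (SCP, L=1) or
multiple causal peaks (MCP, L=min(10, n_candidates)), each with flat priors
or functional priors proportional to per-peak causal effect-size variances
from the stratified score regression. The *fine-mapped linking score* of a
peak-gene pair is its marginal squared correlation times its PIP, shrinking
tagging peaks whose association is explained by a correlated causal peak.

Gene-level fine-mapping (candidate genes for a focal peak) swaps the roles of
the two modalities and uses the same machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .core import DEFAULT_CIS_WINDOW, MultiomeDataset

logger = logging.getLogger(__name__)

MCP_MAX_EFFECTS = 10
DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 100
_PRIOR_FLOOR_REL = 1e-9  # floor for functional priors, relative to mean mass


# ---------------------------------------------------------------------------
# task construction
# ---------------------------------------------------------------------------


def _standardize(v):
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


@dataclass
class FineMapTask:
    """Inputs for one fine-mapping run: standardized y, X, L and priors."""

    focal_id: str
    y: np.ndarray
    X: np.ndarray
    candidate_ids: np.ndarray
    L: int
    prior_weights: np.ndarray

    @classmethod
    def build(cls, focal_id, y, candidates, candidate_ids, L=1, prior_weights=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(candidates, dtype=float)
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("non-finite values in fine-mapping inputs")
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("candidate matrix must be units x candidates")
        if len(y) <= 3:
            raise ValueError("need more than 3 units")
        candidate_ids = np.asarray(candidate_ids, dtype=object)
        sds = X.std(axis=0, ddof=0)
        keep = sds > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant candidate column(s)", stacklevel=2)
            X = X[:, keep]
            candidate_ids = candidate_ids[keep]
            if prior_weights is not None:
                prior_weights = np.asarray(prior_weights, dtype=float)[keep]
        if X.shape[1] == 0:
            raise ValueError("no non-constant candidates")
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        ys = _standardize(y)
        p = Xs.shape[1]
        if prior_weights is None:
            pw = np.full(p, 1.0 / p)
        else:
            pw = np.asarray(prior_weights, dtype=float)
            if (pw < 0).any() or pw.sum() <= 0:
                raise ValueError("prior weights must be nonnegative with positive sum")
            pw = pw / pw.sum()
        L = max(1, int(L))
        return cls(focal_id=str(focal_id), y=ys, X=Xs, candidate_ids=candidate_ids, L=L, prior_weights=pw)


def configure(task_kind: str, n_candidates: int, mode: str, priors: str = "flat", var_beta=None):
    """Resolve (L, prior_weights) for a fine-mapping configuration.

    ``mode``: "scp" (single causal element, L=1) or "mcp" (multiple causal
    elements, L = min(10, n_candidates)). ``priors``: "flat" or "functional";
    functional priors are proportional to max(Var(beta_j), eps) with a small
    floor, and fall back to flat (with a warning) if no candidate has positive
    prior mass. ``task_kind`` is "peak" (candidates are peaks for a focal
    gene) or "gene" (candidates are genes for a focal peak); both use the same
    rules.
    """
    if task_kind not in ("peak", "gene"):
        raise ValueError(f"task_kind must be 'peak' or 'gene', got {task_kind!r}")
    mode = mode.lower()
    if mode == "scp":
        L = 1
    elif mode == "mcp":
        L = min(MCP_MAX_EFFECTS, int(n_candidates))
    else:
        raise ValueError(f"mode must be 'scp' or 'mcp', got {mode!r}")
    if priors == "flat":
        weights = np.full(n_candidates, 1.0 / n_candidates)
    elif priors == "functional":
        if var_beta is None:
            raise ValueError("functional priors require per-candidate Var(beta) estimates")
        v = np.clip(np.asarray(var_beta, dtype=float), 0.0, None)
        if v.sum() <= 0:
            warnings.warn("no positive prior mass; falling back to flat priors", stacklevel=2)
            weights = np.full(n_candidates, 1.0 / n_candidates)
        else:
            floor = _PRIOR_FLOOR_REL * v.mean()
            v = np.maximum(v, floor)
            weights = v / v.sum()
    else:
        raise ValueError(f"priors must be 'flat' or 'functional', got {priors!r}")
    return L, weights


# ---------------------------------------------------------------------------
# single-effect regression
# ---------------------------------------------------------------------------


def _ser_lbf(bhat, s2, V):
    """Per-candidate log Bayes factor of effect variance V vs the null."""
    with np.errstate(divide="ignore"):
        return 0.5 * np.log(s2 / (s2 + V)) + 0.5 * bhat**2 * V / (s2 * (s2 + V))


def _optimize_prior_variance(bhat, s2, log_prior):
    """Maximize the SER marginal likelihood over the prior effect variance V >= 0."""

    def neg_loglik(logV):
        return -logsumexp(log_prior + _ser_lbf(bhat, s2, np.exp(logV)))

    res = minimize_scalar(neg_loglik, bounds=(-30.0, 15.0), method="bounded")
    V = float(np.exp(res.x))
    # the null V=0 has marginal loglik 0 (all BFs equal 1)
    if -res.fun < 0.0:
        return 0.0
    return V


def _fit_ser(Xty, d, sigma2, log_prior, V=None, estimate_V=True):
    """Exact posterior of one single-effect regression on a residual vector.

    Returns (alpha, mu1, mu2, V, lbf_model): posterior assignment
    probabilities, first and second posterior moments of the effect given
    assignment, the (optimized) prior variance, and the SER log Bayes factor.
    """
    bhat = Xty / d
    s2 = sigma2 / d
    if estimate_V:
        V = _optimize_prior_variance(bhat, s2, log_prior)
    if V is None:
        raise ValueError("V must be given when estimate_V is False")
    lbf = _ser_lbf(bhat, s2, V)
    logw = log_prior + lbf
    lbf_model = float(logsumexp(logw))
    alpha = np.exp(logw - lbf_model)
    if V > 0:
        post_var = 1.0 / (1.0 / s2 + 1.0 / V)
        mu1 = post_var / s2 * bhat
        mu2 = post_var + mu1**2
    else:
        mu1 = np.zeros_like(bhat)
        mu2 = np.zeros_like(bhat)
    return alpha, mu1, mu2, V, lbf_model


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


@dataclass
class FineMapResult:
    """Posterior summary of one SuSiE fit."""

    focal_id: str
    candidate_ids: np.ndarray
    alpha: np.ndarray  # (L, p) per-effect assignment probabilities
    mu: np.ndarray  # (L, p) posterior effect means given assignment
    pip: np.ndarray  # (p,)
    prior_variance: np.ndarray  # (L,)
    sigma2: float
    elbo: list
    converged: bool
    n_iter: int
    marginal_r2: np.ndarray  # (p,)

    @property
    def finemapped_score(self) -> np.ndarray:
        return self.marginal_r2 * self.pip

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate_id": self.candidate_ids,
                "marginal_r2": self.marginal_r2,
                "pip": self.pip,
                "finemapped_score": self.finemapped_score,
            }
        )

    def summary(self) -> str:
        lines = [
            f"SuSiE fine-mapping for {self.focal_id}",
            f"  candidates: {len(self.candidate_ids)}   effects L: {self.alpha.shape[0]}",
            f"  converged: {self.converged} after {self.n_iter} iterations   sigma2: {self.sigma2:.4g}",
            f"  {'candidate':<20}{'marginal_r2':>12}{'PIP':>10}{'finemapped':>12}",
        ]
        order = np.argsort(-self.pip)[:10]
        for j in order:
            lines.append(
                f"  {str(self.candidate_ids[j]):<20}{self.marginal_r2[j]:>12.4f}"
                f"{self.pip[j]:>10.4f}{self.finemapped_score[j]:>12.4f}"
            )
        return "\n".join(lines)


class SusieFineMapper:
    """Model object for one fine-mapping task; ``fit()`` runs IBSS.

    ``estimate_prior_variance=True`` optimizes each effect's prior variance by
    maximizing the SER marginal likelihood at every iteration (effects whose
    prior variance collapses to zero contribute their diffuse alpha to PIPs).
    The residual variance sigma2 is re-estimated from the expected residual
    sum of squares each iteration. Convergence is declared when the largest
    change in any alpha entry falls below ``tol``.
    """

    def __init__(
        self,
        task: FineMapTask,
        estimate_prior_variance: bool = True,
        scaled_prior_variance: float = 0.2,
        estimate_residual_variance: bool = True,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ):
        self.task = task
        self.estimate_prior_variance = estimate_prior_variance
        self.scaled_prior_variance = scaled_prior_variance
        self.estimate_residual_variance = estimate_residual_variance
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> FineMapResult:
        t = self.task
        X, y, L = t.X, t.y, t.L
        n, p = X.shape
        d = np.einsum("ij,ij->j", X, X)  # = n for standardized columns
        log_prior = np.log(t.prior_weights)
        var_y = float(y @ y) / n

        sigma2 = var_y
        V = np.full(L, self.scaled_prior_variance * var_y)
        alpha = np.tile(t.prior_weights, (L, 1))
        mu1 = np.zeros((L, p))
        mu2 = np.zeros((L, p))
        Xb = np.zeros((L, n))  # fitted value of each effect

        marginal_r = (X.T @ y) / np.sqrt(d * float(y @ y))
        elbo_trace = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            alpha_old = alpha.copy()
            kl = np.zeros(L)
            r_full = y - Xb.sum(axis=0)
            for l in range(L):
                r_l = r_full + Xb[l]
                Xty = X.T @ r_l
                alpha[l], mu1[l], mu2[l], V[l], lbf_model = _fit_ser(
                    Xty, d, sigma2, log_prior, V=V[l], estimate_V=self.estimate_prior_variance
                )
                b_bar = alpha[l] * mu1[l]
                Xb[l] = X @ b_bar
                # KL(q_l || prior) = E_q[log p(r_l|b)] - log p(r_l)
                rss = float(r_l @ r_l)
                post_e = -(rss - 2.0 * float(b_bar @ Xty) + float((alpha[l] * mu2[l]) @ d)) / (2.0 * sigma2)
                null_ll = -rss / (2.0 * sigma2)
                kl[l] = post_e - (lbf_model + null_ll)
                r_full = r_l - Xb[l]
            erss = self._erss(y, Xb, alpha, mu1, mu2, d)
            elbo = -0.5 * n * np.log(2.0 * np.pi * sigma2) - erss / (2.0 * sigma2) - kl.sum()
            elbo_trace.append(float(elbo))
            if np.max(np.abs(alpha - alpha_old)) < self.tol:
                converged = True
                break  # sigma2 stays the value used in the final sweep
            if self.estimate_residual_variance:
                sigma2 = max(erss / n, 1e-12)
        if not converged:
            logger.warning("IBSS did not converge for %s after %d iterations", t.focal_id, self.max_iter)

        pip = 1.0 - np.prod(1.0 - alpha, axis=0)
        return FineMapResult(
            focal_id=t.focal_id,
            candidate_ids=t.candidate_ids,
            alpha=alpha,
            mu=mu1,
            pip=np.clip(pip, 0.0, 1.0),
            prior_variance=V,
            sigma2=float(sigma2),
            elbo=elbo_trace,
            converged=converged,
            n_iter=it,
            marginal_r2=np.clip(marginal_r, -1, 1) ** 2,
        )

    @staticmethod
    def _erss(y, Xb, alpha, mu1, mu2, d):
        """Expected residual sum of squares under the variational posterior."""
        fit = Xb.sum(axis=0)
        resid = y - fit
        # E||y - Xb||^2 = ||y - X E[b]||^2 + sum_l ( E||X b_l||^2 - ||X E[b_l]||^2 )
        var_term = 0.0
        for l in range(alpha.shape[0]):
            var_term += float((alpha[l] * mu2[l]) @ d) - float(Xb[l] @ Xb[l])
        return float(resid @ resid) + var_term


def susie_ibss(task: FineMapTask, max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL, **kwargs) -> FineMapResult:
    """Functional wrapper around :class:`SusieFineMapper`."""
    return SusieFineMapper(task, max_iter=max_iter, tol=tol, **kwargs).fit()


# ---------------------------------------------------------------------------
# linking scores
# ---------------------------------------------------------------------------


def finemapped_linking_scores(
    dataset: MultiomeDataset,
    mode: str = "scp",
    priors: str = "flat",
    level: str = "peak",
    var_beta: pd.Series | None = None,
    max_dist: int = DEFAULT_CIS_WINDOW,
    marginal_dataset: MultiomeDataset | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Marginal and fine-mapped linking scores for all candidate peak-gene pairs.

    ``level="peak"``: for each focal gene, fine-map over candidate peaks
    centered <1Mb from its TSS. ``level="gene"``: for each focal peak,
    fine-map over candidate genes with TSS <1Mb of its center. ``var_beta``
    (indexed by candidate element id) supplies functional priors.
    ``marginal_dataset`` optionally computes the marginal r^2 on a different
    unit level (e.g. single cells) than the PIPs (cross-source mode). Focal
    elements with zero candidates are omitted and logged.
    """
    pchrom, pcen = dataset.peaks.chroms, dataset.peaks.centers
    gchrom, gtss = dataset.genes.chroms, dataset.genes.tss
    mdat = dataset if marginal_dataset is None else marginal_dataset
    rows = []
    if level == "peak":
        focal_ids, cand_ids = dataset.genes.ids, dataset.peaks.ids
        for gi, gid in enumerate(focal_ids):
            cand = np.flatnonzero((pchrom == gchrom[gi]) & (np.abs(pcen - gtss[gi]) < max_dist))
            if cand.size == 0:
                logger.info("gene %s has no candidate peaks; omitted", gid)
                continue
            res = _run_one(
                dataset.rna[:, gi], dataset.atac[:, cand], cand_ids[cand], "peak", mode, priors, var_beta, fit_kwargs
            )
            if res is None:
                continue
            marg = (
                pd.Series(_marginal_r2(mdat.rna[:, gi], mdat.atac[:, cand]), index=cand_ids[cand])
                if marginal_dataset is not None
                else None
            )
            dist = pd.Series(np.abs(pcen[cand] - gtss[gi]), index=cand_ids[cand])
            rows.append(_link_rows(res, gid, dist, mode, priors, level, marg))
    elif level == "gene":
        focal_ids, cand_ids = dataset.peaks.ids, dataset.genes.ids
        for pi, pid in enumerate(focal_ids):
            cand = np.flatnonzero((gchrom == pchrom[pi]) & (np.abs(gtss - pcen[pi]) < max_dist))
            if cand.size == 0:
                logger.info("peak %s has no candidate genes; omitted", pid)
                continue
            res = _run_one(
                dataset.atac[:, pi], dataset.rna[:, cand], cand_ids[cand], "gene", mode, priors, var_beta, fit_kwargs
            )
            if res is None:
                continue
            marg = (
                pd.Series(_marginal_r2(mdat.atac[:, pi], mdat.rna[:, cand]), index=cand_ids[cand])
                if marginal_dataset is not None
                else None
            )
            dist = pd.Series(np.abs(gtss[cand] - pcen[pi]), index=cand_ids[cand])
            rows.append(_link_rows(res, pid, dist, mode, priors, level, marg))
    else:
        raise ValueError(f"level must be 'peak' or 'gene', got {level!r}")
    if not rows:
        return pd.DataFrame(
            columns=["peak_id", "gene_id", "distance", "marginal_r2", "pip", "finemapped_score", "mode", "source"]
        )
    return pd.concat(rows, ignore_index=True)


def _marginal_r2(y, X):
    ys = _standardize(y)
    Xs = np.asarray(X, dtype=float)
    Xs = Xs - Xs.mean(axis=0)
    norms = np.linalg.norm(Xs, axis=0)
    norms[norms == 0] = 1.0
    r = (Xs / norms).T @ ys / max(np.linalg.norm(ys), 1e-300)
    return np.clip(r, -1, 1) ** 2


def _run_one(y, Xc, cand_ids, task_kind, mode, priors, var_beta, fit_kwargs):
    vb = None
    if priors == "functional":
        if var_beta is None:
            raise ValueError("functional priors require var_beta")
        vb = var_beta.reindex(cand_ids).to_numpy(dtype=float)
        vb = np.where(np.isfinite(vb), vb, 0.0)
    try:
        L, weights = configure(task_kind, Xc.shape[1], mode, priors, vb)
        task = FineMapTask.build("focal", y, Xc, cand_ids, L=L, prior_weights=weights)
    except ValueError as exc:
        logger.info("skipping focal element: %s", exc)
        return None
    return SusieFineMapper(task, **fit_kwargs).fit()


def _link_rows(res: FineMapResult, focal_id, dist: pd.Series, mode, priors, level, marginal_override=None):
    # align on candidate id: constant columns may have been dropped
    dist = dist.reindex(res.candidate_ids).to_numpy()
    marg = (
        res.marginal_r2
        if marginal_override is None
        else marginal_override.reindex(res.candidate_ids).to_numpy(dtype=float)
    )
    frame = pd.DataFrame(
        {
            "peak_id" if level == "peak" else "gene_id": res.candidate_ids,
            "gene_id" if level == "peak" else "peak_id": focal_id,
            "distance": dist,
            "marginal_r2": marg,
            "pip": res.pip,
            "finemapped_score": marg * res.pip,
            "mode": f"{mode}-{priors}",
            "source": "metacell",
        }
    )
    return frame[["peak_id", "gene_id", "distance", "marginal_r2", "pip", "finemapped_score", "mode", "source"]]


def top_peak_baseline(links: pd.DataFrame, score_col: str = "marginal_r2") -> pd.DataFrame:
    """Keep, per gene, only the link with the highest score (ties: lowest peak id)."""
    def _pick(group):
        best = group[score_col].max()
        tied = group[group[score_col] == best]
        return tied.sort_values("peak_id").iloc[:1]

    out = links.sort_values(["gene_id", "peak_id"]).groupby("gene_id", group_keys=False)[links.columns].apply(_pick)
    return out.reset_index(drop=True)
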