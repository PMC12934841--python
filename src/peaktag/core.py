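"""Data model and I/O for paired single-cell ATAC + RNA ("multiome") data.

The central container is :class:`MultiomeDataset`: an accessibility matrix
(units x peaks) and an expression matrix (units x genes) with peak intervals
and gene TSS annotations attached. Units are either single cells or metacells
(kNN aggregates of cells). Coordinates follow BED conventions throughout:
0-based, half-open intervals; a peak's center is ``floor((start + end) / 2)``;
a gene's TSS is ``start`` on the + strand and ``end - 1`` on the - strand.

Matrices are read/written as MatrixMarket (.mtx) with sidecar row/column name
files or as dense TSV; peaks as 4-column BED; genes as a TSV of
(id, chrom, tss, strand) or 6-column BED; evaluation link tables as TSV.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.spatial.distance import cdist

from ._intervals import point_to_interval_distance

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000  # "<1Mb" cis restriction, in bp
DEFAULT_PROMOTER_RADIUS = 1_000  # promoter = within 1kb of any TSS


class PeakSet:
    """Set of ATAC peaks: unique ids with chrom, start, end (0-based half-open)."""

    def __init__(self, ids, chroms, starts, ends):
        df = pd.DataFrame(
            {
                "id": np.asarray(ids, dtype=object),
                "chrom": np.asarray(chroms, dtype=object),
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64),
            }
        )
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"peak interval with start >= end: {row['id']} "
                f"({row['chrom']}:{row['start']}-{row['end']})"
            )
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate peak id: {dup!r}")
        df["center"] = (df["start"] + df["end"]) // 2
        self._df = df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakSet":
        return cls(df["id"], df["chrom"], df["start"], df["end"])

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def ids(self) -> np.ndarray:
        return self._df["id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self._df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self._df["end"].to_numpy()

    @property
    def centers(self) -> np.ndarray:
        return self._df["center"].to_numpy()

    def __len__(self) -> int:
        return len(self._df)

    def subset(self, indices) -> "PeakSet":
        sub = self._df.iloc[np.asarray(indices)].reset_index(drop=True)
        return PeakSet.from_frame(sub)

    def index_of(self, ids) -> np.ndarray:
        lookup = pd.Index(self._df["id"])
        return lookup.get_indexer(ids)


class GeneSet:
    """Set of genes: unique ids with chrom, TSS base position, and strand."""

    def __init__(self, ids, chroms, tss, strands):
        df = pd.DataFrame(
            {
                "id": np.asarray(ids, dtype=object),
                "chrom": np.asarray(chroms, dtype=object),
                "tss": np.asarray(tss, dtype=np.int64),
                "strand": np.asarray(strands, dtype=object),
            }
        )
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if (df["tss"] < 0).any():
            raise ValueError("negative TSS position")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand {df.loc[bad, 'strand'].iloc[0]!r}; expected '+' or '-'")
        self._df = df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneSet":
        return cls(df["id"], df["chrom"], df["tss"], df["strand"])

    @classmethod
    def from_bed(cls, df: pd.DataFrame) -> "GeneSet":
        """From 6-column BED (chrom, start, end, id, score, strand); strand-aware TSS."""
        tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        return cls(df["id"], df["chrom"], tss, df["strand"])

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def ids(self) -> np.ndarray:
        return self._df["id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def tss(self) -> np.ndarray:
        return self._df["tss"].to_numpy()

    def __len__(self) -> int:
        return len(self._df)

    def subset(self, indices) -> "GeneSet":
        sub = self._df.iloc[np.asarray(indices)].reset_index(drop=True)
        return GeneSet.from_frame(sub)

    def index_of(self, ids) -> np.ndarray:
        lookup = pd.Index(self._df["id"])
        return lookup.get_indexer(ids)


@dataclass
class MultiomeDataset:
    """Paired accessibility (units x peaks) and expression (units x genes) matrices.

    ``unit_kind`` records whether rows are single cells or metacells;
    ``unit_covariates`` optionally carries per-unit covariates (e.g. cell
    subtype proportions within each metacell) used for conditional
    correlations.
    """

    atac: np.ndarray
    rna: np.ndarray
    peaks: PeakSet
    genes: GeneSet
    unit_kind: str = "metacell"
    unit_covariates: np.ndarray | None = None

    def __post_init__(self):
        self.atac = np.asarray(self.atac, dtype=float)
        self.rna = np.asarray(self.rna, dtype=float)
        if self.atac.ndim != 2 or self.rna.ndim != 2:
            raise ValueError("atac and rna must be 2-D (units x elements)")
        if self.atac.shape[0] != self.rna.shape[0]:
            raise ValueError(
                f"unit count mismatch: atac has {self.atac.shape[0]} rows, rna has {self.rna.shape[0]}"
            )
        if self.atac.shape[1] != len(self.peaks):
            raise ValueError(
                f"dimension mismatch: atac has {self.atac.shape[1]} columns but "
                f"{len(self.peaks)} peaks annotated"
            )
        if self.rna.shape[1] != len(self.genes):
            raise ValueError(
                f"dimension mismatch: rna has {self.rna.shape[1]} columns but "
                f"{len(self.genes)} genes annotated"
            )
        if self.unit_kind not in ("cell", "metacell"):
            raise ValueError(f"unit_kind must be 'cell' or 'metacell', got {self.unit_kind!r}")

    @property
    def n_units(self) -> int:
        return self.atac.shape[0]

    def subset_peaks(self, indices) -> "MultiomeDataset":
        indices = np.asarray(indices)
        return replace(self, atac=self.atac[:, indices], peaks=self.peaks.subset(indices))

    def subset_genes(self, indices) -> "MultiomeDataset":
        indices = np.asarray(indices)
        return replace(self, rna=self.rna[:, indices], genes=self.genes.subset(indices))

    def without_promoter_peaks(self, radius: int = DEFAULT_PROMOTER_RADIUS) -> "MultiomeDataset":
        """Drop peaks within `radius` bp of any TSS (focus on enhancers)."""
        keep = ~promoter_peak_mask(self.peaks, self.genes, radius)
        return self.subset_peaks(np.flatnonzero(keep))


@dataclass
class EvaluationLinkSet:
    """True/false/untested labels for peak-gene pairs (CRISPR- or eQTL-style)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["peak_id", "gene_id", "label"]))

    VALID_LABELS = ("true", "false", "untested")

    def __post_init__(self):
        t = self.table
        missing = {"peak_id", "gene_id", "label"} - set(t.columns)
        if missing:
            raise ValueError(f"evaluation link table missing columns: {sorted(missing)}")
        bad = ~t["label"].isin(self.VALID_LABELS)
        if bad.any():
            raise ValueError(f"invalid link label {t.loc[bad, 'label'].iloc[0]!r}")
        if t.duplicated(subset=["peak_id", "gene_id"]).any():
            pair = t[t.duplicated(subset=["peak_id", "gene_id"])].iloc[0]
            raise ValueError(f"duplicate label for pair ({pair['peak_id']}, {pair['gene_id']})")

    def __len__(self) -> int:
        return len(self.table)

    def labelled(self, label: str) -> pd.DataFrame:
        return self.table[self.table["label"] == label]


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------


def cis_window(chrom, position, element_chroms, element_positions, max_dist=DEFAULT_CIS_WINDOW):
    """Indices of elements on `chrom` with |position_k - position| < max_dist.

    Distances are center-to-center for peaks and center/TSS-to-TSS for genes;
    the caller passes the appropriate position arrays. The focal element (zero
    distance) qualifies and is included. An unknown chromosome yields an empty
    set (logged at debug level).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    element_chroms = np.asarray(element_chroms)
    element_positions = np.asarray(element_positions, dtype=np.int64)
    on = element_chroms == chrom
    if not on.any():
        logger.debug("cis_window: chromosome %r not present among elements", chrom)
        return np.empty(0, dtype=np.intp)
    idx = np.flatnonzero(on)
    close = np.abs(element_positions[idx] - int(position)) < max_dist
    return idx[close]


def promoter_peak_mask(peaks: PeakSet, genes: GeneSet, radius: int = DEFAULT_PROMOTER_RADIUS) -> np.ndarray:
    """Boolean mask: peak lies within `radius` bp of any gene's TSS.

    A peak is promoter-overlapping when the minimum distance from any base of
    its interval to a TSS is < radius (equivalently, the interval expanded by
    radius on both sides contains the TSS).
    """
    mask = np.zeros(len(peaks), dtype=bool)
    pdf = peaks.df
    for chrom, gsub in genes.df.groupby("chrom", sort=False):
        on = np.flatnonzero((pdf["chrom"] == chrom).to_numpy())
        if on.size == 0:
            continue
        tss = np.sort(gsub["tss"].to_numpy())
        starts = pdf["start"].to_numpy()[on]
        ends = pdf["end"].to_numpy()[on]
        # nearest TSS to each interval: check insertion neighbors
        lo = np.searchsorted(tss, starts) - 1
        hi = np.minimum(lo + 1, len(tss) - 1)
        lo = np.clip(lo, 0, len(tss) - 1)
        d_lo = point_to_interval_distance(tss[lo], starts, ends)
        d_hi = point_to_interval_distance(tss[hi], starts, ends)
        mask[on] = np.minimum(d_lo, d_hi) < radius
    return mask


def exclude_promoter_peaks(peaks: PeakSet, genes: GeneSet, radius: int = DEFAULT_PROMOTER_RADIUS) -> PeakSet:
    """Peaks surviving promoter exclusion (distance to every TSS >= radius)."""
    keep = ~promoter_peak_mask(peaks, genes, radius)
    return peaks.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# metacell aggregation
# ---------------------------------------------------------------------------


def make_metacells(dataset: MultiomeDataset, embedding, n_metacells=None, k_neighbors=50, seed=0) -> MultiomeDataset:
    """Aggregate cells into metacells by kNN summation around seed cells.

    Seed cells are drawn without replacement; each metacell is the sum of the
    seed's ``k_neighbors`` nearest cells (including itself) in the joint
    embedding, per modality. Distance ties are broken by unit index, so the
    result is deterministic given ``seed``.
    """
    if dataset.unit_kind != "cell":
        raise ValueError("make_metacells expects a cell-level dataset")
    embedding = np.asarray(embedding, dtype=float)
    n_cells = dataset.n_units
    if embedding.shape[0] != n_cells:
        raise ValueError("embedding rows must match number of cells")
    if k_neighbors >= n_cells:
        raise ValueError(f"k_neighbors ({k_neighbors}) must be < number of cells ({n_cells})")
    if n_metacells is None:
        n_metacells = max(1, min(500, n_cells // 10))
    rng = np.random.default_rng(seed)
    seeds = np.sort(rng.choice(n_cells, size=n_metacells, replace=False))

    atac_mc = np.empty((n_metacells, dataset.atac.shape[1]))
    rna_mc = np.empty((n_metacells, dataset.rna.shape[1]))
    cov_mc = None
    if dataset.unit_covariates is not None:
        cov_mc = np.empty((n_metacells, dataset.unit_covariates.shape[1]))
    dists = cdist(embedding[seeds], embedding)
    unit_idx = np.arange(n_cells)
    for m in range(n_metacells):
        order = np.lexsort((unit_idx, dists[m]))
        members = order[:k_neighbors]
        atac_mc[m] = dataset.atac[members].sum(axis=0)
        rna_mc[m] = dataset.rna[members].sum(axis=0)
        if cov_mc is not None:
            # covariates are averaged (proportions stay proportions)
            cov_mc[m] = dataset.unit_covariates[members].mean(axis=0)
    return MultiomeDataset(
        atac=atac_mc,
        rna=rna_mc,
        peaks=dataset.peaks,
        genes=dataset.genes,
        unit_kind="metacell",
        unit_covariates=cov_mc,
    )


def tfidf_lsi(atac: np.ndarray, n_components: int = 15, seed: int = 0) -> np.ndarray:
    """TF-IDF + truncated-SVD embedding of an accessibility matrix.

    A lightweight stand-in for iterative-LSI joint reductions, sufficient for
    building metacells on synthetic data.
    """
    from sklearn.decomposition import TruncatedSVD

    X = np.asarray(atac, dtype=float)
    tf = X / np.maximum(X.sum(axis=1, keepdims=True), 1e-12)
    idf = np.log1p(X.shape[0] / np.maximum((X > 0).sum(axis=0), 1))
    M = np.log1p(tf * idf * 1e4)
    svd = TruncatedSVD(n_components=min(n_components, min(M.shape) - 1), random_state=seed)
    return svd.fit_transform(M)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_matrix(path: str) -> np.ndarray:
    if path.endswith(".mtx"):
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        return np.asarray(m, dtype=float)
    # round_trip parsing keeps write->read lossless for %.17g output
    return pd.read_csv(path, sep="\t", header=None, float_precision="round_trip").to_numpy(dtype=float)


def _write_matrix(path: str, matrix: np.ndarray) -> None:
    if path.endswith(".mtx"):
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix))
    else:
        pd.DataFrame(matrix).to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")


def read_peaks_bed(path: str) -> PeakSet:
    """4-column BED (chrom, start, end, id); malformed lines are fatal with line number."""
    chroms, starts, ends, ids = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: interval start >= end ({parts[0]}:{start}-{end})")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            ids.append(parts[3])
    return PeakSet(ids, chroms, starts, ends)


def read_genes(path: str) -> GeneSet:
    """Gene annotation: TSV with header (id, chrom, tss, strand) or 6-column BED."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("id\t") or "tss" in first.split("\t")[:4]:
        df = pd.read_csv(path, sep="\t")
        return GeneSet(df["id"], df["chrom"], df["tss"], df["strand"])
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "id", "score", "strand"],
    )
    return GeneSet.from_bed(df)


def read_multiome(atac_path, rna_path, peaks_bed, genes_path, unit_kind="metacell") -> MultiomeDataset:
    """Load and validate a multiome dataset from standard-format files."""
    for p in (atac_path, rna_path, peaks_bed, genes_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    peaks = read_peaks_bed(peaks_bed)
    genes = read_genes(genes_path)
    atac = _read_matrix(atac_path)
    rna = _read_matrix(rna_path)
    return MultiomeDataset(atac=atac, rna=rna, peaks=peaks, genes=genes, unit_kind=unit_kind)


def write_multiome(dataset: MultiomeDataset, out_dir: str, matrix_format: str = "tsv") -> dict:
    """Write a dataset to a directory; returns the file paths written."""
    os.makedirs(out_dir, exist_ok=True)
    ext = "mtx" if matrix_format == "mtx" else "tsv"
    paths = {
        "atac": os.path.join(out_dir, f"atac.{ext}"),
        "rna": os.path.join(out_dir, f"rna.{ext}"),
        "peaks": os.path.join(out_dir, "peaks.bed"),
        "genes": os.path.join(out_dir, "genes.tsv"),
    }
    _write_matrix(paths["atac"], dataset.atac)
    _write_matrix(paths["rna"], dataset.rna)
    pdf = dataset.peaks.df
    pdf[["chrom", "start", "end", "id"]].to_csv(paths["peaks"], sep="\t", header=False, index=False)
    dataset.genes.df[["id", "chrom", "tss", "strand"]].to_csv(paths["genes"], sep="\t", index=False)
    return paths


def read_evaluation_links(path: str) -> EvaluationLinkSet:
    """TSV of (peak_id, gene_id, label) with labels in {true, false, untested}."""
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": object, "gene_id": object, "label": object})
    return EvaluationLinkSet(df[["peak_id", "gene_id", "label"]])


def write_evaluation_links(links: EvaluationLinkSet, path: str) -> None:
    links.table.to_csv(path, sep="\t", index=False)
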