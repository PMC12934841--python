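import numpy as np
import pytest

from peaktag.core import GeneSet, MultiomeDataset, PeakSet


def make_peaks(rng, n, chroms=("chr1", "chr2"), spacing=40_000, width=600):
    """Random but well-spaced peak layout over a couple of chromosomes."""
    per = n // len(chroms)
    ids, cs, starts, ends = [], [], [], []
    k = 0
    for chrom in chroms:
        n_c = per + (n - per * len(chroms) if chrom == chroms[0] else 0)
        centers = np.sort(rng.choice(np.arange(1, 60) * spacing, size=n_c, replace=False))
        for c in centers:
            ids.append(f"p{k}")
            cs.append(chrom)
            starts.append(int(c - width // 2))
            ends.append(int(c + width // 2))
            k += 1
    return PeakSet(ids, cs, starts, ends)


def make_genes(rng, n, chroms=("chr1", "chr2"), spacing=40_000):
    per = n // len(chroms)
    ids, cs, tss, strands = [], [], [], []
    k = 0
    for chrom in chroms:
        n_c = per + (n - per * len(chroms) if chrom == chroms[0] else 0)
        pos = np.sort(rng.choice(np.arange(1, 60) * spacing + spacing // 2, size=n_c, replace=False))
        for p in pos:
            ids.append(f"g{k}")
            cs.append(chrom)
            tss.append(int(p))
            strands.append("+" if k % 2 == 0 else "-")
            k += 1
    return GeneSet(ids, cs, tss, strands)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def small_dataset(rng):
    """30 peaks / 10 genes / 40 units with correlated structure, promoter-free."""
    peaks = make_peaks(rng, 30)
    genes = make_genes(rng, 10)
    n_units = 40
    latent = rng.normal(size=(n_units, 3))
    atac = np.abs(latent @ rng.normal(size=(3, 30)) + 0.8 * rng.normal(size=(n_units, 30)) + 3.0)
    rna = np.abs(latent @ rng.normal(size=(3, 10)) + 0.8 * rng.normal(size=(n_units, 10)) + 3.0)
    return MultiomeDataset(atac=atac, rna=rna, peaks=peaks, genes=genes, unit_kind="metacell")


@pytest.fixture(scope="session")
def synth_bundle():
    """Default-condition synthetic multiome, generated once per session."""
    from peaktag.synth import SynthConfig, generate

    return generate(SynthConfig(seed=11))
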