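"""Seeded synthetic data with the statistical structure of cis-eQTL fine-mapping.

Generates LD-blocked genotype dosages, expression phenotypes driven by sparse
causal effects, functional feature matrices in which causal variant-gene pairs
are enriched, and (optionally) a complex-trait phenotype sharing causal
variants with a subset of genes.  Every generator takes an integer seed and is
byte-reproducible; all randomness descends from one ``numpy.random.Generator``
per call, split hierarchically with ``Generator.spawn`` where a generator
drives several genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CIS_WINDOW_BP = 1_000_000  # half-width of the cis window around the TSS


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLocus:
    """One gene's cis region: genotypes, expression, and the causal truth.

    Attributes
    ----------
    genotypes
        ``(n, m)`` dosage matrix in {0, 1, 2} as floats.
    expression
        Length-``n`` phenotype vector, or ``None`` until simulated.
    causal_index_set
        Column indices with nonzero true effect.
    effect_sizes
        True effect per causal variant, aligned with ``causal_index_set``.
    block_sizes, rho
        The LD block design the genotypes were drawn from.
    """

    genotypes: np.ndarray
    block_sizes: list[int]
    rho: float
    expression: np.ndarray | None = None
    causal_index_set: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    effect_sizes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class SyntheticCatalog:
    """A multi-gene candidate catalog: pairs, features, truth, loci."""

    pairs: pd.DataFrame          # chrom, pos, ref, alt, gene_id, tissue, tss_distance, pip_a, pip_b
    features: pd.DataFrame       # one row per pair, named feature columns
    truth: np.ndarray            # boolean causal flag per pair
    loci: dict[str, SyntheticLocus] = field(default_factory=dict)
    tss: pd.DataFrame | None = None           # gene_id, chrom, tss_pos, strand
    trait_phenotype: np.ndarray | None = None
    trait_genes: list[str] = field(default_factory=list)
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.features) != len(self.pairs):
            raise ValueError("features row count must equal pairs count")
        rate = float(np.mean(self.truth)) if len(self.truth) else 0.0
        if not 0.0 < rate < 1.0:
            raise ValueError("truth causal rate must be strictly between 0 and 1")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_ld_genotypes(
    n: int,
    block_sizes: list[int],
    rho: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw an ``(n, m)`` dosage matrix with block-equicorrelated LD.

    Each LD block is generated from a Gaussian copula with constant
    within-block correlation ``rho``; blocks are mutually independent.  The
    two latent haplotype draws per individual are thresholded at the allele
    frequency quantile to produce Hardy-Weinberg dosages in {0, 1, 2}.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if n < 2:
        raise ValueError(f"need at least 2 individuals, got {n}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    m = int(np.sum(block_sizes))
    dosage = np.empty((n, m), dtype=float)
    col = 0
    for size in block_sizes:
        # tightly linked variants arise from shared ancestry, so variants in
        # a block share a base allele frequency with mild jitter; without
        # this, MAF mismatch attenuates dosage correlation well below rho
        block_maf = rng.uniform(lo, hi)
        mafs = np.clip(block_maf * rng.uniform(0.8, 1.25, size=size), lo, hi)
        thresholds = stats.norm.ppf(mafs)
        haps = np.zeros((n, size), dtype=float)
        for _ in range(2):  # two haplotypes per individual
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, size))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            haps += (latent < thresholds).astype(float)
        dosage[:, col:col + size] = haps
        col += size
    # guard against degenerate monomorphic columns (possible at small n)
    for j in range(m):
        while np.var(dosage[:, j]) == 0.0:
            flip = rng.integers(0, n, size=max(1, n // 20))
            dosage[flip, j] = rng.integers(0, 3, size=flip.size).astype(float)
    return dosage


def simulate_expression(
    locus: SyntheticLocus,
    n_causal: int,
    beta_sd: float = 0.5,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    causal_indices: np.ndarray | None = None,
    effects: np.ndarray | None = None,
) -> SyntheticLocus:
    """Fill ``locus.expression`` with standardized-genotype effects plus noise.

    ``expression = Z b + e`` where ``Z`` holds column-standardized genotypes,
    ``b`` is nonzero only on the causal set (drawn ``N(0, beta_sd^2)`` unless
    ``effects`` is given) and ``e ~ N(0, noise_sd^2)``.
    """
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be positive, got {noise_sd}")
    if n_causal > locus.m:
        raise ValueError(f"n_causal={n_causal} exceeds m={locus.m}")
    rng = np.random.default_rng(seed)
    if causal_indices is None:
        causal_indices = rng.choice(locus.m, size=n_causal, replace=False)
    causal_indices = np.sort(np.asarray(causal_indices, dtype=int))
    if effects is None:
        effects = rng.normal(0.0, beta_sd, size=causal_indices.size)
    effects = np.asarray(effects, dtype=float)
    G = locus.genotypes
    Z = (G - G.mean(axis=0)) / G.std(axis=0)
    signal = Z[:, causal_indices] @ effects if causal_indices.size else np.zeros(locus.n)
    locus.expression = signal + rng.normal(0.0, noise_sd, size=locus.n)
    locus.causal_index_set = causal_indices
    locus.effect_sizes = effects
    return locus


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def simulate_features(
    truth: np.ndarray,
    tss_distance: np.ndarray,
    enrich_binary: float = 10.0,
    score_informativeness: float = 1.0,
    n_binary: int = 3,
    n_scores: int = 3,
    base_binary_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Build a feature matrix whose columns carry the canonical structure.

    * ``tss_distance`` is passed through as the distance feature.
    * Binary annotations fire ``enrich_binary``-fold more often in causal
      pairs (base rate ``base_binary_rate`` in non-causal pairs).
    * Continuous scores are ``score_informativeness * standardized causal
      indicator + N(0, 1)`` noise; the last score column is pure noise.
    """
    if enrich_binary < 1.0:
        raise ValueError(f"enrich_binary must be >= 1, got {enrich_binary}")
    if score_informativeness < 0.0:
        raise ValueError("score_informativeness must be non-negative")
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth, dtype=bool)
    n = truth.size
    cols: dict[str, np.ndarray] = {"tss_distance": np.asarray(tss_distance, dtype=float)}
    p_causal = min(base_binary_rate * enrich_binary, 1.0)
    for k in range(n_binary):
        p = np.where(truth, p_causal, base_binary_rate)
        cols[f"peak_{k}"] = (rng.uniform(size=n) < p).astype(float)
    z = (truth.astype(float) - truth.mean()) / max(truth.std(), 1e-12)
    for k in range(n_scores):
        informative = score_informativeness if k < n_scores - 1 else 0.0
        cols[f"score_{k}"] = informative * z + rng.standard_normal(n)
    return pd.DataFrame(cols)


def sample_tss_distances(
    truth: np.ndarray,
    tss_decay_bp: float = 20_000.0,
    cis_half_width: int = CIS_WINDOW_BP,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Signed TSS distances: causal two-sided exponential, non-causal uniform."""
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth, dtype=bool)
    out = rng.integers(-cis_half_width, cis_half_width + 1, size=truth.size).astype(float)
    n_causal = int(truth.sum())
    if n_causal:
        mag = rng.exponential(tss_decay_bp, size=n_causal)
        mag = np.minimum(mag, cis_half_width)
        sign = rng.choice([-1.0, 1.0], size=n_causal)
        out[truth] = np.round(sign * mag)
    return out


# ---------------------------------------------------------------------------
# whole-catalog generation
# ---------------------------------------------------------------------------

def simulate_catalog(
    n_genes: int = 50,
    n_individuals: int = 400,
    m_variants: int = 200,
    block_size: int = 10,
    rho: float = 0.9,
    causal_fraction: float = 0.1,
    beta_sd: float = 0.5,
    noise_sd: float = 1.0,
    tss_decay_bp: float = 20_000.0,
    enrich_binary: float = 10.0,
    score_informativeness: float = 1.0,
    n_chromosomes: int = 10,
    tissue: str = "synthetic_tissue",
    trait_gene_fraction: float = 0.0,
    seed: int = 0,
) -> SyntheticCatalog:
    """Simulate a full multi-gene catalog for the end-to-end pipeline.

    Each gene gets an LD-blocked locus; every variant is independently causal
    with probability ``causal_fraction``.  Genes are spread round-robin over
    ``n_chromosomes`` chromosomes so leave-one-chromosome-out splits are
    meaningful.  If ``trait_gene_fraction > 0`` a complex-trait phenotype is
    simulated sharing the causal variants of that fraction of genes.
    """
    root = np.random.default_rng(seed)
    gene_rngs = root.spawn(n_genes)
    feature_rng, trait_rng = root.spawn(2)

    n_blocks = m_variants // block_size
    block_sizes = [block_size] * n_blocks
    pair_rows: list[dict] = []
    truth_parts: list[np.ndarray] = []
    tss_rows: list[dict] = []
    loci: dict[str, SyntheticLocus] = {}
    trait_genes: list[str] = []

    for g in range(n_genes):
        rng = gene_rngs[g]
        gene = f"GENE{g:04d}"
        chrom = f"chr{(g % n_chromosomes) + 1}"
        geno = simulate_ld_genotypes(n_individuals, block_sizes, rho, seed=rng)
        locus = SyntheticLocus(geno, block_sizes, rho)
        causal = np.flatnonzero(rng.uniform(size=m_variants) < causal_fraction)
        simulate_expression(locus, causal.size, beta_sd, noise_sd,
                            seed=rng, causal_indices=causal)
        loci[gene] = locus
        is_causal = np.zeros(m_variants, dtype=bool)
        is_causal[locus.causal_index_set] = True
        truth_parts.append(is_causal)
        tss_pos = 2_000_000 + g * 10_000
        dist = sample_tss_distances(is_causal, tss_decay_bp, seed=rng)
        tss_rows.append({"gene_id": gene, "chrom": chrom, "tss_pos": tss_pos, "strand": "+"})
        for j in range(m_variants):
            pair_rows.append({
                "chrom": chrom,
                "pos": int(tss_pos + dist[j]),
                "ref": "A", "alt": "G",
                "gene_id": gene,
                "tissue": tissue,
                "variant_id": f"{gene}_v{j:04d}",
                "tss_distance": dist[j],
            })
        if trait_gene_fraction > 0 and rng.uniform() < trait_gene_fraction:
            trait_genes.append(gene)

    pairs = pd.DataFrame(pair_rows)
    truth = np.concatenate(truth_parts)
    features = simulate_features(
        truth, pairs["tss_distance"].to_numpy(),
        enrich_binary=enrich_binary,
        score_informativeness=score_informativeness,
        seed=feature_rng,
    )
    catalog = SyntheticCatalog(
        pairs=pairs, features=features, truth=truth, loci=loci,
        tss=pd.DataFrame(tss_rows), trait_genes=trait_genes,
    )
    if trait_genes:
        catalog.trait_phenotype = _simulate_trait(catalog, trait_genes, trait_rng)
    return catalog


def _simulate_trait(
    catalog: SyntheticCatalog,
    trait_genes: list[str],
    rng: np.random.Generator,
    effect_sd: float = 0.4,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Trait phenotype sharing the causal variants of ``trait_genes``."""
    n = next(iter(catalog.loci.values())).n
    y = rng.normal(0.0, noise_sd, size=n)
    for gene in trait_genes:
        locus = catalog.loci[gene]
        if locus.causal_index_set.size == 0:
            continue
        G = locus.genotypes
        Z = (G - G.mean(axis=0)) / G.std(axis=0)
        b = rng.normal(0.0, effect_sd, size=locus.causal_index_set.size)
        y = y + Z[:, locus.causal_index_set] @ b
    return y


def simulate_tpm_matrix(
    n_tf: int = 10,
    tissues: list[str] | None = None,
    specific_fraction: float = 0.5,
    high_tpm: float = 50.0,
    low_tpm: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """TF-by-tissue TPM matrix; a fraction of TFs are sharply tissue-specific."""
    rng = np.random.default_rng(seed)
    if tissues is None:
        tissues = [f"tissue_{i}" for i in range(10)]
    rows = {}
    for t in range(n_tf):
        base = rng.uniform(0.5 * low_tpm, 1.5 * low_tpm, size=len(tissues))
        if rng.uniform() < specific_fraction:
            base[rng.integers(len(tissues))] = high_tpm * rng.uniform(0.8, 1.2)
        rows[f"TF{t:02d}"] = base
    return pd.DataFrame.from_dict(rows, orient="index", columns=tissues)


# ---------------------------------------------------------------------------
# writers (TSV / BED, plain text)
# ---------------------------------------------------------------------------

def write_catalog(catalog: SyntheticCatalog, outdir) -> dict[str, str]:
    """Write pairs, truth, features, TSS table and per-gene genotype TSVs."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    pairs = catalog.pairs.copy()
    pairs["truth"] = catalog.truth.astype(int)
    paths["pairs"] = os.path.join(outdir, "pairs.tsv")
    pairs.to_csv(paths["pairs"], sep="\t", index=False)
    paths["features"] = os.path.join(outdir, "features.tsv")
    catalog.features.to_csv(paths["features"], sep="\t", index=False)
    if catalog.tss is not None:
        paths["tss"] = os.path.join(outdir, "tss.tsv")
        catalog.tss.to_csv(paths["tss"], sep="\t", index=False)
    genodir = os.path.join(outdir, "genotypes")
    os.makedirs(genodir, exist_ok=True)
    for gene, locus in catalog.loci.items():
        df = pd.DataFrame(
            locus.genotypes,
            columns=[f"{gene}_v{j:04d}" for j in range(locus.m)],
        )
        df.to_csv(os.path.join(genodir, f"{gene}.tsv"), sep="\t", index=False)
        if locus.expression is not None:
            pd.DataFrame({"expression": locus.expression}).to_csv(
                os.path.join(genodir, f"{gene}.pheno.tsv"), sep="\t", index=False)
    paths["genotypes"] = genodir
    return paths
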