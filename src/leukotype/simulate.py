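"""Ground-truthed synthetic scRNA-seq data with known maturation structure.

The generator emulates the statistical features the downstream analysis relies
on: cells along a stem-to-mature maturation axis with a latent pseudotime
``t`` in [0, 1], a smooth log-linear expression gradient in a subset of genes,
a per-cell ribosomal-protein (RP) expression fraction that varies linearly
with ``t`` (decreasing for a negative slope, the inverse relation seen in
lymphoid maturation), negative-binomial (gamma-Poisson) UMI counts, leukemia
samples made of transcriptional subclusters with shifted pseudotime
distributions, planted copy-number blocks, and sparse tri-state per-cell
allele calls with one cluster-enriched variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


# populations along the maturation axis, thirds of [0, 1]
POPULATIONS = ("stem-like", "intermediate", "mature")

NO_COVERAGE, REF, ALT = 0, 1, 2


@dataclass
class AlleleCallMatrix:
    """Tri-state allele calls, variants x cells (0 = no coverage, 1 = ref, 2 = alt)."""

    codes: np.ndarray
    variant_ids: np.ndarray
    cell_barcodes: np.ndarray
    sample_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        if self.codes.shape != (len(self.variant_ids), len(self.cell_barcodes)):
            raise ValueError("codes shape does not match variant/cell annotations")
        if not np.isin(self.codes, [NO_COVERAGE, REF, ALT]).all():
            raise ValueError("codes must be in {0, 1, 2}")

    @property
    def n_variants(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.codes.shape[1]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    ``rp_slope`` is the change in expected RP fraction from pseudotime 0 to 1
    (negative for the inverse maturation/RP relation); ``nb_dispersion`` is the
    negative-binomial size parameter theta (var = mu + mu^2/theta).
    """

    n_genes: int = 2000
    n_rp_genes: int = 80
    n_mito_genes: int = 10
    n_cells_per_population: tuple = (667, 667, 666)
    trajectory_gene_fraction: float = 0.3
    base_rp_fraction: float = 0.35
    rp_slope: float = -0.15
    nb_dispersion: float = 5.0
    mean_library_size: float = 2500.0
    n_chromosomes: int = 8
    # (chromosome, (start_gene_idx, end_gene_idx), multiplier); None plants
    # one default 1.5x gain over ~11.5% of the genome (genes 260-490 at the
    # default 2000) in the last leukemia cluster, emulating the
    # cluster-specific chromosome-arm gains seen in ETV6-RUNX1-like samples
    cnv_blocks: tuple | None = None
    baseline_alt_prob: float = 0.10
    enriched_variant_odds: float = 8.0
    coverage_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cnv_blocks is None:
            lo = int(0.13 * self.n_genes)
            hi = min(lo + max(int(0.115 * self.n_genes), 1), self.n_genes)
            self.cnv_blocks = (("chr2", (lo, hi), 1.5),)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.n_rp_genes + self.n_mito_genes > self.n_genes:
            raise ConfigurationError("n_rp_genes + n_mito_genes exceeds n_genes")
        for name in ("trajectory_gene_fraction", "base_rp_fraction", "coverage_rate",
                     "baseline_alt_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.enriched_variant_odds <= 0:
            raise ConfigurationError("enriched_variant_odds must be positive")
        if len(self.n_cells_per_population) != len(POPULATIONS):
            raise ConfigurationError(
                f"n_cells_per_population needs {len(POPULATIONS)} entries")
        if any(n < 0 for n in self.n_cells_per_population):
            raise ConfigurationError("cell counts must be non-negative")
        for chrom, (lo, hi), mult in self.cnv_blocks:
            if mult <= 0:
                raise ConfigurationError("CNV multipliers must be positive")
            if not (0 <= lo < hi <= self.n_genes):
                raise ConfigurationError(f"CNV span ({lo}, {hi}) outside gene range")

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_population))


@dataclass
class SimulationTruth:
    """Ground truth for one simulated sample.

    ``cells`` has one row per generated cell: barcode (index), sample,
    pseudotime, population and cluster.
    """

    cells: pd.DataFrame
    planted_cnv: tuple = ()  # (cluster_label, (start, end), multiplier)
    enriched_variant_id: str | None = None
    enriched_cluster: str | None = None


@dataclass
class _GeneStructure:
    symbols: np.ndarray
    gene_ids: np.ndarray
    is_rp: np.ndarray
    is_mito: np.ndarray
    base_weight: np.ndarray       # relative mean among non-RP genes
    rp_weight: np.ndarray         # relative mean among RP genes
    slope: np.ndarray             # log-linear trajectory slope in t
    annotation: pd.DataFrame = field(repr=False, default=None)


def _gene_structure(config: SimulationConfig) -> _GeneStructure:
    """Deterministic gene layout shared by all samples drawn from one config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_rp, n_mito = config.n_rp_genes, config.n_mito_genes

    symbols = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    is_rp = np.zeros(n, bool)
    is_mito = np.zeros(n, bool)
    # scatter RP genes across the genome; mito genes at the tail
    if n_rp:
        rp_idx = np.unique(np.linspace(0, n - n_mito - 1, n_rp).astype(int))
        # linspace can collide for tiny n; pad deterministically
        extra = np.setdiff1d(np.arange(n - n_mito), rp_idx)[: n_rp - len(rp_idx)]
        rp_idx = np.sort(np.concatenate([rp_idx, extra]))
        is_rp[rp_idx] = True
        half = n_rp // 2
        symbols[rp_idx[:half]] = [f"RPS{i + 1}A" for i in range(half)]
        symbols[rp_idx[half:]] = [f"RPL{i + 1}A" for i in range(n_rp - half)]
    if n_mito:
        mito_idx = np.arange(n - n_mito, n)
        is_mito[mito_idx] = True
        symbols[mito_idx] = [f"MT-G{i + 1}" for i in range(n_mito)]
    gene_ids = np.array([f"SIMG{i:05d}" for i in range(n)], dtype=object)

    base_weight = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    rp_weight = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    # mitochondrial share of the non-RP mass ~4%
    nonrp = ~is_rp
    mito_mass = base_weight[nonrp & ~is_mito].sum() * 0.04 / max(n_mito, 1)
    base_weight[is_mito] = mito_mass

    slope = np.zeros(n)
    candidates = np.flatnonzero(nonrp & ~is_mito)
    n_traj = int(round(config.trajectory_gene_fraction * n))
    traj_idx = rng.choice(candidates, size=min(n_traj, len(candidates)), replace=False)
    slope[traj_idx] = rng.normal(0.0, 1.2, size=len(traj_idx))

    chrom_of = np.minimum(
        (np.arange(n) * config.n_chromosomes) // max(n, 1), config.n_chromosomes - 1)
    annotation = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "chromosome": [f"chr{c + 1}" for c in chrom_of],
            "start": [(i - np.searchsorted(chrom_of, c)) * 1000 + 1
                      for i, c in zip(range(n), chrom_of)],
            "is_rp": is_rp,
            "is_mito": is_mito,
        }
    )
    return _GeneStructure(symbols, gene_ids, is_rp, is_mito, base_weight, rp_weight,
                          slope, annotation)


def gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table (symbol, chromosome, start, flags) for a config."""
    config.validate()
    return _gene_structure(config).annotation.copy()


def _expected_means(genes: _GeneStructure, t: np.ndarray, config: SimulationConfig,
                    cnv_multiplier: np.ndarray | None = None) -> np.ndarray:
    """Expected counts (genes x cells) honouring the RP-fraction law.

    The RP share of each cell's library is set to base + slope * t (clipped),
    the remaining mass is distributed over non-RP genes by their log-linear
    trajectory weights, so the expected RP fraction follows the law exactly.
    """
    n_cells = len(t)
    frac = np.clip(config.base_rp_fraction + config.rp_slope * t, 1e-4, 1 - 1e-4)

    nonrp_w = genes.base_weight[:, None] * np.exp(
        np.outer(genes.slope, t - 0.5))
    nonrp_w[genes.is_rp] = 0.0
    nonrp_w /= nonrp_w.sum(axis=0, keepdims=True)

    rp_w = np.zeros((config.n_genes, n_cells))
    if genes.is_rp.any():
        w = genes.rp_weight[genes.is_rp]
        rp_w[genes.is_rp] = (w / w.sum())[:, None]

    mu = nonrp_w * (1 - frac) + rp_w * frac
    if cnv_multiplier is not None:
        mu = mu * cnv_multiplier
    return mu


def _sample_counts(mu: np.ndarray, library: np.ndarray, theta: float,
                   rng: np.random.Generator) -> sp.csr_matrix:
    """Gamma-Poisson (negative binomial) counts with shared dispersion theta."""
    lam = rng.gamma(shape=theta, scale=(mu * library[None, :]) / theta)
    counts = rng.poisson(lam)
    return sp.csr_matrix(counts)


def _libraries(n_cells: int, config: SimulationConfig,
               rng: np.random.Generator) -> np.ndarray:
    sigma = 0.15
    return rng.lognormal(np.log(config.mean_library_size) - sigma**2 / 2, sigma,
                         size=n_cells)


def _populations_of(t: np.ndarray) -> np.ndarray:
    idx = np.minimum((t * 3).astype(int), 2)
    return np.array([POPULATIONS[i] for i in idx], dtype=object)


def simulate_healthy_trajectory(
    config: SimulationConfig, sample_name: str = "healthy",
) -> tuple[CountMatrix, SimulationTruth]:
    """Healthy maturation spectrum: latent t uniform within each population third."""
    config.validate()
    genes = _gene_structure(config)
    rng = np.random.default_rng(config.seed + 1)

    parts = []
    for i, n_i in enumerate(config.n_cells_per_population):
        lo, hi = i / 3, (i + 1) / 3
        parts.append(rng.uniform(lo, hi, size=int(n_i)))
    t = np.concatenate(parts) if parts else np.empty(0)
    order = rng.permutation(len(t))
    t = t[order]

    library = _libraries(len(t), config, rng)
    mu = _expected_means(genes, t, config)
    counts = _sample_counts(mu, library, config.nb_dispersion, rng)

    barcodes = np.array([f"{sample_name}-{i:05d}" for i in range(len(t))], dtype=object)
    cm = CountMatrix(counts, genes.gene_ids, genes.symbols, barcodes,
                     np.full(len(t), sample_name, dtype=object))
    truth = SimulationTruth(
        cells=pd.DataFrame(
            {"sample": sample_name, "pseudotime": t,
             "population": _populations_of(t), "cluster": None},
            index=pd.Index(barcodes, name="barcode"),
        )
    )
    return cm, truth


def simulate_leukemia_sample(
    config: SimulationConfig,
    n_clusters: int = 2,
    pseudotime_shift: float = 0.3,
    cluster_proportions: tuple | None = None,
    base_center: float = 0.3,
    base_sd: float = 0.08,
    sample_name: str = "leukemia",
) -> tuple[CountMatrix, SimulationTruth]:
    """Leukemia sample with transcriptional subclusters.

    Cluster 1's latent pseudotime is Normal(base_center, base_sd) clipped to
    [0, 1]; cluster k is cluster 1 shifted by (k-1) * pseudotime_shift. CNV
    blocks from the config multiply gene means in the last cluster only.
    """
    config.validate()
    if n_clusters < 1:
        raise ConfigurationError("n_clusters must be >= 1")
    for k in range(n_clusters):
        center = base_center + k * pseudotime_shift
        if not 0.0 <= center <= 1.0:
            raise ConfigurationError(
                f"cluster {k + 1} pseudotime center {center:.2f} outside [0, 1]")
    if cluster_proportions is None:
        cluster_proportions = tuple(1.0 / n_clusters for _ in range(n_clusters))
    if len(cluster_proportions) != n_clusters:
        raise ConfigurationError("one proportion per cluster required")
    props = np.asarray(cluster_proportions, float)
    if props.min() <= 0 or abs(props.sum() - 1.0) > 1e-8:
        raise ConfigurationError("cluster proportions must be positive and sum to 1")

    genes = _gene_structure(config)
    rng = np.random.default_rng(config.seed + 2)
    n_cells = config.n_cells
    # largest-remainder allocation: exact counts for exact proportions
    edges = np.round(np.cumsum(props) * n_cells).astype(int)
    sizes = np.diff(np.concatenate([[0], edges]))

    cluster_labels = [f"C{k + 1}" for k in range(n_clusters)]
    t_parts, label_parts = [], []
    for k, n_k in enumerate(sizes):
        t_k = np.clip(rng.normal(base_center, base_sd, size=int(n_k))
                      + k * pseudotime_shift, 0.0, 1.0)
        t_parts.append(t_k)
        label_parts.append(np.full(int(n_k), cluster_labels[k], dtype=object))
    t = np.concatenate(t_parts)
    labels = np.concatenate(label_parts)
    order = rng.permutation(n_cells)
    t, labels = t[order], labels[order]

    cnv_gene_mult = np.ones(config.n_genes)
    for chrom, (lo, hi), mult in config.cnv_blocks:
        cnv_gene_mult[lo:hi] *= mult
    # planted in the last cluster only
    cnv_cluster = cluster_labels[-1]
    per_cell_mult = np.ones((config.n_genes, n_cells))
    in_cnv = labels == cnv_cluster
    if config.cnv_blocks and in_cnv.any():
        per_cell_mult[:, in_cnv] = cnv_gene_mult[:, None]

    library = _libraries(n_cells, config, rng)
    mu = _expected_means(genes, t, config, cnv_multiplier=per_cell_mult)
    counts = _sample_counts(mu, library, config.nb_dispersion, rng)

    barcodes = np.array([f"{sample_name}-{i:05d}" for i in range(n_cells)], dtype=object)
    cm = CountMatrix(counts, genes.gene_ids, genes.symbols, barcodes,
                     np.full(n_cells, sample_name, dtype=object))
    truth = SimulationTruth(
        cells=pd.DataFrame(
            {"sample": sample_name, "pseudotime": t,
             "population": _populations_of(t), "cluster": labels},
            index=pd.Index(barcodes, name="barcode"),
        ),
        planted_cnv=tuple((cnv_cluster, (lo, hi), mult)
                          for _, (lo, hi), mult in config.cnv_blocks),
    )
    return cm, truth


def simulate_allele_calls(
    truth: SimulationTruth, n_variants: int, config: SimulationConfig,
) -> AlleleCallMatrix:
    """Sparse tri-state allele calls with one cluster-enriched variant.

    Each cell x variant pair is covered with probability ``coverage_rate``;
    covered pairs are alt with ``baseline_alt_prob``, except variant 0 whose
    alt odds are multiplied by ``enriched_variant_odds`` in the last cluster.
    """
    config.validate()
    if n_variants < 1:
        raise ConfigurationError("n_variants must be >= 1")
    clusters = truth.cells["cluster"].to_numpy()
    if pd.isna(clusters).all():
        raise ConfigurationError("truth has no cluster labels")

    rng = np.random.default_rng(config.seed + 3)
    n_cells = len(truth.cells)
    covered = rng.random((n_variants, n_cells)) < config.coverage_rate

    p0 = config.baseline_alt_prob
    p_alt = np.full((n_variants, n_cells), p0)
    cluster_labels = sorted(set(str(c) for c in clusters if not pd.isna(c)))
    enriched_cluster = cluster_labels[-1]
    odds = config.enriched_variant_odds * p0 / (1 - p0)
    p_alt[0, clusters == enriched_cluster] = odds / (1 + odds)

    alt = rng.random((n_variants, n_cells)) < p_alt
    codes = np.where(covered, np.where(alt, ALT, REF), NO_COVERAGE).astype(np.int8)

    variant_ids = np.array([f"VAR{i:04d}" for i in range(n_variants)], dtype=object)
    acm = AlleleCallMatrix(codes, variant_ids,
                           truth.cells.index.to_numpy(),
                           truth.cells["sample"].to_numpy())
    truth.enriched_variant_id = str(variant_ids[0])
    truth.enriched_cluster = str(enriched_cluster)
    return acm
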