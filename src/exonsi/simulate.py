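"""Synthetic data generators for every stage of the pipeline.

The differential-exon generator draws gene-level counts from a
negative binomial and exon-level counts as a binomial share of the gene
count, so the splicing index (exon rpkm over gene rpkm) directly
estimates a known per-exon inclusion rate psi.  Planted exons shift psi
between the two conditions by a fixed amount, giving analytically known
ground truth for power and error-rate studies.  Companion generators
produce pure-null replicate tables (Gaussian attribution), multi-site
phosphoprotein fold-change tables with one planted responder, and
three-channel FRET image stacks built by inverting the sensitized-
emission correction formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CountTable
from .errors import ParameterError
from .fret import FretStack


@dataclass
class SimConfig:
    """Parameters of the planted differential exon-usage simulation.

    Defaults emulate a deep bulk RNA-seq triplicate-vs-triplicate design:
    three replicates per condition, negative-binomial gene counts with
    mild biological overdispersion, and ten percent of exons planted in
    each direction with an absolute inclusion-rate shift ``delta_psi``.
    """

    n_genes: int = 200
    exons_per_gene: float = 5.0
    n_reps_per_condition: int = 3
    frac_up: float = 0.1
    frac_down: float = 0.1
    delta_psi: float = 0.3
    nb_dispersion: float = 0.05
    mean_gene_expression: float = 5000.0
    gene_length: int = 2000
    exon_length_range: tuple[int, int] = (50, 500)
    psi_range: tuple[float, float] = (0.25, 0.6)
    condition_names: tuple[str, str] = ("control", "knockdown")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.n_reps_per_condition < 2:
            raise ParameterError("n_reps_per_condition must be >= 2")
        if not (0 <= self.frac_up and 0 <= self.frac_down
                and self.frac_up + self.frac_down <= 1):
            raise ParameterError("frac_up + frac_down must lie in [0, 1]")
        if not 0 < self.delta_psi < 1:
            raise ParameterError("delta_psi must lie in (0, 1)")
        if self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be >= 0")
        if self.mean_gene_expression <= 0:
            raise ParameterError("mean_gene_expression must be > 0")
        lo, hi = self.psi_range
        if not (0 < lo <= hi < 1) or hi + self.delta_psi >= 1:
            raise ParameterError(
                "psi_range must lie in (0, 1) with psi_range[1] + delta_psi < 1")


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam)


def make_differential_dataset(config: SimConfig
                              ) -> tuple[CountTable, CountTable, pd.DataFrame]:
    """Simulate exon and gene count tables with planted inclusion changes.

    Returns ``(exon_counts, gene_counts, truth)`` where ``truth`` records,
    per exon, the planted direction (``up`` = more included in control,
    ``down`` = more included in knockdown, ``null``) and the true
    inclusion rates in both conditions.  Exon counts are binomial draws
    conditional on the gene count with success probability
    ``psi * exon_length / gene_length``, so exon counts never exceed gene
    counts and the splicing index estimates psi directly.
    """
    rng = np.random.default_rng(config.seed)
    n_reps = config.n_reps_per_condition
    cond_a, cond_b = config.condition_names
    samples = [f"{cond_a}_{i + 1}" for i in range(n_reps)] + \
              [f"{cond_b}_{i + 1}" for i in range(n_reps)]
    conditions = {s: (cond_a if i < n_reps else cond_b)
                  for i, s in enumerate(samples)}

    # gene structure: at least one exon each; Poisson spread around the mean
    exons_per_gene = 1 + rng.poisson(max(config.exons_per_gene - 1.0, 0.0),
                                     size=config.n_genes)
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])
    n_exons = int(exons_per_gene.sum())
    exon_gene = np.repeat(gene_ids, exons_per_gene)
    exon_ids = np.array([f"E{i + 1:06d}" for i in range(n_exons)])
    lo_len, hi_len = config.exon_length_range
    exon_len = rng.integers(lo_len, hi_len + 1, size=n_exons)

    # gene counts per sample: negative binomial around the expression mean
    gene_counts = _nb_counts(rng, config.mean_gene_expression,
                             config.nb_dispersion,
                             size=(config.n_genes, 2 * n_reps))

    # planted inclusion shifts
    n_up = int(round(config.frac_up * n_exons))
    n_down = int(round(config.frac_down * n_exons))
    planted = rng.choice(n_exons, size=n_up + n_down, replace=False)
    direction = np.full(n_exons, "null", dtype=object)
    direction[planted[:n_up]] = "up"
    direction[planted[n_up:]] = "down"

    psi_lo, psi_hi = config.psi_range
    base_psi = rng.uniform(psi_lo, psi_hi, size=n_exons)
    psi_control = base_psi.copy()
    psi_knockdown = base_psi.copy()
    psi_control[direction == "up"] += config.delta_psi
    psi_knockdown[direction == "down"] += config.delta_psi

    # exon counts: binomial thinning of the parent gene count per sample
    gene_index = np.repeat(np.arange(config.n_genes), exons_per_gene)
    length_frac = exon_len / float(config.gene_length)
    exon_counts = np.empty((n_exons, 2 * n_reps), dtype=np.int64)
    for j in range(2 * n_reps):
        psi = psi_control if j < n_reps else psi_knockdown
        p = np.clip(psi * length_frac, 0.0, 1.0)
        exon_counts[:, j] = rng.binomial(gene_counts[gene_index, j], p)

    exon_table = CountTable(
        features=pd.DataFrame({"gene_id": exon_gene, "length": exon_len},
                              index=pd.Index(exon_ids, name="feature_id")),
        counts=pd.DataFrame(exon_counts, index=pd.Index(exon_ids, name="feature_id"),
                            columns=samples),
        conditions=conditions,
    )
    gene_table = CountTable(
        features=pd.DataFrame({"gene_id": gene_ids,
                               "length": np.full(config.n_genes, config.gene_length)},
                              index=pd.Index(gene_ids, name="feature_id")),
        counts=pd.DataFrame(gene_counts, index=pd.Index(gene_ids, name="feature_id"),
                            columns=samples),
        conditions=conditions,
    )
    truth = pd.DataFrame({
        "exon_id": exon_ids,
        "gene_id": exon_gene,
        "direction": direction,
        "psi_control": psi_control,
        "psi_knockdown": psi_knockdown,
    })
    return exon_table, gene_table, truth


def make_null_exon_dataset(n_exons: int, n_reps: int = 3, sigma: float = 0.05,
                           seed: int = 0,
                           mean_range: tuple[float, float] = (0.1, 1.0)
                           ) -> pd.DataFrame:
    """Gaussian-attribution null: no condition effect anywhere.

    Every exon's ``2 * n_reps`` values are drawn from one Gaussian with a
    shared per-exon mean (uniform over ``mean_range``) and spread
    ``sigma``.  Columns are named ``A_1..A_n, B_1..B_n`` for the two
    pseudo-conditions.
    """
    if n_exons < 1:
        raise ParameterError("n_exons must be >= 1")
    if n_reps < 2:
        raise ParameterError("n_reps must be >= 2")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    means = rng.uniform(*mean_range, size=n_exons)
    values = means[:, None] + rng.normal(0.0, sigma, size=(n_exons, 2 * n_reps))
    columns = [f"A_{i + 1}" for i in range(n_reps)] + \
              [f"B_{i + 1}" for i in range(n_reps)]
    index = pd.Index([f"E{i + 1:06d}" for i in range(n_exons)], name="exon_id")
    return pd.DataFrame(values, index=index, columns=columns)


def make_phospho_table(n_proteins: int, sites_per_protein: float = 3.0,
                       planted_protein_log2fc: float = 2.0, seed: int = 0,
                       background_sigma: float = 0.5,
                       planted_sigma: float = 0.2,
                       planted_sites: int | None = None) -> pd.DataFrame:
    """Simulate a phosphosite log2 fold-change table with one planted protein.

    Background site fold-changes are centred at zero; the first protein's
    sites share mean ``planted_protein_log2fc``.  The total number of rows
    is ``round(n_proteins * sites_per_protein)`` with every protein
    keeping at least one site.
    """
    if n_proteins < 1:
        raise ParameterError("n_proteins must be >= 1")
    if sites_per_protein < 1:
        raise ParameterError("sites_per_protein must be >= 1")
    if background_sigma < 0 or planted_sigma < 0:
        raise ParameterError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    total_sites = int(round(n_proteins * sites_per_protein))
    n_sites = np.ones(n_proteins, dtype=np.int64)
    extra = total_sites - n_proteins
    if extra > 0:
        n_sites += rng.multinomial(extra, np.full(n_proteins, 1.0 / n_proteins))
    if planted_sites is not None:
        if planted_sites < 1:
            raise ParameterError("planted_sites must be >= 1")
        n_sites[0] = planted_sites
    protein_ids = np.array([f"PROT{i + 1:05d}" for i in range(n_proteins)])
    rows_protein = np.repeat(protein_ids, n_sites)
    site_ids = np.concatenate([[f"S{k + 1}" for k in range(n)] for n in n_sites])
    log2fc = rng.normal(0.0, background_sigma, size=len(rows_protein))
    log2fc[:n_sites[0]] = rng.normal(planted_protein_log2fc, planted_sigma,
                                     size=n_sites[0])
    return pd.DataFrame({"protein_id": rows_protein, "site_id": site_ids,
                         "log2fc": log2fc})


@dataclass
class FretTruth:
    """Ground truth for a simulated FRET acquisition."""

    kD: float
    kA: float
    f_percent: np.ndarray = field(repr=False)


def make_fret_stack(shape: tuple[int, int] = (64, 64), kD: float = 0.1,
                    kA: float = 0.05, true_F_map: float | np.ndarray = 10.0,
                    donor_level: float = 1000.0, acceptor_level: float = 800.0,
                    noise_sigma: float = 0.0, seed: int = 0
                    ) -> tuple[FretStack, FretStack, FretStack, FretTruth]:
    """Simulate the measurement stack plus single-fluorophore control stacks.

    The transfer channel is synthesised by inverting the efficiency
    formula: ``IF = kD*ID + kA*IA + (F/100)*IA`` plus Gaussian read noise.
    Donor-only and acceptor-only control stacks carry a single fluorophore
    each and are suitable for calibrating kD and kA.
    """
    if kD < 0 or kA < 0:
        raise ParameterError("kD and kA must be >= 0")
    if donor_level < 0 or acceptor_level < 0:
        raise ParameterError("intensity levels must be >= 0")
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    f_map = np.broadcast_to(np.asarray(true_F_map, dtype=float), shape).copy()
    if not np.all(np.isfinite(f_map)):
        raise ParameterError("true_F_map must be finite")
    rng = np.random.default_rng(seed)

    def noisy(x: np.ndarray) -> np.ndarray:
        if noise_sigma == 0:
            return x.copy()
        return x + rng.normal(0.0, noise_sigma, size=x.shape)

    donor = noisy(np.full(shape, donor_level))
    acceptor = noisy(np.full(shape, acceptor_level))
    transfer = noisy(kD * donor + kA * acceptor + (f_map / 100.0) * acceptor)
    stack = FretStack(donor=donor, acceptor=acceptor, transfer=transfer)

    d_only_donor = noisy(np.full(shape, donor_level))
    donor_only = FretStack(donor=d_only_donor,
                           acceptor=noisy(np.zeros(shape)),
                           transfer=noisy(kD * d_only_donor))
    a_only_acceptor = noisy(np.full(shape, acceptor_level))
    acceptor_only = FretStack(donor=noisy(np.zeros(shape)),
                              acceptor=a_only_acceptor,
                              transfer=noisy(kA * a_only_acceptor))
    return stack, donor_only, acceptor_only, FretTruth(kD=kD, kA=kA,
                                                       f_percent=f_map)
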