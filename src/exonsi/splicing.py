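"""Splicing-index exon usage: SI, filters, fold changes and summaries.

The splicing index of an exon in a sample is the ratio of exon rpkm to
host-gene rpkm.  Library-size terms cancel, so SI reduces to
(exon_count / exon_length) / (gene_count / gene_length) and is invariant
to per-sample sequencing depth.  SI is computed per replicate, averaged
per condition, and summarised as log2(control / knockdown) with a small
pseudocount.  Three filters mirror common exon-usage practice: genes
with a single exon are removed, an exon needs more than ``min_reads``
reads in every sample of at least one condition, and a low-variability
screen keeps exons whose replicate SI Fano factor (variance over mean,
within a designated condition) is below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import CountTable
from .errors import DataError, ParameterError

DEFAULT_MIN_READS = 5
DEFAULT_FANO_MAX = 5e-4
DEFAULT_PSEUDOCOUNT = 1e-3


def compute_rpkm(counts, length, library_size):
    """Reads per kilobase of feature per million mapped reads.

    rpkm = counts * 1e9 / (length * library_size).  Accepts scalars or
    arrays (broadcast).
    """
    length = np.asarray(length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length <= 0):
        raise ParameterError("length must be > 0")
    if np.any(library_size <= 0):
        raise ParameterError("library_size must be > 0")
    return np.asarray(counts, dtype=float) * 1e9 / (length * library_size)


def compute_fano(values) -> float:
    """Fano factor of replicate values: sample variance (ddof=1) over mean.

    Returns NaN when the mean is zero or any value is undefined.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ParameterError("need >= 2 replicate values")
    if not np.all(np.isfinite(values)):
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(values.var(ddof=1) / mean)


def si_log2fc(mean_control, mean_knockdown,
              pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2 fold change of condition-mean SI, control over knockdown.

    Positive values mean the exon is more included in control, i.e.
    upregulated by the factor being knocked down.  The pseudocount keeps
    the ratio finite when one condition mean is zero.
    """
    mean_control = np.asarray(mean_control, dtype=float)
    mean_knockdown = np.asarray(mean_knockdown, dtype=float)
    if np.any(mean_control < 0) or np.any(mean_knockdown < 0):
        raise DataError("condition-mean SI must be >= 0")
    return np.log2(mean_control + pseudocount) - np.log2(mean_knockdown + pseudocount)


def ma_summary(log2fc, threshold: float = 0.5) -> tuple[float, float]:
    """Percent of values strictly above +threshold and strictly below -threshold."""
    values = np.asarray(log2fc, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ParameterError("need at least one finite log2FC value")
    above = 100.0 * np.mean(values > threshold)
    below = 100.0 * np.mean(values < -threshold)
    return float(above), float(below)


def set_overlap_percent(a, b) -> float:
    """Percent of set ``a`` contained in set ``b``: 100 * |a & b| / |a|."""
    a = set(a)
    if not a:
        raise ParameterError("first set must be non-empty")
    return 100.0 * len(a & set(b)) / len(a)


@dataclass
class SplicingTable:
    """Per-exon SI values plus condition summaries and filter flags.

    Attributes
    ----------
    si : pandas.DataFrame
        Exon-by-sample splicing index; NaN where the gene rpkm is zero.
    summary : pandas.DataFrame
        Per exon: ``gene_id``, condition-mean SI columns, ``log2fc``
        (control over knockdown), ``fano`` (within the designated
        condition), the filter flags ``pass_multi_exon``,
        ``pass_min_reads``, ``pass_fano`` and their conjunction ``kept``.
    """

    si: pd.DataFrame
    summary: pd.DataFrame
    conditions: dict[str, str]
    control: str
    knockdown: str

    def kept_ids(self) -> list[str]:
        return list(self.summary.index[self.summary["kept"]])


def filter_exons(exon_table: CountTable, min_reads: int = DEFAULT_MIN_READS
                 ) -> pd.DataFrame:
    """Structural and coverage filters on the exon count table.

    ``pass_multi_exon``: the parent gene contributes more than one exon.
    ``pass_min_reads``: there exists a condition in which every sample
    has strictly more than ``min_reads`` reads for the exon.
    """
    gene_ids = exon_table.features["gene_id"]
    exons_per_gene = gene_ids.map(gene_ids.value_counts())
    pass_multi = exons_per_gene > 1

    pass_reads = pd.Series(False, index=exon_table.counts.index)
    for cond in exon_table.condition_names:
        cols = exon_table.condition_samples(cond)
        pass_reads |= (exon_table.counts[cols] > min_reads).all(axis=1)
    return pd.DataFrame({"pass_multi_exon": pass_multi,
                         "pass_min_reads": pass_reads})


def compute_splicing_index(exon_table: CountTable, gene_table: CountTable,
                           control: str | None = None,
                           knockdown: str | None = None,
                           pseudocount: float = DEFAULT_PSEUDOCOUNT,
                           min_reads: int = DEFAULT_MIN_READS,
                           fano_max: float = DEFAULT_FANO_MAX,
                           fano_condition: str | None = None) -> SplicingTable:
    """Per-sample SI with condition means, log2FC, Fano factor and filters.

    ``control`` and ``knockdown`` default to the first and second
    condition labels in sample order.  The Fano screen is evaluated on
    the ``fano_condition`` replicates (default: the knockdown condition).
    """
    if exon_table.samples != gene_table.samples:
        raise DataError("exon and gene tables must share the same samples")
    unknown = set(exon_table.features["gene_id"]) - set(gene_table.counts.index)
    if unknown:
        raise DataError(f"exons reference unknown genes: {sorted(unknown)[:5]}")
    cond_names = exon_table.condition_names
    if control is None or knockdown is None:
        if len(cond_names) != 2:
            raise ParameterError("control/knockdown required unless exactly "
                                 "two conditions are labelled")
        control = control or cond_names[0]
        knockdown = knockdown or cond_names[1]
    for c in (control, knockdown):
        if c not in cond_names:
            raise ParameterError(f"unknown condition {c!r}")
    fano_condition = fano_condition or knockdown

    # library sizes cancel in the exon/gene rpkm ratio
    exon_density = exon_table.counts.div(exon_table.features["length"], axis=0)
    gene_density = gene_table.counts.div(gene_table.features["length"], axis=0)
    gene_ids = exon_table.features["gene_id"]
    parent_density = gene_density.loc[gene_ids].set_axis(exon_table.counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = exon_density / parent_density
    si = si.where(parent_density > 0)  # NA where gene rpkm is zero

    ctrl_cols = exon_table.condition_samples(control)
    kd_cols = exon_table.condition_samples(knockdown)
    mean_ctrl = si[ctrl_cols].mean(axis=1, skipna=False)
    mean_kd = si[kd_cols].mean(axis=1, skipna=False)
    log2fc = pd.Series(
        np.where(mean_ctrl.notna() & mean_kd.notna(),
                 si_log2fc(mean_ctrl.fillna(0), mean_kd.fillna(0), pseudocount),
                 np.nan),
        index=si.index)

    fano_cols = exon_table.condition_samples(fano_condition)
    fano_vals = si[fano_cols]
    mean_fano_cond = fano_vals.mean(axis=1, skipna=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        fano = fano_vals.var(axis=1, ddof=1, skipna=False) / mean_fano_cond
    fano = fano.where(mean_fano_cond > 0)

    flags = filter_exons(exon_table, min_reads=min_reads)
    pass_fano = fano.notna() & (fano < fano_max)
    summary = pd.DataFrame({
        "gene_id": gene_ids,
        f"mean_si_{control}": mean_ctrl,
        f"mean_si_{knockdown}": mean_kd,
        "log2fc": log2fc,
        "fano": fano,
        "pass_multi_exon": flags["pass_multi_exon"],
        "pass_min_reads": flags["pass_min_reads"],
        "pass_fano": pass_fano,
    })
    summary["kept"] = (summary["pass_multi_exon"] & summary["pass_min_reads"]
                       & summary["pass_fano"] & summary["log2fc"].notna())
    return SplicingTable(si=si, summary=summary,
                         conditions=dict(exon_table.conditions),
                         control=control, knockdown=knockdown)


def top_n_by_fc(table: SplicingTable, n: int = 100,
                direction: str = "up") -> list[str]:
    """Ids of the n largest (direction='up') or smallest ('down') log2FC
    among filter-passing exons; ties keep stable input order."""
    if direction not in ("up", "down"):
        raise ParameterError("direction must be 'up' or 'down'")
    scored = table.summary.loc[table.summary["kept"], "log2fc"]
    if n > len(scored):
        raise ParameterError(f"n={n} exceeds the {len(scored)} scored exons")
    sign = -1.0 if direction == "up" else 1.0
    order = np.argsort(sign * scored.to_numpy(), kind="stable")[:n]
    return list(scored.index[order])
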