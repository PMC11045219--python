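"""Phosphoprotein scoring: site-level fold changes summed per protein.

The Phospho Protein Score (PPS) of a protein is the plain sum of the
log2 fold changes of every phosphosite quantified on it.  Proteins whose
sites are consistently more phosphorylated under the active kinase score
high; those favoured by the dead-kinase control score low.  The PPS
ranking feeds preranked gene-set enrichment.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import DataError, FormatError
from .enrichment import RankedList

logger = logging.getLogger(__name__)

_COLUMNS = ["protein_id", "site_id", "log2fc"]


def read_phospho_table(path: str | Path) -> pd.DataFrame:
    """Read a phosphosite TSV (protein_id, site_id, log2fc).

    Rows with a missing fold change are dropped with a logged count,
    matching quantification dropout in real data; duplicate
    (protein, site) pairs are rejected.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"protein_id": str, "site_id": str})
    if list(df.columns[:3]) != _COLUMNS:
        raise FormatError(f"{path}: expected columns {_COLUMNS}")
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
    n_missing = int(df["log2fc"].isna().sum())
    if n_missing:
        logger.warning("%s: dropped %d sites without a quantified log2FC",
                       path, n_missing)
        df = df.dropna(subset=["log2fc"])
    validate_phospho_table(df)
    return df.reset_index(drop=True)


def validate_phospho_table(table: pd.DataFrame) -> None:
    dupes = table.duplicated(subset=["protein_id", "site_id"])
    if dupes.any():
        first = table.loc[dupes, ["protein_id", "site_id"]].iloc[0]
        raise DataError("duplicate (protein, site) pair "
                        f"{tuple(first)}; aggregate sites upstream")
    if not table["log2fc"].map(lambda x: x == x and abs(x) != float("inf")).all():
        raise DataError("log2fc values must be finite")


def compute_pps(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein PPS: sum of site log2FC, with the site count.

    Order-independent; proteins appear in first-occurrence order.
    """
    validate_phospho_table(table)
    grouped = table.groupby("protein_id", sort=False)["log2fc"]
    out = pd.DataFrame({"pps": grouped.sum(), "n_sites": grouped.size()})
    out.index.name = "protein_id"
    return out


def rank_by_pps(pps: pd.DataFrame) -> RankedList:
    """Ranked list by descending PPS; ties keep input order."""
    if len(pps) == 0:
        raise DataError("PPS table is empty")
    return RankedList(ids=pps.index.to_numpy(), scores=pps["pps"].to_numpy())


def write_pps(pps: pd.DataFrame, path: str | Path) -> None:
    pps.reset_index().to_csv(path, sep="\t", index=False)
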