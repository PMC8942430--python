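"""MSP (metagenomic species) abundance from marker genes.

The relative abundance of an MSP in a sample is the arithmetic mean of the
frequencies of its 100 designated marker genes, zeros included.  If fewer
than 10% of the markers are detected (strictly positive frequency) the MSP
is treated as absent and its abundance is set to exactly 0; a sample with
exactly 10 detected markers keeps its mean (the rule is strict).
Higher-rank taxon abundances are sums over member MSPs, and MSP richness is
the number of MSPs with strictly positive abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import MARKERS_PER_MSP, GeneCatalog
from .errors import CatalogError

DETECTION_FRACTION = 0.10
UNCLASSIFIED = "unclassified"


def msp_abundance(freqs: pd.DataFrame, catalog: GeneCatalog,
                  renormalize: bool = False) -> pd.DataFrame:
    """MSPs × samples relative-abundance matrix from marker-gene frequencies.

    Parameters
    ----------
    freqs
        Genes × samples frequency matrix; must contain all marker genes.
    renormalize
        If True, rescale each sample's MSP abundances to sum to 1 (samples
        where no MSP is detected are left at zero).  Default is the raw
        marker-mean scale.
    """
    rows = {}
    for msp in catalog.msp_ids:
        markers = catalog.markers_of(msp)
        if len(markers) != MARKERS_PER_MSP:
            raise CatalogError(f"{msp} has {len(markers)} markers, expected {MARKERS_PER_MSP}")
        missing = markers.difference(freqs.index)
        if len(missing):
            raise CatalogError(f"marker genes of {msp} absent from frequency matrix")
        block = freqs.loc[markers].to_numpy()
        mean = block.mean(axis=0)
        detected = (block > 0).sum(axis=0)
        mean[detected < DETECTION_FRACTION * MARKERS_PER_MSP] = 0.0
        rows[msp] = mean
    out = pd.DataFrame.from_dict(rows, orient="index", columns=freqs.columns)
    if renormalize:
        totals = out.sum(axis=0)
        out = out.div(totals.where(totals > 0, 1.0), axis=1)
    return out


def taxon_abundance(msp: pd.DataFrame, taxonomy: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Roll MSP abundances up to one taxonomic rank.

    `taxonomy` is a long table with columns ``msp_id, rank, name``.  MSPs
    with no entry at the requested rank are pooled under ``unclassified``.
    Taxa with no detected member MSP are simply absent from the output
    (no all-zero rows are fabricated).
    """
    if rank not in set(taxonomy["rank"]):
        raise ValueError(f"rank {rank!r} absent from taxonomy table")
    at_rank = taxonomy[taxonomy["rank"] == rank].set_index("msp_id")["name"]
    labels = at_rank.reindex(msp.index).fillna(UNCLASSIFIED)
    return msp.groupby(labels.to_numpy()).sum().rename_axis(rank)


def msp_richness(msp: pd.DataFrame) -> pd.Series:
    """Number of MSPs with strictly positive abundance per sample."""
    return (msp > 0).sum(axis=0).rename("msp_richness")
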