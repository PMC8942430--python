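"""Gene-level profiling: read attribution, depth downsizing, FPKM frequencies.

The stage mirrors how shotgun gene-count tables are built from catalog
mappings.  Reads that hit a single catalog gene are counted directly; reads
that tie between several genes ("shared reads") are split across their
candidates in proportion to the candidates' unique-read counts.  Count
columns are then rarefied ("downsized") to one common mapped-read depth so
that detection-based metrics (gene richness) are comparable across samples,
and finally length-normalized into an FPKM-style frequency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .errors import CatalogError, ReferenceError_, StageError

RAW = "raw"
DOWNSIZED = "downsized"

# Default depth used on real sequencing runs; tests and examples use small
# targets, the value only sets the config default.
DEFAULT_DOWNSIZE_TARGET = 14_000_000


class AlignmentRecords:
    """Per-sample best-hit alignment records in a compact array layout.

    Each read is a list of candidate gene ids with tied best alignment
    score: one candidate for uniquely mapped reads, two or more for shared
    reads.  Internally a sample is stored as a flat candidate array plus
    CSR-style read offsets.
    """

    def __init__(self, gene_index: pd.Index, per_sample: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.gene_index = pd.Index(gene_index)
        self._per_sample = per_sample

    @property
    def sample_ids(self) -> list[str]:
        return list(self._per_sample)

    def n_reads(self, sample_id: str) -> int:
        _, ptr = self._per_sample[sample_id]
        return len(ptr) - 1

    def arrays(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(flat candidate gene positions, read offsets) for one sample."""
        return self._per_sample[sample_id]

    def records(self, sample_id: str):
        """Yield (read_index, tuple of candidate gene ids)."""
        flat, ptr = self._per_sample[sample_id]
        ids = self.gene_index.to_numpy()
        for r in range(len(ptr) - 1):
            yield r, tuple(ids[flat[ptr[r]:ptr[r + 1]]])

    @classmethod
    def from_records(cls, records: dict[str, list[tuple[str, list[str]]]],
                     gene_index: pd.Index) -> "AlignmentRecords":
        gene_index = pd.Index(gene_index)
        per_sample = {}
        for sample, reads in records.items():
            flat_ids: list[str] = []
            ptr = [0]
            for _read_id, genes in reads:
                if not genes:
                    raise ReferenceError_("read with no candidate genes")
                flat_ids.extend(genes)
                ptr.append(len(flat_ids))
            pos = gene_index.get_indexer(flat_ids)
            if (pos < 0).any():
                bad = sorted({g for g, p in zip(flat_ids, pos) if p < 0})
                raise ReferenceError_(f"candidate genes absent from catalog: {bad[:5]}")
            per_sample[sample] = (pos.astype(np.int64), np.asarray(ptr, dtype=np.int64))
        return cls(gene_index, per_sample)

    # -- TSV round trip (sample_id, read_id, gene_ids ;-joined) --------

    def to_tsv(self, path) -> None:
        rows = []
        for sample in self.sample_ids:
            for read, genes in self.records(sample):
                rows.append((sample, f"r{read}", ";".join(genes)))
        pd.DataFrame(rows, columns=["sample_id", "read_id", "gene_ids"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, gene_index: pd.Index) -> "AlignmentRecords":
        table = pd.read_csv(path, sep="\t", dtype=str)
        records: dict[str, list[tuple[str, list[str]]]] = {}
        for sample, read_id, genes in table.itertuples(index=False):
            records.setdefault(sample, []).append((read_id, genes.split(";")))
        return cls.from_records(records, gene_index)


@dataclass
class CountMatrix:
    """Genes × samples count table with a processing-stage tag."""

    data: pd.DataFrame
    stage: str

    @property
    def mapped_reads(self) -> pd.Series:
        return self.data.sum(axis=0)

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(f"expected a {stage!r}-stage matrix, got {self.stage!r}")


def attribute_reads(alignments: AlignmentRecords, catalog: GeneCatalog) -> CountMatrix:
    """Turn alignment records into a raw gene count matrix.

    Pass 1 counts uniquely mapped reads per gene.  Pass 2 distributes each
    shared read across its candidates proportionally to the candidates'
    pass-1 unique counts; if every candidate has zero unique count the read
    is split uniformly, so read totals are always conserved.
    """
    pos_map = catalog.gene_ids.get_indexer(alignments.gene_index)
    if (pos_map < 0).any():
        bad = alignments.gene_index[pos_map < 0].tolist()
        raise ReferenceError_(f"alignment genes absent from catalog: {bad[:5]}")
    n_genes = catalog.n_genes
    samples = alignments.sample_ids
    if not samples or all(alignments.n_reads(s) == 0 for s in samples):
        raise ReferenceError_("no alignment records supplied")
    out = np.zeros((n_genes, len(samples)))
    for j, sample in enumerate(samples):
        flat_local, ptr = alignments.arrays(sample)
        flat = pos_map[flat_local]
        n_reads = len(ptr) - 1
        cand_per_read = np.diff(ptr)
        read_of = np.repeat(np.arange(n_reads), cand_per_read)
        unique_reads = cand_per_read == 1
        u = np.bincount(flat[unique_reads[read_of]], minlength=n_genes).astype(float)
        shared_sel = ~unique_reads[read_of]
        if shared_sel.any():
            flat_s = flat[shared_sel]
            read_s = read_of[shared_sel]
            w = u[flat_s]
            per_read_sum = np.bincount(read_s, weights=w, minlength=n_reads)
            zero_sum = per_read_sum[read_s] == 0
            w[zero_sum] = 1.0
            denom = np.where(per_read_sum > 0, per_read_sum, cand_per_read)[read_s]
            out[:, j] = u + np.bincount(flat_s, weights=w / denom, minlength=n_genes)
        else:
            out[:, j] = u
    frame = pd.DataFrame(out, index=catalog.gene_ids, columns=samples)
    return CountMatrix(frame, RAW)


def downsize(counts: CountMatrix, target: int, seed: int) -> tuple[CountMatrix, list[str]]:
    """Rarefy every sample to exactly `target` mapped reads.

    Fractional counts (from shared-read attribution) are stochastically
    rounded (floor plus a Bernoulli draw on the fractional part) and the
    integer vector is then subsampled without replacement.  Samples whose
    rounded total falls below the target are excluded and reported.
    """
    counts.require_stage(RAW)
    if target <= 0:
        raise ValueError("downsizing target must be positive")
    rng = np.random.default_rng(seed)
    kept: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for sample in counts.data.columns:
        v = counts.data[sample].to_numpy()
        base = np.floor(v)
        ints = (base + (rng.random(len(v)) < (v - base))).astype(np.int64)
        total = int(ints.sum())
        if total < target:
            excluded.append(sample)
            continue
        # "count" enumerates the reads individually: exact and fast at desk
        # scale; the marginals method avoids the O(total) allocation at
        # sequencing-run scale.
        method = "count" if total <= 5_000_000 else "marginals"
        kept[sample] = rng.multivariate_hypergeometric(ints, target, method=method)
    frame = pd.DataFrame(kept, index=counts.data.index, dtype=float)
    return CountMatrix(frame, DOWNSIZED), excluded


def normalize_frequencies(counts: CountMatrix, catalog: GeneCatalog,
                          per_reads: float = 1e6) -> pd.DataFrame:
    """FPKM-style frequencies: count / gene-length-in-kb / (mapped/per_reads).

    The per-reads constant (default one million, the FPKM convention) only
    rescales columns; every downstream statistic is rank- or ratio-based, so
    the exact constant is a reporting choice.
    """
    counts.require_stage(DOWNSIZED)
    lengths = catalog.lengths().reindex(counts.data.index)
    if lengths.isna().any():
        raise CatalogError("count matrix contains genes absent from the catalog")
    if (lengths <= 0).any():
        raise CatalogError("gene lengths must be strictly positive")
    kb = lengths.to_numpy()[:, None] / 1e3
    mapped = counts.mapped_reads.to_numpy()[None, :]
    scale = np.where(mapped > 0, mapped / per_reads, 1.0)
    return pd.DataFrame(counts.data.to_numpy() / kb / scale,
                        index=counts.data.index, columns=counts.data.columns)


def gene_richness(counts: CountMatrix) -> pd.Series:
    """Number of genes with strictly positive count per downsized sample."""
    counts.require_stage(DOWNSIZED)
    return (counts.data > 0).sum(axis=0).rename("gene_richness")
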