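"""Gene catalog: lengths, MSP membership, marker/core flags, annotations.

A metagenomic species (MSP) is a cluster of at least 100 co-abundant catalog
genes treated as one species-level unit.  Exactly 100 genes per MSP are
flagged as *markers* (the genes whose mean frequency defines the MSP's
abundance), and markers are always among the *core* genes (genes assumed
present in every strain of the MSP).  Genes may additionally carry KEGG
ortholog (KO) identifiers and CAZy family/subfamily labels such as
``GH43_8``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CatalogError

UNASSIGNED = ""  # msp_id value for genes outside any MSP

MARKERS_PER_MSP = 100
MIN_GENES_PER_MSP = 100


@dataclass
class GeneCatalog:
    """Table of catalog genes indexed by ``gene_id``.

    Parameters
    ----------
    frame
        DataFrame indexed by ``gene_id`` with columns ``length_bp`` (int),
        ``msp_id`` (str, :data:`UNASSIGNED` for genes outside any MSP),
        ``is_marker`` (bool), ``is_core`` (bool), ``ko_ids`` (frozenset of
        str) and ``cazy_families`` (frozenset of str).
    """

    frame: pd.DataFrame
    _msp_genes: dict[str, pd.Index] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        grouped = self.frame[self.frame["msp_id"] != UNASSIGNED].groupby("msp_id")
        self._msp_genes = {msp: idx.index for msp, idx in grouped}

    # -- structure -----------------------------------------------------

    def validate(self) -> None:
        f = self.frame
        required = {"length_bp", "msp_id", "is_marker", "is_core", "ko_ids", "cazy_families"}
        missing = required - set(f.columns)
        if missing:
            raise CatalogError(f"catalog missing columns: {sorted(missing)}")
        if (f["length_bp"] <= 0).any():
            raise CatalogError("gene lengths must be strictly positive")
        assigned = f[f["msp_id"] != UNASSIGNED]
        sizes = assigned.groupby("msp_id").size()
        if (sizes < MIN_GENES_PER_MSP).any():
            bad = sizes[sizes < MIN_GENES_PER_MSP].index.tolist()
            raise CatalogError(f"MSPs with fewer than {MIN_GENES_PER_MSP} genes: {bad}")
        markers = assigned.groupby("msp_id")["is_marker"].sum()
        if (markers != MARKERS_PER_MSP).any():
            bad = markers[markers != MARKERS_PER_MSP].index.tolist()
            raise CatalogError(f"MSPs without exactly {MARKERS_PER_MSP} marker genes: {bad}")
        if (f["is_marker"] & ~f["is_core"]).any():
            raise CatalogError("marker genes must be core genes")
        if (f.loc[f["msp_id"] == UNASSIGNED, "is_marker"]).any():
            raise CatalogError("unassigned genes cannot be markers")

    # -- queries -------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def msp_ids(self) -> list[str]:
        return sorted(self._msp_genes)

    @property
    def n_genes(self) -> int:
        return len(self.frame)

    def genes_of(self, msp_id: str) -> pd.Index:
        try:
            return self._msp_genes[msp_id]
        except KeyError:
            raise CatalogError(f"unknown MSP: {msp_id!r}") from None

    def markers_of(self, msp_id: str) -> pd.Index:
        genes = self.genes_of(msp_id)
        flags = self.frame.loc[genes, "is_marker"]
        return genes[flags.to_numpy()]

    def core_of(self, msp_id: str) -> pd.Index:
        genes = self.genes_of(msp_id)
        flags = self.frame.loc[genes, "is_core"]
        return genes[flags.to_numpy()]

    def lengths(self) -> pd.Series:
        return self.frame["length_bp"]

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["ko_ids"] = out["ko_ids"].map(lambda s: ";".join(sorted(s)))
        out["cazy_families"] = out["cazy_families"].map(lambda s: ";".join(sorted(s)))
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "GeneCatalog":
        f = pd.read_csv(
            path, sep="\t", index_col="gene_id",
            dtype={"msp_id": str}, keep_default_na=False,
        )
        f["length_bp"] = f["length_bp"].astype(int)
        f["is_marker"] = f["is_marker"].astype(str).str.lower().isin({"true", "1"})
        f["is_core"] = f["is_core"].astype(str).str.lower().isin({"true", "1"})
        for col in ("ko_ids", "cazy_families"):
            f[col] = f[col].map(lambda s: frozenset(s.split(";")) if s else frozenset())
        return cls(f)


def _as_numpy_positions(index: pd.Index, ids) -> np.ndarray:
    pos = index.get_indexer(ids)
    if (pos < 0).any():
        missing = [g for g, p in zip(list(ids), pos) if p < 0]
        raise CatalogError(f"identifiers absent from catalog: {missing[:5]}")
    return pos
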