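"""MSP-restricted functional carriage of KEGG modules, GMMs and CAZy families.

A sample's "fraction of gut microbiota carrying" a function is computed in
four steps, per detected MSP:

1. restrict the MSP's gene content to its genes detected in the sample,
   plus its core genes;
2. compute the fraction of the module's KO set covered by that restricted
   gene set (for a CAZy family: 1 if any gene carries the family, else 0);
3. the MSP carries the module if the fraction is strictly above 90%;
4. sum the abundances of all carrying MSPs.

Modules are flat item sets: KEGG-module alternative-path logic is not
modeled, matching how gut metabolic modules (GMMs) are defined as KO sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import GeneCatalog
from .errors import ReferenceError_

CARRIAGE_THRESHOLD = 0.90

KINDS = ("kegg", "gmm", "cazy")


@dataclass(frozen=True)
class ModuleDefinition:
    """A functional module: a KO set (kegg/gmm) or one CAZy family (cazy)."""

    module_id: str
    kind: str
    items: frozenset[str]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown module kind: {self.kind!r}")
        if not self.items:
            raise ValueError(f"module {self.module_id} has no items")
        if self.kind == "cazy" and len(self.items) != 1:
            raise ValueError("cazy modules carry exactly one family label")


def modules_from_tsv(path) -> list[ModuleDefinition]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ModuleDefinition(row.module_id, row.kind, frozenset(row.items.split(";")))
        for row in table.itertuples(index=False)
    ]


def modules_to_tsv(modules: list[ModuleDefinition], path) -> None:
    pd.DataFrame(
        [(m.module_id, m.kind, ";".join(sorted(m.items))) for m in modules],
        columns=["module_id", "kind", "items"],
    ).to_csv(path, sep="\t", index=False)


def restrict_gene_content(msp_id: str, detected_genes: set[str],
                          catalog: GeneCatalog) -> set[str]:
    """(MSP genes ∩ detected genes) ∪ MSP core genes."""
    genes = set(catalog.genes_of(msp_id))
    core = set(catalog.core_of(msp_id))
    return (genes & set(detected_genes)) | core


def module_completeness(gene_set: set[str], module: ModuleDefinition,
                        catalog: GeneCatalog) -> float:
    """Fraction of the module's items annotated on genes of `gene_set`."""
    if not gene_set:
        return 0.0
    column = "cazy_families" if module.kind == "cazy" else "ko_ids"
    present: set[str] = set()
    ann = catalog.frame[column]
    for gene in gene_set:
        present |= ann[gene]
    return len(module.items & present) / len(module.items)


def functional_profile(msp: pd.DataFrame, freqs: pd.DataFrame,
                       modules: list[ModuleDefinition], catalog: GeneCatalog,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Modules × samples carriage-abundance matrix plus MSP provenance.

    `msp` is the post-detection-rule MSP abundance matrix ("detected" means
    abundance > 0); `freqs` supplies per-sample gene detection.  Returns
    the abundance matrix and a long provenance table (sample_id, module_id,
    msp_id, completeness) listing each carrying MSP.
    """
    unknown = msp.index.difference(pd.Index(catalog.msp_ids))
    if len(unknown):
        raise ReferenceError_(f"MSPs absent from catalog: {unknown.tolist()[:5]}")
    out = pd.DataFrame(0.0, index=[m.module_id for m in modules], columns=msp.columns)
    provenance = []
    detected_by_sample = {s: set(freqs.index[freqs[s] > 0]) for s in msp.columns}
    for sample in msp.columns:
        detected_genes = detected_by_sample[sample]
        for msp_id in msp.index:
            abundance = msp.at[msp_id, sample]
            if abundance <= 0:
                continue
            restricted = restrict_gene_content(msp_id, detected_genes, catalog)
            for module in modules:
                frac = module_completeness(restricted, module, catalog)
                if frac > CARRIAGE_THRESHOLD:
                    out.at[module.module_id, sample] += abundance
                    provenance.append((sample, module.module_id, msp_id, frac))
    prov = pd.DataFrame(provenance,
                        columns=["sample_id", "module_id", "msp_id", "completeness"])
    return out, prov
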