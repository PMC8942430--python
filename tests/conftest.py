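"""Shared fixtures: small generated catalogs and hand-built ones.

Hand-built catalogs let tests control annotations exactly while still
satisfying the structural invariants (>=100 genes and exactly 100 markers
per MSP, markers core).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fibrascope as fs
from fibrascope.catalog import MARKERS_PER_MSP, UNASSIGNED, GeneCatalog


def manual_catalog(msp_specs: dict[str, list[tuple]], n_unassigned: int = 0,
                   marker_length: int = 1000) -> GeneCatalog:
    """Catalog with 100 anonymous markers per MSP plus explicit extra genes.

    `msp_specs` maps msp_id to a list of extra-gene tuples
    ``(gene_id, length_bp, is_core, ko_set, cazy_set)``.  Marker genes are
    named ``{msp}_mk{i:03d}``, carry no annotations and are all core.
    """
    rows = []
    for msp_id, extras in msp_specs.items():
        for i in range(MARKERS_PER_MSP):
            rows.append((f"{msp_id}_mk{i:03d}", marker_length, msp_id,
                         True, True, frozenset(), frozenset()))
        for gene_id, length, is_core, kos, cazys in extras:
            rows.append((gene_id, length, msp_id, False, is_core,
                         frozenset(kos), frozenset(cazys)))
    for i in range(n_unassigned):
        rows.append((f"bg_{i:03d}", 800, UNASSIGNED, False, False,
                     frozenset(), frozenset()))
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "length_bp", "msp_id", "is_marker", "is_core",
                 "ko_ids", "cazy_families"],
    ).set_index("gene_id")
    return GeneCatalog(frame)


@pytest.fixture(scope="session")
def catalog3() -> GeneCatalog:
    """Small generated catalog: 3 MSPs, some unassigned genes."""
    return fs.generate_catalog(n_genes=350, n_msp=3, seed=7)


@pytest.fixture(scope="session")
def cohort10(catalog3):
    """10-subject crossover cohort with no planted effects."""
    design, composition = fs.generate_cohort(catalog3, n_subjects=10, seed=11)
    return design, composition


def marker_frequency_frame(catalog: GeneCatalog, fill: float = 0.0) -> pd.DataFrame:
    """All-`fill` genes x 1-sample frequency frame over the catalog genes."""
    return pd.DataFrame({"s1": np.full(catalog.n_genes, fill)},
                        index=catalog.gene_ids)
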