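"""Synthetic study generator: catalog, crossover cohort, alignments, clinic.

Emulates the data shapes of a 2-arm, 2-period crossover dietary-fiber trial
profiled by shotgun metagenomics: a gene catalog organized into MSPs of at
least 100 genes with 100 marker genes each, latent log-normal MSP
compositions per subject × visit, read-to-gene alignment records (unique
and within-MSP shared reads), and a clinical table whose coupled variables
track planted microbiome effects.  Planted effects are multiplicative
shifts on a target MSP between the pre and post visits of one bread arm,
numerically calibrated so the post-vs-pre Cliff's delta approaches a
requested target in expectation.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import design as dsg
from .catalog import MARKERS_PER_MSP, MIN_GENES_PER_MSP, UNASSIGNED, GeneCatalog
from .errors import ReferenceError_, SizingError
from .gene_profiling import AlignmentRecords

# CAZy family/subfamily vocabulary used for annotation draws; includes the
# glycoside-hydrolase subfamilies relevant to fiber degradation.
DEFAULT_CAZY_VOCAB = (
    "GH2", "GH3", "GH5", "GH10", "GH13", "GH13_29", "GH26", "GH28",
    "GH29", "GH30_2", "GH31", "GH32", "GH36", "GH43_8", "GH43_28",
    "GH43_33", "GH51", "GH76", "GH78", "GH92", "GH95", "GH115",
    "GT2", "GT4", "GT17", "GT35",
    "PL1", "PL9", "PL11", "PL26",
    "CE1", "CE4", "CE8", "CE12",
)

TAXONOMY_RANKS = ("phylum", "family", "genus")


# ---------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------

def generate_catalog(n_genes: int, n_msp: int, *,
                     ko_density: float = 0.6, cazy_density: float = 0.15,
                     unassigned_fraction: float = 0.1,
                     core_fraction: float = 0.6,
                     n_ko_vocab: int = 300,
                     cazy_vocab: tuple[str, ...] = DEFAULT_CAZY_VOCAB,
                     seed: int = 0) -> GeneCatalog:
    """Random gene catalog with MSP structure and annotations.

    Each of the `n_msp` MSPs receives at least 100 genes, the first 100 of
    which are flagged as markers (markers are always core); a further
    `core_fraction` of the remaining member genes is core.  Roughly
    `unassigned_fraction` of genes stay outside any MSP, subject to the
    100-genes-per-MSP floor.  Gene lengths are log-normal (median ≈ 1.1 kb).
    """
    for name, d in (("ko_density", ko_density), ("cazy_density", cazy_density),
                    ("unassigned_fraction", unassigned_fraction),
                    ("core_fraction", core_fraction)):
        if not 0 <= d <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_msp < 1 or n_genes < MIN_GENES_PER_MSP * n_msp:
        raise SizingError(
            f"{n_genes} genes cannot host {n_msp} MSPs of >= {MIN_GENES_PER_MSP} genes")
    rng = np.random.default_rng(seed)
    n_unassigned = min(int(round(unassigned_fraction * n_genes)),
                       n_genes - MIN_GENES_PER_MSP * n_msp)
    n_assigned = n_genes - n_unassigned
    extra = rng.multinomial(n_assigned - MIN_GENES_PER_MSP * n_msp,
                            np.full(n_msp, 1 / n_msp))
    sizes = MIN_GENES_PER_MSP + extra

    gene_ids = [f"gene_{i:07d}" for i in range(n_genes)]
    lengths = np.clip(np.rint(rng.lognormal(7.0, 0.5, n_genes)), 150, 30_000).astype(int)
    msp_col = np.full(n_genes, UNASSIGNED, dtype=object)
    marker = np.zeros(n_genes, dtype=bool)
    core = np.zeros(n_genes, dtype=bool)
    start = 0
    for k, size in enumerate(sizes):
        sl = slice(start, start + size)
        msp_col[sl] = f"msp_{k + 1:04d}"
        marker[start:start + MARKERS_PER_MSP] = True
        core[start:start + MARKERS_PER_MSP] = True
        tail = np.arange(start + MARKERS_PER_MSP, start + size)
        core[tail[rng.random(len(tail)) < core_fraction]] = True
        start += size

    ko_vocab = np.array([f"K{i + 1:05d}" for i in range(n_ko_vocab)])
    ko_sets = [
        frozenset({rng.choice(ko_vocab)}) if rng.random() < ko_density else frozenset()
        for _ in range(n_genes)
    ]
    cazy_arr = np.asarray(cazy_vocab, dtype=object)
    cazy_sets = [
        frozenset({rng.choice(cazy_arr)}) if rng.random() < cazy_density else frozenset()
        for _ in range(n_genes)
    ]
    frame = pd.DataFrame(
        {
            "length_bp": lengths,
            "msp_id": msp_col,
            "is_marker": marker,
            "is_core": core,
            "ko_ids": ko_sets,
            "cazy_families": cazy_sets,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneCatalog(frame)


def generate_taxonomy(catalog: GeneCatalog, *, genera: int | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Random hierarchical taxonomy for the catalog's MSPs (long table).

    MSPs are grouped into genera, genera into families, families into
    phyla; a small fraction of MSPs is left unannotated at the genus rank
    to exercise the unclassified pooling path.
    """
    rng = np.random.default_rng(seed)
    msps = catalog.msp_ids
    n_gen = genera or max(1, len(msps) // 3)
    n_fam = max(1, n_gen // 2)
    n_phy = max(1, n_fam // 3)
    genus_of = rng.integers(0, n_gen, len(msps))
    family_of_genus = rng.integers(0, n_fam, n_gen)
    phylum_of_family = rng.integers(0, n_phy, n_fam)
    rows = []
    for msp, g in zip(msps, genus_of):
        f = family_of_genus[g]
        rows.append((msp, "phylum", f"phylum_{phylum_of_family[f] + 1:02d}"))
        rows.append((msp, "family", f"family_{f + 1:03d}"))
        if rng.random() > 0.05:  # leave some unclassified at genus rank
            rows.append((msp, "genus", f"genus_{g + 1:03d}"))
    return pd.DataFrame(rows, columns=["msp_id", "rank", "name"])


# ---------------------------------------------------------------------
# Cohort: design + latent compositions with planted effects
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative pre→post shift on one MSP in one bread arm.

    `cliffs_delta_target` is the Cliff's delta the post-vs-pre abundance
    distributions should approach in expectation; its sign gives the
    direction (positive = increase).
    """

    target_id: str
    cliffs_delta_target: float
    arm: str = dsg.MULTI_FIBER

    def __post_init__(self):
        if abs(self.cliffs_delta_target) > 1:
            raise ValueError("Cliff's delta target must lie in [-1, 1]")
        if self.arm not in dsg.BREADS:
            raise ReferenceError_(f"unknown arm: {self.arm!r}")

    @property
    def direction(self) -> str:
        return "increase" if self.cliffs_delta_target >= 0 else "decrease"


def calibrate_log_multiplier(delta_target: float, n_subjects: int,
                             sigma_subject: float, sigma_visit: float) -> float:
    """Log multiplier whose expected post-vs-pre Cliff's delta is the target.

    Under the log-normal latent model, a post-minus-pre log-abundance
    difference is N(L, 2σ_v²) for same-subject pairs and
    N(L, 2σ_s² + 2σ_v²) for cross-subject pairs; the expected Cliff's delta
    over the n × n pairs is the n-weighted mixture of the two normal
    orderings.  Solved for L by bisection.
    """
    target = float(np.clip(delta_target, -0.999, 0.999))
    if target == 0:
        return 0.0
    s_same = np.sqrt(2) * sigma_visit
    s_cross = np.sqrt(2 * (sigma_subject ** 2 + sigma_visit ** 2))
    w_same = 1.0 / n_subjects

    def expected_delta(log_m: float) -> float:
        same = 2 * norm.cdf(log_m / s_same) - 1
        cross = 2 * norm.cdf(log_m / s_cross) - 1
        return w_same * same + (1 - w_same) * cross

    hi = 60.0 * max(s_same, s_cross, 1.0)
    return float(brentq(lambda L: expected_delta(L) - target, -hi, hi))


def generate_cohort(catalog: GeneCatalog, n_subjects: int = 39,
                    effects: tuple[PlantedEffect, ...] = (), *,
                    sigma_msp: float = 1.5, sigma_subject: float = 0.8,
                    sigma_visit: float = 0.4,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crossover design plus latent MSP composition per sample.

    Sequence allocation is balanced (difference at most one subject).  Log
    abundances are mean (per MSP, spread `sigma_msp`) + subject effect
    (`sigma_subject`) + visit noise (`sigma_visit`); planted effects add a
    calibrated log shift at the post visit of their arm, and samples are
    renormalized to the simplex.
    """
    if n_subjects < 1:
        raise SizingError("need at least 1 subject")
    msps = catalog.msp_ids
    msp_pos = {m: i for i, m in enumerate(msps)}
    for eff in effects:
        if eff.target_id not in msp_pos:
            raise ReferenceError_(f"planted-effect target not in catalog: {eff.target_id!r}")
    rng = np.random.default_rng(seed)

    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    half = n_subjects // 2
    seqs = np.array([dsg.SEQ_MF_FIRST] * (n_subjects - half) + [dsg.SEQ_CTL_FIRST] * half)
    rng.shuffle(seqs)
    design = dsg.build_design(dict(zip(subjects, seqs)))

    n_msp = len(msps)
    mu = rng.normal(0.0, sigma_msp, n_msp)
    subj_eff = rng.normal(0.0, sigma_subject, (n_subjects, n_msp))
    log_a = np.empty((len(design), n_msp))
    subject_row = {s: i for i, s in enumerate(subjects)}
    for i, row in design.iterrows():
        log_a[i] = mu + subj_eff[subject_row[row["subject_id"]]] \
            + rng.normal(0.0, sigma_visit, n_msp)
        for eff in effects:
            if row["bread"] == eff.arm and row["phase"] == "post":
                log_a[i, msp_pos[eff.target_id]] += calibrate_log_multiplier(
                    eff.cliffs_delta_target, n_subjects, sigma_subject, sigma_visit)
    comp = np.exp(log_a)
    comp /= comp.sum(axis=1, keepdims=True)
    composition = pd.DataFrame(comp, index=pd.Index(design["sample_id"], name="sample_id"),
                               columns=msps)
    return design, composition


# ---------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------

def simulate_alignments(composition: pd.DataFrame, catalog: GeneCatalog,
                        depth: int, *, shared_fraction: float = 0.0,
                        background_weight: float = 0.02,
                        seed: int = 0) -> AlignmentRecords:
    """Read-to-gene alignment records for each sample of `composition`.

    Gene sampling probability is proportional to MSP abundance × gene
    length within the MSP, with `background_weight` of the read mass spread
    over non-MSP genes by length.  A `shared_fraction` of reads carries a
    second tied candidate drawn from the same MSP (paralog-like catalog
    redundancy); the rest map uniquely.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= shared_fraction < 1:
        raise ValueError("shared_fraction must lie in [0, 1)")
    if catalog.n_genes == 0:
        raise ValueError("empty catalog")
    rng = np.random.default_rng(seed)
    frame = catalog.frame
    lengths = frame["length_bp"].to_numpy(dtype=float)
    msp_series = frame["msp_id"]
    assigned = (msp_series != UNASSIGNED).to_numpy()

    # pools of interchangeable genes: one per MSP plus the unassigned pool
    pools: list[np.ndarray] = []
    pool_of = np.full(catalog.n_genes, -1, dtype=np.int64)
    rank_in_pool = np.zeros(catalog.n_genes, dtype=np.int64)
    codes, uniques = pd.factorize(msp_series.to_numpy())
    for code in range(len(uniques)):
        members = np.flatnonzero(codes == code)
        pools.append(members)
        pool_of[members] = code
        rank_in_pool[members] = np.arange(len(members))
    pool_sizes = np.array([len(p) for p in pools])

    missing = composition.columns.difference(pd.Index(catalog.msp_ids))
    if len(missing):
        raise ReferenceError_(f"composition MSPs absent from catalog: {missing.tolist()[:5]}")
    per_sample: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    msp_members = {m: catalog.gene_ids.get_indexer(catalog.genes_of(m))
                   for m in composition.columns}
    for sample_id, abunds in composition.iterrows():
        w = np.zeros(catalog.n_genes)
        for msp, a in abunds.items():
            members = msp_members[msp]
            lw = lengths[members]
            w[members] = a * lw / lw.sum()
        has_bg = (~assigned).any() and background_weight > 0
        w_total = w.sum()
        if w_total > 0:
            w *= (1 - background_weight if has_bg else 1.0) / w_total
        if has_bg:
            bg = lengths * ~assigned
            w += background_weight * bg / bg.sum()
        primary = rng.choice(catalog.n_genes, size=depth, p=w / w.sum())
        shared = rng.random(depth) < shared_fraction
        shared &= pool_sizes[pool_of[primary]] >= 2  # need a distinct paralog
        n_cand = 1 + shared.astype(np.int64)
        ptr = np.concatenate([[0], np.cumsum(n_cand)])
        flat = np.empty(ptr[-1], dtype=np.int64)
        flat[ptr[:-1]] = primary
        if shared.any():
            prim_s = primary[shared]
            sizes = pool_sizes[pool_of[prim_s]]
            offset = 1 + rng.integers(0, sizes - 1)
            ranks = (rank_in_pool[prim_s] + offset) % sizes
            secondary = np.array(
                [pools[pool_of[g]][r] for g, r in zip(prim_s, ranks)], dtype=np.int64)
            flat[ptr[:-1][shared] + 1] = secondary
        per_sample[sample_id] = (flat, ptr)
    return AlignmentRecords(catalog.gene_ids, per_sample)


# ---------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------

#: Baseline (mean, between-subject SD, within-visit SD) per fasting variable,
#: chosen near the cohort's published baseline distributions.
FASTING_BASELINES = {
    "glucose": (5.3, 0.40, 0.18),   # mM
    "insulin": (12.0, 4.0, 1.8),    # mIU/l
    "tc": (5.1, 0.80, 0.25),        # mM
    "hdl": (1.22, 0.25, 0.06),      # mM
    "tg": (1.3, 0.45, 0.18),        # mM
}

#: Postprandial curve parameters: (peak time min, amplitude mean, amplitude SD)
POSTPRANDIAL_SHAPES = {
    "glucose_pp": ("glucose", 45.0, 2.0, 0.5),
    "insulin_pp": ("insulin", 60.0, 75.0, 20.0),
}


@dataclass(frozen=True)
class ClinicalCoupling:
    """Linear coupling of a planted MSP's delta to a clinical variable.

    The subject's standardized multi-fiber pre→post abundance delta of
    `target_id` is multiplied by `slope` and added to the variable at the
    post-MF visit: directly (in the variable's units) for fasting
    variables, or to the postprandial amplitude for `glucose_pp` /
    `insulin_pp` (which moves peaks and both AUCs monotonically).
    """

    target_id: str
    variable: str
    slope: float


def simulate_clinical(design: pd.DataFrame, composition: pd.DataFrame,
                      couplings: tuple[ClinicalCoupling, ...] = (), *,
                      grid: tuple[int, ...] | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Long clinical table (subject, visit, variable, time_min, value).

    Fasting variables are subject-level baselines plus visit noise,
    truncated at zero.  Postprandial glucose/insulin curves are unimodal
    gamma-like shapes starting exactly at the fasting value at t = 0 on the
    fixed minute grid.  Couplings add a linear term in the subject's
    standardized planted-feature delta at the post-MF visit.
    """
    from .clinical import POSTPRANDIAL_GRID
    grid_arr = np.asarray(grid if grid is not None else POSTPRANDIAL_GRID, dtype=float)
    rng = np.random.default_rng(seed)
    subjects = design["subject_id"].unique()

    # standardized per-subject MF-arm deltas of coupled targets
    z_delta: dict[str, pd.Series] = {}
    for c in couplings:
        if c.target_id not in composition.columns:
            raise ReferenceError_(f"coupling target not in composition: {c.target_id!r}")
        pairs = dsg.paired_samples(design, dsg.MULTI_FIBER)
        delta = (composition.loc[pairs["post"], c.target_id].to_numpy()
                 - composition.loc[pairs["pre"], c.target_id].to_numpy())
        # scaled but NOT centered: a systematic planted shift moves the
        # coupled variable's group mean, not just its correlation
        z = delta / (delta.std() or 1.0)
        z_delta[c.target_id] = pd.Series(z, index=pairs.index)

    subj_base = {
        var: dict(zip(subjects, rng.normal(mean, sd_subj, len(subjects))))
        for var, (mean, sd_subj, _sd_visit) in FASTING_BASELINES.items()
    }
    rows = []
    for _, srow in design.iterrows():
        subject, visit = srow["subject_id"], srow["visit"]
        is_post_mf = srow["bread"] == dsg.MULTI_FIBER and srow["phase"] == "post"
        fasting = {}
        for var, (_mean, _sd_s, sd_v) in FASTING_BASELINES.items():
            val = subj_base[var][subject] + rng.normal(0.0, sd_v)
            for c in couplings:
                if c.variable == var and is_post_mf:
                    val += c.slope * z_delta[c.target_id].get(subject, 0.0)
            fasting[var] = max(val, 0.0)
            rows.append((subject, visit, var, np.nan, fasting[var]))
        for series_var, (base_var, t_peak, amp_mean, amp_sd) in POSTPRANDIAL_SHAPES.items():
            amp = rng.normal(amp_mean, amp_sd)
            for c in couplings:
                if c.variable == series_var and is_post_mf:
                    amp += c.slope * z_delta[c.target_id].get(subject, 0.0)
            amp = max(amp, 0.05 * amp_mean)
            shape = (grid_arr / t_peak) * np.exp(1 - grid_arr / t_peak)
            values = np.maximum(fasting[base_var] + amp * shape, 0.0)
            for t, v in zip(grid_arr, values):
                rows.append((subject, visit, series_var, t, v))
    return pd.DataFrame(rows, columns=["subject_id", "visit", "variable",
                                       "time_min", "value"])
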