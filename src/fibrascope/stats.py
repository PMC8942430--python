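"""Ecology metrics and the differential/correlation statistical layer.

The differential screen follows the rank-based longitudinal workflow used
for crossover microbiome trials: per feature, an ANOVA-type statistic (ATS)
for the bread × visit interaction in the fully within-subject 2×2 layout;
Benjamini–Hochberg correction across features with significance at
q ≤ 0.1; then, per bread arm, a Wilcoxon signed-rank test (post vs pre,
paired) and a Cliff's delta effect size (post vs pre distributions,
unpaired) graded negligible/small/medium/large at |d| thresholds
0.147 / 0.33 / 0.474.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import design as dsg
from .errors import DegenerateDataError, ReferenceError_

GRADE_THRESHOLDS = (0.147, 0.33, 0.474)
GRADES = ("negligible", "small", "medium", "large")

CELLS = ("mf_pre", "mf_post", "ctl_pre", "ctl_post")


# ---------------------------------------------------------------------
# Ecology
# ---------------------------------------------------------------------

def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share a feature index")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise DegenerateDataError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def intra_individual_dissimilarity(features: pd.DataFrame,
                                   design: pd.DataFrame) -> pd.DataFrame:
    """Per-subject pre→post Bray–Curtis shift for each bread arm.

    Returns a subjects × {multi_fiber, control} table; subjects missing a
    visit in an arm get NaN there.
    """
    out = {}
    for bread in dsg.BREADS:
        pairs = dsg.paired_samples(design, bread)
        vals = {}
        for subject, row in pairs.iterrows():
            if row["pre"] in features.columns and row["post"] in features.columns:
                vals[subject] = bray_curtis(features[row["pre"]], features[row["post"]])
        out[bread] = pd.Series(vals)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------
# Rank-based longitudinal interaction test (ANOVA-type statistic)
# ---------------------------------------------------------------------

def ats_interaction(cells: np.ndarray) -> float:
    """ATS p-value for the treatment × time interaction of a within-subject
    2×2 layout.

    `cells` is an (n_subjects, 4) array ordered (mf_pre, mf_post, ctl_pre,
    ctl_post).  All 4n observations are mid-ranked jointly; the ANOVA-type
    statistic for the interaction contrast is referred to an F(f̂, ∞)
    distribution with box-type degrees of freedom f̂ (here f̂ = 1 since the
    contrast has one row).  Invariant under strictly monotone transforms.
    """
    cells = np.asarray(cells, dtype=float)
    cells = cells[~np.isnan(cells).any(axis=1)]
    n, d = cells.shape
    if d != 4:
        raise ValueError("expected 4 cells per subject (bread × phase)")
    if n < 2:
        raise DegenerateDataError("need at least 2 complete subjects")
    if np.ptp(cells) == 0:
        raise DegenerateDataError("all values tied; interaction test undefined")
    big_n = n * d
    ranks = sps.rankdata(cells.reshape(-1)).reshape(n, d)
    y = ranks / big_n
    ybar = y.mean(axis=0)
    contrast = np.array([1.0, -1.0, -1.0, 1.0])
    t_mat = np.outer(contrast, contrast) / (contrast @ contrast)
    v = np.cov(y.T, ddof=1)
    tv = t_mat @ v
    trace_tv = np.trace(tv)
    if trace_tv <= 0:
        raise DegenerateDataError("degenerate rank covariance; interaction test undefined")
    f_stat = n * (ybar @ t_mat @ ybar) / trace_tv
    f_hat = trace_tv ** 2 / np.trace(tv @ tv)
    # F(f, inf) equals chi-square(f)/f
    return float(sps.chi2.sf(f_hat * f_stat, f_hat))


def rank_interaction_test(feature: pd.Series, design: pd.DataFrame) -> float:
    """ATS interaction p-value for one feature indexed by sample_id."""
    cells = subject_cell_table(feature, design)
    return ats_interaction(cells.to_numpy())


def subject_cell_table(feature: pd.Series, design: pd.DataFrame) -> pd.DataFrame:
    """Pivot a sample-indexed feature into subjects × (mf_pre … ctl_post).

    Subjects with any missing cell are dropped.
    """
    merged = design.assign(
        value=feature.reindex(design["sample_id"]).to_numpy(),
        cell=design["bread"].map({dsg.MULTI_FIBER: "mf", dsg.CONTROL: "ctl"})
        + "_" + design["phase"],
    )
    wide = merged.pivot(index="subject_id", columns="cell", values="value")
    missing = [c for c in CELLS if c not in wide.columns]
    if missing:
        raise ReferenceError_(f"design lacks cells: {missing}")
    return wide[list(CELLS)].dropna()


# ---------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------

EXACT_LIMIT = 25


def wilcoxon_signed_rank(pre, post, zero_method: str = "wilcox") -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact null distribution (enumeration of all 2ⁿ sign assignments over the
    mid-ranked |differences|, ties included) for up to 25 nonzero pairs;
    tie-corrected normal approximation with continuity correction above.
    Zero differences are dropped by default (`wilcox`); with `pratt` they
    enter the ranking but not the statistic.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = post - pre
    d = d[~np.isnan(d)]
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if zero_method == "wilcox":
        d = d[d != 0]
        if len(d) < 2:
            raise DegenerateDataError("need at least 2 nonzero paired differences")
        ranks = sps.rankdata(np.abs(d))
    else:
        if (d == 0).all() or len(d) < 2:
            raise DegenerateDataError("need at least 2 nonzero paired differences")
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]
    w_plus = ranks[d > 0].sum()
    if len(d) <= EXACT_LIMIT:
        return _exact_signed_rank_p(ranks, w_plus)
    return _normal_signed_rank_p(ranks, w_plus)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by dynamic programming over sign assignments.

    Mid-ranks are doubled to integers; the distribution of 2·W⁺ over all 2ⁿ
    equally likely sign vectors is built by convolution, which is identical
    to exhaustive enumeration.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        nxt = 0.5 * pmf
        nxt[r:] += 0.5 * pmf[: total + 1 - r]
        pmf = nxt
    w2 = int(round(2 * w_plus))
    cdf = pmf[: w2 + 1].sum()
    sf = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _normal_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48  # tie correction
    if var <= 0:
        raise DegenerateDataError("zero variance in signed-rank statistic")
    z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------

def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) − P(x < y) over all cross pairs, in [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("Cliff's delta needs two non-empty samples")
    diff = x[:, None] - y[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


@dataclass(frozen=True)
class EffectSizeGrade:
    delta: float
    grade: str


def grade_effect_size(delta: float) -> EffectSizeGrade:
    """Magnitude grade of a Cliff's delta at |d| = 0.147 / 0.33 / 0.474."""
    if not np.isfinite(delta) or abs(delta) > 1:
        raise ValueError("Cliff's delta must lie in [-1, 1]")
    a = abs(delta)
    for threshold, grade in zip(GRADE_THRESHOLDS, GRADES):
        if a < threshold:
            return EffectSizeGrade(delta, grade)
    return EffectSizeGrade(delta, GRADES[-1])


# ---------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------

def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------
# Differential screen
# ---------------------------------------------------------------------

Q_THRESHOLD = 0.1


def differential_screen(features: pd.DataFrame, design: pd.DataFrame,
                        q_threshold: float = Q_THRESHOLD,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-based longitudinal screen over a features × samples matrix.

    Per feature: ATS interaction p-value; BH across analyzable features;
    significance flag at q ≤ `q_threshold`; per-bread paired Wilcoxon and
    Cliff's delta (post vs pre) with magnitude grades.  Features whose
    interaction test is degenerate (all tied, or too few complete subjects)
    are excluded from the BH family and reported separately.
    """
    missing = [s for s in design["sample_id"] if s not in features.columns]
    if missing:
        raise ReferenceError_(f"design samples absent from feature matrix: {missing[:5]}")
    rows, excluded = [], []
    for feature_id, values in features.iterrows():
        try:
            cells = subject_cell_table(values, design)
            p_int = ats_interaction(cells.to_numpy())
        except DegenerateDataError as err:
            excluded.append((feature_id, str(err)))
            continue
        row = {"feature_id": feature_id, "p_interaction": p_int}
        for bread, tag in ((dsg.MULTI_FIBER, "mf"), (dsg.CONTROL, "ctl")):
            pre = cells[f"{tag}_pre"].to_numpy()
            post = cells[f"{tag}_post"].to_numpy()
            try:
                row[f"p_wilcoxon_{tag}"] = wilcoxon_signed_rank(pre, post)
            except DegenerateDataError:
                row[f"p_wilcoxon_{tag}"] = np.nan
            delta = cliffs_delta(post, pre)
            row[f"cliffs_delta_{tag}"] = delta
            row[f"grade_{tag}"] = grade_effect_size(delta).grade
        rows.append(row)
    results = pd.DataFrame(rows)
    if len(results):
        results["q_value"] = benjamini_hochberg(results["p_interaction"].to_numpy())
        results["significant"] = results["q_value"] <= q_threshold
        order = ["feature_id", "p_interaction", "q_value", "significant",
                 "p_wilcoxon_mf", "cliffs_delta_mf", "grade_mf",
                 "p_wilcoxon_ctl", "cliffs_delta_ctl", "grade_ctl"]
        results = results[order]
    report = pd.DataFrame(excluded, columns=["feature_id", "reason"])
    return results, report


# ---------------------------------------------------------------------
# Delta–delta correlations
# ---------------------------------------------------------------------

def delta_delta_spearman(feature_deltas: pd.DataFrame,
                         clinical_deltas: pd.DataFrame,
                         q_threshold: float = Q_THRESHOLD,
                         p_threshold: float = 0.05) -> pd.DataFrame:
    """Spearman correlations between per-subject feature and clinical deltas.

    Both inputs are subjects × variables tables of post − pre changes in the
    multi-fiber arm.  Returns a long table (feature, variable, n, rho, p, q,
    significant_q, significant_p); pairs with fewer than 3 complete subjects
    are skipped and reported with NaN rho.
    """
    subjects = feature_deltas.index.intersection(clinical_deltas.index)
    rows = []
    for feat in feature_deltas.columns:
        for var in clinical_deltas.columns:
            x = feature_deltas.loc[subjects, feat]
            y = clinical_deltas.loc[subjects, var]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                rows.append((feat, var, int(ok.sum()), np.nan, np.nan))
                continue
            rho, p = sps.spearmanr(x[ok], y[ok])
            rows.append((feat, var, int(ok.sum()), float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["feature", "variable", "n", "rho", "p"])
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["significant_q"] = out["q"] <= q_threshold
    out["significant_p"] = out["p"] <= p_threshold
    return out
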