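"""Per-feature differential abundance between cytotypes.

Works on the filtered, log2-normalized feature table:

* strain-specific tetraploid-vs-diploid log2 fold changes and equal-variance
  t-tests, plus a "general" contrast (the ploidy main effect of an additive
  strain + ploidy linear model), each with Benjamini-Hochberg FDR control;
* a per-feature balanced two-way ANOVA (strain, ploidy, interaction) with BH
  correction per term and the 7-region Venn partition of significant flags;
* qualitative ploidy-specific calls on the raw (unfiltered) table: present in
  every replicate of one cytotype and absent in every replicate of the other;
* UpSet-style intersection counts of differentially abundant features (DAFs)
  across strains.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable

GENERAL = "general"


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _log2_group_matrices(
    table: FeatureTable, strain: str
) -> tuple[np.ndarray, np.ndarray]:
    meta = table.non_qc().sample_meta
    data = table.non_qc().data
    sel4 = (meta["strain"] == strain) & (meta["ploidy"] == "4n")
    sel2 = (meta["strain"] == strain) & (meta["ploidy"] == "2n")
    x4 = data.loc[sel4.to_numpy()].to_numpy(dtype=float)
    x2 = data.loc[sel2.to_numpy()].to_numpy(dtype=float)
    if x4.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError(
            f"strain {strain!r} needs >= 2 replicates in both cytotypes"
        )
    return x4, x2


def _additive_design(meta: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Treatment-coded design matrix for abundance ~ strain + ploidy.

    Returns (X, index of the ploidy column)."""
    strains = sorted(meta["strain"].unique())
    n = len(meta)
    X = np.ones((n, len(strains) + 1))
    for k, s in enumerate(strains[1:], start=1):
        X[:, k] = (meta["strain"] == s).to_numpy(float)
    X[:, -1] = (meta["ploidy"] == "4n").to_numpy(float)
    return X, X.shape[1] - 1


def log2_fold_changes(table: FeatureTable, strain: str = "ALL") -> pd.Series:
    """Per-feature log2 fold change, 4n minus 2n, on an already-log2 table.

    For a single strain this is the difference of cytotype means; for
    ``strain="ALL"`` it is the ploidy main effect of the additive
    strain + ploidy linear model fitted across all strains.
    """
    bio = table.non_qc()
    if strain != "ALL":
        x4, x2 = _log2_group_matrices(table, strain)
        lfc = x4.mean(axis=0) - x2.mean(axis=0)
    else:
        for s in bio.strains():
            _log2_group_matrices(table, s)  # validates replication
        X, ploidy_col = _additive_design(bio.sample_meta)
        beta = np.linalg.lstsq(X, bio.data.to_numpy(dtype=float), rcond=None)[0]
        lfc = beta[ploidy_col]
    return pd.Series(lfc, index=table.feature_ids, name=f"lfc_{strain}")


@dataclass
class ContrastResult:
    """Per-feature statistics for each diploid-tetraploid contrast.

    ``tables`` maps contrast name (strain label or ``"general"``) to a
    DataFrame indexed by feature with columns ``lfc``, ``p``, ``p_adj``,
    ``direction`` and ``is_daf``.
    """

    tables: dict
    alpha: float = 0.05

    def daf_sets(self, direction: str | None = None) -> dict:
        """Per-strain sets of significant features, optionally one direction."""
        out = {}
        for name, tab in self.tables.items():
            if name == GENERAL:
                continue
            sel = tab["is_daf"]
            if direction is not None:
                sel = sel & (tab["direction"] == direction)
            out[name] = set(tab.index[sel])
        return out


def _ttest_groups(x4: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised equal-variance two-sided t-test per feature (columns)."""
    n4, n2 = x4.shape[0], x2.shape[0]
    df = n4 + n2 - 2
    diff = x4.mean(axis=0) - x2.mean(axis=0)
    ss = x4.var(axis=0, ddof=1) * (n4 - 1) + x2.var(axis=0, ddof=1) * (n2 - 1)
    pooled = ss / df
    se = np.sqrt(pooled * (1.0 / n4 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s); p set to 1",
            RuntimeWarning,
            stacklevel=3,
        )
        p[zero_var] = 1.0
    return diff, p


def contrast_tests(table: FeatureTable, alpha: float = 0.05) -> ContrastResult:
    """Strain-specific and general diploid-tetraploid contrasts with BH FDR.

    Input must be the filtered, log2-normalized table.  Each strain contrast
    is an equal-variance two-sided t-test of the cytotype means; the general
    contrast tests the ploidy coefficient of the additive strain + ploidy
    model.  BH adjustment is applied within each contrast; a DAF is a feature
    with adjusted p below ``alpha``.
    """
    bio = table.non_qc()
    tables = {}
    for strain in bio.strains():
        x4, x2 = _log2_group_matrices(table, strain)
        lfc, p = _ttest_groups(x4, x2)
        tables[strain] = _contrast_frame(table.feature_ids, lfc, p, alpha)

    X, ploidy_col = _additive_design(bio.sample_meta)
    Y = bio.data.to_numpy(dtype=float)
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[ploidy_col, ploidy_col])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[ploidy_col] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    zero = se == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s) in general contrast; p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        p[zero] = 1.0
    tables[GENERAL] = _contrast_frame(table.feature_ids, beta[ploidy_col], p, alpha)
    return ContrastResult(tables=tables, alpha=alpha)


def _contrast_frame(feature_ids, lfc, p, alpha) -> pd.DataFrame:
    p_adj = _bh(p)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(lfc >= 0, "up_in_4n", "down_in_4n"),
            "is_daf": p_adj < alpha,
        },
        index=pd.Index(feature_ids, name="feature"),
    )


@dataclass
class AnovaClassification:
    """Per-feature two-way ANOVA significance flags and the Venn partition."""

    flags: pd.DataFrame  # boolean columns: strain, ploidy, interaction
    p_values: pd.DataFrame
    p_adjusted: pd.DataFrame
    alpha: float = 0.05

    def venn_partition(self) -> dict:
        """Counts of the 7 non-empty flag combinations plus 'none'."""
        f = self.flags
        regions = {
            "strain_only": f.strain & ~f.ploidy & ~f.interaction,
            "ploidy_only": ~f.strain & f.ploidy & ~f.interaction,
            "interaction_only": ~f.strain & ~f.ploidy & f.interaction,
            "strain_ploidy": f.strain & f.ploidy & ~f.interaction,
            "strain_interaction": f.strain & ~f.ploidy & f.interaction,
            "ploidy_interaction": ~f.strain & f.ploidy & f.interaction,
            "all_three": f.strain & f.ploidy & f.interaction,
            "none": ~f.strain & ~f.ploidy & ~f.interaction,
        }
        return {k: int(v.sum()) for k, v in regions.items()}


def two_way_anova_classify(
    table: FeatureTable, alpha: float = 0.05
) -> AnovaClassification:
    """Balanced two-way fixed-effects ANOVA per feature with BH per term.

    Requires a complete, balanced strain x ploidy design (the sums of squares
    of types I/II/III coincide there); unbalanced input is refused.
    """
    bio = table.non_qc()
    meta = bio.sample_meta
    counts = meta.groupby(["strain", "ploidy"], observed=True).size()
    strains = sorted(meta["strain"].unique())
    if len(counts) != 2 * len(strains) or counts.nunique() != 1:
        raise ValueError("two-way ANOVA requires a complete balanced design")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("two-way ANOVA requires replication within cells")

    Y = bio.data.to_numpy(dtype=float)
    n, n_feat = Y.shape
    a, b = len(strains), 2
    grand = Y.mean(axis=0)

    strain_codes = pd.Categorical(meta["strain"], categories=strains).codes
    ploidy_codes = (meta["ploidy"] == "4n").to_numpy(int)

    strain_means = np.vstack([Y[strain_codes == i].mean(axis=0) for i in range(a)])
    ploidy_means = np.vstack([Y[ploidy_codes == j].mean(axis=0) for j in range(b)])
    cell_means = np.vstack(
        [
            Y[(strain_codes == i) & (ploidy_codes == j)].mean(axis=0)
            for i in range(a)
            for j in range(b)
        ]
    )

    ss_strain = b * r * ((strain_means - grand) ** 2).sum(axis=0)
    ss_ploidy = a * r * ((ploidy_means - grand) ** 2).sum(axis=0)
    ss_cells = r * ((cell_means - grand) ** 2).sum(axis=0)
    ss_inter = ss_cells - ss_strain - ss_ploidy
    ss_total = ((Y - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_cells

    df_strain, df_ploidy = a - 1, b - 1
    df_inter = df_strain * df_ploidy
    df_err = n - a * b
    ms_err = ss_err / df_err

    def term_p(ss, df):
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ss / df) / ms_err
        p = stats.f.sf(f, df, df_err)
        p[~np.isfinite(f)] = 1.0  # constant features
        return p

    pvals = pd.DataFrame(
        {
            "strain": term_p(ss_strain, df_strain),
            "ploidy": term_p(ss_ploidy, df_ploidy),
            "interaction": term_p(np.maximum(ss_inter, 0.0), df_inter),
        },
        index=pd.Index(table.feature_ids, name="feature"),
    )
    padj = pvals.apply(lambda col: _bh(col.to_numpy()), axis=0)
    flags = padj < alpha
    return AnovaClassification(flags=flags, p_values=pvals, p_adjusted=padj, alpha=alpha)


PLOIDY_SPECIFIC_LABELS = (
    "absent_in_2n_present_in_4n",
    "present_in_2n_absent_in_4n",
    "not_specific",
)


def ploidy_specific_features(
    unfiltered_table: FeatureTable, strain: str, absence_threshold: float = 0.0
) -> pd.Series:
    """Qualitative presence/absence calls for one strain on raw abundances.

    A feature is ploidy-specific when it is at or below ``absence_threshold``
    (or missing) in every replicate of one cytotype and strictly above the
    threshold in every replicate of the other.
    """
    meta = unfiltered_table.non_qc().sample_meta
    data = unfiltered_table.non_qc().data
    out = {}
    vals = {}
    for ploidy in ("2n", "4n"):
        sel = (meta["strain"] == strain) & (meta["ploidy"] == ploidy)
        vals[ploidy] = np.nan_to_num(
            data.loc[sel.to_numpy()].to_numpy(dtype=float), nan=0.0
        )
    absent2 = np.all(vals["2n"] <= absence_threshold, axis=0)
    absent4 = np.all(vals["4n"] <= absence_threshold, axis=0)
    present2 = np.all(vals["2n"] > absence_threshold, axis=0)
    present4 = np.all(vals["4n"] > absence_threshold, axis=0)
    labels = np.full(unfiltered_table.n_features, "not_specific", dtype=object)
    labels[absent2 & present4] = "absent_in_2n_present_in_4n"
    labels[present2 & absent4] = "present_in_2n_absent_in_4n"
    return pd.Series(
        labels, index=pd.Index(unfiltered_table.feature_ids, name="feature"),
        name=f"ploidy_specific_{strain}",
    )


@dataclass
class UpSetCounts:
    """Exact-region intersection counts of per-strain DAF sets."""

    regions: dict  # frozenset of strains -> count of features in exactly that subset
    per_strain_totals: dict
    universe_size: int

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def daf_intersections(daf_sets: dict) -> UpSetCounts:
    """UpSet-style exact intersection counts over per-strain DAF sets.

    ``daf_sets`` maps strain label to the set of significant feature ids;
    every non-empty strain subset gets the count of features significant in
    exactly that subset (2^k - 1 cells for k strains).
    """
    strains = sorted(daf_sets)
    if not strains:
        raise ValueError("need at least one strain")
    if all(isinstance(v, pd.Series) for v in daf_sets.values()):
        # boolean masks over a shared feature universe
        first = daf_sets[strains[0]].index
        for s in strains[1:]:
            if not daf_sets[s].index.equals(first):
                raise ValueError("per-strain DAF masks must share one feature universe")
        daf_sets = {s: set(v.index[v.astype(bool)]) for s, v in daf_sets.items()}
    universe = set().union(*daf_sets.values())
    regions = {}
    for size in range(1, len(strains) + 1):
        for combo in itertools.combinations(strains, size):
            inside = set.intersection(*(daf_sets[s] for s in combo)) if combo else set()
            outside = set().union(*(daf_sets[s] for s in strains if s not in combo), set())
            regions[frozenset(combo)] = len(inside - outside)
    totals = {s: len(daf_sets[s]) for s in strains}
    return UpSetCounts(
        regions=regions, per_strain_totals=totals, universe_size=len(universe)
    )
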