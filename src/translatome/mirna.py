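"""Systematic microRNA-family target-repression analysis.

For every seed-collapsed microRNA family, the expression (or fold change)
distribution of its conserved targets is compared against all other
analysed genes by a KS shift test; repression is a target/non-target mean
ratio below 1 with a significant shift.  Cross-tissue comparisons ask in
which tissue that repression is stronger, and a rank-binned regression
relates a gene's total conserved-site load to its fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .drivers import FoldChangeTable
from .errors import EmptyInputError, InvalidConfigError
from .setshift import set_shift_test

__all__ = [
    "MiRNAFamily",
    "RepressionRecord",
    "RepressionFraction",
    "SiteDensityFit",
    "collapse_families",
    "target_repression_within_tissue",
    "cross_tissue_target_shift",
    "stronger_repression_fraction",
    "site_density_vs_fc",
]

ALPHA = 0.05


@dataclass
class MiRNAFamily:
    """A seed family: members share the seed, hence one merged target set."""

    family_id: str
    targets: frozenset
    site_count: dict  # gene_id -> conserved sites (max over members)

    def __post_init__(self):
        if not self.targets:
            raise InvalidConfigError(f"family {self.family_id} has no targets")


def collapse_families(target_table: pd.DataFrame, family_map: dict | None = None) -> list:
    """Merge per-microRNA target rows into seed families.

    ``target_table`` columns: (mirna_id | family_id), gene_id, n_sites.
    ``family_map`` maps member microRNA ids to family ids; unmapped ids
    become singleton families.  Targets are the union over members and the
    per-gene site count is the maximum over members.  Output is sorted by
    family id.
    """
    if target_table.empty:
        raise EmptyInputError("target table is empty")
    table = target_table.copy()
    id_col = "mirna_id" if "mirna_id" in table.columns else "family_id"
    fam_map = family_map or {}
    table["family"] = [fam_map.get(m, m) for m in table[id_col]]
    families = []
    for fam, sub in table.groupby("family", sort=True):
        sites = sub.groupby("gene_id")["n_sites"].max()
        families.append(
            MiRNAFamily(str(fam), frozenset(sites.index), sites.astype(int).to_dict())
        )
    return families


@dataclass
class RepressionRecord:
    """One family's target-vs-non-target comparison on one metric.

    ``ratio`` is the linear-scale mean of targets over the mean of
    non-targets (expression mode) or the ratio of mean linear fold changes
    (contrast mode); repression means ratio < 1 with ks_p < 0.05.
    """

    family_id: str
    metric: str            # "RPF" | "RNA" | "Eff"
    label: str             # tissue or contrast
    ratio: float
    ks_p: float
    ks_d: float
    n_targets: int
    direction: str
    repressed: bool
    skipped: bool = False


def _skipped(family: MiRNAFamily, metric: str, label: str, n: int) -> RepressionRecord:
    return RepressionRecord(family.family_id, metric, label, np.nan, np.nan, np.nan,
                            n, "none", False, skipped=True)


def target_repression_within_tissue(
    expr_values: pd.Series,
    family: MiRNAFamily,
    metric: str = "RNA",
    label: str = "",
    min_targets: int = 10,
) -> RepressionRecord:
    """Compare a family's targets against all other genes on one expression
    metric within one tissue.

    ``expr_values`` are linear-scale values (e.g. RPKM or Eff) indexed by
    gene_id.  The KS test runs on log2(x + 1); the mean ratio is computed
    on the linear scale.  Families with fewer than ``min_targets`` detected
    targets are returned as skipped records.
    """
    values = expr_values.dropna()
    targets = [g for g in values.index if g in family.targets]
    if len(targets) < min_targets:
        return _skipped(family, metric, label, len(targets))
    log_vals = np.log2(values + 1.0)
    ks = set_shift_test(log_vals, targets, background_mode="all_other_genes")
    nontarget_mean = float(values[~values.index.isin(family.targets)].mean())
    ratio = float(values[targets].mean()) / nontarget_mean
    return RepressionRecord(
        family.family_id, metric, label, ratio, ks.p_value, ks.d_statistic,
        len(targets), ks.shift_direction,
        repressed=(ratio < 1.0 and ks.p_value < ALPHA),
    )


def cross_tissue_target_shift(
    fc: FoldChangeTable,
    family: MiRNAFamily,
    metric: str = "Eff",
    min_targets: int = 10,
) -> RepressionRecord:
    """Compare targets' and non-targets' cross-tissue fold changes by KS.

    The effect size is the ratio of mean linear fold changes
    (mean 2^log2FC over targets / mean over non-targets); a ratio < 1 with
    a significant KS p means the family's targets are relatively more
    repressed in the contrast's numerator tissue.
    """
    col = {"RNA": "log2_rna_fc", "RPF": "log2_rpf_fc", "Eff": "log2_eff_fc"}.get(metric)
    if col is None:
        raise InvalidConfigError(f"unknown metric {metric!r}")
    vals = fc.data[col].dropna()
    targets = [g for g in vals.index if g in family.targets]
    if len(targets) < min_targets:
        return _skipped(family, metric, fc.contrast, len(targets))
    ks = set_shift_test(vals, targets, background_mode="all_other_genes")
    linear = np.power(2.0, vals)
    ratio = float(linear[targets].mean()) / float(
        linear[~linear.index.isin(family.targets)].mean()
    )
    return RepressionRecord(
        family.family_id, metric, fc.contrast, ratio, ks.p_value, ks.d_statistic,
        len(targets), ks.shift_direction,
        repressed=(ratio < 1.0 and ks.p_value < ALPHA),
    )


@dataclass
class RepressionFraction:
    """Fraction of eligible families more repressed in the first tissue."""

    metric: str
    fraction: float
    n_stronger_first: int
    n_eligible: int
    n_ties: int
    empty: bool = False


def stronger_repression_fraction(
    records_a,
    records_b,
    eligible_families=None,
    metric: str | None = None,
) -> RepressionFraction:
    """Fraction of families whose target/non-target ratio is smaller (more
    repressed) in tissue A than in tissue B.

    ``records_a`` / ``records_b`` are matched per-family RepressionRecords
    for the two tissues on one metric.  When ``eligible_families`` is None,
    a family is eligible if its targets are significantly repressed in at
    least one of the two tissues; ties (equal ratios) are excluded from the
    denominator and reported.
    """
    by_a = {r.family_id: r for r in records_a if not r.skipped}
    by_b = {r.family_id: r for r in records_b if not r.skipped}
    shared = sorted(set(by_a) & set(by_b))
    if eligible_families is None:
        eligible = [f for f in shared if by_a[f].repressed or by_b[f].repressed]
    else:
        eligible = [f for f in shared if f in set(eligible_families)]
    metric = metric or (records_a[0].metric if records_a else "")
    stronger = ties = 0
    for f in eligible:
        ra, rb = by_a[f].ratio, by_b[f].ratio
        if ra < rb:
            stronger += 1
        elif ra == rb:
            ties += 1
    denom = len(eligible) - ties
    if denom == 0:
        return RepressionFraction(metric, np.nan, 0, len(eligible), ties, empty=True)
    return RepressionFraction(metric, stronger / denom, stronger, len(eligible), ties)


@dataclass
class SiteDensityFit:
    """Rank-binned OLS of mean conserved-site load on fold-change bins."""

    bin_mean_sites: np.ndarray
    bin_mean_fc: np.ndarray
    slope: float
    intercept: float
    slope_p: float
    n_bins: int


def site_density_vs_fc(fc_values: pd.Series, site_totals: pd.Series, n_bins: int = 20) -> SiteDensityFit:
    """Regress per-bin mean conserved microRNA site counts on fold-change rank bins.

    Genes are ordered by fold change (ties broken by gene_id), split into
    ``n_bins`` equal-size rank bins, and the per-bin mean of total
    conserved sites is fit on the bin index by ordinary least squares.
    """
    if n_bins < 2:
        raise InvalidConfigError("n_bins must be >= 2")
    shared = fc_values.dropna().index.intersection(site_totals.index)
    if len(shared) < n_bins:
        raise EmptyInputError("need at least n_bins genes with both FC and site totals")
    frame = pd.DataFrame(
        {"fc": fc_values.loc[shared], "sites": site_totals.loc[shared]}
    )
    order = sorted(frame.index, key=lambda g: (frame.at[g, "fc"], g))
    sites_sorted = frame.loc[order, "sites"].to_numpy(dtype=float)
    fc_sorted = frame.loc[order, "fc"].to_numpy(dtype=float)
    bins_sites = [b.mean() for b in np.array_split(sites_sorted, n_bins)]
    bins_fc = [b.mean() for b in np.array_split(fc_sorted, n_bins)]
    x = np.arange(n_bins, dtype=float)
    y = np.asarray(bins_sites)
    if np.allclose(y, y[0]):
        return SiteDensityFit(y, np.asarray(bins_fc), 0.0, float(y[0]), 1.0, n_bins)
    fit = scipy.stats.linregress(x, y)
    return SiteDensityFit(
        y, np.asarray(bins_fc), float(fit.slope), float(fit.intercept),
        float(fit.pvalue), n_bins
    )
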