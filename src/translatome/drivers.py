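"""Fold-change decomposition and driver classification.

A gene's footprint (RPF) fold change between two conditions decomposes in
log2 space into an mRNA-abundance component and a translational-efficiency
component: log2 FC_RPF = log2 FC_RNA + log2 FC_Eff.  Genes whose RPF
change passes a fold threshold are partitioned into translation-driven,
synergistic, and RNA-driven classes (up and down) by the relative
magnitude of the two components, and the global share of the translational
component is estimated by the ratio-of-correlations method with the
replicate-to-replicate correlation as the noise ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import EmptyInputError, InvalidConfigError, PairingError
from .quantify import ExpressionSet

__all__ = [
    "FoldChangeTable",
    "DriverAssignment",
    "ContributionEstimate",
    "GROUP_CATEGORY",
    "fold_changes",
    "fold_changes_by_replicate",
    "classify_drivers",
    "summarize_driver_classes",
    "contribution_ratio",
    "delta_eff_ranking",
]

#: group number -> (category, direction); groups 1-3 are up, 4-6 down
GROUP_CATEGORY = {
    1: ("translation_driven", "up"),
    2: ("synergistic", "up"),
    3: ("rna_driven", "up"),
    4: ("translation_driven", "down"),
    5: ("synergistic", "down"),
    6: ("rna_driven", "down"),
}
CATEGORY_GROUPS = {"translation_driven": (1, 4), "synergistic": (2, 5), "rna_driven": (3, 6)}


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold changes for RNA, RPF and Eff in one contrast.

    ``data`` is indexed by gene_id with columns log2_rna_fc, log2_rpf_fc,
    log2_eff_fc; the Eff column is computed as RPF − RNA so the additive
    identity holds to machine precision.
    """

    data: pd.DataFrame
    contrast: str
    pseudocount: float

    def __post_init__(self):
        required = {"log2_rna_fc", "log2_rpf_fc", "log2_eff_fc"}
        if not required.issubset(self.data.columns):
            raise InvalidConfigError(f"fold-change table missing columns {required - set(self.data.columns)}")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        self.data.rename_axis("gene_id").to_csv(path, sep="\t")


def _condition_means(rpkm_es: ExpressionSet, assay: str, condition: str) -> pd.Series:
    cols = rpkm_es.columns_for(assay=assay, condition=condition)
    if not cols:
        raise PairingError(f"no {assay} samples for condition {condition!r}")
    return rpkm_es.data[cols].mean(axis=1)


def fold_changes(
    rpkm_es: ExpressionSet,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.5,
    contrast: str | None = None,
    center: str = "median",
) -> FoldChangeTable:
    """log2 fold changes b/a from replicate-averaged RPKM with a pseudocount.

    Per assay, FC = (mean_b + pseudocount) / (mean_a + pseudocount) in
    log2; the Eff fold change is RPF − RNA in log2 space, which guarantees
    the decomposition identity exactly.

    ``center="median"`` (default) subtracts the per-assay median log2 FC
    across genes before forming the Eff component.  Depth-normalized RPKM
    is compositional: when strongly regulated genes move a lot of library
    mass between conditions, every gene's ratio shifts by the same constant.
    Median-centering removes that shared offset under the usual assumption
    that most genes are unregulated (the same rationale as median-of-ratios
    library-size estimation).  ``center="none"`` gives the raw ratios.
    """
    if rpkm_es.unit != "RPKM":
        raise InvalidConfigError("fold_changes expects an RPKM ExpressionSet")
    if pseudocount < 0:
        raise InvalidConfigError("pseudocount must be >= 0")
    if center not in ("median", "none"):
        raise InvalidConfigError("center must be 'median' or 'none'")
    out = {}
    for assay in ("RNA", "RPF"):
        a = _condition_means(rpkm_es, assay, condition_a)
        b = _condition_means(rpkm_es, assay, condition_b)
        lfc = np.log2((b + pseudocount) / (a + pseudocount))
        if center == "median":
            lfc = lfc - float(np.median(lfc))
        out[f"log2_{assay.lower()}_fc"] = lfc
    frame = pd.DataFrame(out, index=rpkm_es.data.index)
    frame["log2_eff_fc"] = frame["log2_rpf_fc"] - frame["log2_rna_fc"]
    return FoldChangeTable(
        frame[["log2_rna_fc", "log2_rpf_fc", "log2_eff_fc"]],
        contrast=contrast or f"{condition_b}_vs_{condition_a}",
        pseudocount=pseudocount,
    )


def fold_changes_by_replicate(
    rpkm_es: ExpressionSet,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.5,
    contrast: str | None = None,
    center: str = "median",
) -> list:
    """One FoldChangeTable per replicate index, pairing replicate k of each
    condition — the inputs of the ratio-of-correlations estimator."""
    reps_a = sorted(
        rpkm_es.samples.loc[rpkm_es.samples["condition"] == condition_a, "replicate"].unique()
    )
    reps_b = sorted(
        rpkm_es.samples.loc[rpkm_es.samples["condition"] == condition_b, "replicate"].unique()
    )
    if reps_a != reps_b or not reps_a:
        raise PairingError("conditions must share the same replicate indices")
    tables = []
    for rep in reps_a:
        cols = [
            name
            for name, row in rpkm_es.samples.iterrows()
            if row["replicate"] == rep and row["condition"] in (condition_a, condition_b)
        ]
        sub = ExpressionSet(rpkm_es.data[cols], rpkm_es.samples.loc[cols], unit="RPKM")
        tables.append(
            fold_changes(sub, condition_a, condition_b, pseudocount,
                         contrast=(contrast or f"{condition_b}_vs_{condition_a}") + f"_rep{rep}",
                         center=center)
        )
    return tables


@dataclass
class DriverAssignment:
    gene_id: str
    group: int
    category: str
    direction: str


def classify_drivers(
    fc: FoldChangeTable,
    rpf_fold_threshold: float = 4.0,
    component_threshold: float | None = None,
) -> pd.DataFrame:
    """Partition genes with |RPF fold change| >= threshold into six groups.

    Direction (up: groups 1-3, down: 4-6) follows the sign of the RPF
    change.  With a = log2 RNA FC, b = log2 Eff FC and component threshold
    c (default log2(threshold)/2): translation-driven when |a| < c,
    RNA-driven when |b| < c, synergistic when both exceed c with the same
    sign; both large with opposite signs is resolved by the larger
    magnitude (tie -> RNA-driven).  The partition is exhaustive and
    mutually exclusive for every gene passing the RPF gate.
    """
    if rpf_fold_threshold <= 1:
        raise InvalidConfigError("rpf_fold_threshold must be > 1 (fold scale)")
    log2_gate = math.log2(rpf_fold_threshold)
    c = component_threshold if component_threshold is not None else log2_gate / 2.0
    if c <= 0:
        raise InvalidConfigError("component_threshold must be > 0 (log2 scale)")

    rows = []
    for gid, rna, rpf, eff in fc.data[
        ["log2_rna_fc", "log2_rpf_fc", "log2_eff_fc"]
    ].itertuples(index=True):
        if abs(rpf) < log2_gate:
            continue
        up = rpf > 0
        if abs(rna) < c:
            category = "translation_driven"
        elif abs(eff) < c:
            category = "rna_driven"
        elif (rna > 0) == (eff > 0):
            category = "synergistic"
        else:  # both large, opposite signs: the bigger component wins; tie -> RNA
            category = "rna_driven" if abs(rna) >= abs(eff) else "translation_driven"
        offset = {"translation_driven": 1, "synergistic": 2, "rna_driven": 3}[category]
        group = offset if up else offset + 3
        rows.append((gid, group, category, "up" if up else "down"))
    return pd.DataFrame(rows, columns=["gene_id", "group", "category", "direction"]).set_index(
        "gene_id"
    )


def summarize_driver_classes(assignments) -> dict:
    """Category counts and percentages from assignments or six group counts.

    Accepts either the classify_drivers() DataFrame or a sequence of six
    per-group counts (groups 1..6).  Percentages are rounded to one
    decimal.  A zero total returns ``{"empty": True}``.
    """
    if isinstance(assignments, pd.DataFrame):
        group_counts = [int((assignments["group"] == g).sum()) for g in range(1, 7)]
    else:
        group_counts = [int(x) for x in assignments]
        if len(group_counts) != 6 or any(x < 0 for x in group_counts):
            raise InvalidConfigError("expected six non-negative group counts")
    total = sum(group_counts)
    if total == 0:
        return {"empty": True, "total": 0}
    out = {"empty": False, "total": total, "group_counts": group_counts}
    for category, (g_up, g_down) in CATEGORY_GROUPS.items():
        n = group_counts[g_up - 1] + group_counts[g_down - 1]
        out[category] = {"count": n, "pct": round(100.0 * n / total, 1)}
    return out


@dataclass
class ContributionEstimate:
    """Ratio-of-correlations contribution of Eff vs RNA to RPF fold changes.

    r_rep (correlation between the two replicate estimates of the RPF fold
    change) is the reproducibility ceiling; r_eff and r_rna are computed on
    replicate-averaged fold changes.  The percentages normalize the two
    noise-corrected ratios to sum to 100 and are only reported when both
    ratios are positive and r_rep > 0.
    """

    r_rna: float
    r_eff: float
    r_rep: float
    eff_ratio: float
    rna_ratio: float
    eff_contribution_pct: float | None
    rna_contribution_pct: float | None
    reliable: bool


def contribution_ratio(fc_rep1: FoldChangeTable, fc_rep2: FoldChangeTable) -> ContributionEstimate:
    """Estimate the Eff vs RNA share of RPF fold-change variation."""
    if list(fc_rep1.data.index) != list(fc_rep2.data.index):
        raise PairingError("replicate fold-change tables must share the gene list")
    rpf1 = fc_rep1.data["log2_rpf_fc"].to_numpy()
    rpf2 = fc_rep2.data["log2_rpf_fc"].to_numpy()
    avg = (fc_rep1.data + fc_rep2.data) / 2.0
    r_rep = float(scipy.stats.pearsonr(rpf1, rpf2).statistic)
    r_rna = float(scipy.stats.pearsonr(avg["log2_rna_fc"], avg["log2_rpf_fc"]).statistic)
    r_eff = float(scipy.stats.pearsonr(avg["log2_eff_fc"], avg["log2_rpf_fc"]).statistic)
    reliable = r_rep > 0
    eff_ratio = r_eff / r_rep if reliable else float("nan")
    rna_ratio = r_rna / r_rep if reliable else float("nan")
    if reliable and eff_ratio > 0 and rna_ratio > 0:
        eff_pct = 100.0 * eff_ratio / (eff_ratio + rna_ratio)
        rna_pct = 100.0 - eff_pct
    else:
        eff_pct = rna_pct = None
    return ContributionEstimate(r_rna, r_eff, r_rep, eff_ratio, rna_ratio, eff_pct, rna_pct, reliable)


def delta_eff_ranking(fc_contrast1: FoldChangeTable, fc_contrast2: FoldChangeTable) -> pd.DataFrame:
    """Rank genes by the difference of Eff fold changes between contrasts.

    Key = log2 Eff FC(contrast 1) − log2 Eff FC(contrast 2), descending;
    ties broken by gene_id.  Returns a DataFrame ordered by rank with the
    key in column ``delta_log2_eff_fc``.
    """
    g1, g2 = set(fc_contrast1.data.index), set(fc_contrast2.data.index)
    shared = [g for g in fc_contrast1.data.index if g in g2]
    if not shared:
        raise EmptyInputError("contrasts share no genes")
    key = (
        fc_contrast1.data.loc[shared, "log2_eff_fc"]
        - fc_contrast2.data.loc[shared, "log2_eff_fc"]
    )
    frame = pd.DataFrame({"delta_log2_eff_fc": key})
    frame = frame.sort_values(
        by=["delta_log2_eff_fc"], ascending=False, kind="mergesort"
    )
    # mergesort is stable; pre-sort index for the deterministic tie-break
    frame = frame.loc[
        sorted(frame.index, key=lambda g: (-frame.at[g, "delta_log2_eff_fc"], g))
    ]
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
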