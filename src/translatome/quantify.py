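"""Count-matrix quantification: detection filter, RPKM, translational
efficiency, and sample-level correlation / clustering summaries.

RPKM here is reads per kilobase of *coding sequence* per million mapped
reads, for both assays — footprints and mRNA fragments are both expressed
relative to the CDS so that their ratio (translational efficiency, Eff) is
a density ratio over the same denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .errors import (
    DegenerateSampleError,
    EmptyInputError,
    InvalidConfigError,
    PairingError,
    WrongUnitError,
)

__all__ = [
    "ExpressionSet",
    "EffMatrix",
    "LinkageTree",
    "parse_sample_name",
    "filter_detected",
    "rpkm",
    "translational_efficiency",
    "sample_correlation",
    "hierarchical_cluster",
]

ASSAYS = ("RPF", "RNA")


def parse_sample_name(name: str) -> tuple:
    """Split ``<assay>_<condition>_rep<k>`` into (assay, condition, replicate).

    The condition itself may contain underscores (e.g. ``BAT_D0``).
    """
    parts = name.split("_")
    if len(parts) < 3 or parts[0] not in ASSAYS or not parts[-1].startswith("rep"):
        raise PairingError(f"cannot parse sample name {name!r}")
    try:
        rep = int(parts[-1][3:])
    except ValueError as exc:
        raise PairingError(f"cannot parse replicate in {name!r}") from exc
    return parts[0], "_".join(parts[1:-1]), rep


@dataclass
class ExpressionSet:
    """Gene × sample abundance matrix with per-sample metadata.

    ``samples`` is indexed by column name with columns
    ``assay`` (RPF|RNA), ``condition`` and ``replicate``.  The design is
    paired: every (condition, replicate) present for RPF must also exist
    for RNA and vice versa.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self):
        if self.unit not in ("counts", "RPKM"):
            raise InvalidConfigError(f"unknown unit {self.unit!r}")
        if (self.data.to_numpy() < 0).any():
            raise InvalidConfigError("expression values must be non-negative")
        if list(self.data.columns) != list(self.samples.index):
            raise PairingError("sample metadata does not match matrix columns")
        pairs = {
            assay: set(map(tuple, sub[["condition", "replicate"]].itertuples(index=False)))
            for assay, sub in self.samples.groupby("assay")
        }
        if len(pairs) == 2 and pairs.get("RPF") != pairs.get("RNA"):
            raise PairingError("paired design violated: RPF/RNA (condition, replicate) sets differ")

    @classmethod
    def from_matrix(cls, data: pd.DataFrame, unit: str = "counts") -> "ExpressionSet":
        """Build metadata by parsing ``<assay>_<condition>_rep<k>`` column names."""
        meta = pd.DataFrame(
            [parse_sample_name(c) for c in data.columns],
            index=data.columns,
            columns=["assay", "condition", "replicate"],
        )
        return cls(data=data, samples=meta, unit=unit)

    @classmethod
    def from_tsv(cls, path, unit: str = "counts") -> "ExpressionSet":
        return cls.from_matrix(pd.read_csv(path, sep="\t", index_col=0), unit=unit)

    def to_tsv(self, path) -> None:
        self.data.rename_axis("gene_id").to_csv(path, sep="\t")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def conditions(self) -> list:
        seen: dict = {}
        for c in self.samples["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def for_assay(self, assay: str) -> "ExpressionSet":
        cols = self.samples.index[self.samples["assay"] == assay]
        return ExpressionSet(self.data[cols], self.samples.loc[cols], unit=self.unit)

    def columns_for(self, assay: str | None = None, condition: str | None = None) -> list:
        mask = pd.Series(True, index=self.samples.index)
        if assay is not None:
            mask &= self.samples["assay"] == assay
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def subset_genes(self, gene_ids) -> "ExpressionSet":
        return ExpressionSet(self.data.loc[gene_ids], self.samples, unit=self.unit)


def filter_detected(counts: ExpressionSet, min_reads: int = 10, conditions=None) -> list:
    """Genes covered by at least ``min_reads`` raw reads in both assays.

    The threshold is applied to the replicate-pooled count per assay within
    each condition of the comparison set (default: every condition present);
    a gene must clear it in *both* assays in *every* condition.  Input gene
    order is preserved.
    """
    if counts.unit != "counts":
        raise WrongUnitError("detection filter requires raw counts, not RPKM")
    conds = list(conditions) if conditions is not None else counts.conditions
    keep = np.ones(len(counts.data), dtype=bool)
    for cond in conds:
        for assay in ASSAYS:
            cols = counts.columns_for(assay=assay, condition=cond)
            if not cols:
                raise PairingError(f"no {assay} samples for condition {cond!r}")
            keep &= counts.data[cols].sum(axis=1).to_numpy() >= min_reads
    return [g for g, k in zip(counts.data.index, keep) if k]


def rpkm(counts: ExpressionSet, genes) -> ExpressionSet:
    """Reads per kilobase of CDS per million mapped reads.

    ``genes`` is a list of :class:`~translatome.simulate.GeneModel` or a
    mapping/Series gene_id -> cds_len.  The per-sample mapped total is the
    column sum over the genes present in the matrix, so RPKM is invariant
    to scaling any one library.
    """
    if counts.unit != "counts":
        raise WrongUnitError("rpkm() expects raw counts")
    if isinstance(genes, (dict, pd.Series)):
        cds = pd.Series(genes)
    else:
        cds = pd.Series({g.gene_id: g.cds_len for g in genes})
    missing = counts.data.index.difference(cds.index)
    if len(missing):
        raise PairingError(f"no annotation for genes: {list(missing[:3])}...")
    cds = cds.loc[counts.data.index].astype(float)
    if (cds <= 0).any():
        raise InvalidConfigError("cds_len must be > 0 for all genes")
    totals = counts.data.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise DegenerateSampleError(f"zero total counts in sample(s): {bad}")
    mat = counts.data.div(cds / 1000.0, axis=0).div(totals / 1e6, axis=1)
    return ExpressionSet(mat, counts.samples, unit="RPKM")


@dataclass
class EffMatrix:
    """Per-(condition, replicate) translational efficiency: RPF RPKM / RNA RPKM.

    Undefined entries (RNA RPKM = 0 with pseudocount 0) are NaN, never inf.
    """

    data: pd.DataFrame  # genes x "<condition>_rep<k>"
    pseudocount: float = 0.0
    sample_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def columns_for(self, condition: str) -> list:
        return [c for c in self.data.columns
                if c.rsplit("_rep", 1)[0] == condition]

    def to_tsv(self, path) -> None:
        self.data.rename_axis("gene_id").to_csv(path, sep="\t")


def translational_efficiency(
    rpf: ExpressionSet, rna: ExpressionSet, pseudocount: float = 0.0
) -> EffMatrix:
    """Eff = (RPF RPKM + pseudocount) / (RNA RPKM + pseudocount) per sample pair.

    Samples are matched by (condition, replicate); a missing partner is a
    pairing error.  With pseudocount 0, genes with zero RNA signal get NaN.
    """
    if rpf.unit != "RPKM" or rna.unit != "RPKM":
        raise WrongUnitError("translational efficiency is defined on RPKM matrices")
    if pseudocount < 0:
        raise InvalidConfigError("pseudocount must be >= 0")
    if list(rpf.data.index) != list(rna.data.index):
        raise PairingError("RPF and RNA matrices must share the same gene list")

    def keyed(es):
        return {
            (row.condition, row.replicate): name
            for name, row in es.samples.iterrows()
        }

    k_rpf, k_rna = keyed(rpf), keyed(rna)
    if set(k_rpf) != set(k_rna):
        raise PairingError("RPF/RNA (condition, replicate) pairs do not match")
    out = {}
    pairs = []
    for (cond, rep) in sorted(k_rpf):
        num = rpf.data[k_rpf[(cond, rep)]].to_numpy(dtype=float) + pseudocount
        den = rna.data[k_rna[(cond, rep)]].to_numpy(dtype=float) + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        name = f"{cond}_rep{rep}"
        out[name] = eff
        pairs.append((name, cond, rep))
    frame = pd.DataFrame(out, index=rpf.data.index)
    meta = pd.DataFrame(pairs, columns=["sample", "condition", "replicate"]).set_index("sample")
    return EffMatrix(frame, pseudocount=pseudocount, sample_pairs=meta)


def sample_correlation(exprs: ExpressionSet, log_transform: bool = True) -> pd.DataFrame:
    """Pearson correlation between samples on log2(x + 1) values.

    Constant columns yield NaN entries (undefined correlation) rather than
    an error; the diagonal is 1 wherever defined.
    """
    if exprs.data.shape[1] < 2:
        raise EmptyInputError("need at least 2 samples for a correlation matrix")
    x = np.log2(exprs.data.to_numpy(dtype=float) + 1.0) if log_transform else \
        exprs.data.to_numpy(dtype=float)
    frame = pd.DataFrame(x, columns=exprs.data.columns)
    return frame.corr(method="pearson")


@dataclass
class LinkageTree:
    """Average-linkage agglomerative tree over samples on distance 1 − r."""

    labels: list
    linkage: np.ndarray  # scipy linkage matrix over `labels` order

    @property
    def merges(self) -> list:
        """Ordered merge list: (left, right, height) with cluster indices
        < n referring to leaves (``labels``) and >= n to prior merges."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def cut(self, k: int) -> dict:
        """Partition the samples into k flat clusters; label -> cluster id."""
        assign = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_dict(self) -> dict:
        return {"labels": self.labels,
                "merges": [[a, b, h] for a, b, h in self.merges]}


def hierarchical_cluster(corr: pd.DataFrame) -> LinkageTree:
    """Cluster samples by average linkage on distance 1 − correlation.

    Sample labels are ordered lexicographically before linkage so ties are
    broken deterministically and the tree is invariant to input column
    order.  A single sample yields a trivial (empty-merge) tree.
    """
    if not corr.index.equals(corr.columns):
        raise InvalidConfigError("correlation matrix must be square and labelled")
    labels = sorted(corr.columns)
    if len(labels) == 1:
        return LinkageTree(labels, np.empty((0, 4)))
    mat = corr.loc[labels, labels].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise InvalidConfigError("correlation matrix contains undefined entries")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    return LinkageTree(labels, linkage)
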