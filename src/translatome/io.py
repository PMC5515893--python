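"""Plain-text readers and writers for the package's tabular formats.

All tables are TSV.  Counts matrices have a first ``gene_id`` column and
sample columns named ``<assay>_<condition>_rep<k>``; annotation carries
UTR/CDS lengths plus semicolon-joined category labels; positional
footprints are sparse (gene_id, position, count) triples in 0-based
transcript coordinates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidConfigError
from .simulate import GeneModel, PositionalCounts

__all__ = [
    "write_annotation",
    "read_annotation",
    "read_annotation_gtf",
    "write_targets",
    "read_targets",
    "write_positional_counts",
    "read_positional_counts",
]


def write_annotation(genes, path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "utr5_len": [g.utr5_len for g in genes],
            "cds_len": [g.cds_len for g in genes],
            "utr3_len": [g.utr3_len for g in genes],
            "categories": [";".join(sorted(g.categories)) for g in genes],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> list:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    genes = []
    for row in frame.itertuples(index=False):
        cats = getattr(row, "categories", "")
        cats = frozenset() if pd.isna(cats) or not cats else frozenset(str(cats).split(";"))
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                utr5_len=int(row.utr5_len),
                cds_len=int(row.cds_len),
                utr3_len=int(row.utr3_len),
                categories=cats,
            )
        )
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


def read_annotation_gtf(path) -> list:
    """Derive UTR/CDS lengths from a GTF subset (exon and CDS features).

    Assumes one transcript per gene on a single strand: the 5′UTR is the
    exonic length upstream of the first CDS base (in transcription
    direction), the 3′UTR the exonic length downstream of the last.
    """
    cols = ["seqname", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"]
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise InvalidConfigError("malformed GTF line (expected 9 tab-separated fields)")
            rows.append(parts)
    if not rows:
        raise EmptyInputError("empty GTF input")
    frame = pd.DataFrame(rows, columns=cols)
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    frame["gene_id"] = [_gtf_attr(a, "gene_id") for a in frame["attrs"]]
    if frame["gene_id"].isna().any():
        raise InvalidConfigError("GTF feature without a gene_id attribute")
    genes = []
    for gid, sub in frame.groupby("gene_id", sort=True):
        exons = sub[sub["feature"] == "exon"]
        cds = sub[sub["feature"] == "CDS"]
        if exons.empty or cds.empty:
            raise InvalidConfigError(f"gene {gid}: need both exon and CDS features")
        strand = sub["strand"].iloc[0]
        cds_len = int((cds["end"] - cds["start"] + 1).sum())
        # exonic length strictly upstream/downstream of the CDS span
        cds_lo, cds_hi = int(cds["start"].min()), int(cds["end"].max())
        up = int(
            (np.minimum(exons["end"], cds_lo - 1) - exons["start"] + 1).clip(lower=0).sum()
        )
        down = int(
            (exons["end"] - np.maximum(exons["start"], cds_hi + 1) + 1).clip(lower=0).sum()
        )
        utr5, utr3 = (up, down) if strand != "-" else (down, up)
        genes.append(GeneModel(gene_id=str(gid), utr5_len=utr5, cds_len=cds_len, utr3_len=utr3))
    return genes


def write_targets(frame: pd.DataFrame, path) -> None:
    frame[["family_id", "gene_id", "n_sites"]].to_csv(path, sep="\t", index=False)


def read_targets(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    id_col = "mirna_id" if "mirna_id" in frame.columns else "family_id"
    missing = {id_col, "gene_id", "n_sites"} - set(frame.columns)
    if missing:
        raise InvalidConfigError(f"target table missing columns {missing}")
    return frame


def write_positional_counts(records, path) -> None:
    """Sparse TSV (gene_id, position, count); zero positions are omitted."""
    rows = []
    for pc in records:
        nz = np.nonzero(pc.counts)[0]
        for pos in nz:
            rows.append((pc.gene_id, int(pos), int(pc.counts[pos])))
    pd.DataFrame(rows, columns=["gene_id", "position", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_positional_counts(path, genes) -> dict:
    """gene_id -> PositionalCounts, densified to each gene's total length."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    lengths = {g.gene_id: g.total_len for g in genes}
    out = {}
    for gid, sub in frame.groupby("gene_id", sort=True):
        if gid not in lengths:
            raise InvalidConfigError(f"positional counts for unannotated gene {gid}")
        counts = np.zeros(lengths[gid], dtype=np.int64)
        pos = sub["position"].to_numpy(dtype=int)
        if (pos < 0).any() or (pos >= lengths[gid]).any():
            raise InvalidConfigError(f"{gid}: position outside transcript")
        counts[pos] = sub["count"].to_numpy(dtype=int)
        out[gid] = PositionalCounts(gid, counts)
    return out
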