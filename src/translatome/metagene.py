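"""Metagene footprint profiling: P-site assignment, start/stop-aligned
average density profiles and 3-nt periodicity scoring.

The P-site of a footprint is placed a fixed 14 nt beyond its 5′ end; all
coordinates are 0-based, half-open, transcript-relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import EmptyInputError, InvalidConfigError
from .simulate import GeneModel, PositionalCounts

__all__ = [
    "DEFAULT_PSITE_OFFSET",
    "MetageneProfile",
    "PeriodicityResult",
    "psite_shift",
    "metagene_profile",
    "periodicity_score",
]

DEFAULT_PSITE_OFFSET = 14

#: default windows (nt relative to the first nucleotide of the start/stop codon)
DEFAULT_WINDOWS = {"start": (-50, 100), "stop": (-100, 50)}


def psite_shift(positions: PositionalCounts, offset: int = DEFAULT_PSITE_OFFSET) -> PositionalCounts:
    """Reassign each 5′-end count at position p to the P-site p + offset.

    Reads whose shifted position falls beyond the transcript end are
    dropped and accumulated in the ``dropped`` counter.
    """
    if offset < 0:
        raise InvalidConfigError("P-site offset must be >= 0")
    counts = positions.counts
    n = counts.size
    shifted = np.zeros(n, dtype=np.int64)
    if offset == 0:
        shifted[:] = counts
        lost = 0
    else:
        shifted[offset:] = counts[: n - offset]
        lost = int(counts[n - offset:].sum())
    return PositionalCounts(positions.gene_id, shifted, dropped=positions.dropped + lost)


@dataclass
class MetageneProfile:
    """Average normalized footprint density around the start or stop codon.

    Each gene's windowed density vector is divided by that gene's mean CDS
    density before averaging, so a uniformly covered CDS contributes 1.0 at
    every in-CDS offset.  ``n_genes_per_offset`` records how many genes
    were long enough to contribute at each offset.
    """

    align_at: str
    offsets: np.ndarray
    density: np.ndarray
    n_genes: int
    n_genes_per_offset: np.ndarray

    def peak_offset(self) -> int:
        """Offset of the profile maximum (NaN-safe)."""
        return int(self.offsets[int(np.nanargmax(self.density))])


def metagene_profile(
    psites,
    genes,
    align_at: str = "start",
    window: tuple | None = None,
) -> MetageneProfile:
    """Average per-gene normalized P-site density aligned at start/stop codons.

    ``psites`` maps gene_id -> :class:`PositionalCounts` (or is a list of
    them); genes without annotation or with zero mean CDS density are
    skipped.  Offsets outside a short transcript contribute nothing (the
    per-offset gene count shrinks instead).
    """
    if align_at not in ("start", "stop"):
        raise InvalidConfigError("align_at must be 'start' or 'stop'")
    lo, hi = window if window is not None else DEFAULT_WINDOWS[align_at]
    if hi <= lo:
        raise InvalidConfigError("window must be a non-empty (lo, hi) range")
    if isinstance(psites, dict):
        pc_map = psites
    else:
        pc_map = {p.gene_id: p for p in psites}
    gene_map = {g.gene_id: g for g in genes} if not isinstance(genes, dict) else genes

    offsets = np.arange(lo, hi + 1)
    total = np.zeros(offsets.size)
    n_per = np.zeros(offsets.size, dtype=np.int64)
    used = 0
    for gid, pc in pc_map.items():
        gene = gene_map.get(gid)
        if gene is None:
            continue
        v = pc.counts.astype(float)
        cds = v[gene.cds_start:gene.cds_end]
        mean_cds = cds.mean() if cds.size else 0.0
        if mean_cds <= 0:
            continue
        anchor = gene.cds_start if align_at == "start" else gene.cds_end - 3
        pos = anchor + offsets
        ok = (pos >= 0) & (pos < v.size)
        total[ok] += v[pos[ok]] / mean_cds
        n_per[ok] += 1
        used += 1
    if used == 0:
        raise EmptyInputError("no gene with positive CDS density in the input")
    with np.errstate(invalid="ignore"):
        density = np.where(n_per > 0, total / np.maximum(n_per, 1), np.nan)
    return MetageneProfile(align_at, offsets, density, used, n_per)


@dataclass
class PeriodicityResult:
    """Fractions of in-CDS P-sites per codon frame and a periodicity score.

    score = max(f0, f1, f2) − 1/3: zero for frame-uniform (RNA-like) data,
    2/3 when every P-site sits in one frame.  ``defined`` is False when no
    in-CDS P-site was seen.
    """

    frame_fractions: tuple
    score: float
    chi2_stat: float
    p_value: float
    n_psites: int
    defined: bool = True


def periodicity_score(psites, genes) -> PeriodicityResult:
    """Codon-frame distribution of all in-CDS P-sites across genes.

    Frame = (position − cds_start) mod 3 per gene; returns the three frame
    fractions, score = f_max − 1/3, and a chi-square test against the
    uniform frame distribution.
    """
    if isinstance(psites, dict):
        pc_map = psites
    else:
        pc_map = {p.gene_id: p for p in psites}
    gene_map = {g.gene_id: g for g in genes} if not isinstance(genes, dict) else genes
    frames = np.zeros(3, dtype=np.int64)
    for gid, pc in pc_map.items():
        gene = gene_map.get(gid)
        if gene is None:
            continue
        cds = pc.counts[gene.cds_start:gene.cds_end]
        rel = np.arange(cds.size) % 3
        for f in range(3):
            frames[f] += int(cds[rel == f].sum())
    n = int(frames.sum())
    if n == 0:
        return PeriodicityResult((np.nan,) * 3, np.nan, np.nan, np.nan, 0, defined=False)
    fracs = tuple(frames / n)
    chi2, p = scipy.stats.chisquare(frames)
    return PeriodicityResult(fracs, float(max(fracs) - 1.0 / 3.0), float(chi2), float(p), n)
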