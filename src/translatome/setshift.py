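"""Cumulative-distribution comparison machinery.

Gene-set regulation is assessed by comparing the empirical cumulative
distribution of a value (a fold change or an expression level) over a gene
set against a background population with the two-sample Kolmogorov–Smirnov
statistic, plus a ranked-list permutation enrichment score and the
hypergeometric category-overlap test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, InvalidConfigError

__all__ = [
    "ECDF",
    "KSResult",
    "EnrichmentResult",
    "ecdf",
    "ks_two_sample",
    "set_shift_test",
    "ranked_enrichment",
    "hypergeometric_test",
    "benjamini_hochberg",
]

EXACT_SMALL_LIMIT = 12


@dataclass
class ECDF:
    """Right-continuous empirical CDF: F(x) = fraction of values <= x."""

    support: np.ndarray    # sorted unique values
    fractions: np.ndarray  # cumulative fractions, ends at 1

    def __call__(self, x):
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        out = np.concatenate(([0.0], self.fractions))[idx]
        return float(out) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def ecdf(values) -> ECDF:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("cannot build an ECDF from an empty vector")
    if not np.isfinite(values).all():
        raise InvalidConfigError("ECDF input must be finite")
    support, counts = np.unique(values, return_counts=True)
    return ECDF(support, np.cumsum(counts) / values.size)


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """sup over the pooled support of |ECDF_x − ECDF_y|."""
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    cx = np.searchsorted(xs, pooled, side="right") / xs.size
    cy = np.searchsorted(ys, pooled, side="right") / ys.size
    return float(np.abs(cx - cy).max())


@dataclass
class KSResult:
    """Two-sample KS comparison with a shift direction.

    ``shift_direction`` is "right" when the first sample's mean exceeds the
    second's (its cumulative curve lies to the right), "left" for the
    converse, "none" for equal means or D = 0.
    """

    d_statistic: float
    p_value: float
    n_x: int
    n_y: int
    shift_direction: str = "none"
    mode: str = "asymptotic"


def _direction(x: np.ndarray, y: np.ndarray, d: float) -> str:
    if d == 0:
        return "none"
    diff = float(np.mean(x) - np.mean(y))
    if diff > 0:
        return "right"
    if diff < 0:
        return "left"
    return "none"


def ks_two_sample(
    x,
    y,
    mode: str = "asymptotic",
    n_permutations: int = 1000,
    seed: int = 0,
) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test.

    Modes: ``asymptotic`` (Kolmogorov distribution at effective
    n = n_x n_y / (n_x + n_y)), ``exact_small`` (exhaustive enumeration of
    all C(n_x + n_y, n_x) label assignments, allowed for pooled size <= 12),
    and ``permutation`` (seeded label resampling; p includes the observed
    assignment, so p >= 1/(n_permutations + 1)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidConfigError("KS input must be finite")
    d = _ks_d(x, y)
    direction = _direction(x, y, d)

    if mode == "asymptotic":
        p = float(scipy.stats.ks_2samp(x, y, method="asymp").pvalue)
    elif mode == "exact_small":
        n = x.size + y.size
        if n > EXACT_SMALL_LIMIT:
            raise InvalidConfigError(
                f"exact_small enumerates label assignments only for pooled n <= {EXACT_SMALL_LIMIT}"
            )
        pooled = np.concatenate([x, y])
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), x.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            if _ks_d(pooled[mask], pooled[~mask]) >= d - 1e-12:
                count += 1
            total += 1
        p = count / total
    elif mode == "permutation":
        if n_permutations < 1:
            raise InvalidConfigError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _ks_d(perm[: x.size], perm[x.size:]) >= d - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise InvalidConfigError(f"unknown mode {mode!r}")
    return KSResult(d, min(1.0, max(p, 0.0)), int(x.size), int(y.size), direction, mode)


def set_shift_test(
    values,
    gene_set,
    background_mode: str = "all_other_genes",
    mode: str = "asymptotic",
    **ks_kw,
) -> KSResult:
    """KS shift of a gene set's values against a background population.

    ``values`` maps gene_id -> value (dict or pandas Series).  Background
    ``all_other_genes`` compares the set against its complement (independent
    samples, the default for testing); ``all_genes`` compares it against the
    full population including the set, matching the cumulative-fraction
    plots where the black curve is "all detectable genes".
    """
    import pandas as pd

    series = pd.Series(values, dtype=float)
    in_set = series.index.isin(set(gene_set))
    if not in_set.any():
        raise EmptyInputError("gene set does not intersect the analysed genes")
    if background_mode == "all_other_genes":
        bg = series[~in_set].to_numpy()
    elif background_mode == "all_genes":
        bg = series.to_numpy()
    else:
        raise InvalidConfigError(f"unknown background_mode {background_mode!r}")
    if bg.size == 0:
        raise EmptyInputError("background population is empty")
    return ks_two_sample(series[in_set].to_numpy(), bg, mode=mode, **ks_kw)


@dataclass
class EnrichmentResult:
    """Ranked-list permutation enrichment of one gene set.

    ES is the extremum of the classic (unweighted) KS running sum down the
    ranked list; NES = ES / mean(|ES| over gene-label permutations);
    p = fraction of permuted |ES| >= |ES| with the observed assignment
    included, hence p >= 1/(n_permutations + 1).
    """

    set_label: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int
    warning: str | None = None


def _running_es(hits: np.ndarray) -> float:
    n = hits.size
    k = int(hits.sum())
    step = np.where(hits, 1.0 / k, -1.0 / (n - k))
    path = np.cumsum(step)
    i = int(np.abs(path).argmax())
    return float(path[i])


def ranked_enrichment(
    ranking,
    gene_set,
    n_permutations: int = 1000,
    seed: int = 0,
    set_label: str = "set",
) -> EnrichmentResult:
    """Permutation enrichment of ``gene_set`` in an ordered gene ranking."""
    ranked = list(ranking)
    members = set(gene_set)
    hits = np.array([g in members for g in ranked], dtype=bool)
    k = int(hits.sum())
    if k == 0:
        raise EmptyInputError("gene set has no member in the ranking")
    if k == len(ranked):
        raise InvalidConfigError("gene set covers the whole ranking")
    warning = "n_permutations < 100: p-value resolution is poor" if n_permutations < 100 else None
    es = _running_es(hits)
    rng = np.random.default_rng(seed)
    perm_abs = np.empty(n_permutations)
    count = 0
    for i in range(n_permutations):
        perm_abs[i] = abs(_running_es(rng.permutation(hits)))
        if perm_abs[i] >= abs(es) - 1e-12:
            count += 1
    denom = float(perm_abs.mean())
    nes = es / denom if denom > 0 else math.copysign(math.inf, es)
    p = (count + 1) / (n_permutations + 1)
    return EnrichmentResult(set_label, es, nes, p, n_permutations, seed, warning)


def hypergeometric_test(set_genes, category_genes, universe_size: int) -> float:
    """Upper-tail hypergeometric p for observing >= the actual overlap.

    Models the gene set as a draw of size |set| from a universe of
    ``universe_size`` genes containing |category| successes.
    """
    set_genes = set(set_genes)
    category_genes = set(category_genes)
    if len(set_genes) > universe_size or len(category_genes) > universe_size:
        raise InvalidConfigError("set/category larger than the universe")
    overlap = len(set_genes & category_genes)
    return float(
        scipy.stats.hypergeom.sf(
            overlap - 1, universe_size, len(category_genes), len(set_genes)
        )
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg FDR-adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
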