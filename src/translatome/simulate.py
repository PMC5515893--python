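"""Synthetic ribosome-profiling / RNA-seq data with known ground truth.

The generator emulates a paired-design study of adipocyte biology: two
differentiation lineages (brown and white preadipocytes, day 0 and day 5)
plus two adipose depots (BAT, WAT), duplicate libraries, and for every
sample both a ribosome-footprint (RPF) and an RNA-seq library.  Every
downstream stage of the package — translational-efficiency quantification,
driver classification, gene-set shift tests, microRNA repression analysis —
can be exercised against the exact regulatory effects planted here.

Ground truth is expressed in log2 space and obeys the decomposition
identity ``log2 RPF FC = log2 RNA FC + log2 Eff FC`` by construction:
RNA and translational-efficiency (Eff) effects are the free parameters and
the footprint effect is their sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = [
    "GeneModel",
    "SimConfig",
    "SimTruth",
    "PauseParams",
    "PositionalCounts",
    "REGULATION_CLASSES",
    "generate_annotation",
    "generate_truth",
    "gaussian_truth",
    "simulate_counts",
    "simulate_footprint_positions",
    "family_table",
    "family_targets",
]

#: regulation classes a gene may carry in one contrast, plus "unregulated"
REGULATION_CLASSES = (
    "translation_up",
    "synergistic_up",
    "rna_up",
    "translation_down",
    "synergistic_down",
    "rna_down",
)


@dataclass(frozen=True)
class GeneModel:
    """Structural annotation of one gene's representative transcript.

    Coordinates are transcript-relative, 0-based, half-open: the CDS spans
    ``[utr5_len, utr5_len + cds_len)`` and the first nucleotide of the stop
    codon sits at ``utr5_len + cds_len - 3``.
    """

    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    categories: frozenset = frozenset()
    site_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.cds_len < 3 or self.cds_len % 3 != 0:
            raise InvalidConfigError(
                f"{self.gene_id}: cds_len must be a positive multiple of 3, got {self.cds_len}"
            )
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise InvalidConfigError(f"{self.gene_id}: negative UTR length")

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        return self.utr5_len + self.cds_len

    @property
    def total_sites(self) -> int:
        return int(sum(self.site_counts.values()))


def _default_class_fractions() -> dict:
    return {
        "translation_up": 0.02,
        "synergistic_up": 0.04,
        "rna_up": 0.04,
        "translation_down": 0.02,
        "synergistic_down": 0.04,
        "rna_down": 0.04,
    }


def _default_contrasts() -> dict:
    # contrast name -> (denominator condition, numerator condition)
    return {
        "brown": ("BAT_D0", "BAT_D5"),
        "white": ("WAT_D0", "WAT_D5"),
        "tissue": ("WAT", "BAT"),
    }


def _default_categories() -> dict:
    return {"mitochondrion": 0.04, "lipid_metabolism": 0.03, "translation": 0.03}


@dataclass
class SimConfig:
    """All knobs of the generator; every output is a pure function of this.

    Defaults mirror the study design the package targets: 5000 genes,
    duplicate libraries of ~2e7 mapped reads (the source design reports
    >10 million reads per library), negative-binomial dispersion 0.05,
    20% of genes regulated per contrast, 219 seed-collapsed microRNA
    families with 100 conserved targets each, and 75% of families
    repressing more strongly in brown adipose.
    """

    n_genes: int = 5000
    n_replicates: int = 2
    conditions: Sequence[str] = ("BAT_D0", "BAT_D5", "WAT_D0", "WAT_D5", "BAT", "WAT")
    contrasts: Mapping[str, tuple] = field(default_factory=_default_contrasts)
    class_fractions: Mapping[str, Mapping[str, float]] | None = None  # per contrast
    # log2 effect-size ranges (magnitudes)
    effect_range_driver: tuple = (2.6, 3.4)
    effect_range_synergistic: tuple = (1.8, 2.4)
    effect_range_minor: tuple = (0.0, 0.25)
    component_threshold: float = 1.0  # log2; separates driving from minor components
    nb_dispersion: float = 0.05
    library_size: float = 2e7
    # annotation
    utr5_len: int = 100
    utr3_len: int = 200
    cds_median: float = 900.0
    cds_sigma: float = 0.45
    category_fractions: Mapping[str, float] = field(default_factory=_default_categories)
    # baselines (log-normal)
    baseline_rpkm_median: float = 20.0
    baseline_rpkm_sigma: float = 1.0
    baseline_eff_median: float = 1.0
    baseline_eff_sigma: float = 0.4
    # microRNA families
    n_families: int = 219
    targets_per_family: int = 50
    site_count_mean: float = 1.5
    tissue_bias: float = 0.75
    repression_strength_range: tuple = (0.2, 0.5)
    repression_tissue_delta: float = 0.3
    repression_target: str = "rna"  # "rna" | "eff" | "both"
    seed: int = 0

    def __post_init__(self):
        if self.class_fractions is None:
            self.class_fractions = {c: _default_class_fractions() for c in self.contrasts}

    def validate(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be >= 1")
        if self.library_size <= 0:
            raise InvalidConfigError("library_size must be > 0")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")
        if self.n_families < 0 or self.targets_per_family < 0:
            raise InvalidConfigError("family sizes must be >= 0")
        if self.targets_per_family > self.n_genes:
            raise InvalidConfigError("targets_per_family exceeds n_genes")
        if not 0 <= self.tissue_bias <= 1:
            raise InvalidConfigError("tissue_bias must lie in [0, 1]")
        if self.repression_target not in ("rna", "eff", "both"):
            raise InvalidConfigError("repression_target must be rna|eff|both")
        for name, (a, b) in self.contrasts.items():
            if a not in self.conditions or b not in self.conditions:
                raise InvalidConfigError(f"contrast {name!r} references unknown condition")
        for contrast, fracs in self.class_fractions.items():
            if contrast not in self.contrasts:
                raise InvalidConfigError(f"class_fractions for unknown contrast {contrast!r}")
            for cls in fracs:
                if cls not in REGULATION_CLASSES:
                    raise InvalidConfigError(f"unknown regulation class {cls!r}")
            if sum(fracs.values()) > 1 + 1e-12:
                raise InvalidConfigError("class_fractions must sum to <= 1")
        c = self.component_threshold
        if not (self.effect_range_minor[1] < c <= self.effect_range_driver[0]):
            raise InvalidConfigError(
                "effect ranges inconsistent with class definition: minor range must stay "
                "below the component threshold and the driving range above it"
            )
        if self.effect_range_synergistic[0] < c:
            raise InvalidConfigError(
                "synergistic range must keep both components above the component threshold"
            )

    def with_(self, **kw) -> "SimConfig":
        """Return a copy with fields replaced (class_fractions re-derived if reset to None)."""
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Planted regulatory effects for every gene and contrast.

    ``log2_rpf_fc`` is derived, never stored: the decomposition identity
    holds to machine precision by construction.
    """

    gene_ids: list
    baseline_rna_rpkm: np.ndarray
    baseline_eff: np.ndarray
    log2_rna_fc: dict          # contrast -> array (n_genes,)
    log2_eff_fc: dict          # contrast -> array
    true_class: dict           # contrast -> object array of class labels
    repression_strength: dict  # tissue -> {family_id: log2 strength >= 0}

    def log2_rpf_fc(self, contrast: str) -> np.ndarray:
        return self.log2_rna_fc[contrast] + self.log2_eff_fc[contrast]

    def regulated_mask(self, contrast: str) -> np.ndarray:
        return self.true_class[contrast] != "unregulated"

    def to_frame(self) -> pd.DataFrame:
        cols = {"gene_id": self.gene_ids,
                "baseline_rna_rpkm": self.baseline_rna_rpkm,
                "baseline_eff": self.baseline_eff}
        for contrast in self.log2_rna_fc:
            cols[f"log2_rna_fc_{contrast}"] = self.log2_rna_fc[contrast]
            cols[f"log2_eff_fc_{contrast}"] = self.log2_eff_fc[contrast]
            cols[f"true_class_{contrast}"] = self.true_class[contrast]
        return pd.DataFrame(cols)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


def generate_annotation(config: SimConfig) -> list:
    """Draw gene structures, category memberships and microRNA target sites.

    CDS lengths are log-normal (median ``cds_median``) rounded to a multiple
    of 3 with a 300-nt floor; UTR lengths are the fixed configured values.
    Each of ``n_families`` seed families receives ``targets_per_family``
    target genes (sampled without replacement) with at least one site each;
    extra sites are Poisson so that the per-target mean is ``site_count_mean``.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    n = config.n_genes
    cds = np.exp(rng.normal(math.log(config.cds_median), config.cds_sigma, n))
    cds = np.maximum(300, (np.round(cds / 3).astype(int)) * 3)

    categories = [set() for _ in range(n)]
    for cat, frac in config.category_fractions.items():
        k = int(frac * n)
        for i in rng.permutation(n)[:k]:
            categories[i].add(cat)

    site_counts: list = [dict() for _ in range(n)]
    extra_mean = max(0.0, config.site_count_mean - 1.0)
    for f in range(config.n_families):
        fam = f"miR-fam-{f:03d}"
        targets = rng.choice(n, size=config.targets_per_family, replace=False)
        extras = rng.poisson(extra_mean, size=config.targets_per_family)
        for g, e in zip(targets, extras):
            site_counts[g][fam] = 1 + int(e)

    digits = max(4, len(str(n - 1)))
    return [
        GeneModel(
            gene_id=f"g{i:0{digits}d}",
            utr5_len=config.utr5_len,
            cds_len=int(cds[i]),
            utr3_len=config.utr3_len,
            categories=frozenset(categories[i]),
            site_counts=site_counts[i],
        )
        for i in range(n)
    ]


def family_targets(genes: Sequence[GeneModel]) -> dict:
    """family_id -> sorted list of gene indices targeted by that family."""
    out: dict = {}
    for i, g in enumerate(genes):
        for fam in g.site_counts:
            out.setdefault(fam, []).append(i)
    return {fam: sorted(ix) for fam, ix in sorted(out.items())}


def family_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Long-format conserved-target table (family_id, gene_id, n_sites)."""
    rows = [
        (fam, g.gene_id, sites)
        for g in genes
        for fam, sites in sorted(g.site_counts.items())
    ]
    return pd.DataFrame(rows, columns=["family_id", "gene_id", "n_sites"]).sort_values(
        ["family_id", "gene_id"], ignore_index=True
    )


def generate_truth(genes: Sequence[GeneModel], config: SimConfig) -> SimTruth:
    """Allocate regulation classes and draw planted log2 effects.

    Allocation is by exact count — ``floor(fraction * n_genes)`` genes per
    class, chosen by a seeded permutation — so expected group sizes are
    testable exactly.  Driving components get |log2| in
    ``effect_range_driver``, synergistic components in
    ``effect_range_synergistic`` (both same sign), minor components in
    ``effect_range_minor`` with the sign of the regulated direction.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    n = len(genes)

    baseline_rna = np.exp(rng.normal(math.log(config.baseline_rpkm_median),
                                     config.baseline_rpkm_sigma, n))
    baseline_eff = np.exp(rng.normal(math.log(config.baseline_eff_median),
                                     config.baseline_eff_sigma, n))

    log2_rna_fc, log2_eff_fc, true_class = {}, {}, {}
    for contrast in config.contrasts:
        fracs = config.class_fractions.get(contrast, {})
        rna = np.zeros(n)
        eff = np.zeros(n)
        cls = np.full(n, "unregulated", dtype=object)
        perm = rng.permutation(n)
        pos = 0
        for class_name in REGULATION_CLASSES:
            k = int(fracs.get(class_name, 0.0) * n)
            idx = perm[pos:pos + k]
            pos += k
            sign = 1.0 if class_name.endswith("_up") else -1.0
            if class_name.startswith("translation"):
                eff[idx] = sign * rng.uniform(*config.effect_range_driver, k)
                rna[idx] = sign * rng.uniform(*config.effect_range_minor, k)
            elif class_name.startswith("rna"):
                rna[idx] = sign * rng.uniform(*config.effect_range_driver, k)
                eff[idx] = sign * rng.uniform(*config.effect_range_minor, k)
            else:  # synergistic
                rna[idx] = sign * rng.uniform(*config.effect_range_synergistic, k)
                eff[idx] = sign * rng.uniform(*config.effect_range_synergistic, k)
            cls[idx] = class_name
        log2_rna_fc[contrast] = rna
        log2_eff_fc[contrast] = eff
        true_class[contrast] = cls

    # per-family, per-tissue repression strengths (log2, applied as negative effects)
    fams = sorted(family_targets(genes))
    repression: dict = {"BAT": {}, "WAT": {}}
    if fams:
        base = rng.uniform(*config.repression_strength_range, len(fams))
        stronger_in_bat = np.zeros(len(fams), dtype=bool)
        k = int(config.tissue_bias * len(fams))
        stronger_in_bat[rng.permutation(len(fams))[:k]] = True
        for i, fam in enumerate(fams):
            delta = config.repression_tissue_delta
            if stronger_in_bat[i]:
                repression["BAT"][fam] = base[i] + delta
                repression["WAT"][fam] = base[i]
            else:
                repression["BAT"][fam] = base[i]
                repression["WAT"][fam] = base[i] + delta

    return SimTruth(
        gene_ids=[g.gene_id for g in genes],
        baseline_rna_rpkm=baseline_rna,
        baseline_eff=baseline_eff,
        log2_rna_fc=log2_rna_fc,
        log2_eff_fc=log2_eff_fc,
        true_class=true_class,
        repression_strength=repression,
    )


def gaussian_truth(
    genes: Sequence[GeneModel],
    config: SimConfig,
    contrast: str,
    eff_variance_share: float,
    total_log2_sd: float = 1.0,
) -> SimTruth:
    """Continuous (Gaussian) effects for one contrast, with a fixed share of
    the total log2 RPF fold-change variance coming from translational
    efficiency.  Used to study the ratio-of-correlations contribution
    estimator under a known Eff/RNA variance split.
    """
    if not 0 <= eff_variance_share <= 1:
        raise InvalidConfigError("eff_variance_share must lie in [0, 1]")
    if contrast not in config.contrasts:
        raise InvalidConfigError(f"unknown contrast {contrast!r}")
    truth = generate_truth(genes, config.with_(class_fractions={c: {} for c in config.contrasts}))
    rng = _rng(config.seed, 3)
    n = len(genes)
    eff_sd = total_log2_sd * math.sqrt(eff_variance_share)
    rna_sd = total_log2_sd * math.sqrt(1 - eff_variance_share)
    truth.log2_rna_fc[contrast] = rng.normal(0.0, rna_sd, n)
    truth.log2_eff_fc[contrast] = rng.normal(0.0, eff_sd, n)
    return truth


def _condition_effects(truth: SimTruth, genes: Sequence[GeneModel], config: SimConfig):
    """Fold planted contrast effects and miRNA repression into per-condition
    log2 multipliers for RNA abundance and translational efficiency."""
    n = len(genes)
    rna = {c: np.zeros(n) for c in config.conditions}
    eff = {c: np.zeros(n) for c in config.conditions}
    for contrast, (a, b) in config.contrasts.items():
        rna[b] = rna[b] + truth.log2_rna_fc[contrast]
        eff[b] = eff[b] + truth.log2_eff_fc[contrast]
    targets = family_targets(genes)
    for tissue in ("BAT", "WAT"):
        if tissue not in config.conditions:
            continue
        for fam, strength in truth.repression_strength.get(tissue, {}).items():
            idx = targets.get(fam, [])
            if not idx or strength == 0:
                continue
            if config.repression_target in ("rna", "both"):
                rna[tissue][idx] -= strength
            if config.repression_target in ("eff", "both"):
                eff[tissue][idx] -= strength
    return rna, eff


def simulate_counts(truth: SimTruth, genes: Sequence[GeneModel], config: SimConfig):
    """Draw raw RPF and RNA count matrices for every condition × replicate.

    RNA counts are negative binomial with mean proportional to
    baseline RPKM × condition effect × CDS length × library size; RPF means
    are further multiplied by the gene's baseline Eff and the condition's
    Eff effect.  ``nb_dispersion = 0`` selects the Poisson limit.
    Replicates are independent draws; the whole matrix is a pure function
    of (truth, genes, config.seed).

    Returns a :class:`translatome.quantify.ExpressionSet` of raw counts.
    """
    from .quantify import ExpressionSet  # local import avoids a cycle

    config.validate()
    rng = _rng(config.seed, 2)
    n = len(genes)
    cds_kb = np.array([g.cds_len for g in genes]) / 1000.0
    depth = config.library_size / 1e6
    rna_eff_log2, eff_eff_log2 = _condition_effects(truth, genes, config)

    columns, data = [], {}
    for cond in config.conditions:
        mu_rna = truth.baseline_rna_rpkm * 2.0 ** rna_eff_log2[cond] * cds_kb * depth
        mu_rpf = mu_rna * truth.baseline_eff * 2.0 ** eff_eff_log2[cond]
        for assay, mu in (("RPF", mu_rpf), ("RNA", mu_rna)):
            for rep in range(1, config.n_replicates + 1):
                name = f"{assay}_{cond}_rep{rep}"
                if config.nb_dispersion <= 0:
                    draw = rng.poisson(mu)
                else:
                    size = 1.0 / config.nb_dispersion
                    p = size / (size + mu)
                    draw = rng.negative_binomial(size, p)
                columns.append(name)
                data[name] = draw.astype(np.int64)
    frame = pd.DataFrame(data, index=[g.gene_id for g in genes], columns=columns)
    return ExpressionSet.from_matrix(frame, unit="counts")


@dataclass(frozen=True)
class PauseParams:
    """Ribosome pausing and codon-frame structure of simulated footprints.

    ``start_pause`` / ``stop_pause`` multiply the P-site sampling weight of
    the three start-codon / stop-codon nucleotides; ``frame_weights`` is the
    probability of the P-site landing in codon frame 0/1/2.
    """

    start_pause: float = 10.0
    stop_pause: float = 5.0
    frame_weights: tuple = (0.7, 0.15, 0.15)

    def validate(self) -> None:
        if self.start_pause < 1 or self.stop_pause < 1:
            raise InvalidConfigError("pause multipliers must be >= 1")
        if abs(sum(self.frame_weights) - 1.0) > 1e-9:
            raise InvalidConfigError("frame weights must sum to 1")
        if any(w < 0 for w in self.frame_weights):
            raise InvalidConfigError("frame weights must be >= 0")


@dataclass
class PositionalCounts:
    """Per-position 5′-end (or P-site) read counts over one transcript."""

    gene_id: str
    counts: np.ndarray
    dropped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise InvalidConfigError(f"{self.gene_id}: negative positional count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def simulate_footprint_positions(
    gene: GeneModel,
    n_reads: int,
    pause_params: PauseParams | None = None,
    seed: int = 0,
    mode: str = "rpf",
    psite_offset: int = 14,
) -> PositionalCounts:
    """Place reads on one transcript and return 5′-end counts per position.

    In RPF mode the P-site (5′ end + ``psite_offset``) is sampled over CDS
    positions with weight frame_weight[frame] times the start/stop pause
    multiplier where applicable; the 5′ end is the P-site minus the offset,
    and reads whose 5′ end would fall before the transcript start are
    dropped (counted in ``dropped``).  In RNA mode 5′ ends are uniform over
    the full transcript, UTRs included.
    """
    if n_reads < 0:
        raise InvalidConfigError("n_reads must be >= 0")
    if mode not in ("rpf", "rna"):
        raise InvalidConfigError("mode must be 'rpf' or 'rna'")
    pause = pause_params or PauseParams()
    pause.validate()
    rng = np.random.default_rng(seed)
    total = gene.total_len
    if n_reads == 0:
        return PositionalCounts(gene.gene_id, np.zeros(total, dtype=np.int64))
    if mode == "rna":
        five = rng.integers(0, total, n_reads)
        return PositionalCounts(gene.gene_id, np.bincount(five, minlength=total))

    w = np.array(pause.frame_weights)[np.arange(gene.cds_len) % 3].astype(float)
    w[:3] *= pause.start_pause
    w[-3:] *= pause.stop_pause
    psites = rng.choice(gene.cds_len, size=n_reads, p=w / w.sum())
    five = gene.cds_start + psites - psite_offset
    kept = five[five >= 0]
    counts = np.bincount(kept, minlength=total)
    return PositionalCounts(gene.gene_id, counts, dropped=int(n_reads - kept.size))
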