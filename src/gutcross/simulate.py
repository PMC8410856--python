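"""Synthetic paired-cohort generator for infant gut-microbiome experiments.

Emulates the statistical structure of two 16S cohorts of one-year-olds: a
delivery-mode-like cohort (~83 samples, 23 exposed / 60 control) and a
perinatal-antibiotics-like cohort (~97 samples, 70 / 27), each dominated by a
Bacteroides-like focal genus that is depleted in the exposed group (58% vs
36% mean relative abundance in the emulated contrast). Counts follow a
Dirichlet-multinomial: per-sample composition drawn from a Dirichlet around
the group mean, reads from a multinomial at an uneven per-sample depth.
Predicted-pathway tables are linear mixtures of taxon counts through a
genome-content matrix, the same structure genome-content prediction tools
produce, including the per-taxon stratified decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .tables import (
    CohortMetadata,
    CountTable,
    StratifiedContributions,
    TableError,
)

__all__ = [
    "SimulationConfig",
    "GenomeContentMatrix",
    "CohortBundle",
    "default_baseline",
    "focal_effect_for_target",
    "simulate_cohort",
    "random_genome_content",
    "derive_pathway_table",
    "simulate_paired_cohorts",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def default_baseline(n_taxa: int = 20, focal_index: int = 0,
                     focal_abund: float = 0.58, decay: float = 0.9) -> np.ndarray:
    """Baseline mean composition: dominant focal taxon + geometric tail.

    The focal taxon takes ``focal_abund`` of the community; the remaining
    mass is spread over the other taxa with geometric decay ``decay``,
    emulating the skewed genus-level profile of the infant gut.
    """
    if not 0 < focal_abund < 1:
        raise ConfigError("focal_abund must be in (0, 1)")
    weights = decay ** np.arange(n_taxa - 1)
    tail = (1.0 - focal_abund) * weights / weights.sum()
    base = np.insert(tail, focal_index, focal_abund)
    return base


def focal_effect_for_target(baseline_focal: float, target_focal: float) -> float:
    """Multiplicative focal shift so the exposed mean lands on ``target_focal``.

    The exposed mean is the baseline with the focal entry scaled then
    renormalized, so the required factor solves
    b*f / (b*f + (1-b)) = t  =>  f = t(1-b) / (b(1-t)).
    """
    b, t = baseline_focal, target_focal
    return t * (1 - b) / (b * (1 - t))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_exposed, n_control : int
        Samples per exposure class (e.g. C-section vs vaginal).
    n_taxa, n_pathways : int
        Feature-space sizes for the taxon and derived pathway tables.
    focal_taxon_index : int
        Index of the dominant taxon carrying the exposure signal.
    baseline_mean_relabund : ndarray
        Control-group mean composition; must sum to 1.
    focal_effect : float
        Multiplicative shift of the focal taxon in the exposed group
        (< 1 depletes it); the mean is renormalized afterwards.
    concentration : float
        Dirichlet precision; smaller = more between-infant overdispersion.
    depth_range : (int, int)
        Uniform range of per-sample sequencing depths.
    seed : int
        Single cohort seed; all sub-draws use a deterministic stream split.
    covariate_rate : float or None
        If set, samples additionally get an independent Bernoulli binary
        covariate (e.g. an antibiotics label inside a delivery-mode cohort).
    """

    n_exposed: int
    n_control: int
    n_taxa: int = 20
    n_pathways: int = 60
    focal_taxon_index: int = 0
    baseline_mean_relabund: np.ndarray | None = None
    focal_effect: float = focal_effect_for_target(0.58, 0.36)
    concentration: float = 100.0
    depth_range: tuple[int, int] = (1200, 60000)
    seed: int = 0
    covariate_rate: float | None = None
    replacement_taxon_index: int | None = None
    sample_prefix: str = "S"

    def baseline(self) -> np.ndarray:
        if self.baseline_mean_relabund is None:
            return default_baseline(self.n_taxa, self.focal_taxon_index)
        return np.asarray(self.baseline_mean_relabund, dtype=float)

    def validate(self) -> None:
        base = self.baseline()
        if base.shape != (self.n_taxa,):
            raise ConfigError("baseline length must equal n_taxa")
        if (base < 0).any():
            raise ConfigError("baseline proportions must be non-negative")
        if abs(base.sum() - 1.0) > 1e-9:
            raise ConfigError("baseline proportions must sum to 1")
        if self.focal_effect <= 0:
            raise ConfigError("focal_effect must be positive")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigError("depth_range must satisfy 1 <= min <= max")
        if min(self.n_exposed, self.n_control) < 1:
            raise ConfigError("both classes need at least one sample")
        if not 0 <= self.focal_taxon_index < self.n_taxa:
            raise ConfigError("focal_taxon_index out of range")
        if self.replacement_taxon_index is not None:
            if not 0 <= self.replacement_taxon_index < self.n_taxa:
                raise ConfigError("replacement_taxon_index out of range")
            if self.replacement_taxon_index == self.focal_taxon_index:
                raise ConfigError("replacement taxon must differ from focal")


def _group_mean(base: np.ndarray, focal: int, effect: float,
                replacement: int | None = None) -> np.ndarray:
    """Exposed-group mean composition.

    The focal taxon is rescaled by ``effect``. Without a replacement taxon
    the vector is renormalized, spreading the lost (or gained) mass over the
    whole community; with one, that specific taxon absorbs the mass instead —
    the replacement structure real depletions show (a dominant genus's niche
    is taken over by particular taxa, not by everyone proportionally).
    """
    mean = base.copy()
    b = base[focal]
    # realized focal mean is b*e / (b*e + 1 - b) in both modes, so `effect`
    # means the same thing regardless of how the lost mass is redistributed
    target = b * effect / (b * effect + 1.0 - b)
    if replacement is None:
        mean[focal] *= effect
        return mean / mean.sum()
    mean[focal] = target
    mean[replacement] += b - target
    if mean[replacement] < 0:
        raise ConfigError("replacement taxon abundance would go negative")
    return mean


def simulate_cohort(config: SimulationConfig) -> tuple[CountTable, CohortMetadata]:
    """Draw one cohort's taxon count table and metadata.

    Exposed samples come from a Dirichlet-multinomial whose mean has the
    focal taxon rescaled by ``focal_effect`` and renormalized; control
    samples use the baseline mean. Depths are uniform over ``depth_range``.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    base = config.baseline()
    ss = np.random.SeedSequence(config.seed)
    s_depth, s_comp, s_cov = ss.spawn(3)
    rng_depth = np.random.default_rng(s_depth)
    rng_comp = np.random.default_rng(s_comp)

    n = config.n_exposed + config.n_control
    exposure = np.array([1] * config.n_exposed + [0] * config.n_control)
    depths = rng_depth.integers(config.depth_range[0], config.depth_range[1] + 1,
                                size=n)
    mean_exposed = _group_mean(base, config.focal_taxon_index,
                               config.focal_effect,
                               config.replacement_taxon_index)
    counts = np.zeros((config.n_taxa, n), dtype=np.int64)
    for j in range(n):
        mean = mean_exposed if exposure[j] == 1 else base
        p = rng_comp.dirichlet(config.concentration * mean)
        counts[:, j] = rng_comp.multinomial(depths[j], p)

    sample_ids = [f"{config.sample_prefix}{j + 1:04d}" for j in range(n)]
    taxon_ids = [f"G{t + 1:04d}" for t in range(config.n_taxa)]
    table = CountTable(pd.DataFrame(counts, index=taxon_ids, columns=sample_ids))

    meta = pd.DataFrame({"exposure": exposure}, index=pd.Index(sample_ids))
    if config.covariate_rate is not None:
        rng_cov = np.random.default_rng(s_cov)
        meta["covariate"] = rng_cov.binomial(1, config.covariate_rate, size=n)
    meta.index.name = "sample_id"
    return table, CohortMetadata(meta)


@dataclass
class GenomeContentMatrix:
    """Pathway copy number per unit taxon abundance (taxa x pathways)."""

    contributions: np.ndarray
    taxon_ids: list[str]
    pathway_ids: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.contributions, dtype=float)
        if c.shape != (len(self.taxon_ids), len(self.pathway_ids)):
            raise ConfigError("genome-content shape does not match ids")
        if (c < 0).any():
            raise ConfigError("copy numbers must be non-negative")
        if (c.sum(axis=0) == 0).any():
            empty = int(np.argmax(c.sum(axis=0) == 0))
            raise ConfigError(
                f"pathway {self.pathway_ids[empty]!r} has no contributing taxon")
        self.contributions = c


def random_genome_content(n_taxa: int, n_pathways: int,
                          focal_taxon_index: int = 0,
                          block: Sequence[int] = (),
                          seed: int = 0,
                          density: float = 0.3,
                          focal_load: float = 5.0,
                          taxon_ids: list[str] | None = None,
                          pathway_ids: list[str] | None = None) -> GenomeContentMatrix:
    """Sparse random genome-content map with a focal-taxon pathway block.

    Pathways in ``block`` are loaded predominantly on the focal taxon
    (copy number ``focal_load`` vs a weak 0.1-0.5 background), so their
    abundances track the focal taxon's; other pathways get Bernoulli(density)
    copy numbers in [0.5, 2].
    """
    rng = np.random.default_rng(seed)
    mask = rng.random((n_taxa, n_pathways)) < density
    copy = rng.uniform(0.5, 2.0, size=(n_taxa, n_pathways)) * mask
    block = np.asarray(sorted(block), dtype=int)
    if block.size:
        if block.min() < 0 or block.max() >= n_pathways:
            raise ConfigError("pathway block index out of range")
        bg_mask = rng.random((n_taxa, block.size)) < density
        copy[:, block] = rng.uniform(0.1, 0.5, size=(n_taxa, block.size)) * bg_mask
        copy[focal_taxon_index, block] = focal_load
    # every pathway needs at least one contributing genome
    for p in np.where(copy.sum(axis=0) == 0)[0]:
        copy[rng.integers(n_taxa), p] = rng.uniform(0.5, 2.0)
    t_ids = taxon_ids or [f"G{t + 1:04d}" for t in range(n_taxa)]
    p_ids = pathway_ids or [f"PWY{p + 1:04d}" for p in range(n_pathways)]
    return GenomeContentMatrix(copy, t_ids, p_ids)


def derive_pathway_table(
    taxa: CountTable, gcm: GenomeContentMatrix
) -> tuple[CountTable, StratifiedContributions]:
    """Mix taxon counts through the genome-content map into pathway counts.

    pathway(s, p) = sum_t count(s, t) * copy(t, p), rounded to integer; the
    stratified result keeps the unrounded per-taxon terms.
    """
    if taxa.feature_ids != gcm.taxon_ids:
        raise TableError("taxon ids of table and genome-content matrix differ")
    counts = taxa.matrix.astype(float)  # taxa x samples
    strat_values = gcm.contributions[:, :, None] * counts[:, None, :]
    strat = StratifiedContributions(
        strat_values, gcm.taxon_ids, gcm.pathway_ids, taxa.sample_ids
    )
    totals = strat.pathway_totals()
    pathway_table = CountTable(
        pd.DataFrame(
            np.rint(totals).astype(np.int64),
            index=gcm.pathway_ids,
            columns=taxa.sample_ids,
        )
    )
    return pathway_table, strat


class CohortBundle(NamedTuple):
    """Everything one synthetic cohort produces."""

    taxa: CountTable
    pathways: CountTable
    stratified: StratifiedContributions
    metadata: CohortMetadata
    gcm: GenomeContentMatrix


def simulate_paired_cohorts(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    gcm_a: GenomeContentMatrix,
    gcm_b: GenomeContentMatrix,
    shared_pathway_block: Sequence[int] = (),
) -> tuple[CohortBundle, CohortBundle]:
    """Two cohorts whose exposure signal rides the same pathway features.

    The cohorts may deplete different focal taxa, but when
    ``shared_pathway_block`` is non-empty both focal taxa must load on those
    pathways, so the block carries a concordant exposure signal in both
    cohorts — the structure that lets pathway-level models transfer across
    cohorts even when taxon-level ones do not.
    """
    block = np.asarray(sorted(shared_pathway_block), dtype=int)
    for cfg, gcm, name in ((config_a, gcm_a, "A"), (config_b, gcm_b, "B")):
        if block.size:
            if block.min() < 0 or block.max() >= len(gcm.pathway_ids):
                raise ConfigError(f"shared block out of range for cohort {name}")
            if not (gcm.contributions[cfg.focal_taxon_index, block] > 0).all():
                raise ConfigError(
                    f"cohort {name} focal taxon does not load on the shared block")
    bundles = []
    for cfg, gcm in ((config_a, gcm_a), (config_b, gcm_b)):
        taxa, meta = simulate_cohort(cfg)
        pathways, strat = derive_pathway_table(taxa, gcm)
        bundles.append(CohortBundle(taxa, pathways, strat, meta, gcm))
    return bundles[0], bundles[1]
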