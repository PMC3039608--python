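"""Configuration objects for the synthetic-data generator.

The generator emulates the two inputs of the analysis: a table of published
gene-disease association studies with ancestry labels, and multi-population
diploid genotypes for the genes those associations point at.  Population
allele frequencies follow the Balding-Nichols model, whose parametric FST
equals the divergence parameter F -- which is what makes estimator-recovery
tests possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "CountSpec",
    "PopulationSpec",
    "SimulationConfig",
]


@dataclass(frozen=True)
class CountSpec:
    """Truncated shifted-Poisson spec for integer counts.

    Draws ``min + Poisson(mean - min)`` clipped to ``[min, max]``.
    """

    min: int
    max: int
    mean: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"need min <= mean <= max, got {self}")
        if self.min < 0:
            raise ValueError("counts must be non-negative")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = self.min + rng.poisson(self.mean - self.min, size=size)
        return np.clip(draws, self.min, self.max)


@dataclass(frozen=True)
class PopulationSpec:
    """One analysis population: label, diploid sample size, divergence F.

    ``fst`` is the Balding-Nichols divergence of this population from the
    shared ancestral frequency; it must lie in [0, 1).  F = 0 means the
    population sits exactly at the ancestral frequency.
    """

    label: str
    n_diploid: int
    fst: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"divergence F must be in [0, 1), got {self.fst}")
        if self.n_diploid < 2:
            raise ValueError("need at least 2 diploid samples per population")


def _default_populations() -> tuple[PopulationSpec, ...]:
    # HapMap-like sample sizes: 60 CEU-like, 90 pooled CHB+JPT-like, 60 YRI-like.
    return (
        PopulationSpec("EUR", 60, 0.10),
        PopulationSpec("EAS", 90, 0.10),
        PopulationSpec("AFR", 60, 0.15),
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    n_genes:
        Genes in the simulated "genome"; must be at least ``n_associations``
        (each association references a distinct gene) and the surplus forms
        the genome-wide background pool for the resampling test.
    snps_per_gene:
        Count distribution for SNPs per gene.
    populations:
        Analysis populations with diploid sample sizes and divergence F.
    gene_divergence_range:
        Genes vary in how differentiated they are: each gene g draws a
        multiplier d_g ~ Uniform(range) applied to every population's F
        (clipped to [0, 0.98]).  ``(1.0, 1.0)`` disables the variation.
    n_associations:
        Gene-disease associations simulated, one gene each.
    studies_per_continent:
        Count distribution for the number of studies per association in each
        of Europe and East Asia.
    frac_heterogeneous:
        Fraction of associations causal in exactly one continent; the rest
        are causal in both.
    divergence_coupling:
        Strength in [0, 1] with which heterogeneous associations are steered
        towards the most divergent genes (1 = deterministic top ranks,
        0 = no relation between heterogeneity and divergence).
    power_true / alpha_false:
        Probability that a study is positive when the association is causal /
        not causal in the study's continent.
    frac_other_continent:
        Per-association probability of one extra study from a minor-ancestry
        or mixed label (exercises the ancestry normalisation path).
    outgroup_error_rate:
        Per-species probability that the simulated outgroup allele is the
        derived rather than the ancestral human allele.
    missing_rate:
        Per-call probability of a missing genotype.
    ancestral_freq_range:
        Support of the Uniform prior on the ancestral derived-allele
        frequency; bounded away from 0/1 so most SNPs are polymorphic.
    annotation_probs:
        (intronic, exonic, UTR) probabilities for per-SNP annotation class.
    """

    n_genes: int = 120
    snps_per_gene: CountSpec = field(default_factory=lambda: CountSpec(4, 40, 14))
    populations: tuple[PopulationSpec, ...] = field(default_factory=_default_populations)
    gene_divergence_range: tuple[float, float] = (0.25, 1.75)
    n_associations: int = 40
    studies_per_continent: CountSpec = field(default_factory=lambda: CountSpec(8, 16, 10))
    frac_heterogeneous: float = 0.5
    divergence_coupling: float = 1.0
    power_true: float = 0.8
    alpha_false: float = 0.05
    frac_other_continent: float = 0.10
    marker_frac: float = 0.10
    outgroup_error_rate: float = 0.01
    missing_rate: float = 0.02
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    annotation_probs: tuple[float, float, float] = (0.95, 0.02, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_heterogeneous",
            "divergence_coupling",
            "power_true",
            "alpha_false",
            "frac_other_continent",
            "marker_frac",
            "outgroup_error_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < self.n_associations:
            raise ValueError("n_genes must cover the genes referenced by associations")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if abs(sum(self.annotation_probs) - 1.0) > 1e-9:
            raise ValueError("annotation_probs must sum to 1")
        if len({p.label for p in self.populations}) != len(self.populations):
            raise ValueError("population labels must be unique")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
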