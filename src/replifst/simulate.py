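"""Synthetic association-study records and multi-population genotypes.

Three generators, mirroring the two real-world inputs of the analysis plus
the ground truth that real data never exposes:

* :func:`simulate_population_frequencies` -- Balding-Nichols per-population
  derived-allele frequencies for every SNP of every gene;
* :func:`simulate_genotype_table` -- diploid genotypes binomially sampled
  from those frequencies, with outgroup alleles for two species and missing
  calls;
* :func:`simulate_study_records` -- published-study records (gene, disease,
  outcome, ancestry label, sample size, year) drawn from a power /
  false-positive model with per-continent causal status.

All randomness flows through one ``numpy`` Generator so a fixed seed gives
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "GenotypeTable",
    "simulate_population_frequencies",
    "simulate_genotype_table",
    "make_ground_truth",
    "simulate_study_records",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))

#: ancestry labels the record generator emits, keyed by true continent
CONTINENT_LABELS = {
    "Europe": ["Caucasian", "Finnish", "European American", "Italian", "German"],
    "EastAsia": ["Japanese", "Chinese", "Korean", "Han Chinese"],
    "Other": ["Iranian", "Mixed", "African American", "Brazilian", "Indian"],
}


@dataclass
class GenotypeTable:
    """SNP x sample diploid dosage matrix with its sidecar metadata.

    ``dosages`` holds derived-allele counts per diploid genotype
    (0/1/2; -1 = missing call).  ``snps`` carries one row per SNP
    (gene, 0-based position, annotation class, ancestral/derived alleles,
    outgroup alleles for two species); ``samples`` maps each sample to its
    population.
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.snps), len(self.samples)):
            raise ValueError("dosage matrix shape does not match metadata")
        bad = ~np.isin(self.dosages, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def pop_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples belonging to one population."""
        return np.flatnonzero((self.samples["population"] == label).to_numpy())

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.snps.loc[mask].reset_index(drop=True),
            self.dosages[np.asarray(mask)],
            self.samples,
        )


def simulate_population_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-SNP ancestral and per-population derived-allele frequencies.

    The ancestral frequency p0 of each SNP is Uniform on
    ``config.ancestral_freq_range``; each population's frequency is
    Beta(p0(1-F)/F, (1-p0)(1-F)/F) with F the population's divergence times
    the gene's divergence multiplier.  F = 0 returns p0 exactly.

    Returns a frequency table with one row per SNP: ``snp_id, gene, pos,
    annotation, ancestral, derived, gene_divergence, p0`` and one ``p_<POP>``
    column per population.
    """
    rng = config.rng() if rng is None else rng

    genes = np.array([f"G{i:04d}" for i in range(config.n_genes)])
    n_snps_per_gene = config.snps_per_gene.sample(rng, config.n_genes)
    lo, hi = config.gene_divergence_range
    gene_div = rng.uniform(lo, hi, config.n_genes)

    gene_idx = np.repeat(np.arange(config.n_genes), n_snps_per_gene)
    m = gene_idx.size
    p0 = rng.uniform(*config.ancestral_freq_range, m)

    # within-gene 0-based positions, 1 kb apart; genes laid end to end on chr1
    offsets = np.concatenate([np.arange(k) for k in n_snps_per_gene])
    gene_start = np.concatenate([[0], np.cumsum(n_snps_per_gene)[:-1]]) * 2000
    pos = gene_start[gene_idx] + offsets * 1000

    anc = _BASES[rng.integers(0, 4, m)]
    der = _BASES[(np.searchsorted(_BASES, anc) + rng.integers(1, 4, m)) % 4]
    annotation = rng.choice(
        ["intronic", "exonic", "UTR"], size=m, p=list(config.annotation_probs)
    )

    table = pd.DataFrame(
        {
            "snp_id": [f"rs{i:06d}" for i in range(m)],
            "gene": genes[gene_idx],
            "pos": pos,
            "annotation": annotation,
            "ancestral": anc,
            "derived": der,
            "gene_divergence": gene_div[gene_idx],
            "p0": p0,
        }
    )

    for popspec in config.populations:
        F = np.clip(popspec.fst * gene_div[gene_idx], 0.0, 0.98)
        pk = np.where(F == 0, p0, _balding_nichols(rng, p0, F))
        table[f"p_{popspec.label}"] = pk
    return table


def _balding_nichols(
    rng: np.random.Generator, p0: np.ndarray, F: np.ndarray
) -> np.ndarray:
    with np.errstate(divide="ignore"):
        scale = np.where(F > 0, (1.0 - F) / np.maximum(F, 1e-12), np.inf)
    a = np.where(F > 0, p0 * scale, 1.0)  # dummy params where F == 0
    b = np.where(F > 0, (1.0 - p0) * scale, 1.0)
    return rng.beta(a, b)


def simulate_genotype_table(
    freqs: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Binomially sample diploid dosages from a frequency table.

    Each genotype is Binomial(2, p_k) for the sample's population; missing
    calls are injected at ``config.missing_rate``; each outgroup species
    carries the ancestral allele independently with probability
    ``1 - outgroup_error_rate`` (and otherwise the derived allele).
    """
    rng = config.rng() if rng is None else rng
    m = len(freqs)

    sample_ids, sample_pops, blocks = [], [], []
    for popspec in config.populations:
        pk = freqs[f"p_{popspec.label}"].to_numpy()
        geno = rng.binomial(2, pk[:, None], size=(m, popspec.n_diploid))
        blocks.append(geno.astype(np.int8))
        sample_ids += [f"{popspec.label}_{j:03d}" for j in range(popspec.n_diploid)]
        sample_pops += [popspec.label] * popspec.n_diploid
    dosages = np.concatenate(blocks, axis=1)

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = -1

    anc = freqs["ancestral"].to_numpy()
    der = freqs["derived"].to_numpy()
    snps = freqs[
        ["snp_id", "gene", "pos", "annotation", "ancestral", "derived"]
    ].copy()
    for species in ("chimp", "macaque"):
        err = rng.random(m) < config.outgroup_error_rate
        snps[f"outgroup_{species}"] = np.where(err, der, anc)
    snps["chrom"] = "chr1"

    samples = pd.DataFrame({"sample_id": sample_ids, "population": sample_pops})
    return GenotypeTable(snps.reset_index(drop=True), dosages, samples)


def make_ground_truth(
    config: SimulationConfig,
    freqs: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign associations to genes and draw per-continent causal status.

    ``frac_heterogeneous`` of the associations are causal in exactly one
    continent (which one is a fair coin); the rest are causal in both.
    With coupling strength s, heterogeneous status is steered towards the
    most divergent genes: each association's priority is
    ``s * divergence_rank + (1-s) * Uniform`` and the top
    ``n_heterogeneous`` priorities get the heterogeneous label.  s = 1
    places them exactly on the most divergent genes, s = 0 is random.

    Returns one row per association: ``gene, disease, causal_EUR,
    causal_EAS, gene_divergence``.
    """
    rng = config.rng() if rng is None else rng
    gene_div = (
        freqs.groupby("gene", sort=True)["gene_divergence"].first().sort_index()
    )
    genes = rng.choice(gene_div.index.to_numpy(), config.n_associations, replace=False)
    div = gene_div.loc[genes].to_numpy()

    n = config.n_associations
    n_het = int(round(config.frac_heterogeneous * n))
    rank = pd.Series(div).rank(method="first").to_numpy() / n  # high rank = divergent
    s = config.divergence_coupling
    priority = s * rank + (1.0 - s) * rng.random(n)
    het = np.zeros(n, bool)
    het[np.argsort(-priority)[:n_het]] = True

    het_in_eur = rng.random(n) < 0.5
    causal_eur = ~het | het_in_eur
    causal_eas = ~het | ~het_in_eur

    return pd.DataFrame(
        {
            "gene": genes,
            "disease": [f"D{i:03d}" for i in range(n)],
            "causal_EUR": causal_eur,
            "causal_EAS": causal_eas,
            "gene_divergence": div,
        }
    )


def simulate_study_records(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
    freqs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw published-study records for every association in ``truth``.

    Per continent (Europe, East Asia) each association receives
    ``studies_per_continent`` studies; a study is positive with probability
    ``power_true`` when the association is causal in that continent and
    ``alpha_false`` otherwise.  Ancestry labels are free-text strings drawn
    from continent-specific pools (plus occasional minor-ancestry records),
    sample sizes are log-normal, years Uniform over 1990-2010.  When a
    frequency table is supplied, a fraction ``config.marker_frac`` of the
    records report the actual SNP marker tested (drawn from the gene's
    SNPs), mirroring how rarely real study records carry marker IDs.
    """
    rng = config.rng() if rng is None else rng
    gene_markers: dict[str, np.ndarray] = {}
    if freqs is not None:
        gene_markers = {
            g: grp["snp_id"].to_numpy() for g, grp in freqs.groupby("gene")
        }

    def _marker(gene: str) -> str:
        pool = gene_markers.get(gene)
        if pool is None or rng.random() >= config.marker_frac:
            return ""
        return str(rng.choice(pool))

    rows: list[dict] = []
    rec = 0
    for assoc in truth.itertuples(index=False):
        for continent, causal in (
            ("Europe", assoc.causal_EUR),
            ("EastAsia", assoc.causal_EAS),
        ):
            k = int(config.studies_per_continent.sample(rng, 1)[0])
            p_pos = config.power_true if causal else config.alpha_false
            for _ in range(k):
                rows.append(
                    {
                        "record_id": f"R{rec:05d}",
                        "gene": assoc.gene,
                        "disease": assoc.disease,
                        "outcome": "Y" if rng.random() < p_pos else "N",
                        "ancestry_label": str(
                            rng.choice(CONTINENT_LABELS[continent])
                        ),
                        "sample_size": int(np.round(rng.lognormal(6.0, 0.6))),
                        "year": int(rng.integers(1990, 2011)),
                        "marker_id": _marker(assoc.gene),
                    }
                )
                rec += 1
        if rng.random() < config.frac_other_continent:
            rows.append(
                {
                    "record_id": f"R{rec:05d}",
                    "gene": assoc.gene,
                    "disease": assoc.disease,
                    "outcome": "Y" if rng.random() < config.alpha_false else "N",
                    "ancestry_label": str(rng.choice(CONTINENT_LABELS["Other"])),
                    "sample_size": int(np.round(rng.lognormal(6.0, 0.6))),
                    "year": int(rng.integers(1990, 2011)),
                    "marker_id": "",
                }
            )
            rec += 1
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypeTable, pd.DataFrame, pd.DataFrame]:
    """One-stop generation: (frequencies, genotypes, truth, study records).

    A single Generator seeded from ``config.seed`` feeds all four stages, so
    the whole bundle is reproducible from the config alone.
    """
    rng = config.rng()
    freqs = simulate_population_frequencies(config, rng)
    genotypes = simulate_genotype_table(freqs, config, rng)
    truth = make_ground_truth(config, freqs, rng)
    records = simulate_study_records(config, truth, rng, freqs=freqs)
    return freqs, genotypes, truth, records
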