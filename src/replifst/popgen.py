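"""Per-SNP and per-gene population-differentiation statistics.

The central statistic is the Weir-Cockerham method-of-moments FST estimator
(theta) computed from allele counts, applied pairwise between populations
and globally across all of them.  Per gene, theta is aggregated three ways:
the mean over all SNPs, the maximum over all SNPs, and the mean over
tagSNPs only (a greedy r^2 >= 0.8 set cover per population, intersected
across populations).  The module also computes the extreme-frequency
percentage (SNPs rare in one continent but common in the other) and the
ancestral/derived status of each population's major allele by two-outgroup
parsimony.

Negative theta values (pure sampling noise around 0) are retained in all
aggregates by default; clamping them at 0 would bias gene means upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "allele_frequencies",
    "allele_counts",
    "fst_wc",
    "fst_wc_vector",
    "pairwise_fst_table",
    "aggregate_gene_fst",
    "pairwise_r2",
    "select_tag_snps",
    "extreme_frequency_pct",
    "classify_major_allele",
    "classify_table",
    "remove_monomorphic",
    "gene_fst_profiles",
]


# ---------------------------------------------------------------------------
# allele counts and frequencies


def allele_counts(
    gt: GenotypeTable, pops: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Derived-allele and total allele counts per SNP per population.

    Returns ``(n, x, pops)`` where ``n[k, j]`` is the number of successfully
    typed alleles (2 x non-missing samples) and ``x[k, j]`` the number of
    derived alleles, for population k at SNP j.
    """
    pops = gt.populations if pops is None else pops
    m = len(gt.snps)
    n = np.zeros((len(pops), m))
    x = np.zeros((len(pops), m))
    for k, pop in enumerate(pops):
        cols = gt.pop_columns(pop)
        d = gt.dosages[:, cols]
        ok = d >= 0
        n[k] = 2 * ok.sum(axis=1)
        x[k] = np.where(ok, d, 0).sum(axis=1)
    return n, x, pops


def allele_frequencies(
    gt: GenotypeTable, pops: list[str] | None = None
) -> pd.DataFrame:
    """Per-SNP per-population derived-allele frequency.

    Frequency = derived-allele count / (2 x non-missing samples); NaN where
    a population has no non-missing call.  Columns are population labels,
    index is the SNP id.
    """
    n, x, pops = allele_counts(gt, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, x / np.maximum(n, 1), np.nan)
    return pd.DataFrame(freq.T, index=gt.snps["snp_id"].to_numpy(), columns=pops)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def fst_wc_vector(n: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Weir-Cockerham theta per SNP from allele counts of r populations.

    ``n`` (r, m) holds sampled-allele totals, ``x`` (r, m) derived-allele
    counts.  Populations with n = 0 at a SNP are dropped from that SNP's
    estimate.  Returns theta per SNP; NaN where fewer than two populations
    have data or the pooled sample is monomorphic.  Negative estimates are
    retained.

    With n_i alleles at frequency p_i over r populations:

        nbar = sum(n_i)/r
        nc   = (sum(n_i) - sum(n_i^2)/sum(n_i)) / (r - 1)
        pbar = sum(n_i p_i)/sum(n_i)
        s2   = sum(n_i (p_i - pbar)^2) / ((r - 1) nbar)
        a = (nbar/nc) [s2 - (pbar(1-pbar) - s2 (r-1)/r) / (nbar - 1)]
        b = (nbar/(nbar-1)) [pbar(1-pbar) - s2 (r-1)/r]
        theta = a / (a + b)
    """
    n = np.asarray(n, float)
    x = np.asarray(x, float)
    if n.ndim == 1:
        n, x = n[:, None], x[:, None]
    valid = n > 0
    r = valid.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, x / np.maximum(n, 1), 0.0)
        nsum = n.sum(axis=0)
        nbar = nsum / np.maximum(r, 1)
        nc = (nsum - (n**2).sum(axis=0) / np.maximum(nsum, 1)) / np.maximum(r - 1, 1)
        pbar = (n * p).sum(axis=0) / np.maximum(nsum, 1)
        s2 = (n * (p - pbar) ** 2 * valid).sum(axis=0) / np.maximum(
            (r - 1) * nbar, 1e-300
        )
        pq = pbar * (1.0 - pbar)
        a = (nbar / nc) * (s2 - (pq - s2 * (r - 1) / r) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pq - s2 * (r - 1) / r)
        theta = a / (a + b)

    undefined = (r < 2) | (pbar <= 0) | (pbar >= 1) | ~np.isfinite(theta)
    if undefined.any():
        logger.debug("%d SNPs with undefined theta (monomorphic or <2 pops)",
                     int(undefined.sum()))
    return np.where(undefined, np.nan, theta)


def fst_wc(n, x) -> float:
    """Scalar Weir-Cockerham theta for one SNP (see :func:`fst_wc_vector`)."""
    n = np.asarray(n, float)
    if (n > 0).sum() < 2:
        raise ValueError("need at least two populations with data")
    return float(fst_wc_vector(n[:, None], np.asarray(x, float)[:, None])[0])


#: population pairs analysed throughout, plus the all-population global value
DEFAULT_PAIRS = (("EUR", "EAS"), ("EUR", "AFR"), ("EAS", "AFR"))


def pairwise_fst_table(
    gt: GenotypeTable,
    pairs: tuple[tuple[str, str], ...] | None = None,
    include_global: bool = True,
    pool_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-SNP theta for each population pair and (optionally) globally.

    ``pool_map`` relabels raw sample populations into analysis populations
    before counting (e.g. pooling two East Asian panels into one).  Columns
    are ``"EUR_EAS"``-style pair names plus ``"GLOBAL"``; index is snp_id.
    """
    gt = _pooled(gt, pool_map)
    pops = gt.populations
    if pairs is None:
        pairs = tuple(p for p in DEFAULT_PAIRS if p[0] in pops and p[1] in pops)
    n, x, pops = allele_counts(gt)
    idx = {p: k for k, p in enumerate(pops)}
    out = {}
    for a, b in pairs:
        rows = [idx[a], idx[b]]
        out[f"{a}_{b}"] = fst_wc_vector(n[rows], x[rows])
    if include_global and len(pops) > 2:
        out["GLOBAL"] = fst_wc_vector(n, x)
    return pd.DataFrame(out, index=gt.snps["snp_id"].to_numpy())


def _pooled(gt: GenotypeTable, pool_map: dict[str, str] | None) -> GenotypeTable:
    if not pool_map:
        return gt
    samples = gt.samples.copy()
    samples["population"] = samples["population"].map(lambda p: pool_map.get(p, p))
    return GenotypeTable(gt.snps, gt.dosages, samples)


def aggregate_gene_fst(
    thetas: pd.Series, mode: str = "mean", tags: set[str] | None = None
) -> float:
    """Collapse per-SNP thetas of one gene to a single value.

    ``mode``: ``mean`` (over SNPs with defined theta), ``max``, or
    ``tag_mean`` (mean over the supplied tagSNP ids only).  NaN when no
    defined theta is available for the mode.
    """
    t = thetas.dropna()
    if mode == "tag_mean":
        if tags is None:
            raise ValueError("tag_mean requires a tag set")
        t = t[t.index.isin(tags)]
    if t.empty:
        return float("nan")
    if mode in ("mean", "tag_mean"):
        return float(t.mean())
    if mode == "max":
        return float(t.max())
    raise ValueError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# linkage disequilibrium and tagSNPs


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Missing calls (< 0) are excluded pairwise-complete.  Requires both SNPs
    polymorphic in the retained samples.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("need >= 2 pairwise-complete calls of polymorphic SNPs")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """All-pairs composite r^2 within one population (rows = SNPs)."""
    m = d.shape[0]
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            try:
                out[i, j] = out[j, i] = pairwise_r2(d[i], d[j])
            except ValueError:
                pass
    return out


def select_tag_snps(
    gt: GenotypeTable,
    gene: str,
    r2_min: float = 0.8,
    maf_min: float = 0.1,
    call_min: float = 0.75,
    pops: list[str] | None = None,
    pool_map: dict[str, str] | None = None,
) -> set[str]:
    """Greedy tagSNP cover for one gene, intersected across populations.

    Per population, SNPs failing the MAF (>= ``maf_min``) or call-rate
    (>= ``call_min``) filters are ineligible.  The greedy cover repeatedly
    picks the eligible SNP tagging (r^2 >= ``r2_min``) the most untagged
    eligible SNPs, breaking ties by lower genomic position, until all
    eligible SNPs are covered.  The final tag set is the intersection of the
    per-population tag sets.  Minimality is not promised; the contract is
    that within each population every eligible SNP has r^2 >= ``r2_min``
    with at least one of that population's tags.
    """
    gt = _pooled(gt, pool_map)
    pops = gt.populations if pops is None else pops
    mask = (gt.snps["gene"] == gene).to_numpy()
    if not mask.any():
        logger.warning("gene %s has no SNPs", gene)
        return set()
    sub = gt.subset_snps(mask)
    snp_ids = sub.snps["snp_id"].to_numpy()
    pos = sub.snps["pos"].to_numpy()

    tag_sets: list[set[str]] = []
    for pop in pops:
        cols = sub.pop_columns(pop)
        d = sub.dosages[:, cols].astype(float)
        ok = d >= 0
        call_rate = ok.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(ok, d, 0).sum(axis=1) / np.maximum(2 * ok.sum(axis=1), 1)
        maf = np.minimum(freq, 1 - freq)
        eligible = np.flatnonzero((call_rate >= call_min) & (maf >= maf_min))
        if eligible.size == 0:
            logger.warning("gene %s: no eligible SNPs in population %s", gene, pop)
            tag_sets.append(set())
            continue
        r2 = _r2_matrix(d[eligible])
        covers = np.nan_to_num(r2) >= r2_min
        np.fill_diagonal(covers, True)
        uncovered = np.ones(eligible.size, bool)
        tags: set[str] = set()
        while uncovered.any():
            gain = (covers & uncovered).sum(axis=1)
            best = gain.max()
            cand = np.flatnonzero(gain == best)
            pick = cand[np.argmin(pos[eligible][cand])]  # tie: lower position
            tags.add(snp_ids[eligible[pick]])
            uncovered &= ~covers[pick]
        tag_sets.append(tags)

    return set.intersection(*tag_sets) if tag_sets else set()


# ---------------------------------------------------------------------------
# extreme frequencies


def extreme_frequency_pct(
    maf_a: np.ndarray, maf_b: np.ndarray, rare: float = 0.1, common: float = 0.2
) -> float:
    """Percent of SNPs rare in exactly one population and common in the other.

    Rare means MAF < ``rare``; common means MAF > ``common`` (both strict,
    so a MAF of exactly 0.2 does not count as common).  The denominator is
    the number of SNPs with a defined MAF in both populations; NaN when
    empty.
    """
    maf_a = np.asarray(maf_a, float)
    maf_b = np.asarray(maf_b, float)
    ok = ~np.isnan(maf_a) & ~np.isnan(maf_b)
    if not ok.any():
        return float("nan")
    a, b = maf_a[ok], maf_b[ok]
    hit = ((a < rare) & (b > common)) | ((b < rare) & (a > common))
    return float(100.0 * hit.sum() / ok.sum())


# ---------------------------------------------------------------------------
# ancestral / derived classification


def classify_major_allele(
    derived_freq: float, ancestral_ok: bool, tie: str = "DER"
) -> str:
    """Long-term evolutionary status of a population's major allele.

    Returns ``"DER"`` when the derived allele is the major one (frequency
    > 0.5), ``"ANC"`` when the ancestral allele is, and ``"excluded"``
    when no ancestral call is available or the frequency is undefined.
    A frequency of exactly 0.5 goes to ``tie`` (default DER, reading the
    ">= 0.5 is major" rule on the derived allele).
    """
    if not ancestral_ok or derived_freq is None or np.isnan(derived_freq):
        return "excluded"
    if derived_freq > 0.5:
        return "DER"
    if derived_freq < 0.5:
        return "ANC"
    return tie


def ancestral_calls(snps: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Parsimony ancestral allele per SNP from two outgroup species.

    A call is made only when both outgroup alleles agree and match one of
    the two human alleles.  Returns ``(ok, ancestral_is_derived)``:
    ``ok`` marks callable SNPs and ``ancestral_is_derived`` flags SNPs
    where the inferred ancestral state is the allele labelled "derived" in
    the table (outgroup errors make the inference flip).
    """
    c = snps["outgroup_chimp"].to_numpy()
    q = snps["outgroup_macaque"].to_numpy()
    anc = snps["ancestral"].to_numpy()
    der = snps["derived"].to_numpy()
    agree = c == q
    matches = (c == anc) | (c == der)
    ok = agree & matches
    return ok, ok & (c == der)


def classify_table(
    gt: GenotypeTable, pops: list[str] | None = None, tie: str = "DER"
) -> pd.DataFrame:
    """ANC/DER/excluded status per SNP per population (index snp_id)."""
    pops = gt.populations if pops is None else pops
    freqs = allele_frequencies(gt, pops)
    ok, flipped = ancestral_calls(gt.snps)
    out = {}
    for pop in pops:
        f = freqs[pop].to_numpy().astype(float)
        # frequency of the INFERRED derived allele
        f_inf = np.where(flipped, 1.0 - f, f)
        out[pop] = [
            classify_major_allele(fi, oki, tie) for fi, oki in zip(f_inf, ok)
        ]
    return pd.DataFrame(out, index=gt.snps["snp_id"].to_numpy())


# ---------------------------------------------------------------------------
# filters and gene profiles


def remove_monomorphic(
    gt: GenotypeTable, pops: tuple[str, str] = ("EUR", "EAS")
) -> GenotypeTable:
    """Drop SNPs monomorphic in the pooled sample of the two populations.

    Mirrors the pre-filter applied before continental analyses; such SNPs
    have undefined pairwise theta between the two populations, so removing
    them never changes the pairwise aggregates computed on the remainder.
    """
    n, x, _ = allele_counts(gt, list(pops))
    nsum = n.sum(axis=0)
    xsum = x.sum(axis=0)
    poly = (xsum > 0) & (xsum < nsum) & (nsum > 0)
    return gt.subset_snps(poly)


@dataclass
class GeneProfileConfig:
    """Knobs for per-gene profiling."""

    r2_min: float = 0.8
    maf_min: float = 0.1
    call_min: float = 0.75
    rare: float = 0.1
    common: float = 0.2
    extreme_pair: tuple[str, str] = ("EUR", "EAS")
    clamp_negative: bool = False  # clamp theta at 0 before aggregating
    tag_pops: list[str] | None = None


def gene_fst_profiles(
    gt: GenotypeTable,
    pairs: tuple[tuple[str, str], ...] | None = None,
    config: GeneProfileConfig | None = None,
    pool_map: dict[str, str] | None = None,
    compute_tags: bool = True,
) -> pd.DataFrame:
    """Per-gene FST profile across population pairs and pooling modes.

    One row per gene with ``n_snps``, ``pct_intronic``, ``n_tag_snps``,
    ``extreme_freq_pct`` (for ``config.extreme_pair``) and, per pair column
    ``<A>_<B>`` plus ``GLOBAL``: ``mean_fst_*``, ``max_fst_*`` and (when
    tags are computed) ``tag_mean_fst_*``.
    """
    config = config or GeneProfileConfig()
    gt = _pooled(gt, pool_map)
    theta = pairwise_fst_table(gt, pairs=pairs)
    if config.clamp_negative:
        theta = theta.clip(lower=0.0)
    freqs = allele_frequencies(gt)
    maf = np.minimum(freqs, 1 - freqs)
    snps = gt.snps.set_index("snp_id")
    theta["gene"] = snps["gene"]

    rows = []
    for gene, sub in theta.groupby("gene", sort=True):
        row: dict = {"gene": gene, "n_snps": len(sub)}
        ann = snps.loc[sub.index, "annotation"]
        row["pct_intronic"] = 100.0 * (ann == "intronic").mean()
        tags: set[str] | None = None
        if compute_tags:
            tags = select_tag_snps(
                gt,
                gene,
                r2_min=config.r2_min,
                maf_min=config.maf_min,
                call_min=config.call_min,
                pops=config.tag_pops,
            )
            row["n_tag_snps"] = len(tags)
        a, b = config.extreme_pair
        if a in maf.columns and b in maf.columns:
            row["extreme_freq_pct"] = extreme_frequency_pct(
                maf.loc[sub.index, a], maf.loc[sub.index, b],
                rare=config.rare, common=config.common,
            )
        for col in [c for c in theta.columns if c != "gene"]:
            row[f"mean_fst_{col}"] = aggregate_gene_fst(sub[col], "mean")
            row[f"max_fst_{col}"] = aggregate_gene_fst(sub[col], "max")
            if tags is not None:
                row[f"tag_mean_fst_{col}"] = aggregate_gene_fst(
                    sub[col], "tag_mean", tags
                )
        rows.append(row)
    return pd.DataFrame(rows)
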