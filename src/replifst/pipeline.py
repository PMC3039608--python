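"""End-to-end analysis: simulate -> curate -> FST -> phi -> report tables.

:func:`run_full_analysis` reproduces the complete analysis ladder on a
synthetic dataset: it builds the Global and Continental association sets,
profiles every gene's differentiation, computes the discordance index phi,
and emits

* a Global-Set comparison of disease-gene mean FST against genome-wide
  background sets (gene-resampling test),
* a correlation grid of phi against FST under the three pooling modes
  (gene mean, per SNP, tagSNPs) for the full and conservative sets,
* forward stepwise regressions of phi on eight candidate predictors, with
  and without the two largest genes (whose SNP counts dominate the
  SNP-level analyses),
* per-population ancestral/derived major-allele tables split at the median
  replicability, with Yates-corrected chi-square tests,
* a marker-level phi-FST correlation when study records carry marker IDs,

together with a machine-readable run manifest.  Everything is driven by
one seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .curation import (
    apply_conservative_filter,
    assign_continents,
    build_continental_set,
    build_global_set,
)
from .discordance import add_phi
from .inference import (
    derived_allele_test,
    forward_stepwise,
    median_split,
    resampling_mean_fst_test,
    spearman_correlation,
)
from .popgen import (
    GeneProfileConfig,
    classify_table,
    gene_fst_profiles,
    pairwise_fst_table,
    remove_monomorphic,
    select_tag_snps,
)
from .simulate import GenotypeTable, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisThresholds",
    "build_predictor_matrix",
    "derived_allele_strata",
    "phi_fst_dataset",
    "run_full_analysis",
]

#: the eight candidate predictors of phi
PREDICTORS = [
    "mean_fst",
    "n_snps",
    "pct_intronic",
    "n_studies",
    "n_studies_eur",
    "n_studies_eas",
    "mean_sample_size",
    "mean_year",
]


@dataclass
class AnalysisThresholds:
    """Curation and analysis thresholds, surfaced in the run manifest."""

    min_studies: int = 4
    min_per_continent: int = 4
    conservative_pct: float = 50.0
    min_snps_for_mean_fst: int = 10
    n_resamples: int = 10_000
    p_enter: float = 0.05
    p_remove: float = 0.10
    study_count_cutoffs: tuple[int, ...] = (0,)
    drop_diseases: tuple[str, ...] = ()


def build_predictor_matrix(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    fst_column: str = "mean_fst_EUR_EAS",
    min_snps: int | None = None,
    include_extreme_freq: bool = False,
) -> pd.DataFrame:
    """Join Continental-Set summaries with gene profiles into a model matrix.

    One row per association with the eight candidate predictors and the
    response ``phi``; rows with any missing value are dropped and logged.
    ``min_snps`` excludes genes too short for a reliable mean FST.
    """
    prof_cols = ["gene", "n_snps", "pct_intronic", fst_column, "extreme_freq_pct"]
    merged = summaries.merge(
        profiles[[c for c in prof_cols if c in profiles.columns]],
        on="gene",
        how="left",
    )
    merged = merged.rename(columns={fst_column: "mean_fst"})
    cols = PREDICTORS + (["extreme_freq_pct"] if include_extreme_freq else [])
    keep = merged[cols + ["phi"]].notna().all(axis=1)
    if min_snps is not None:
        keep &= merged["n_snps"] >= min_snps
    dropped = (~keep).sum()
    if dropped:
        logger.info("predictor matrix: dropped %d incomplete/short-gene rows", dropped)
    out = merged[keep].reset_index(drop=True)
    return out[["gene", "disease", "phi"] + cols]


def derived_allele_strata(
    global_summaries: pd.DataFrame,
    gt: GenotypeTable,
    pops: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Ancestral/derived major-allele counts by replicability stratum.

    Associations are split at the median replicability (ties in both
    strata); each association contributes the ANC/DER classification counts
    of all SNPs in its gene, once per association.  Returns the long table
    (population x stratum with ANC, DER, der_pct, n_assoc) and per-population
    ``(chi2, p)`` from the Yates-corrected test.
    """
    pops = gt.populations if pops is None else pops
    status = classify_table(gt, pops)
    status["gene"] = gt.snps.set_index("snp_id")["gene"]
    per_gene = {
        pop: status.groupby("gene")[pop].value_counts().unstack(fill_value=0)
        for pop in pops
    }
    low, high, med = median_split(global_summaries)

    rows, tests = [], {}
    for pop in pops:
        counts = per_gene[pop]
        stratum_counts = {}
        for name, stratum in (("low", low), ("high", high)):
            anc = der = 0
            for gene in stratum["gene"]:
                if gene in counts.index:
                    anc += int(counts.loc[gene].get("ANC", 0))
                    der += int(counts.loc[gene].get("DER", 0))
            stratum_counts[name] = (anc, der)
            tot = anc + der
            rows.append(
                {
                    "population": pop,
                    "stratum": f"<= median" if name == "low" else ">= median",
                    "median_pct": med,
                    "n_assoc": len(stratum),
                    "ANC": anc,
                    "DER": der,
                    "der_pct": 100.0 * der / tot if tot else float("nan"),
                }
            )
        table = np.array([stratum_counts["low"], stratum_counts["high"]])
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            tests[pop] = derived_allele_test(table)
        else:
            tests[pop] = (float("nan"), float("nan"))
    return pd.DataFrame(rows), tests


def phi_fst_dataset(
    config: SimulationConfig,
    compute_tags: bool = False,
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Simulate one dataset and return per-association phi and gene FST.

    The workhorse of the parameter-recovery experiments: runs the full
    simulate -> curate -> FST -> phi chain and returns one row per
    Continental-Set association with ``phi`` and ``mean_fst_EUR_EAS`` (plus
    the other profile columns).
    """
    th = thresholds or AnalysisThresholds()
    freqs, gt, truth, records = simulate_dataset(config)
    records = assign_continents(records)
    continental = build_continental_set(
        records, min_per_continent=th.min_per_continent, drop_diseases=th.drop_diseases
    )
    continental = add_phi(continental)
    gt2 = remove_monomorphic(gt, ("EUR", "EAS"))
    profiles = gene_fst_profiles(
        gt2, pairs=(("EUR", "EAS"),), compute_tags=compute_tags
    )
    merged = continental.merge(profiles, on="gene", how="left")
    return merged.merge(
        truth[["gene", "causal_EUR", "causal_EAS", "gene_divergence"]],
        on="gene",
        how="left",
    )


def _correlation_grid(
    continental: pd.DataFrame,
    profiles: pd.DataFrame,
    theta: pd.DataFrame,
    snp_gene: pd.Series,
    tag_sets: dict[str, set[str]],
    thresholds: AnalysisThresholds,
    exclude_genes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Spearman phi ~ FST under pooling mode x set x study-count cutoff."""
    rows = []
    sets = {
        "full": continental,
        "conservative": apply_conservative_filter(
            continental, thresholds.conservative_pct
        ),
    }
    for set_name, summ in sets.items():
        summ = summ[~summ["gene"].isin(exclude_genes)]
        for cutoff in thresholds.study_count_cutoffs:
            sub = summ[summ["n_studies"] >= cutoff]
            phi_by_gene = sub.set_index("gene")["phi"]
            prof = profiles.set_index("gene").reindex(phi_by_gene.index)
            for pooling, values in (
                ("gene_mean", prof["mean_fst_EUR_EAS"]),
                ("gene_tag_mean", prof.get("tag_mean_fst_EUR_EAS")),
            ):
                if values is None:
                    continue
                ok = values.notna() & (
                    prof["n_snps"] >= thresholds.min_snps_for_mean_fst
                )
                rows.append(
                    _grid_row(set_name, pooling, cutoff,
                              values[ok], phi_by_gene[ok])
                )
            # per-SNP pooling: every SNP inherits the phi of its gene
            snp_theta = theta["EUR_EAS"]
            genes = snp_gene.reindex(snp_theta.index)
            phi_per_snp = genes.map(phi_by_gene)
            ok = snp_theta.notna() & phi_per_snp.notna()
            rows.append(
                _grid_row(set_name, "per_snp", cutoff,
                          snp_theta[ok], phi_per_snp[ok], pseudo=True)
            )
            tag_ids = set().union(*tag_sets.values()) if tag_sets else set()
            ok_tag = ok & snp_theta.index.isin(tag_ids)
            rows.append(
                _grid_row(set_name, "per_tag_snp", cutoff,
                          snp_theta[ok_tag], phi_per_snp[ok_tag], pseudo=True)
            )
    return pd.DataFrame(rows)


def _grid_row(set_name, pooling, cutoff, x, y, pseudo=False) -> dict:
    row = {
        "set": set_name,
        "pooling": pooling,
        "min_studies": cutoff,
        "n": int(len(x)),
        "rho": float("nan"),
        "p_value": float("nan"),
        "pseudo_replicated": pseudo,
    }
    if len(x) >= 4 and np.asarray(x, float).std() > 0 and np.asarray(y, float).std() > 0:
        rho, p = spearman_correlation(x, y)
        row["rho"], row["p_value"] = rho, p
    return row


def run_full_analysis(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    thresholds: AnalysisThresholds | None = None,
) -> dict:
    """Run the whole analysis on one synthetic dataset; see module docstring.

    Returns a dict bundle of DataFrames and summary numbers; when
    ``outdir`` is given every table is written as TSV along with a JSON
    summary and run manifest.
    """
    th = thresholds or AnalysisThresholds()
    freqs, gt, truth, records = simulate_dataset(config)
    records = assign_continents(records)
    global_set = build_global_set(records, min_studies=th.min_studies)
    continental = build_continental_set(
        records, min_per_continent=th.min_per_continent, drop_diseases=th.drop_diseases
    )
    continental = add_phi(continental)

    gt_cont = remove_monomorphic(gt, ("EUR", "EAS"))
    profiles = gene_fst_profiles(gt_cont, config=GeneProfileConfig())
    theta = pairwise_fst_table(gt_cont)
    snp_gene = gt_cont.snps.set_index("snp_id")["gene"]
    # tag membership per Continental-Set gene, for the per-tagSNP pooling
    tag_sets = {
        gene: select_tag_snps(gt_cont, gene)
        for gene in continental["gene"].unique()
    }

    # --- Global-Set FST comparison against genome background -------------
    disease_genes = global_set["gene"].unique()
    pool = profiles.set_index("gene")["mean_fst_GLOBAL"]
    if "mean_fst_GLOBAL" not in profiles.columns:
        pool = profiles.set_index("gene")["mean_fst_EUR_EAS"]
    disease_mean = float(pool.reindex(disease_genes).dropna().mean())
    resamp = resampling_mean_fst_test(
        disease_mean,
        pool.dropna().to_numpy(),
        set_size=int(pool.reindex(disease_genes).dropna().size),
        n_resamples=th.n_resamples,
        seed=np.random.default_rng(config.seed + 1),
        tail="lower",
    )

    # --- Table 1 analogue: phi ~ FST correlation grid ---------------------
    top2 = (
        profiles[profiles["gene"].isin(continental["gene"])]
        .nlargest(2, "n_snps")["gene"]
        .tolist()
    )
    table1 = _correlation_grid(
        continental, profiles, theta, snp_gene, tag_sets, th
    )
    table1_no_top2 = _correlation_grid(
        continental, profiles, theta, snp_gene, tag_sets, th,
        exclude_genes=tuple(top2),
    )

    # --- Table 2 analogue: forward stepwise -------------------------------
    def _stepwise(summ, exclude=()):
        mat = build_predictor_matrix(
            summ[~summ["gene"].isin(exclude)],
            profiles,
            min_snps=th.min_snps_for_mean_fst,
        )
        if len(mat) <= len(PREDICTORS) + 2:
            logger.warning("stepwise skipped: only %d usable rows", len(mat))
            return None
        return forward_stepwise(
            mat[PREDICTORS], mat["phi"], p_enter=th.p_enter, p_remove=th.p_remove
        )

    conservative = apply_conservative_filter(continental, th.conservative_pct)
    table2 = {
        "full": _stepwise(continental),
        "full_no_top2": _stepwise(continental, exclude=top2),
        "conservative": _stepwise(conservative),
        "conservative_no_top2": _stepwise(conservative, exclude=top2),
    }

    # --- Table 3 analogue: derived-allele strata --------------------------
    table3, table3_tests = derived_allele_strata(global_set, gt_cont)

    # --- marker-level correlation -----------------------------------------
    marker = _marker_analysis(records, continental, theta)

    bundle = {
        "records": records,
        "global_set": global_set,
        "continental_set": continental,
        "profiles": profiles,
        "global_fst_comparison": {
            "disease_mean_fst": disease_mean,
            "background_mean_fst": resamp.null_mean,
            "n_disease_genes": int(pool.reindex(disease_genes).dropna().size),
            "resampling_p": str(resamp),
            "resampling_k": resamp.k,
            "n_resamples": resamp.n_resamples,
        },
        "table1": table1,
        "table1_no_top2": table1_no_top2,
        "largest_genes": top2,
        "table2": table2,
        "table3": table3,
        "table3_tests": table3_tests,
        "marker_analysis": marker,
        "manifest": {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "thresholds": vars(th).copy(),
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        },
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _marker_analysis(
    records: pd.DataFrame, continental: pd.DataFrame, theta: pd.DataFrame
) -> dict:
    marked = records[records["marker_id"].astype(str) != ""]
    phi_map = continental.set_index(["gene", "disease"])["phi"]
    rows = []
    for (gene, disease, marker), _ in marked.groupby(
        ["gene", "disease", "marker_id"]
    ):
        if (gene, disease) not in phi_map.index:
            continue
        if marker not in theta.index:
            continue
        t = theta.loc[marker, "EUR_EAS"]
        if pd.isna(t):
            continue
        rows.append({"marker": marker, "fst": float(t),
                     "phi": float(phi_map.loc[(gene, disease)])})
    df = pd.DataFrame(rows)
    out = {"n_markers": len(df), "rho": float("nan"), "p_value": float("nan")}
    if len(df) >= 4 and df["fst"].std() > 0 and df["phi"].std() > 0:
        out["rho"], out["p_value"] = spearman_correlation(df["fst"], df["phi"])
    out["table"] = df
    return out


def _write_bundle(bundle: dict, outdir: Path) -> None:
    from .io import write_study_records, write_table

    outdir.mkdir(parents=True, exist_ok=True)
    write_study_records(bundle["records"], outdir / "study_records.tsv")
    write_table(bundle["global_set"], outdir / "global_set.tsv")
    write_table(bundle["continental_set"], outdir / "continental_set.tsv")
    write_table(bundle["profiles"], outdir / "gene_fst_profiles.tsv")
    write_table(bundle["table1"], outdir / "table1_correlations.tsv")
    write_table(bundle["table1_no_top2"], outdir / "table1_no_largest.tsv")
    write_table(bundle["table3"], outdir / "table3_derived_alleles.tsv")
    if bundle["marker_analysis"]["n_markers"]:
        write_table(bundle["marker_analysis"]["table"], outdir / "marker_fst_phi.tsv")

    stepwise_rows = []
    for name, model in bundle["table2"].items():
        if model is None or model.empty:
            continue
        frame = model.to_frame()
        frame.insert(0, "model", name)
        frame["model_f"] = model.f_value
        frame["model_f_df"] = f"{model.f_df[0]},{model.f_df[1]}"
        frame["adj_r2"] = model.adj_r2
        stepwise_rows.append(frame)
    if stepwise_rows:
        write_table(pd.concat(stepwise_rows), outdir / "table2_stepwise.tsv")

    summary = {
        "global_fst_comparison": bundle["global_fst_comparison"],
        "largest_genes": bundle["largest_genes"],
        "table3_tests": {
            pop: {"chi2": c, "p": p} for pop, (c, p) in bundle["table3_tests"].items()
        },
        "marker_analysis": {
            k: v for k, v in bundle["marker_analysis"].items() if k != "table"
        },
        "manifest": bundle["manifest"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
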