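"""Curation of raw study records into Global and Continental association sets.

The raw input is one row per published association study (gene, disease,
outcome Y/N, free-text ancestry label).  Curation assigns each study to a
continent through an explicit mapping table, pools studies per gene-disease
pair, and applies the filtering ladder: at least four studies overall for
the Global Set, at least four studies in each of Europe and East Asia for
the Continental Set, and an optional conservative cut at 50% replicability.

Replicability of an association is the percentage of its studies that
reported a positive result.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CONTINENTS",
    "DEFAULT_ANCESTRY_MAP",
    "normalize_ancestry",
    "assign_continents",
    "build_global_set",
    "build_continental_set",
    "apply_conservative_filter",
    "load_mapping_table",
    "apply_disease_synonyms",
]

CONTINENTS = (
    "Africa",
    "Europe",
    "MiddleEast",
    "EastAsia",
    "Oceania",
    "America",
    "Mixed",
    "Unassigned",
)

#: Default free-text ancestry label -> continent mapping.  Recent world-wide
#: migrations are assigned to the source continent (African Americans ->
#: Africa, European Americans -> Europe); explicitly mixed panels -> Mixed.
DEFAULT_ANCESTRY_MAP: dict[str, str] = {
    "caucasian": "Europe",
    "european": "Europe",
    "european american": "Europe",
    "finnish": "Europe",
    "italian": "Europe",
    "german": "Europe",
    "british": "Europe",
    "spanish": "Europe",
    "french": "Europe",
    "japanese": "EastAsia",
    "chinese": "EastAsia",
    "han chinese": "EastAsia",
    "korean": "EastAsia",
    "african": "Africa",
    "african american": "Africa",
    "yoruba": "Africa",
    "iranian": "MiddleEast",
    "turkish": "MiddleEast",
    "arab": "MiddleEast",
    "amerindian": "America",
    "native american": "America",
    "aboriginal australian": "Oceania",
    "mixed": "Mixed",
}


def load_mapping_table(path) -> dict[str, str]:
    """Read a two-column TSV (label, continent) into a mapping dict."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("mapping table must have exactly two columns")
    mapping = dict(zip(df.iloc[:, 0].str.lower(), df.iloc[:, 1]))
    bad = set(mapping.values()) - set(CONTINENTS)
    if bad:
        raise ValueError(f"unknown continents in mapping table: {sorted(bad)}")
    return mapping


def normalize_ancestry(label: str, mapping: Mapping[str, str] | None = None) -> str:
    """Map one free-text ancestry label to a continent.

    Unknown labels map to ``Unassigned`` (never silently dropped); the
    decision is logged so curators can extend the mapping table.
    """
    mapping = DEFAULT_ANCESTRY_MAP if mapping is None else mapping
    if label is None or (isinstance(label, float) and np.isnan(label)):
        logger.info("ancestry label missing -> Unassigned")
        return "Unassigned"
    key = str(label).strip().lower()
    continent = mapping.get(key)
    if continent is None:
        logger.info("ancestry label %r not in mapping -> Unassigned", label)
        return "Unassigned"
    return continent


def assign_continents(
    records: pd.DataFrame, mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Add a ``continent`` column from the ``ancestry_label`` column."""
    out = records.copy()
    out["continent"] = [
        normalize_ancestry(lab, mapping) for lab in out["ancestry_label"]
    ]
    return out


def apply_disease_synonyms(
    records: pd.DataFrame, synonyms: Mapping[str, str] | None
) -> pd.DataFrame:
    """Collapse disease names through an explicit synonym table.

    The table maps variant spellings to a canonical disease ID; anything
    not in the table is kept as-is.  No fuzzy matching is attempted.
    """
    if not synonyms:
        return records
    out = records.copy()
    out["disease"] = out["disease"].map(lambda d: synonyms.get(d, d))
    return out


def _positive(records: pd.DataFrame) -> pd.Series:
    outcome = records["outcome"].astype(str).str.upper()
    bad = ~outcome.isin(["Y", "N", "POSITIVE", "NEGATIVE"])
    if bad.any():
        raise ValueError(
            f"non-binary outcomes: {sorted(records.loc[bad, 'outcome'].unique())}"
        )
    return outcome.isin(["Y", "POSITIVE"])


def build_global_set(records: pd.DataFrame, min_studies: int = 4) -> pd.DataFrame:
    """Pool studies per (gene, disease) pair regardless of continent.

    Returns one row per pair with at least ``min_studies`` studies, with
    ``n_studies``, ``n_positive`` and ``replicability_pct`` =
    100 * positives / total.
    """
    if records.empty:
        logger.warning("no study records: Global Set is empty")
        return pd.DataFrame(
            columns=["gene", "disease", "n_studies", "n_positive", "replicability_pct"]
        )
    df = records.assign(_pos=_positive(records))
    grp = df.groupby(["gene", "disease"], sort=True)
    out = grp.agg(
        n_studies=("_pos", "size"),
        n_positive=("_pos", "sum"),
        mean_sample_size=("sample_size", "mean"),
        mean_year=("year", "mean"),
    ).reset_index()
    out = out[out["n_studies"] >= min_studies].reset_index(drop=True)
    out["replicability_pct"] = 100.0 * out["n_positive"] / out["n_studies"]
    return out


def build_continental_set(
    records: pd.DataFrame,
    min_per_continent: int = 4,
    drop_diseases: Iterable[str] = (),
) -> pd.DataFrame:
    """Pool Europe and East Asia studies per (gene, disease) pair.

    Only pairs with at least ``min_per_continent`` studies in Europe AND in
    East Asia are retained; studies from any other continent are excluded
    from the counts.  ``drop_diseases`` removes continent-endemic phenotypes
    (the malaria-style exclusions) before counting.
    """
    cols = [
        "gene",
        "disease",
        "n_studies_eur",
        "n_positive_eur",
        "n_studies_eas",
        "n_positive_eas",
        "replicability_eur",
        "replicability_eas",
        "n_studies",
        "n_positive",
        "mean_sample_size",
        "mean_year",
    ]
    if records.empty:
        logger.warning("no study records: Continental Set is empty")
        return pd.DataFrame(columns=cols)
    if "continent" not in records.columns:
        raise ValueError("records need a continent column (run assign_continents)")
    df = records[~records["disease"].isin(set(drop_diseases))]
    df = df[df["continent"].isin(["Europe", "EastAsia"])]
    df = df.assign(_pos=_positive(df))

    def _one(grp: pd.DataFrame) -> pd.Series:
        eur = grp[grp["continent"] == "Europe"]
        eas = grp[grp["continent"] == "EastAsia"]
        return pd.Series(
            {
                "n_studies_eur": len(eur),
                "n_positive_eur": int(eur["_pos"].sum()),
                "n_studies_eas": len(eas),
                "n_positive_eas": int(eas["_pos"].sum()),
                "mean_sample_size": grp["sample_size"].mean(),
                "mean_year": grp["year"].mean(),
            }
        )

    pooled = (
        df.groupby(["gene", "disease"], sort=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    keep = (pooled["n_studies_eur"] >= min_per_continent) & (
        pooled["n_studies_eas"] >= min_per_continent
    )
    out = pooled[keep].reset_index(drop=True)
    for c in ["n_studies_eur", "n_positive_eur", "n_studies_eas", "n_positive_eas"]:
        out[c] = out[c].astype(int)
    out["replicability_eur"] = 100.0 * out["n_positive_eur"] / out["n_studies_eur"]
    out["replicability_eas"] = 100.0 * out["n_positive_eas"] / out["n_studies_eas"]
    out["n_studies"] = out["n_studies_eur"] + out["n_studies_eas"]
    out["n_positive"] = out["n_positive_eur"] + out["n_positive_eas"]
    return out[cols]


def apply_conservative_filter(
    summaries: pd.DataFrame,
    threshold_pct: float = 50.0,
    min_snps_for_mean_fst: int = 10,
) -> pd.DataFrame:
    """Keep associations replicated at least ``threshold_pct`` of the time.

    For the Continental Set (per-continent replicability columns present)
    the cut is satisfied by EITHER continent; for the Global Set it applies
    to the overall replicability.  The threshold is inclusive (>=).

    Genes with fewer than ``min_snps_for_mean_fst`` SNPs give unreliable
    gene-average FST values: when the summaries carry an ``n_snps`` column a
    boolean ``use_mean_fst`` column is added flagging the rows eligible for
    mean-FST analyses.  Such rows are NOT dropped -- they remain available
    for per-SNP analyses.
    """
    if {"replicability_eur", "replicability_eas"} <= set(summaries.columns):
        keep = (summaries["replicability_eur"] >= threshold_pct) | (
            summaries["replicability_eas"] >= threshold_pct
        )
    else:
        keep = summaries["replicability_pct"] >= threshold_pct
    out = summaries[keep].reset_index(drop=True)
    if "n_snps" in out.columns:
        out = out.assign(use_mean_fst=out["n_snps"] >= min_snps_for_mean_fst)
    return out
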