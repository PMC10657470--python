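"""Per-taxon contribution to selected pathways, stratified by diagnosis group.

Given a taxon-stratified pathway table, compute each taxon's fractional
contribution per sample (stratum abundance over the sample's total
stratified abundance for that pathway, pooled to genus or kept at
species rank), then summarize per diagnosis group as the mean fraction
over the group's samples, renormalized to percentages that sum to 100.
Samples whose stratified total is zero carry no information about the
split and are excluded (NA). A pooled-abundance mode (sum abundances
over the group before taking fractions) is available for comparison;
the mean-of-fractions default weights every sample equally rather than
letting high-biomass samples dominate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import PathwayAbundanceTable, STRATUM_SEP

__all__ = ["taxon_fractions", "group_contribution", "contribution_tables",
           "DEFAULT_PATHWAYS"]

#: arginine / ornithine / citrulline biosynthesis pathway ids
DEFAULT_PATHWAYS = (
    "ARG-POLYAMINE-SYN",
    "ARGSYNBSUB-PWY",
    "ARGININE-SYN4-PWY",
    "ARGSYN-PWY",
    "CITRULBIO-PWY",
)


def _taxon_at_rank(stratum: str, rank: str) -> str:
    """Extract the genus or species label from a ``g__X.s__Y`` stratum suffix."""
    if stratum == "unclassified":
        return "unclassified"
    parts = stratum.split(".")
    tags = {p.split("__", 1)[0]: p.split("__", 1)[1] for p in parts if "__" in p}
    if rank == "genus":
        return tags.get("g", "unclassified")
    if rank == "species":
        return tags.get("s", tags.get("g", "unclassified"))
    raise ValueError(f"rank must be 'genus' or 'species', got {rank!r}")


def _resolve_pathway_key(table: PathwayAbundanceTable, pathway_id: str) -> str:
    for key in table.pathway_keys:
        if key == pathway_id or key.split(":", 1)[0].strip() == pathway_id:
            return key
    raise KeyError(f"pathway {pathway_id!r} not found in table")


def taxon_fractions(table: PathwayAbundanceTable, pathway_id: str,
                    rank: str = "genus") -> pd.DataFrame:
    """Samples x taxa fractional contributions for one pathway.

    Fractions are relative to the sample's stratified total; rows of a
    taxon split across several strata are pooled at the chosen rank.
    All-zero samples come back as NA rows.
    """
    key = _resolve_pathway_key(table, pathway_id)
    strata = table.stratified_keys(key)
    if not strata:
        raise KeyError(f"pathway {pathway_id!r} has no stratified rows")
    pooled: dict[str, np.ndarray] = {}
    for skey in strata:
        stratum = skey.split(STRATUM_SEP, 1)[1]
        taxon = _taxon_at_rank(stratum, rank)
        vals = table.data[skey].to_numpy(dtype=float)
        pooled[taxon] = pooled.get(taxon, 0.0) + vals
    df = pd.DataFrame(pooled, index=table.data.index)
    totals = df.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = df.div(totals, axis=0)
    frac[totals == 0] = np.nan
    return frac


def group_contribution(fractions: pd.DataFrame, groups: pd.Series,
                       mode: str = "mean_of_fractions",
                       abundances: pd.DataFrame | None = None) -> pd.DataFrame:
    """Taxa x groups percent-contribution table (columns sum to 100).

    ``groups`` maps sample id -> group label. ``mode`` is either
    ``"mean_of_fractions"`` (default) or ``"pooled"`` (requires the raw
    stratum ``abundances`` pooled at the same rank).
    """
    groups = groups.reindex(fractions.index)
    if groups.isna().any():
        missing = list(fractions.index[groups.isna()])
        raise ValueError(f"samples without a group assignment: {missing[:5]}")
    cols = {}
    for label in pd.unique(groups):
        members = fractions.index[groups == label]
        sub = fractions.loc[members].dropna(how="all")
        if sub.empty:
            warnings.warn(f"group {label!r} has no usable samples; omitted",
                          UserWarning, stacklevel=2)
            continue
        if mode == "mean_of_fractions":
            mean = sub.mean(axis=0, skipna=True)
        elif mode == "pooled":
            if abundances is None:
                raise ValueError("pooled mode needs the rank-pooled abundances")
            pooled = abundances.loc[members].sum(axis=0)
            mean = pooled / pooled.sum() if pooled.sum() > 0 else pooled
        else:
            raise ValueError(f"unknown mode {mode!r}")
        total = mean.sum()
        cols[label] = 100.0 * mean / total if total > 0 else mean * 0.0
    if not cols:
        raise ValueError("no group produced usable samples")
    out = pd.DataFrame(cols).round(2)
    out.index.name = "taxon"
    return out


def contribution_tables(table: PathwayAbundanceTable, groups: pd.Series,
                        pathway_ids=DEFAULT_PATHWAYS, rank: str = "genus",
                        mode: str = "mean_of_fractions") -> pd.DataFrame:
    """Long-format contribution table across a pathway set.

    Columns: pathway, taxon, one percent column per group — the shape
    of a published per-genus contribution table.
    """
    frames = []
    for pid in pathway_ids:
        frac = taxon_fractions(table, pid, rank=rank)
        pooled = None
        if mode == "pooled":
            key = _resolve_pathway_key(table, pid)
            pooled_cols: dict[str, np.ndarray] = {}
            for skey in table.stratified_keys(key):
                taxon = _taxon_at_rank(skey.split(STRATUM_SEP, 1)[1], rank)
                pooled_cols[taxon] = pooled_cols.get(taxon, 0.0) + table.data[skey].to_numpy()
            pooled = pd.DataFrame(pooled_cols, index=table.data.index)
        contrib = group_contribution(frac, groups, mode=mode, abundances=pooled)
        contrib = contrib.reset_index()
        contrib.insert(0, "pathway", pid)
        frames.append(contrib)
    return pd.concat(frames, ignore_index=True)
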