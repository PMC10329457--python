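"""Presence, widespread and core classification of ASVs across surveys.

All thresholds are strict: a sample is kept when reads > min_reads, an ASV
is present when RA > min_ra, widespread when its present-site fraction >
site_fraction, and core when present (by the per-unit sample-fraction rule)
in every grouping unit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("site", "sample", "asv", "relative_abundance")


def validate_survey(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"survey table missing column {col!r}")
    ra = table["relative_abundance"].astype(float)
    if ((ra < 0) | (ra > 1)).any():
        bad = table.index[(ra < 0) | (ra > 1)].tolist()
        raise ValueError(f"relative abundance outside [0, 1] at rows {bad}")
    return table


def filter_samples(table: pd.DataFrame, min_reads: int = 1000) -> pd.DataFrame:
    """Keep samples whose read count is strictly above ``min_reads``."""
    validate_survey(table)
    if "reads" not in table.columns:
        raise ValueError("read-count filtering requested but 'reads' column missing")
    per_sample = table.groupby("sample")["reads"].first()
    keep = set(per_sample.index[per_sample.astype(float) > min_reads])
    return table[table["sample"].isin(keep)].reset_index(drop=True)


def presence_calls(table: pd.DataFrame, min_ra: float = 0.0001) -> pd.DataFrame:
    """ASV x sample boolean presence matrix; present iff RA > ``min_ra``."""
    validate_survey(table)
    wide = table.pivot_table(
        index="asv", columns="sample", values="relative_abundance",
        aggfunc="first", fill_value=0.0,
    )
    return wide > min_ra


def mean_ra_present(table: pd.DataFrame, presence: pd.DataFrame) -> pd.Series:
    """Mean RA per ASV over the samples where it is present.

    ASVs present nowhere are omitted (their mean is undefined).
    """
    validate_survey(table)
    wide = table.pivot_table(
        index="asv", columns="sample", values="relative_abundance",
        aggfunc="first", fill_value=0.0,
    )
    pres = presence.reindex(index=wide.index, columns=wide.columns, fill_value=False)
    means = wide.where(pres).mean(axis=1, skipna=True)
    return means.dropna()


def _site_of_sample(table: pd.DataFrame) -> pd.Series:
    return table.groupby("sample")["site"].first()


def classify_widespread(
    table: pd.DataFrame,
    presence: pd.DataFrame,
    site_fraction: float = 0.8,
    mode: str = "any_sample",
    per_site_sample_fraction: float = 0.5,
) -> pd.Series:
    """Widespread = present in strictly more than ``site_fraction`` of sites.

    Site-level presence defaults to "present in >= 1 sample of the site"
    (``mode="any_sample"``); ``mode="sample_fraction"`` instead requires
    presence in strictly more than ``per_site_sample_fraction`` of the
    site's samples.
    """
    validate_survey(table)
    if mode not in ("any_sample", "sample_fraction"):
        raise ValueError("mode must be 'any_sample' or 'sample_fraction'")
    site_of = _site_of_sample(table)
    sites = sorted(site_of.unique())
    per_site = _per_site_presence(presence, site_of, sites, mode,
                                  per_site_sample_fraction)
    frac = per_site.mean(axis=1)
    out = frac > site_fraction
    out.name = "widespread"
    return out


def classify_core(
    table: pd.DataFrame,
    presence: pd.DataFrame,
    per_species_fraction: float = 0.7,
) -> pd.Series:
    """Core = present in every grouping unit (site/species column).

    Per unit, an ASV counts as present when its present-sample fraction is
    strictly above ``per_species_fraction``.
    """
    validate_survey(table)
    site_of = _site_of_sample(table)
    sites = sorted(site_of.unique())
    for s in sites:
        if (site_of == s).sum() == 0:
            raise ValueError(f"unit {s!r} has zero samples")
    per_site = _per_site_presence(presence, site_of, sites,
                                  "sample_fraction", per_species_fraction)
    out = per_site.all(axis=1)
    out.name = "core"
    return out


def _per_site_presence(presence: pd.DataFrame, site_of: pd.Series,
                       sites: list, mode: str, frac: float) -> pd.DataFrame:
    cols = {}
    for s in sites:
        samples = [c for c in presence.columns if site_of.get(c) == s]
        if not samples:
            raise ValueError(f"unit {s!r} has zero samples in presence matrix")
        block = presence[samples]
        cols[s] = block.any(axis=1) if mode == "any_sample" else block.mean(axis=1) > frac
    return pd.DataFrame(cols, index=presence.index)


def prevalence_table(
    table: pd.DataFrame,
    min_ra: float = 0.0001,
    site_fraction: float = 0.8,
    per_species_fraction: float = 0.7,
) -> pd.DataFrame:
    """One row per ASV: prevalence, mean RA among present samples, flags."""
    presence = presence_calls(table, min_ra=min_ra)
    site_of = _site_of_sample(table)
    sites = sorted(site_of.unique())
    per_site = _per_site_presence(presence, site_of, sites, "any_sample", 0.0)
    widespread = classify_widespread(table, presence, site_fraction=site_fraction)
    core = classify_core(table, presence, per_species_fraction=per_species_fraction)
    mean_ra = mean_ra_present(table, presence)
    out = pd.DataFrame({
        "prevalence": per_site.mean(axis=1),
        "mean_ra_present": mean_ra.reindex(presence.index),
        "widespread": widespread,
        "core": core,
    })
    out.index.name = "asv"
    out["mean_ra_present"] = out["mean_ra_present"].fillna(np.nan)
    return out.reset_index()
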