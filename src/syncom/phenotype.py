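"""Root-growth-inhibition (RGI) classification and reversion testing.

A treatment is RGI-inducing when mean primary-root elongation across all
its seedlings falls strictly below the cutoff (default 3 cm). Reversion of
an inducer by a partner is tested with a one-sided Welch t-test (combined >
alone) under BH-FDR across partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("treatment", "elongation_cm")
CONTROL_LABEL = "NB"


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype table contract (long format, one row per seedling)."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    if (table["elongation_cm"].astype(float) < 0).any():
        bad = table.index[table["elongation_cm"].astype(float) < 0].tolist()
        raise ValueError(f"negative elongation at rows {bad}")
    return table


@dataclass
class RgiCall:
    strain_id: str
    mean_cm: float
    n: int
    rgi: bool
    cutoff_cm: float


@dataclass
class ReversionResult:
    inducer: str
    partner: str
    mean_alone: float
    mean_combined: float
    statistic: float
    p: float
    q: float
    reverted: bool


def classify_rgi(
    table: pd.DataFrame,
    cutoff_cm: float = 3.0,
    exclude: tuple[str, ...] = (CONTROL_LABEL,),
) -> list[RgiCall]:
    """Flag mono-association treatments whose pooled mean elongation < cutoff.

    Seedlings are pooled across plates and experiments. Treatments in
    ``exclude`` (the no-bacteria control by default) are not classified.
    """
    validate_phenotypes(table)
    calls = []
    for strain, group in table.groupby("treatment", sort=True):
        if strain in exclude:
            continue
        vals = group["elongation_cm"].astype(float).to_numpy()
        if vals.size == 0:
            logger.warning("treatment %s has no measurements; omitted", strain)
            continue
        mean = float(vals.mean())
        calls.append(RgiCall(str(strain), mean, int(vals.size), mean < cutoff_cm, cutoff_cm))
    return calls


def combined_label(inducer: str, partner: str) -> str:
    """Treatment label used for co-inoculation of two strains."""
    return f"{inducer}+{partner}"


def reversion_test(
    table: pd.DataFrame,
    inducer: str,
    partners: list[str],
    alpha_q: float = 0.05,
    alternative: str = "greater",
) -> list[ReversionResult]:
    """Welch t-tests of co-inoculated vs inducer-alone elongation.

    One result per partner; p-values are BH-adjusted across the partners of
    this inducer. ``reverted`` requires q < ``alpha_q`` and a combined mean
    at least as large as the alone mean. ``alternative="two-sided"`` is
    available for non-directional use.
    """
    validate_phenotypes(table)
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    by_treatment = {t: g["elongation_cm"].astype(float).to_numpy()
                    for t, g in table.groupby("treatment")}
    if inducer not in by_treatment:
        raise ValueError(f"missing treatment {inducer!r}")
    alone = by_treatment[inducer]
    if alone.size < 2:
        raise ValueError(f"treatment {inducer!r} needs n >= 2")
    results: list[ReversionResult] = []
    for partner in partners:
        label = combined_label(inducer, partner)
        if label not in by_treatment:
            raise ValueError(f"missing treatment {label!r}")
        combined = by_treatment[label]
        if combined.size < 2:
            raise ValueError(f"treatment {label!r} needs n >= 2")
        t, p = stats.ttest_ind(combined, alone, equal_var=False,
                               alternative=alternative)
        results.append(ReversionResult(
            inducer=inducer, partner=partner,
            mean_alone=float(alone.mean()), mean_combined=float(combined.mean()),
            statistic=float(t), p=float(p), q=np.nan, reverted=False,
        ))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.reverted = bool(q < alpha_q and r.mean_combined >= r.mean_alone)
    return results


def standardize_to_control(
    table: pd.DataFrame,
    control_label: str = CONTROL_LABEL,
    by: str | None = "genotype",
) -> pd.DataFrame:
    """Divide each measurement by its group's control-treatment mean.

    Grouping defaults to genotype; pass ``by=None`` for a single global
    group. The control group's standardized mean is exactly 1.
    """
    validate_phenotypes(table)
    out = table.copy()
    groups = [(None, out)] if by is None else list(out.groupby(by, sort=False))
    for key, group in groups:
        control = group.loc[group["treatment"] == control_label, "elongation_cm"]
        if control.empty:
            raise ValueError(f"no {control_label!r} control in group {key!r}")
        ctrl_mean = float(control.astype(float).mean())
        if ctrl_mean == 0:
            raise ValueError(f"control mean is zero in group {key!r}")
        out.loc[group.index, "elongation_cm"] = (
            group["elongation_cm"].astype(float) / ctrl_mean
        )
    return out


def group_iqr(table: pd.DataFrame, treatment: str) -> tuple[float, float]:
    """25th/75th percentiles of one treatment's elongation values.

    Uses linear interpolation between order statistics (numpy's default
    percentile convention). Requires >= 4 measurements.
    """
    validate_phenotypes(table)
    vals = table.loc[table["treatment"] == treatment, "elongation_cm"].astype(float)
    if vals.size < 4:
        raise ValueError(
            f"treatment {treatment!r} has {vals.size} measurements; need >= 4 for an IQR"
        )
    q25, q75 = np.percentile(vals.to_numpy(), [25, 75], method="linear")
    return float(q25), float(q75)
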