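"""Gene-set resampling test for a shift in mean standardized expression.

The observed statistic is the difference between the set-mean expression in
two treatments; the null distribution comes from resampling equal-sized
gene sets uniformly from the whole matrix (target genes not excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized expression with sample treatment labels."""

    values: pd.DataFrame
    treatments: pd.Series  # sample id -> treatment label

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.treatments.index)
        if missing:
            raise ValueError(f"samples without treatment label: {sorted(missing)}")

    def samples_for(self, treatment: str) -> list[str]:
        wanted = set(self.treatments.index[self.treatments == treatment])
        return [s for s in self.values.columns if s in wanted]


@dataclass
class GeneSetTestResult:
    set_genes: list[str]
    t1: str
    t2: str
    observed: float
    B: int
    null_mean: float
    null_sd: float
    p: float
    alternative: str
    null_stats: np.ndarray


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, SD 1 (population SD, ddof=0)."""
    v = m.values.to_numpy(dtype=float)
    sd = v.std(axis=1, ddof=0)
    flat = list(m.values.index[sd == 0])
    if flat:
        raise ValueError(f"zero-variance genes cannot be z-scored: {flat}")
    z = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        m.treatments,
    )


def _set_statistic(values: np.ndarray, gene_idx: np.ndarray,
                   cols1: np.ndarray, cols2: np.ndarray) -> float:
    sub = values[gene_idx]
    return float(sub[:, cols1].mean() - sub[:, cols2].mean())


def geneset_permutation_test(
    m: ExpressionMatrix,
    set_genes: list[str],
    t1: str,
    t2: str,
    B: int = 10_000,
    seed: int | None = None,
    alternative: str = "two_sided",
) -> GeneSetTestResult:
    """Resampling p-value for the set-mean expression difference t1 - t2.

    ``B`` random gene sets of the same size are drawn without replacement
    from all genes; p = (1 + #{null at least as extreme}) / (B + 1), so the
    smallest attainable p is 1/(B+1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError("alternative must be two_sided, greater or less")
    gene_pos = {g: i for i, g in enumerate(m.values.index)}
    missing = [g for g in set_genes if g not in gene_pos]
    if missing:
        raise ValueError(f"set genes absent from matrix: {missing}")
    for t in (t1, t2):
        if not m.samples_for(t):
            raise ValueError(f"no samples with treatment {t!r}")
    values = m.values.to_numpy(dtype=float)
    col_pos = {s: j for j, s in enumerate(m.values.columns)}
    cols1 = np.array([col_pos[s] for s in m.samples_for(t1)])
    cols2 = np.array([col_pos[s] for s in m.samples_for(t2)])
    target = np.array([gene_pos[g] for g in set_genes])
    observed = _set_statistic(values, target, cols1, cols2)

    rng = np.random.default_rng(seed)
    n_genes, size = values.shape[0], len(set_genes)
    # per-gene treatment-mean difference lets each null stat be a simple mean
    diff = values[:, cols1].mean(axis=1) - values[:, cols2].mean(axis=1)
    null = np.empty(B)
    for b in range(B):
        null[b] = diff[rng.choice(n_genes, size=size, replace=False)].mean()

    if alternative == "greater":
        extreme = np.sum(null >= observed)
    elif alternative == "less":
        extreme = np.sum(null <= observed)
    else:
        extreme = np.sum(np.abs(null) >= abs(observed))
    p = (1 + int(extreme)) / (B + 1)
    return GeneSetTestResult(
        set_genes=list(set_genes), t1=t1, t2=t2, observed=observed, B=B,
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=0)),
        p=float(p), alternative=alternative, null_stats=null,
    )


def set_mean_trajectory(
    m: ExpressionMatrix,
    set_genes: list[str],
    treatments: list[str],
) -> pd.DataFrame:
    """Per-treatment set-mean expression with normal-approximation 95% CI.

    Each gene contributes its mean over the treatment's samples; the CI is
    mean +/- 1.96 * SE over those gene-level means. Needs >= 2 genes.
    """
    if len(set_genes) < 2:
        raise ValueError("need >= 2 genes for a confidence interval")
    missing = [g for g in set_genes if g not in m.values.index]
    if missing:
        raise ValueError(f"set genes absent from matrix: {missing}")
    rows = []
    for t in treatments:
        samples = m.samples_for(t)
        if not samples:
            raise ValueError(f"no samples with treatment {t!r}")
        gene_means = m.values.loc[set_genes, samples].mean(axis=1).to_numpy()
        mean = float(gene_means.mean())
        se = float(gene_means.std(ddof=1) / np.sqrt(len(gene_means)))
        rows.append({
            "treatment": t, "mean": mean,
            "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se,
            "n_samples": len(samples), "n_genes": len(set_genes),
        })
    return pd.DataFrame(rows)
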