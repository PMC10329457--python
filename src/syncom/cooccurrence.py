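"""Co-occurrence module detection and per-module family enrichment.

The pipeline is: standardize a strain x sample relative-abundance matrix by
row means, build a Pearson-correlation dissimilarity, cluster with the
Ward.D2 criterion, cut the tree into ``k`` modules, and test family
overrepresentation per module with an upper-tail hypergeometric test under
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

_REQUIRED_META = ("fraction", "condition", "replicate")


@dataclass
class AbundanceTable:
    """Strains x samples abundance matrix with sample metadata and taxonomy.

    Parameters
    ----------
    values:
        Non-negative matrix, rows indexed by strain id, columns by sample id.
    sample_meta:
        One row per sample with at least columns ``fraction``, ``condition``
        and ``replicate``. Optional; validated against ``values`` columns
        when present.
    taxonomy:
        One row per strain; the ``family`` column feeds enrichment tests.
        Optional.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate strain ids in abundance table")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids in abundance table")
        if v.size and (v.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundance values must be >= 0")
        if self.sample_meta is not None:
            missing = set(v.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DissimilarityMatrix:
    """Symmetric strain x strain dissimilarity, d = 1 - Pearson r."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.values.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(a), 0.0, atol=1e-10):
            raise ValueError("dissimilarity diagonal must be zero")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ModuleAssignment:
    """Partition of strains into modules plus the linkage merge history."""

    labels: pd.Series  # strain id -> module label (1..k)
    k: int
    linkage_matrix: np.ndarray  # scipy linkage format, leaf order = strain_ids
    strain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labels.nunique() != self.k:
            raise ValueError("k must equal the number of distinct labels")

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def standardize_abundance(table: AbundanceTable) -> tuple[AbundanceTable, list[str]]:
    """Divide each strain's abundances by that strain's mean across samples.

    All-zero strains cannot be standardized (mean 0); they are dropped with
    a warning and returned as a side list. Every retained row has mean 1.
    """
    if table.values.empty:
        raise ValueError("empty abundance table")
    means = table.values.mean(axis=1)
    zero_rows = list(table.values.index[means == 0])
    if zero_rows:
        logger.warning("dropping all-zero strains before standardization: %s", zero_rows)
    kept = table.values.drop(index=zero_rows)
    if kept.empty:
        raise ValueError("all strains have zero total abundance")
    std = kept.div(kept.mean(axis=1), axis=0)
    tax = table.taxonomy.drop(index=zero_rows, errors="ignore") if table.taxonomy is not None else None
    return AbundanceTable(std, table.sample_meta, tax), zero_rows


def correlation_dissimilarity(table: AbundanceTable) -> DissimilarityMatrix:
    """Pearson dissimilarity d(i, j) = 1 - r(i, j) between strain rows."""
    v = table.values
    if v.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    variances = v.var(axis=1, ddof=0)
    flat = list(v.index[variances == 0])
    if flat:
        raise ValueError(
            f"zero-variance strains cannot be correlated: {flat}; drop or jitter them"
        )
    r = np.corrcoef(v.to_numpy(dtype=float))
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # remove float asymmetry
    return DissimilarityMatrix(pd.DataFrame(d, index=v.index, columns=v.index))


def detect_modules(d: DissimilarityMatrix, k: int = 4) -> ModuleAssignment:
    """Cut a Ward.D2 hierarchical clustering of ``d`` into ``k`` modules.

    Ward.D2 semantics: the Lance-Williams update operates on squared
    dissimilarities and merge heights are reported back on the
    dissimilarity scale (what scipy's ``linkage(..., method="ward")`` does
    on a precomputed condensed distance matrix). Strains are ordered
    lexicographically by id before clustering so the result is invariant
    to input order; among equal merge costs the lowest index pair wins.
    """
    n = len(d.strain_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = sorted(range(n), key=lambda i: str(d.strain_ids[i]))
    ids = [d.strain_ids[i] for i in order]
    mat = d.values.to_numpy(dtype=float)[np.ix_(order, order)]
    condensed = squareform(np.clip(mat, 0.0, None), checks=False)
    Z = linkage(condensed, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel 1..k by first appearance over lexicographic strain order
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[lab] for lab in raw], index=ids, name="module")
    return ModuleAssignment(labels=labels, k=k, linkage_matrix=Z, strain_ids=ids)


@dataclass
class FamilyEnrichmentRow:
    module: int
    family: str
    in_module: int
    module_size: int
    in_universe: int
    universe_size: int
    p: float
    q: float
    significant: bool


def family_enrichment(
    assignment: ModuleAssignment,
    taxonomy: pd.Series,
    q_threshold: float = 0.1,
) -> list[FamilyEnrichmentRow]:
    """Hypergeometric overrepresentation of families within modules.

    For every (module, family-present-in-module) pair the upper-tail
    probability P(X >= observed) is computed with the population being all
    assigned strains; q-values are BH-adjusted across all tested pairs and
    flagged significant when q < ``q_threshold``.
    """
    strains = list(assignment.labels.index)
    missing = [s for s in strains if s not in taxonomy.index or pd.isna(taxonomy.loc[s])]
    if missing:
        raise ValueError(f"strains missing taxonomy: {missing}")
    fam = taxonomy.loc[strains]
    universe_size = len(strains)
    fam_counts = fam.value_counts()

    rows: list[FamilyEnrichmentRow] = []
    for module in sorted(assignment.labels.unique()):
        members = assignment.members(module)
        module_fams = fam.loc[members].value_counts()
        for family, in_module in sorted(module_fams.items()):
            in_universe = int(fam_counts[family])
            p = float(
                hypergeom.sf(in_module - 1, universe_size, in_universe, len(members))
            )
            rows.append(
                FamilyEnrichmentRow(
                    module=int(module),
                    family=str(family),
                    in_module=int(in_module),
                    module_size=len(members),
                    in_universe=in_universe,
                    universe_size=universe_size,
                    p=min(p, 1.0),
                    q=np.nan,
                    significant=False,
                )
            )
    if rows:
        qs = bh_adjust([r.p for r in rows])
        for r, q in zip(rows, qs):
            r.q = float(q)
            r.significant = bool(q < q_threshold)
    return rows


def enrichment_frame(rows: list[FamilyEnrichmentRow]) -> pd.DataFrame:
    """Tabular view of enrichment results (stable column order)."""
    cols = [
        "module", "family", "in_module", "module_size",
        "in_universe", "universe_size", "p", "q", "significant",
    ]
    return pd.DataFrame([vars(r) for r in rows], columns=cols)
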