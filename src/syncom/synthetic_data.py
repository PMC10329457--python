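"""Generators for every input the pipeline consumes, with recorded truth.

Each generator takes an explicit seed, uses a single ``numpy`` Generator
stream, and is byte-deterministic given its arguments. The returned truth
objects record the planted structure so downstream recovery can be tested
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cooccurrence import AbundanceTable
from .geneset import ExpressionMatrix
from .hotspot import GeneRecord, OrthogroupTable

FRACTIONS = ("substrate", "root", "shoot")


# ---------------------------------------------------------------------------
# truth records


@dataclass
class ModuleTruth:
    labels: dict[str, int]  # strain id -> module 1..K
    fraction_effects: dict[int, float]  # module -> plant-fraction multiplier
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.labels.values(), default=1) < 1:
            raise ValueError("module labels start at 1")


@dataclass
class HotspotTruth:
    reference_genome: str
    scaffold_id: str
    hotspot_gene_ids: list[str]
    hotspot_orthogroups: list[str]
    interval: tuple[int, int]  # 1-based inclusive, bp
    decoy_gene_ids: list[str]
    decoy_orthogroups: list[str]


@dataclass
class PhenotypeTruth:
    strain_stats: dict[str, dict]  # strain -> {rgi, mean_elongation_cm, sd_cm}
    suppressor_pairs: list[tuple[str, str, bool]] = field(default_factory=list)


@dataclass
class ExpressionTruth:
    marker_genes: list[str]
    delta: float
    n_null_genes: int
    treatments: tuple[str, str]


@dataclass
class SurveyTruth:
    core_asvs: list[str]
    occupancy: dict[str, dict[str, float]]  # asv -> site -> presence prob


# ---------------------------------------------------------------------------
# abundance


def simulate_abundance(
    n_strains: int,
    n_samples: int,
    k_modules: int,
    module_sd: float = 1.0,
    noise_sd: float = 0.3,
    seed: int | None = None,
) -> tuple[AbundanceTable, ModuleTruth]:
    """Log-normal latent-factor abundance matrix with K planted modules.

    Strain i in module k has log-abundance ``a_i + f_k[s] + mu_k(fraction)
    + eps`` where the latent factor ``f_k`` is shared by the whole module
    (loading 1, so at zero noise module rows are exactly proportional),
    ``mu_k`` is a per-module plant-enrichment shift applied to root/shoot
    samples, and ``eps ~ Normal(0, noise_sd)``.
    """
    if n_strains < 1 or n_samples < 2:
        raise ValueError("need n_strains >= 1 and n_samples >= 2")
    if not 1 <= k_modules <= n_strains:
        raise ValueError("need 1 <= k_modules <= n_strains")
    if module_sd <= 0:
        raise ValueError("module_sd must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    strains = [f"strain_{i:04d}" for i in range(1, n_strains + 1)]
    samples = [f"sample_{j:04d}" for j in range(1, n_samples + 1)]
    labels = {s: (i % k_modules) + 1 for i, s in enumerate(strains)}
    meta = pd.DataFrame(
        {
            "fraction": [FRACTIONS[j % 3] for j in range(n_samples)],
            "condition": [f"cond_{(j // 3) % 2 + 1}" for j in range(n_samples)],
            "replicate": [j // 6 + 1 for j in range(n_samples)],
        },
        index=pd.Index(samples, name="sample"),
    )

    factors = rng.normal(0.0, module_sd, size=(k_modules, n_samples))
    # alternate enriched / depleted modules in plant fractions
    fraction_effects = {k: (0.8 if k % 2 == 1 else -0.8) for k in range(1, k_modules + 1)}
    plant = np.array([f in ("root", "shoot") for f in meta["fraction"]], dtype=float)
    baselines = rng.normal(0.0, 0.5, size=n_strains)

    log_x = np.empty((n_strains, n_samples))
    for i, s in enumerate(strains):
        k = labels[s]
        log_x[i] = baselines[i] + factors[k - 1] + fraction_effects[k] * plant
    log_x += rng.normal(0.0, noise_sd, size=log_x.shape)
    values = pd.DataFrame(np.exp(log_x), index=pd.Index(strains, name="strain"),
                          columns=samples)

    families = [f"family_{labels[s]:02d}" for s in strains]
    taxonomy = pd.DataFrame(
        {"phylum": "phylum_1", "family": families},
        index=pd.Index(strains, name="strain"),
    )
    table = AbundanceTable(values=values, sample_meta=meta, taxonomy=taxonomy)
    truth = ModuleTruth(labels=labels, fraction_effects=fraction_effects,
                        noise_sd=noise_sd)
    return table, truth


# ---------------------------------------------------------------------------
# pangenome


def simulate_pangenome(
    n_background: int,
    n_focal: int,
    hotspot_size: int,
    decoy_count: int,
    gap_bp: int = 500,
    genes_per_genome: int = 40,
    assembly_gap_bp: int = 10_000,
    seed: int | None = None,
) -> tuple[dict[str, list[GeneRecord]], OrthogroupTable, HotspotTruth]:
    """Pangenome with a planted contiguous clade-unique cluster plus decoys.

    Focal genomes all carry the hotspot and decoy orthogroups; background
    genomes never do. On the reference (first focal) genome the hotspot
    genes sit adjacent with intervening gaps of ``gap_bp`` (< the assembly
    gap threshold) and each decoy sits >= 2 x ``assembly_gap_bp`` away from
    any other clade-specific gene. Housekeeping orthogroups shared by every
    genome provide non-specific background.
    """
    if n_focal < 1 or n_background < 0:
        raise ValueError("need n_focal >= 1 and n_background >= 0")
    if hotspot_size < 0 or decoy_count < 0:
        raise ValueError("hotspot_size and decoy_count must be >= 0")
    if gap_bp >= assembly_gap_bp:
        raise ValueError("planted gap_bp must be below the assembly gap threshold")
    n_specific = hotspot_size + decoy_count
    if genes_per_genome < n_specific + 1:
        raise ValueError("genes_per_genome too small to place clade-specific genes")
    rng = np.random.default_rng(seed)

    focal = [f"focal_{i:03d}" for i in range(1, n_focal + 1)]
    background = [f"bg_{i:03d}" for i in range(1, n_background + 1)]
    hotspot_ogs = [f"OG_HS_{i:03d}" for i in range(1, hotspot_size + 1)]
    decoy_ogs = [f"OG_DC_{i:03d}" for i in range(1, decoy_count + 1)]
    n_housekeeping = genes_per_genome - n_specific
    hk_ogs = [f"OG_HK_{i:03d}" for i in range(1, n_housekeeping + 1)]

    annotations: dict[str, list[GeneRecord]] = {}
    og_rows: list[tuple[str, str, str]] = []  # gene, genome, og

    def place(genome: str, ogs_in_order: list[str], gaps: list[int]) -> None:
        """Lay genes left to right with the given intervening gaps."""
        genes = []
        pos = 1
        for idx, og_id in enumerate(ogs_in_order):
            length = int(rng.integers(600, 1400))
            start, end = pos, pos + length - 1
            gene_id = f"{genome}_g{idx + 1:04d}"
            genes.append(GeneRecord(gene_id, genome, f"{genome}_scf1",
                                    start, end,
                                    "+" if rng.random() < 0.5 else "-", og_id))
            og_rows.append((gene_id, genome, og_id))
            pos = end + 1 + (gaps[idx] if idx < len(gaps) else 0)
        annotations[genome] = genes

    def small_gap() -> int:
        return int(rng.integers(50, 400))

    far = 2 * assembly_gap_bp
    for genome in focal:
        # order: half the housekeeping genes, hotspot block, decoys spread
        # far apart, rest of housekeeping
        half = n_housekeeping // 2
        order = hk_ogs[:half] + hotspot_ogs + decoy_ogs + hk_ogs[half:]
        gaps = []
        for j in range(len(order) - 1):
            left, right = order[j], order[j + 1]
            specific_l = left in hotspot_ogs or left in decoy_ogs
            specific_r = right in hotspot_ogs or right in decoy_ogs
            if left in hotspot_ogs and right in hotspot_ogs:
                gaps.append(gap_bp)
            elif (specific_l and right in decoy_ogs) or (left in decoy_ogs and specific_r):
                gaps.append(far)
            elif left in hotspot_ogs and specific_r:
                gaps.append(far)
            else:
                gaps.append(small_gap())
        place(genome, order, gaps)
    for genome in background:
        order = list(hk_ogs)
        gaps = [small_gap() for _ in range(len(order) - 1)]
        place(genome, order, gaps)

    og_table = OrthogroupTable.from_frame(pd.DataFrame(
        og_rows, columns=["gene_id", "genome_id", "orthogroup_id"]
    )) if og_rows else OrthogroupTable(members={}, genome_universe=set(focal + background))
    og_table.genome_universe |= set(focal + background)

    ref = focal[0]
    ref_genes = {g.orthogroup_id: g for g in annotations[ref]}
    hotspot_genes = [ref_genes[og].gene_id for og in hotspot_ogs]
    decoy_genes = [ref_genes[og].gene_id for og in decoy_ogs]
    if hotspot_ogs:
        interval = (min(ref_genes[og].start for og in hotspot_ogs),
                    max(ref_genes[og].end for og in hotspot_ogs))
    else:
        interval = (0, 0)
    truth = HotspotTruth(
        reference_genome=ref, scaffold_id=f"{ref}_scf1",
        hotspot_gene_ids=hotspot_genes, hotspot_orthogroups=list(hotspot_ogs),
        interval=interval, decoy_gene_ids=decoy_genes,
        decoy_orthogroups=list(decoy_ogs),
    )
    return annotations, og_table, truth


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    strain_means: dict[str, float],
    sd_cm: float = 0.5,
    n_plants: int = 20,
    seed: int | None = None,
    pairs: dict[tuple[str, str], float] | None = None,
    nb_mean_cm: float = 6.0,
    rgi_cutoff_cm: float = 3.0,
) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Plate-replicated root lengths: Normal(mean, sd) truncated at 0.

    ``pairs`` optionally plants co-inoculation treatments "inducer+partner"
    at the given combined means; the truth marks a pair reverted when its
    combined mean exceeds the inducer's planted mean.
    """
    if sd_cm <= 0:
        raise ValueError("sd_cm must be > 0")
    if n_plants < 2:
        raise ValueError("need n_plants >= 2 per treatment")
    rng = np.random.default_rng(seed)
    pairs = pairs or {}

    treatments: dict[str, float] = {"NB": nb_mean_cm}
    treatments.update(strain_means)
    for (inducer, partner), mean in pairs.items():
        treatments[f"{inducer}+{partner}"] = mean

    rows = []
    for treatment in treatments:  # insertion order; deterministic
        mean = treatments[treatment]
        a = (0.0 - mean) / sd_cm  # truncate at zero
        draws = truncnorm.rvs(a, np.inf, loc=mean, scale=sd_cm,
                              size=n_plants, random_state=rng)
        for i, x in enumerate(draws):
            rows.append({
                "plate": f"plate_{i % 2 + 1}",
                "treatment": treatment,
                "genotype": "Col-0",
                "seedling": f"{treatment}_s{i + 1:03d}",
                "elongation_cm": round(float(x), 4),
            })
    table = pd.DataFrame(rows, columns=["plate", "treatment", "genotype",
                                        "seedling", "elongation_cm"])
    truth = PhenotypeTruth(
        strain_stats={
            s: {"rgi": m < rgi_cutoff_cm, "mean_elongation_cm": m, "sd_cm": sd_cm}
            for s, m in strain_means.items()
        },
        suppressor_pairs=[
            (ind, part, mean > strain_means[ind])
            for (ind, part), mean in pairs.items()
        ],
    )
    return table, truth


def default_strain_means(n_strains: int, n_rgi: int,
                         rgi_range: tuple[float, float] = (1.0, 2.5),
                         normal_range: tuple[float, float] = (4.0, 7.0)) -> dict[str, float]:
    """Evenly spaced planted means: first ``n_rgi`` strains below 3 cm."""
    if not 0 <= n_rgi <= n_strains:
        raise ValueError("need 0 <= n_rgi <= n_strains")
    means: dict[str, float] = {}
    for i in range(n_strains):
        sid = f"strain_{i + 1:04d}"
        if i < n_rgi:
            lo, hi = rgi_range
            frac = i / max(n_rgi - 1, 1)
        else:
            lo, hi = normal_range
            frac = (i - n_rgi) / max(n_strains - n_rgi - 1, 1)
        means[sid] = round(lo + frac * (hi - lo), 3)
    return means


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    n_genes: int,
    samples_per_treatment: int,
    marker_size: int,
    delta: float,
    seed: int | None = None,
    treatments: tuple[str, str] = ("t1", "t2"),
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Null genes iid Normal(0,1); marker genes shifted by delta in t2."""
    if marker_size > n_genes:
        raise ValueError("marker_size must be <= n_genes")
    if n_genes < 1 or samples_per_treatment < 1:
        raise ValueError("dimensions must be positive")
    if len(treatments) != 2 or treatments[0] == treatments[1]:
        raise ValueError("need two distinct treatment labels")
    rng = np.random.default_rng(seed)

    genes = [f"gene_{i:05d}" for i in range(1, n_genes + 1)]
    markers = genes[:marker_size]
    samples, labels = [], []
    for t in treatments:
        for j in range(1, samples_per_treatment + 1):
            samples.append(f"{t}_s{j:02d}")
            labels.append(t)
    values = rng.normal(0.0, 1.0, size=(n_genes, len(samples)))
    t2_cols = np.array([lab == treatments[1] for lab in labels])
    values[:marker_size, t2_cols] += delta
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        pd.Series(labels, index=samples, name="treatment"),
    )
    truth = ExpressionTruth(marker_genes=markers, delta=delta,
                            n_null_genes=n_genes - marker_size,
                            treatments=treatments)
    return matrix, truth


# ---------------------------------------------------------------------------
# survey


def simulate_survey(
    n_sites: int,
    samples_per_site: int,
    n_asvs: int,
    core_count: int,
    seed: int | None = None,
    core_presence_prob: float = 1.0,
    noncore_site_prob: float = 0.5,
    noncore_sample_prob: float = 0.6,
    min_ra: float = 0.0001,
) -> tuple[pd.DataFrame, SurveyTruth]:
    """Multi-site relative-abundance survey with planted core ASVs.

    Core ASVs are present (RA drawn well above ``min_ra``) in every sample
    under the noiseless default; non-core ASVs occupy a random subset of
    sites and of samples within them. Absent entries get RA 0.
    """
    if core_count > n_asvs:
        raise ValueError("core_count must be <= n_asvs")
    if n_sites < 1 or samples_per_site < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)

    sites = [f"site_{i:02d}" for i in range(1, n_sites + 1)]
    asvs = [f"asv_{i:04d}" for i in range(1, n_asvs + 1)]
    core = asvs[:core_count]
    occupancy: dict[str, dict[str, float]] = {}
    rows = []
    for asv in asvs:
        is_core = asv in core
        occupancy[asv] = {}
        for site in sites:
            if is_core:
                p = core_presence_prob
            else:
                p = noncore_sample_prob if rng.random() < noncore_site_prob else 0.0
            occupancy[asv][site] = p
    for site in sites:
        for j in range(1, samples_per_site + 1):
            sample = f"{site}_smp{j:02d}"
            for asv in asvs:
                present = rng.random() < occupancy[asv][site]
                ra = float(rng.uniform(10 * min_ra, 500 * min_ra)) if present else 0.0
                rows.append({"site": site, "sample": sample, "asv": asv,
                             "relative_abundance": ra, "reads": 5000})
    table = pd.DataFrame(rows, columns=["site", "sample", "asv",
                                        "relative_abundance", "reads"])
    truth = SurveyTruth(core_asvs=list(core), occupancy=occupancy)
    return table, truth
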