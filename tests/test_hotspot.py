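import itertools

import numpy as np
import pytest

from syncom.hotspot import (
    CladeSpecificSelection,
    GeneRecord,
    OrthogroupTable,
    assemble_hotspots,
    genes_in_interval,
    hotspot_report,
    interval_intersect,
    interval_length_kb,
    select_clade_specific,
)
from syncom.synthetic_data import simulate_pangenome


def _og_table(og_to_genomes: dict[str, list[str]], universe: set[str]):
    members = {
        og: {(g, f"{g}_{og}") for g in genomes}
        for og, genomes in og_to_genomes.items()
    }
    return OrthogroupTable(members=members, genome_universe=set(universe))


# ---------------------------------------------------------------------------
# select_clade_specific


def test_select_extreme_case():
    focal = {f"f{i}" for i in range(10)}
    background = {f"b{i}" for i in range(175)}
    og = _og_table({"OG1": sorted(focal)}, focal | background)
    sel = select_clade_specific(og, focal, background)
    assert sel.selected == {"OG1"}
    assert sel.focal_prevalence["OG1"] == 1.0
    assert sel.background_prevalence["OG1"] == 0.0


def test_select_requires_full_focal_prevalence():
    focal = {f"f{i}" for i in range(10)}
    background = {f"b{i}" for i in range(175)}
    og = _og_table({"OG1": [f"f{i}" for i in range(9)]}, focal | background)
    assert select_clade_specific(og, focal, background).selected == set()


def test_select_background_boundary_arithmetic():
    # 8/175 = 4.57% < 5% selected; 9/175 = 5.14% excluded
    focal = {f"f{i}" for i in range(10)}
    background = {f"b{i}" for i in range(175)}
    og = _og_table({
        "OG8": sorted(focal) + [f"b{i}" for i in range(8)],
        "OG9": sorted(focal) + [f"b{i}" for i in range(9)],
    }, focal | background)
    sel = select_clade_specific(og, focal, background)
    assert sel.selected == {"OG8"}
    assert sel.background_prevalence["OG8"] == pytest.approx(8 / 175)
    assert sel.background_prevalence["OG9"] == pytest.approx(9 / 175)


def test_select_overlapping_sets_error():
    og = _og_table({"OG1": ["a"]}, {"a", "b"})
    with pytest.raises(ValueError):
        select_clade_specific(og, {"a"}, {"a", "b"})
    with pytest.raises(ValueError):
        select_clade_specific(og, set(), {"b"})


def test_select_monotone_in_max_bg_prev():
    focal = {"f0"}
    background = {f"b{i}" for i in range(40)}
    rng = np.random.default_rng(3)
    ogs = {f"OG{k}": ["f0"] + [f"b{i}" for i in
                              rng.choice(40, size=rng.integers(0, 6), replace=False)]
           for k in range(15)}
    og = _og_table(ogs, focal | background)
    prev = set()
    for thr in (0.01, 0.05, 0.1, 0.2):
        cur = select_clade_specific(og, focal, background, max_bg_prev=thr).selected
        assert prev <= cur
        prev = cur


# ---------------------------------------------------------------------------
# assemble_hotspots


def _genes(spec, genome="ref", scaffold="scf1"):
    """spec: list of (gene_id, start, end, og)."""
    return [GeneRecord(g, genome, scaffold, s, e, "+", og) for g, s, e, og in spec]


def _selection(ogs):
    return CladeSpecificSelection(
        selected=set(ogs), focal={"ref"}, background=set(),
        focal_prevalence={}, background_prevalence={}, max_bg_prev=0.05)


def test_gap_boundary_strictly_less_than_10kb():
    # 9,999 intervening bases -> merged; 10,000 -> split
    merged = assemble_hotspots(
        _genes([("g1", 1, 1000, "A"), ("g2", 11000, 12000, "B")]),
        _selection(["A", "B"]), gap_bp=10_000, min_genes=1)
    assert len(merged) == 1
    split = assemble_hotspots(
        _genes([("g1", 1, 1000, "A"), ("g2", 11001, 12000, "B")]),
        _selection(["A", "B"]), gap_bp=10_000, min_genes=1)
    assert len(split) == 2


def test_run_of_nine_not_reported_at_min_ten():
    spec = [(f"g{i}", 1 + i * 1000, 900 + i * 1000, f"OG{i}") for i in range(9)]
    out = assemble_hotspots(_genes(spec), _selection([f"OG{i}" for i in range(9)]),
                            min_genes=10)
    assert out == []
    out = assemble_hotspots(_genes(spec), _selection([f"OG{i}" for i in range(9)]),
                            min_genes=9)
    assert len(out) == 1


def test_exclusive_threshold_flag():
    spec = [(f"g{i}", 1 + i * 1000, 900 + i * 1000, f"OG{i}") for i in range(10)]
    sel = _selection([f"OG{i}" for i in range(10)])
    assert len(assemble_hotspots(_genes(spec), sel, min_genes=10, inclusive=True)) == 1
    assert assemble_hotspots(_genes(spec), sel, min_genes=10, inclusive=False) == []


def test_overlapping_genes_always_merge():
    out = assemble_hotspots(
        _genes([("g1", 1, 5000, "A"), ("g2", 3000, 4000, "B")]),
        _selection(["A", "B"]), min_genes=1)
    assert len(out) == 1 and out[0].gene_count == 2


def test_paralogs_gene_vs_orthogroup_count():
    spec = [(f"g{i}", 1 + i * 500, 400 + i * 500, "OG1" if i < 2 else f"OG{i}")
            for i in range(3)]
    sel = _selection(["OG1", "OG2"])
    by_genes = assemble_hotspots(_genes(spec), sel, min_genes=3, count="genes")
    assert len(by_genes) == 1  # 3 genes
    by_ogs = assemble_hotspots(_genes(spec), sel, min_genes=3, count="orthogroups")
    assert by_ogs == []  # only 2 distinct orthogroups


def test_multiple_genomes_error():
    genes = _genes([("g1", 1, 10, "A")]) + _genes([("g2", 1, 10, "A")], genome="other")
    with pytest.raises(ValueError):
        assemble_hotspots(genes, _selection(["A"]))


def test_assembly_input_order_invariant(rng):
    spec = [(f"g{i}", 1 + i * 3000, 800 + i * 3000, f"OG{i}") for i in range(12)]
    genes = _genes(spec)
    sel = _selection([f"OG{i}" for i in range(12)])
    ref = assemble_hotspots(genes, sel, gap_bp=5000, min_genes=1)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    out = assemble_hotspots(shuffled, sel, gap_bp=5000, min_genes=1)
    assert [[g.gene_id for g in h.genes] for h in out] == \
        [[g.gene_id for g in h.genes] for h in ref]


def bruteforce_runs(genes, gap_bp):
    """Connected components under the pairwise gap relation."""
    idx = list(range(len(genes)))
    parent = dict(zip(idx, idx))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(idx, 2):
        a, b = genes[i], genes[j]
        if a.scaffold_id != b.scaffold_id:
            continue
        gap = max(a.start, b.start) - min(a.end, b.end) - 1
        if gap < gap_bp:
            parent[find(i)] = find(j)
    comps = {}
    for i in idx:
        comps.setdefault(find(i), []).append(genes[i])
    return sorted(
        (sorted(g.gene_id for g in comp) for comp in comps.values()),
        key=lambda ids: ids[0],
    )


@pytest.mark.parametrize("seed", range(5))
def test_assembly_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 30))
    starts = np.cumsum(rng.integers(200, 20_000, size=n))
    genes = [GeneRecord(f"g{i}", "ref", "scf1", int(s), int(s + rng.integers(100, 900)),
                        "+", f"OG{i}") for i, s in enumerate(starts)]
    sel = _selection([f"OG{i}" for i in range(n)])
    gap_bp = int(rng.integers(1000, 15_000))
    got = assemble_hotspots(genes, sel, gap_bp=gap_bp, min_genes=1)
    got_sets = sorted((sorted(g.gene_id for g in h.genes) for h in got),
                      key=lambda ids: ids[0])
    assert got_sets == bruteforce_runs(genes, gap_bp)


def test_gap_monotonicity():
    rng = np.random.default_rng(17)
    starts = np.cumsum(rng.integers(500, 12_000, size=20))
    genes = [GeneRecord(f"g{i}", "ref", "scf1", int(s), int(s + 400), "+", f"OG{i}")
             for i, s in enumerate(starts)]
    sel = _selection([f"OG{i}" for i in range(20)])
    counts = [len(assemble_hotspots(genes, sel, gap_bp=g, min_genes=1))
              for g in (1000, 3000, 6000, 10000, 20000)]
    assert counts == sorted(counts, reverse=True)


def test_every_selected_gene_in_exactly_one_run():
    ann, og, truth = simulate_pangenome(10, 3, 8, 3, seed=4)
    focal = {g for g in ann if g.startswith("focal")}
    background = {g for g in ann if g.startswith("bg")}
    sel = select_clade_specific(og, focal, background)
    runs = assemble_hotspots(ann[truth.reference_genome], sel, min_genes=1)
    seen = [g.gene_id for h in runs for g in h.genes]
    expected = {g.gene_id for g in ann[truth.reference_genome]
                if g.orthogroup_id in sel.selected}
    assert sorted(seen) == sorted(expected)
    assert len(seen) == len(set(seen))


def test_planted_pangenome_recovery():
    ann, og, truth = simulate_pangenome(20, 3, 12, 5, seed=3)
    focal = {g for g in ann if g.startswith("focal")}
    background = {g for g in ann if g.startswith("bg")}
    sel = select_clade_specific(og, focal, background)
    found = assemble_hotspots(ann[truth.reference_genome], sel)
    assert len(found) == 1
    assert sorted(g.gene_id for g in found[0].genes) == sorted(truth.hotspot_gene_ids)
    assert (found[0].start, found[0].end) == truth.interval


def test_undersized_planted_hotspot_not_reported():
    ann, og, truth = simulate_pangenome(20, 3, 9, 5, seed=3)
    focal = {g for g in ann if g.startswith("focal")}
    background = {g for g in ann if g.startswith("bg")}
    sel = select_clade_specific(og, focal, background)
    assert assemble_hotspots(ann[truth.reference_genome], sel, min_genes=10) == []


def test_nothing_planted_nothing_selected():
    ann, og, truth = simulate_pangenome(10, 2, 0, 0, seed=6)
    focal = {g for g in ann if g.startswith("focal")}
    background = {g for g in ann if g.startswith("bg")}
    sel = select_clade_specific(og, focal, background)
    assert sel.selected == set()


# ---------------------------------------------------------------------------
# intervals


def test_interval_length_printed_inserts():
    assert interval_length_kb(29_100, 64_406) == 35
    assert interval_length_kb(52_627, 67_679) == 15


def test_interval_length_single_base():
    assert interval_length_kb(5, 5) == 0


def test_interval_length_invalid():
    with pytest.raises(ValueError):
        interval_length_kb(10, 5)
    with pytest.raises(ValueError):
        interval_length_kb(0, 5)


def test_interval_intersect_printed_inserts():
    assert interval_intersect((29_100, 64_406), (52_627, 67_679)) == (52_627, 64_406)


def test_interval_intersect_disjoint_and_idempotent():
    assert interval_intersect((1, 10), (20, 30)) is None
    assert interval_intersect((5, 9), (5, 9)) == (5, 9)


def test_interval_intersect_different_scaffolds_warns(caplog):
    out = interval_intersect((1, 10), (5, 20), scaffold_a="s1", scaffold_b="s2")
    assert out is None


def test_genes_in_interval():
    genes = _genes([("g1", 10, 20, "A"), ("g2", 30, 40, "B"), ("g3", 35, 60, "C")])
    inside = genes_in_interval(genes, "scf1", (25, 45))
    assert [g.gene_id for g in inside] == ["g2"]


# ---------------------------------------------------------------------------
# hotspot_report


def test_report_empty():
    og = _og_table({}, {"a"})
    sel = CladeSpecificSelection(set(), {"a"}, set(), {}, {}, 0.05)
    summary, matrix = hotspot_report([], og, sel)
    assert summary.empty and list(summary.columns)[0] == "hotspot_id"
    assert matrix.empty


def test_report_planted_presence_matrix():
    ann, og, truth = simulate_pangenome(20, 3, 12, 5, seed=3)
    focal = {g for g in ann if g.startswith("focal")}
    background = {g for g in ann if g.startswith("bg")}
    sel = select_clade_specific(og, focal, background)
    found = assemble_hotspots(ann[truth.reference_genome], sel)
    summary, matrix = hotspot_report(found, og, sel)
    col = matrix.columns[0]
    for g in focal:
        assert matrix.loc[g, col] == 1.0
    for g in background:
        assert matrix.loc[g, col] < sel.max_bg_prev


def test_report_intervals_disjoint_sorted():
    spec = ([(f"a{i}", 1 + i * 500, 400 + i * 500, f"A{i}") for i in range(10)]
            + [(f"b{i}", 100_000 + i * 500, 100_400 + i * 500, f"B{i}")
               for i in range(10)])
    sel = _selection([f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)])
    found = assemble_hotspots(_genes(spec), sel, min_genes=10)
    summary, _ = hotspot_report(found, _og_table({}, {"ref"}),
                                CladeSpecificSelection(sel.selected, {"ref"}, set(),
                                                       {}, {}, 0.05))
    assert len(summary) == 2
    assert summary["start"].is_monotonic_increasing
    assert summary.loc[0, "end"] < summary.loc[1, "start"]
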