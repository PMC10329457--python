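"""Readers and writers for the formats the pipeline touches.

GFF3 coordinates are 1-based inclusive throughout; BED export converts to
0-based half-open. TSV writers are byte-stable given fixed inputs. Every
output directory gets a provenance record (version, config snapshot, input
checksums, timestamp).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cooccurrence import AbundanceTable, ModuleAssignment
from .geneset import ExpressionMatrix
from .hotspot import GeneRecord, Hotspot, OrthogroupTable


class ParseError(ValueError):
    """Raised on malformed input files; carries path and line number."""

    def __init__(self, path, line_no: int | None, message: str):
        self.path, self.line_no = path, line_no
        where = f"{path}:{line_no}" if line_no is not None else str(path)
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[GeneRecord]:
    """Parse gene features from a GFF3 file into GeneRecords.

    Only rows with feature type ``gene`` are kept. The gene id comes from
    the ``ID`` attribute, the genome id from the ``genome`` attribute when
    present (else the file stem). Records are returned sorted by
    (scaffold, start).
    """
    path = Path(path)
    records: list[GeneRecord] = []
    default_genome = path.stem
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, line_no, f"expected 9 columns, got {len(fields)}")
            scaffold, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, line_no, "non-integer coordinates") from None
            if start > end or start < 1:
                raise ParseError(path, line_no, f"bad interval {start}..{end}")
            attr_map = _parse_attributes(attrs)
            if "ID" not in attr_map:
                raise ParseError(path, line_no, "gene feature missing ID attribute")
            if strand not in ("+", "-"):
                raise ParseError(path, line_no, f"bad strand {strand!r}")
            records.append(GeneRecord(
                gene_id=attr_map["ID"],
                genome_id=attr_map.get("genome", default_genome),
                scaffold_id=scaffold, start=start, end=end, strand=strand,
                orthogroup_id=attr_map.get("orthogroup"),
            ))
    records.sort(key=lambda g: (g.scaffold_id, g.start, g.end, g.gene_id))
    return records


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk and "=" in chunk:
            key, _, val = chunk.partition("=")
            out[key] = val
    return out


def write_gff3(records: list[GeneRecord], path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(records, key=lambda g: (g.scaffold_id, g.start, g.end, g.gene_id)):
        attrs = f"ID={g.gene_id};genome={g.genome_id}"
        if g.orthogroup_id is not None:
            attrs += f";orthogroup={g.orthogroup_id}"
        lines.append("\t".join([
            g.scaffold_id, "syncom", "gene", str(g.start), str(g.end),
            ".", g.strand, ".", attrs,
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_hotspot_gff3(hotspots: list[Hotspot], path) -> None:
    """Regions plus member genes, 1-based inclusive."""
    lines = ["##gff-version 3"]
    for h in hotspots:
        lines.append("\t".join([
            h.scaffold_id, "syncom", "region", str(h.start), str(h.end),
            ".", ".", ".", f"ID=hotspot_{h.hotspot_id}",
        ]))
        for g in h.genes:
            lines.append("\t".join([
                g.scaffold_id, "syncom", "gene", str(g.start), str(g.end),
                ".", g.strand, ".",
                f"ID={g.gene_id};Parent=hotspot_{h.hotspot_id};orthogroup={g.orthogroup_id}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start < 1 or start > end:
        raise ValueError(f"bad interval {start}..{end}")
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if bed_start < 0 or bed_start >= bed_end:
        raise ValueError(f"bad BED interval {bed_start}..{bed_end}")
    return bed_start + 1, bed_end


def write_hotspot_bed(hotspots: list[Hotspot], path) -> None:
    lines = []
    for h in hotspots:
        s, e = to_bed_interval(h.start, h.end)
        lines.append(f"{h.scaffold_id}\t{s}\t{e}\thotspot_{h.hotspot_id}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path, required: tuple[str, ...], numeric: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(path, None, "empty file")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns {missing}")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(path, int(bad) + 2,
                             f"non-numeric value {df.at[bad, col]!r} in column {col!r}") from None
    return df


def read_abundance(path, meta_path=None, taxonomy_path=None) -> AbundanceTable:
    """Abundance TSV: first column ``strain``, remaining columns samples."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(path, None, "empty file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(path, None, "abundance matrix contains missing values")
    meta = None
    if meta_path is not None:
        meta = _read_tsv(meta_path, ("sample", "fraction", "condition", "replicate"))
        meta = meta.set_index("sample")
    tax = None
    if taxonomy_path is not None:
        tax = read_taxonomy(taxonomy_path)
    return AbundanceTable(values=df, sample_meta=meta, taxonomy=tax)


def write_abundance(table: AbundanceTable, path, meta_path=None, taxonomy_path=None) -> None:
    out = table.values.copy()
    out.index.name = "strain"
    out.to_csv(path, sep="\t")
    if meta_path is not None and table.sample_meta is not None:
        m = table.sample_meta.copy()
        m.index.name = "sample"
        m.to_csv(meta_path, sep="\t")
    if taxonomy_path is not None and table.taxonomy is not None:
        t = table.taxonomy.copy()
        t.index.name = "strain"
        t.to_csv(taxonomy_path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    df = _read_tsv(path, ("strain", "family"))
    return df.set_index("strain")


def read_orthogroups(path) -> OrthogroupTable:
    df = _read_tsv(path, ("gene_id", "genome_id", "orthogroup_id"))
    return OrthogroupTable.from_frame(df)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    rows = []
    for og_id in sorted(table.members):
        for genome, gene in sorted(table.members[og_id]):
            rows.append({"gene_id": gene, "genome_id": genome, "orthogroup_id": og_id})
    pd.DataFrame(rows, columns=["gene_id", "genome_id", "orthogroup_id"]).to_csv(
        path, sep="\t", index=False)


def read_clades(path) -> tuple[set[str], set[str]]:
    """Clade definition TSV: columns genome_id, role in {focal, background}."""
    df = _read_tsv(path, ("genome_id", "role"))
    bad = sorted(set(df["role"]) - {"focal", "background"})
    if bad:
        raise ParseError(path, None, f"unknown roles {bad}")
    focal = set(df.loc[df["role"] == "focal", "genome_id"])
    background = set(df.loc[df["role"] == "background", "genome_id"])
    return focal, background


def read_phenotypes(path) -> pd.DataFrame:
    return _read_tsv(path, ("treatment", "elongation_cm"), numeric=("elongation_cm",))


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_expression(path, treatments_path) -> ExpressionMatrix:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(path, None, "empty file")
    values = pd.read_csv(path, sep="\t", index_col=0)
    tmeta = _read_tsv(treatments_path, ("sample", "treatment"))
    return ExpressionMatrix(values, tmeta.set_index("sample")["treatment"])


def write_expression(m: ExpressionMatrix, path, treatments_path) -> None:
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    t = m.treatments.rename_axis("sample").reset_index()
    t.to_csv(treatments_path, sep="\t", index=False)


def read_survey(path) -> pd.DataFrame:
    df = _read_tsv(path, ("site", "sample", "asv", "relative_abundance"),
                   numeric=("relative_abundance",))
    if "reads" in df.columns:
        df["reads"] = pd.to_numeric(df["reads"])
    return df


def write_survey(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    genes = [ln.strip() for ln in lines if ln.strip()]
    if not genes:
        raise ParseError(path, None, "gene-set file is empty")
    return genes


# ---------------------------------------------------------------------------
# Newick dendrogram


def linkage_to_newick(linkage_matrix: np.ndarray, leaf_names: list[str]) -> str:
    """Newick string with merge heights as branch lengths.

    A child's branch length is its parent's merge height minus its own
    (leaves have height 0), so root-to-leaf path length equals the root
    merge height.
    """
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}

    def node(idx: int, parent_height: float) -> str:
        if idx < n:
            return f"{leaf_names[idx]}:{parent_height:.6g}"
        row = linkage_matrix[idx - n]
        h = float(row[2])
        left, right = int(row[0]), int(row[1])
        return f"({node(left, h)},{node(right, h)}):{parent_height - h:.6g}"

    if n == 1:
        return f"{leaf_names[0]};"
    root = len(linkage_matrix) + n - 1
    row = linkage_matrix[-1]
    h = float(row[2])
    heights[root] = h
    return f"({node(int(row[0]), h)},{node(int(row[1]), h)});"


def write_modules(assignment: ModuleAssignment, tsv_path, newick_path=None) -> None:
    df = assignment.labels.rename_axis("strain").reset_index()
    df.to_csv(tsv_path, sep="\t", index=False)
    if newick_path is not None:
        Path(newick_path).write_text(
            linkage_to_newick(assignment.linkage_matrix, assignment.strain_ids) + "\n",
            encoding="utf-8")


# ---------------------------------------------------------------------------
# provenance


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir, config: dict, input_paths: list) -> Path:
    from . import __version__
    record = {
        "tool": "syncom",
        "version": __version__,
        "config": config,
        "inputs": {str(p): sha256_file(p) for p in input_paths},
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    out = Path(out_dir) / "provenance.json"
    out.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out
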