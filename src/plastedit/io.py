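"""Readers and writers for the formats the pipeline touches.

TSV dialect: UTF-8, tab-delimited, ``#``-prefixed comment lines, ``.`` for
missing values. Coordinates are 1-based; intervals closed. Efficiencies are
stored as fractions at full precision in machine tables and rendered as
two-decimal percentages only in human-facing report output.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .types import (
    REGION_CDS,
    REGION_DOWNSTREAM,
    REGION_INTERGENIC,
    REGION_INTRON,
    EditingSite,
    EfficiencyTable,
    GeneModel,
    Reference,
    SiteCounts,
)

#: Canonical sample labels of the two-genotype, two-stage design.
TABLE1_SAMPLES = ("HD12-S1", "HD12-S2", "Gmpgl2-S1", "Gmpgl2-S2")

_COUNTS_COLUMNS = ["position", "strand", "ref_base", "var_base", "n_ref", "n_var"]
_SITE_META_COLUMNS = ["gene", "position", "strand", "region", "change"]


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Reference:
    """Read the first record of a FASTA file as the plastome reference."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    rec = records[0]
    return Reference(name=rec.id, sequence=str(rec.seq))


def write_fasta(reference: Reference, path: str | Path) -> None:
    rec = SeqRecord(Seq(reference.sequence), id=reference.name, description="")
    with open(path, "w") as handle:
        SeqIO.write([rec], handle, "fasta")


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3-style file with gene and exon features.

    Exons are attached to genes via their ``Parent`` attribute; a gene with
    no exon features is treated as a single-exon gene over its span.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        if g.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {g.id}: unknown strand symbol {g.strand!r}"
            )
        exons = sorted(
            (c.start, c.end) for c in db.children(g, featuretype="exon")
        )
        if not exons:
            exons = [(g.start, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                strand=g.strand,
                exons=tuple(exons),
                gene_span=(g.start, g.end),
            )
        )
    return genes


def write_annotation(
    genes: list[GeneModel], path: str | Path, seqid: str = "plastome"
) -> None:
    """Write gene models as GFF3 (gene + exon features)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        s, e = gene.gene_span
        lines.append(
            f"{seqid}\tplastedit\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\t"
            f"ID={gene.gene_id}"
        )
        for i, (xs, xe) in enumerate(gene.exons, 1):
            lines.append(
                f"{seqid}\tplastedit\texon\t{xs}\t{xe}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Per-site allele counts
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype=str,
            na_values=["."],
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df


def read_site_counts(path: str | Path, sample_label: str) -> list[SiteCounts]:
    """Read a per-site allele-count table for one sample.

    Rows are transcript-sense: ``ref_base``/``var_base`` already reflect the
    transcript strand given in the ``strand`` column.
    """
    df = _read_tsv(path, _COUNTS_COLUMNS)
    records: list[SiteCounts] = []
    for i, row in enumerate(df.itertuples(index=False), 1):
        try:
            rec = SiteCounts(
                position=int(row.position),
                strand=str(row.strand),
                ref_base=str(row.ref_base),
                var_base=str(row.var_base),
                n_ref=int(row.n_ref),
                n_var=int(row.n_var),
                sample=sample_label,
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        records.append(rec)
    return records


def write_site_counts(records: list[SiteCounts], path: str | Path) -> None:
    lines = ["\t".join(_COUNTS_COLUMNS)]
    for r in records:
        lines.append(
            f"{r.position}\t{r.strand}\t{r.ref_base}\t{r.var_base}\t"
            f"{r.n_ref}\t{r.n_var}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Efficiency tables
# ---------------------------------------------------------------------------

def write_efficiency_table(table: EfficiencyTable, path: str | Path) -> None:
    """Machine table: metadata columns then one fraction column per sample.

    Fractions are written at full float precision so that a write/read
    round trip reproduces records exactly; use :func:`render_percent_table`
    for the two-decimal percentage report form.
    """
    header = _SITE_META_COLUMNS + list(table.samples)
    lines = ["\t".join(header)]
    for site in table.sites:
        cells = [
            site.gene_id if site.gene_id is not None else ".",
            str(site.position),
            site.strand,
            site.region if site.region is not None else ".",
            site.change if site.change is not None else ".",
        ]
        for sample in table.samples:
            eff = site.efficiency_by_sample.get(sample)
            cells.append(repr(eff) if eff is not None else ".")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_efficiency_table(path: str | Path) -> EfficiencyTable:
    df = _read_tsv(path, _SITE_META_COLUMNS)
    samples = [c for c in df.columns if c not in _SITE_META_COLUMNS]
    sites: list[EditingSite] = []
    # row access via iloc: sample labels like "HD12-S1" are not identifiers,
    # so itertuples would mangle them
    for i in range(len(df)):
        row = df.iloc[i]
        eff: dict[str, float] = {}
        for sample in samples:
            cell = row[sample]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            eff[sample] = float(cell)
        try:
            sites.append(
                EditingSite(
                    gene_id=None if _missing(row["gene"]) else str(row["gene"]),
                    position=int(row["position"]),
                    strand=str(row["strand"]),
                    region=None if _missing(row["region"]) else str(row["region"]),
                    change=None if _missing(row["change"]) else str(row["change"]),
                    efficiency_by_sample=eff,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 1}: {exc}") from None
    return EfficiencyTable(sites=sites, samples=samples)


def _missing(cell) -> bool:
    return cell is None or (isinstance(cell, float) and math.isnan(cell))


def format_percent(fraction: float) -> str:
    """Render a fraction as the report percentage form, e.g. ``'79.02%'``."""
    return f"{100.0 * fraction:.2f}%"


def render_percent_table(table: EfficiencyTable) -> pd.DataFrame:
    """Human-facing report: efficiencies as two-decimal percent strings."""
    rows = []
    for site in table.sites:
        row: dict[str, object] = {
            "gene": site.gene_id,
            "position": site.position,
            "region": site.region,
            "change": site.change,
        }
        for sample in table.samples:
            eff = site.efficiency_by_sample.get(sample)
            row[sample] = format_percent(eff) if eff is not None else "."
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundled curated table
# ---------------------------------------------------------------------------

_LABEL_REGIONS = {
    "downstream": REGION_DOWNSTREAM,
    "intergenic": REGION_INTERGENIC,
    "intron": REGION_INTRON,
}

_FIXTURE_BREAKDOWN = {
    REGION_CDS: 38,
    REGION_INTRON: 2,
    REGION_INTERGENIC: 2,
    REGION_DOWNSTREAM: 1,
}


def parse_percent(cell: str) -> float:
    """Parse a printed percent cell ('79.02%', '0%') to a fraction."""
    text = str(cell).strip()
    if not text.endswith("%"):
        raise FormatError(f"expected a percent cell, got {cell!r}")
    return float(text[:-1]) / 100.0


def load_table1_fixture() -> EfficiencyTable:
    """Load the bundled curated table of 43 editing sites x 4 samples.

    The printed per-cell label is split into a region class and, for coding
    sites, an amino-acid-change label. The expected composition (43 sites;
    38 coding, 2 intron, 2 intergenic, 1 downstream) is asserted at load
    time so a corrupted asset fails fast.
    """
    src = resources.files("plastedit").joinpath(
        "data/table1_editing_efficiencies.tsv"
    )
    with resources.as_file(src) as path:
        df = _read_tsv(path, ["gene", "position", "label", *TABLE1_SAMPLES])
    sites: list[EditingSite] = []
    for _, row in df.iterrows():
        label = str(row["label"]).strip()
        region = _LABEL_REGIONS.get(label.lower(), REGION_CDS)
        change = label if region == REGION_CDS else None
        eff = {s: parse_percent(row[s]) for s in TABLE1_SAMPLES}
        sites.append(
            EditingSite(
                gene_id=str(row["gene"]),
                position=int(row["position"]),
                strand="+",
                region=region,
                change=change,
                efficiency_by_sample=eff,
            )
        )
    table = EfficiencyTable(sites=sites, samples=list(TABLE1_SAMPLES))
    counts = {region: 0 for region in _FIXTURE_BREAKDOWN}
    for site in table.sites:
        counts[site.region] += 1
    if len(table) != 43 or counts != _FIXTURE_BREAKDOWN:
        raise ValidationError(
            f"curated table corrupted: {len(table)} rows, breakdown {counts}"
        )
    return table


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration as a plain dict."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return data
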