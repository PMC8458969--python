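"""Synthetic plastomes, truth panels and binomially sampled read counts.

The generator emulates what a pileup over aligned chloroplast RNA-seq reads
would deliver: at a true editing site with efficiency ``e`` and coverage
``m``, the variant-read count is ``Binomial(m, e*(1-eps) + (1-e)*eps)``
with a symmetric, position-independent sequencing error rate ``eps``; at a
non-edited C it is ``Binomial(m, eps)``. Coverage is fixed per site or
negative-binomially dispersed. All counts are reported transcript-sense.

Two panel sources are provided:

* :func:`generate_reference` draws a random toy plastome (genes on both
  strands, optional introns) and a random truth panel — a pure function of
  the configuration seed;
* :func:`panel_from_table1` deterministically builds a toy plastome hosting
  the 43 curated sites with their printed efficiencies, region classes
  (38 CDS, 2 intron, 2 intergenic, 1 downstream) and codon contexts chosen
  to reproduce each printed substitution type. The printed genomic
  positions are kept as site *labels*; toy coordinates are synthetic.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .caller import codon_context, format_change, predict_amino_acid_change
from .errors import ConfigError, GenerationError, ValidationError
from .io import TABLE1_SAMPLES, load_table1_fixture, _read_tsv
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
    revcomp,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
#: C-free filler codons used by the deterministic builder so that every C it
#: plants is accounted for.
_C_FREE_CODONS = ("GAA", "GGT", "ATT", "GAT", "TGG", "AGA")

#: Codon context (transcript sense) and edited offset realising each printed
#: substitution type under the plastid genetic code.
CHANGE_CODONS: dict[str, tuple[str, int]] = {
    "Ser-Leu": ("TCA", 2),
    "Ser-Phe": ("TCT", 2),
    "Pro-Leu": ("CCA", 2),
    "Thr-Met": ("ACG", 2),
    "Thr-Ile": ("ACA", 2),
    "His-Tyr": ("CAT", 1),
    "Unchanged": ("CTC", 3),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator.

    Defaults describe the study conditions being emulated: a four-sample
    (two genotypes x two stages) design, 43 editing sites, deep plastid
    transcript coverage (2,000x fixed) and an Illumina-like per-base error
    rate of 1e-3.
    """

    seed: int = 0
    n_genes: int = 12
    gene_length_range: tuple[int, int] = (300, 900)
    intron_probability: float = 0.3
    intron_length_range: tuple[int, int] = (60, 150)
    minus_strand_fraction: float = 0.5
    intergenic_length_range: tuple[int, int] = (150, 400)
    n_sites: int = 43
    samples: tuple[str, ...] = TABLE1_SAMPLES
    coverage_mean: float = 2000.0
    coverage_dispersion: float | None = None
    error_rate: float = 0.001
    affected_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_sites < 0:
            raise ConfigError("n_sites must be >= 0")
        for lo, hi in (
            self.gene_length_range,
            self.intron_length_range,
            self.intergenic_length_range,
        ):
            if not 0 < lo <= hi:
                raise ConfigError(f"bad length range ({lo}, {hi})")
        for name, p in (
            ("intron_probability", self.intron_probability),
            ("minus_strand_fraction", self.minus_strand_fraction),
            ("error_rate", self.error_rate),
            ("affected_fraction", self.affected_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be positive")
        if len(self.samples) != 4:
            raise ConfigError(
                "the design needs four samples (wild type / mutant at two "
                "stages)"
            )


@dataclass(frozen=True)
class TruthSite:
    """Ground truth for one editing site.

    ``label`` is the site's public identifier (the printed genomic position
    for curated panels); ``position`` is the coordinate on the toy
    reference. ``efficiency`` maps sample label to the true edited fraction.
    """

    gene_id: str
    label: int
    position: int
    strand: str
    region: str
    efficiency: Mapping[str, float]
    codon: str | None = None
    codon_offset: int | None = None
    change: str | None = None

    def __post_init__(self) -> None:
        for sample, e in self.efficiency.items():
            if not 0.0 <= e <= 1.0:
                raise ValidationError(
                    f"site {self.gene_id}-{self.label}, sample {sample}: "
                    f"true efficiency {e} outside [0, 1]"
                )


@dataclass
class TruthPanel:
    """Truth sites plus the toy reference and annotation they live on."""

    reference: Reference
    genes: list[GeneModel]
    sites: list[TruthSite]
    samples: list[str]
    error_rate: float = 0.0
    coverage_mean: float = 2000.0
    coverage_dispersion: float | None = None

    def __post_init__(self) -> None:
        gene_by_id = {g.gene_id: g for g in self.genes}
        for site in self.sites:
            base = self.reference.base(site.position)
            sense = base if site.strand == "-" else base
            if site.strand == "-":
                sense = revcomp(base)
            if sense != "C":
                raise ValidationError(
                    f"truth site {site.gene_id}-{site.label} at "
                    f"{site.position}{site.strand} is not a transcript-sense C"
                )
            if site.region in (REGION_CDS, REGION_INTRON):
                if site.gene_id not in gene_by_id:
                    raise ValidationError(
                        f"truth site {site.gene_id}-{site.label}: unknown gene"
                    )

    def site_keys(self) -> list[tuple[str, int]]:
        return [(s.gene_id, s.label) for s in self.sites]


# ---------------------------------------------------------------------------
# Random toy plastome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n)]


class _GenomeAssembler:
    """Accumulates sequence chunks left to right with 1-based coordinates."""

    def __init__(self) -> None:
        self.chunks: list[str] = []
        self.cursor = 1  # next free position

    def emit(self, seq: str) -> int:
        start = self.cursor
        self.chunks.append(seq)
        self.cursor += len(seq)
        return start

    def sequence(self) -> str:
        return "".join(self.chunks)


def _place_gene(
    asm: _GenomeAssembler,
    gene_id: str,
    strand: str,
    cds: str,
    exon1_len: int | None,
    intron_seq: str | None,
) -> GeneModel:
    """Emit a gene's pre-mRNA (transcript sense) onto the plus strand."""
    if intron_seq is not None:
        pre = cds[:exon1_len] + intron_seq + cds[exon1_len:]
    else:
        pre = cds
    placed = pre if strand == "+" else revcomp(pre)
    start = asm.emit(placed)
    end = start + len(pre) - 1
    if intron_seq is None:
        exons = ((start, end),)
    else:
        ilen = len(intron_seq)
        if strand == "+":
            exons = (
                (start, start + exon1_len - 1),
                (start + exon1_len + ilen, end),
            )
        else:
            # transcript exon1 occupies the high-coordinate side
            exons = (
                (start, end - exon1_len - ilen),
                (end - exon1_len + 1, end),
            )
    return GeneModel(
        gene_id=gene_id, strand=strand, exons=exons, gene_span=(start, end)
    )


def _transcript_to_genomic(gene: GeneModel, t: int) -> int:
    """Map a 1-based pre-mRNA (unspliced, transcript-sense) offset to a
    genomic coordinate."""
    if gene.strand == "+":
        return gene.gene_span[0] + t - 1
    return gene.gene_span[1] - (t - 1)


def _draw_efficiencies(
    rng: np.random.Generator, config: SimulationConfig
) -> dict[str, float]:
    """Two-genotype x two-stage true efficiencies for one site."""
    wt1 = rng.uniform(0.25, 0.95)
    wt2 = float(np.clip(wt1 + rng.normal(0.0, 0.08), 0.0, 1.0))
    if rng.random() < config.affected_fraction:
        drop = rng.uniform(0.15, 0.8)
        mut1 = max(wt1 - drop, 0.0)
        mut2 = max(wt2 - drop * rng.uniform(0.6, 1.1), 0.0)
    else:
        mut1 = float(np.clip(wt1 + rng.normal(0.0, 0.02), 0.0, 1.0))
        mut2 = float(np.clip(wt2 + rng.normal(0.0, 0.02), 0.0, 1.0))
    wt_s1, wt_s2, mut_s1, mut_s2 = config.samples
    return {wt_s1: wt1, wt_s2: wt2, mut_s1: mut1, mut_s2: mut2}


def generate_reference(
    config: SimulationConfig,
) -> tuple[Reference, list[GeneModel], TruthPanel]:
    """Draw a random toy plastome, gene models and truth panel.

    Pure function of ``config`` (including its seed): the same configuration
    always yields byte-identical FASTA/GFF3/panel output. Genes are placed
    on both strands; truth sites are exonic transcript-sense Cs, so every
    site carries a codon context and a substitution label.
    """
    rng = np.random.default_rng(config.seed)
    asm = _GenomeAssembler()
    strands = [
        "-" if x < config.minus_strand_fraction else "+"
        for x in rng.random(config.n_genes)
    ]
    if config.n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "-" if strands[-1] == "+" else "+"

    genes: list[GeneModel] = []
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        asm.emit(_random_seq(rng, int(rng.integers(*_incl(config.intergenic_length_range)))))
        n_codons = int(rng.integers(max(lo // 3, 4), hi // 3 + 1))
        cds = "ATG" + "".join(_random_codons(rng, n_codons - 2)) + "TAA"
        exon1_len = None
        intron_seq = None
        if rng.random() < config.intron_probability and len(cds) >= 60:
            exon1_len = int(rng.integers(10, len(cds) - 10))
            intron_seq = _random_seq(
                rng, int(rng.integers(*_incl(config.intron_length_range)))
            )
        genes.append(
            _place_gene(asm, f"g{i + 1:02d}", strands[i], cds, exon1_len, intron_seq)
        )
    asm.emit(_random_seq(rng, int(rng.integers(*_incl(config.intergenic_length_range)))))
    reference = Reference(name="synthetic_plastome", sequence=asm.sequence())

    # candidate truth sites: exonic transcript-sense Cs with a complete codon
    candidates: list[tuple[GeneModel, int]] = []
    for gene in genes:
        usable = (gene.transcript_length // 3) * 3
        for s, e in gene.exons:
            for pos in range(s, e + 1):
                base = reference.base(pos)
                sense = base if gene.strand == "+" else revcomp(base)
                if sense != "C":
                    continue
                if gene.transcript_offset(pos) > usable:
                    continue
                candidates.append((gene, pos))
    if config.n_sites > len(candidates):
        raise GenerationError(
            f"requested {config.n_sites} sites but the toy plastome has only "
            f"{len(candidates)} usable transcript-sense Cs"
        )
    chosen_idx = sorted(
        rng.choice(len(candidates), size=config.n_sites, replace=False).tolist()
    )
    sites: list[TruthSite] = []
    for idx in chosen_idx:
        gene, pos = candidates[idx]
        codon, offset = codon_context(pos, gene, reference)
        change = format_change(predict_amino_acid_change(codon, offset))
        sites.append(
            TruthSite(
                gene_id=gene.gene_id,
                label=pos,
                position=pos,
                strand=gene.strand,
                region=REGION_CDS,
                efficiency=_draw_efficiencies(rng, config),
                codon=codon,
                codon_offset=offset,
                change=change,
            )
        )
    panel = TruthPanel(
        reference=reference,
        genes=genes,
        sites=sites,
        samples=list(config.samples),
        error_rate=config.error_rate,
        coverage_mean=config.coverage_mean,
        coverage_dispersion=config.coverage_dispersion,
    )
    return reference, genes, panel


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return (lo, hi + 1)


# ---------------------------------------------------------------------------
# Deterministic panel seeded from the curated table
# ---------------------------------------------------------------------------

_FLANK_FILLER = 600       # nt of intergenic filler after every gene
_DOWNSTREAM_DIST = 50     # planted distance for the downstream site
_INTERGENIC_DIST = 250    # planted distance for intergenic sites (> window)
_EXON1_LEN = 18           # exon 1 length of intron-bearing toy genes
_INTRON_LEN = 120
_INTRON_C_OFFSET = 50     # planted C within the intron (transcript sense)


def _c_free_filler(rng: np.random.Generator, length: int) -> list[str]:
    pool = "AGT"
    return [pool[i] for i in rng.integers(0, 3, size=length)]


def panel_from_table1() -> TruthPanel:
    """Deterministic 43-site truth panel on a purpose-built toy plastome.

    Per-sample true efficiencies equal the curated printed values
    (as fractions). Coding sites are planted inside toy CDSs with codon
    contexts that reproduce each printed substitution type; the two intron
    sites sit inside real inter-exon gaps, the two intergenic sites in
    filler beyond the downstream window of their nearest gene, and the
    single downstream site within that window. One multi-site gene (ndhB)
    is placed on the minus strand so strand arithmetic is exercised.
    """
    fixture = load_table1_fixture()
    rng = np.random.default_rng(709973)
    rows_by_gene: "OrderedDict[str, list[EditingSite]]" = OrderedDict()
    for row in fixture.sites:
        rows_by_gene.setdefault(row.gene_id, []).append(row)

    asm = _GenomeAssembler()
    genes: list[GeneModel] = []
    sites: list[TruthSite] = []
    asm.emit("".join(_c_free_filler(rng, _FLANK_FILLER)))

    for gene_id, rows in rows_by_gene.items():
        cds_rows = [r for r in rows if r.region == REGION_CDS]
        intron_rows = [r for r in rows if r.region == REGION_INTRON]
        flank_rows = [
            r
            for r in rows
            if r.region in (REGION_DOWNSTREAM, REGION_INTERGENIC)
        ]
        strand = "-" if gene_id == "ndhB" else "+"

        codons = ["ATG"]
        site_slots: list[tuple[EditingSite, int, str, int]] = []
        for r in cds_rows:
            codons.extend(
                _C_FREE_CODONS[i] for i in rng.integers(0, len(_C_FREE_CODONS), 3)
            )
            codon, offset = CHANGE_CODONS[r.change]
            site_slots.append((r, len(codons), codon, offset))
            codons.append(codon)
        codons.extend(
            _C_FREE_CODONS[i] for i in rng.integers(0, len(_C_FREE_CODONS), 3)
        )
        codons.append("TAA")
        cds = "".join(codons)

        exon1_len = None
        intron_seq = None
        if intron_rows:
            exon1_len = min(_EXON1_LEN, len(cds) - 3)
            intron = _c_free_filler(rng, _INTRON_LEN)
            intron[_INTRON_C_OFFSET - 1] = "C"
            intron_seq = "".join(intron)
        gene = _place_gene(asm, gene_id, strand, cds, exon1_len, intron_seq)
        genes.append(gene)

        for r, codon_index, codon, offset in site_slots:
            s_cds = codon_index * 3 + offset  # 1-based within spliced CDS
            t = s_cds
            if intron_seq is not None and s_cds > exon1_len:
                t += len(intron_seq)
            sites.append(
                TruthSite(
                    gene_id=gene_id,
                    label=r.position,
                    position=_transcript_to_genomic(gene, t),
                    strand=strand,
                    region=REGION_CDS,
                    efficiency=dict(r.efficiency_by_sample),
                    codon=codon,
                    codon_offset=offset,
                    change=r.change,
                )
            )
        for r in intron_rows:
            t = exon1_len + _INTRON_C_OFFSET
            sites.append(
                TruthSite(
                    gene_id=gene_id,
                    label=r.position,
                    position=_transcript_to_genomic(gene, t),
                    strand=strand,
                    region=REGION_INTRON,
                    efficiency=dict(r.efficiency_by_sample),
                )
            )

        filler = _c_free_filler(rng, _FLANK_FILLER)
        for r in flank_rows:
            dist = (
                _DOWNSTREAM_DIST
                if r.region == REGION_DOWNSTREAM
                else _INTERGENIC_DIST
            )
            # flank sites are only attached to plus-strand genes here, so
            # "past the 3' end" means into the following filler
            filler[dist - 1] = "C"
            sites.append(
                TruthSite(
                    gene_id=gene_id,
                    label=r.position,
                    position=gene.gene_span[1] + dist,
                    strand="+",
                    region=r.region,
                    efficiency=dict(r.efficiency_by_sample),
                )
            )
        asm.emit("".join(filler))

    reference = Reference(name="toy_plastome_table1", sequence=asm.sequence())
    return TruthPanel(
        reference=reference,
        genes=genes,
        sites=sites,
        samples=list(TABLE1_SAMPLES),
        error_rate=0.0,
        coverage_mean=2000.0,
        coverage_dispersion=None,
    )


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def transcript_c_positions(
    reference: Reference, genes: Sequence[GeneModel]
) -> list[tuple[int, str]]:
    """Every transcript-sense C: gene spans on their own strand, the rest of
    the genome on the plus strand."""
    out: list[tuple[int, str]] = []
    covered: set[int] = set()
    for gene in genes:
        s, e = gene.gene_span
        for pos in range(s, e + 1):
            covered.add(pos)
            base = reference.base(pos)
            sense = base if gene.strand == "+" else revcomp(base)
            if sense == "C":
                out.append((pos, gene.strand))
    for pos in range(1, reference.length + 1):
        if pos not in covered and reference.base(pos) == "C":
            out.append((pos, "+"))
    out.sort()
    return out


def simulate_counts(
    panel: TruthPanel,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict[str, list[SiteCounts]]:
    """Binomially sample per-sample allele counts at every transcript-sense C.

    Coverage and error rate come from the panel (which records the study
    conditions it encodes); ``rng`` (or ``config.seed``) drives sampling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if config is not None else 0)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)
    eps = panel.error_rate
    site_by_key = {(s.position, s.strand): s for s in panel.sites}
    positions = transcript_c_positions(panel.reference, panel.genes)
    # make sure every truth site is simulated even if a panel was built on
    # an edited universe
    for key in site_by_key:
        if key not in positions:
            positions.append(key)
    out: dict[str, list[SiteCounts]] = {}
    for sample in panel.samples:
        records = []
        for pos, strand in positions:
            if panel.coverage_dispersion is None:
                m = int(round(panel.coverage_mean))
            else:
                k = panel.coverage_dispersion
                p_nb = k / (k + panel.coverage_mean)
                m = int(rng.negative_binomial(k, p_nb))
            site = site_by_key.get((pos, strand))
            if site is not None:
                e = site.efficiency[sample]
                p = e * (1.0 - eps) + (1.0 - e) * eps
            else:
                p = eps
            n_var = int(rng.binomial(m, p)) if m > 0 else 0
            records.append(
                SiteCounts(
                    position=pos,
                    strand=strand,
                    ref_base="C",
                    var_base="T",
                    n_ref=m - n_var,
                    n_var=n_var,
                    sample=sample,
                )
            )
        out[sample] = records
    return out


def estimated_table(
    panel: TruthPanel, counts_by_sample: Mapping[str, Sequence[SiteCounts]]
) -> EfficiencyTable:
    """Targeted re-estimation of panel-site efficiencies from counts.

    Rows are keyed by (gene, site label) with the panel's region and change
    annotation, so the result feeds straight into the differential
    classifier. Samples with zero coverage at a site stay missing.
    """
    index: dict[str, dict[tuple[int, str], SiteCounts]] = {}
    for sample, records in counts_by_sample.items():
        index[sample] = {(r.position, r.strand): r for r in records}
    sites = []
    for ts in panel.sites:
        eff = {}
        for sample in counts_by_sample:
            rec = index[sample].get((ts.position, ts.strand))
            if rec is None or rec.coverage == 0:
                continue
            eff[sample] = rec.n_var / rec.coverage
        sites.append(
            EditingSite(
                position=ts.label,
                strand=ts.strand,
                gene_id=ts.gene_id,
                region=ts.region,
                change=ts.change,
                efficiency_by_sample=eff,
            )
        )
    return EfficiencyTable(sites=sites, samples=list(counts_by_sample))


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------

_PANEL_META = [
    "gene", "label", "position", "strand", "region", "codon",
    "codon_offset", "change",
]


def write_truth_panel(panel: TruthPanel, path: str | Path) -> None:
    header = _PANEL_META + list(panel.samples)
    lines = ["\t".join(header)]
    for s in panel.sites:
        cells = [
            s.gene_id,
            str(s.label),
            str(s.position),
            s.strand,
            s.region,
            s.codon if s.codon is not None else ".",
            str(s.codon_offset) if s.codon_offset is not None else ".",
            s.change if s.change is not None else ".",
        ]
        cells.extend(repr(s.efficiency[sample]) for sample in panel.samples)
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_sites(path: str | Path) -> list[TruthSite]:
    """Read panel sites back (reference/annotation travel as FASTA/GFF3)."""
    df = _read_tsv(path, _PANEL_META)
    samples = [c for c in df.columns if c not in _PANEL_META]
    sites = []
    for i in range(len(df)):
        row = df.iloc[i]
        codon = row["codon"]
        sites.append(
            TruthSite(
                gene_id=str(row["gene"]),
                label=int(row["label"]),
                position=int(row["position"]),
                strand=str(row["strand"]),
                region=str(row["region"]),
                efficiency={s: float(row[s]) for s in samples},
                codon=None if _isna(codon) else str(codon),
                codon_offset=None
                if _isna(row["codon_offset"])
                else int(float(row["codon_offset"])),
                change=None if _isna(row["change"]) else str(row["change"]),
            )
        )
    return sites


def _isna(cell) -> bool:
    return cell is None or (isinstance(cell, float) and np.isnan(cell))
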