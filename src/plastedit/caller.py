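"""Editing-site calling from per-site allele counts.

The core quantities:

* **editing efficiency** at a site: ``n_var / (n_ref + n_var)``, the edited
  fraction of reads covering the position (reads carrying third alleles are
  not part of the count table and are ignored);
* the **discovery filter**: a position is a candidate editing site when the
  reference-read count, the variant-read count, and the variant frequency
  all clear their thresholds (defaults: ref >= 2, var >= 3, frequency within
  the inclusive window [0.1, 0.9]);
* **region annotation** with precedence CDS > intron > downstream >
  intergenic, downstream being a strand-aware window 3' of a gene end;
* **amino-acid consequence** of editing a C within a codon, translated with
  the plastid (bacterial) genetic code.

The frequency window applies at discovery only; once a position is accepted
in any sample its efficiency is reported in every covered sample, which is
why curated tables legitimately contain values of 0% or >90%.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .errors import (
    ConfigError,
    ContractError,
    RangeError,
    UndefinedEfficiencyError,
    ValidationError,
)
from .types import (
    REGION_CDS,
    REGION_DOWNSTREAM,
    REGION_INTERGENIC,
    REGION_INTRON,
    UNCHANGED,
    EditingSite,
    FilterThresholds,
    GeneModel,
    Reference,
    SiteCounts,
)

#: Plastid protein-coding genes use the bacterial/plastid genetic code.
PLASTID_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: Default size (nt) of the strand-aware window 3' of a gene end within
#: which a site is labelled "downstream" rather than "intergenic".
DEFAULT_DOWNSTREAM_WINDOW = 200


def compute_efficiency(counts: SiteCounts) -> float:
    """Editing efficiency ``n_var / (n_ref + n_var)`` as a fraction."""
    total = counts.n_ref + counts.n_var
    if total == 0:
        raise UndefinedEfficiencyError(
            f"position {counts.position} sample {counts.sample}: zero coverage"
        )
    return counts.n_var / total


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the discovery filter; ``reason`` names the first violated
    criterion (min_ref, min_var, freq_lo, freq_hi, no_coverage)."""

    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


def apply_discovery_filter(
    counts: SiteCounts, thresholds: FilterThresholds | None = None
) -> FilterDecision:
    """Evaluate the three discovery criteria in their stated order."""
    if thresholds is None:
        thresholds = FilterThresholds()
    if counts.coverage == 0:
        return FilterDecision(False, "no_coverage")
    if counts.n_ref < thresholds.min_ref:
        return FilterDecision(False, "min_ref")
    if counts.n_var < thresholds.min_var:
        return FilterDecision(False, "min_var")
    freq = counts.n_var / counts.coverage
    if freq < thresholds.freq_lo:
        return FilterDecision(False, "freq_lo")
    if freq > thresholds.freq_hi:
        return FilterDecision(False, "freq_hi")
    return FilterDecision(True)


def _normalise_panel(panel) -> list[tuple[int, str]]:
    out = []
    for entry in panel:
        if hasattr(entry, "position"):
            out.append((int(entry.position), getattr(entry, "strand", "+")))
        else:
            pos, strand = entry
            out.append((int(pos), strand))
    return out


def call_sites(
    counts: Iterable[SiteCounts],
    thresholds: FilterThresholds | None = None,
    mode: str = "discovery",
    panel: Sequence | None = None,
) -> list[EditingSite]:
    """Turn per-sample allele counts into editing sites.

    discovery
        a position becomes a site if it passes the filter in at least one
        sample; its efficiency is then reported in every sample with
        coverage (the frequency window is not re-applied at reporting).
    targeted
        efficiency is reported at every panel position regardless of the
        filter; the panel is a sequence of (position, strand) pairs or of
        objects with ``position``/``strand`` attributes.

    Returned sites are unannotated (``gene_id``/``region``/``change`` unset);
    see :func:`annotate_sites`.
    """
    grouped: "OrderedDict[tuple[int, str], dict[str, SiteCounts]]" = OrderedDict()
    for rec in counts:
        key = (rec.position, rec.strand)
        per_sample = grouped.setdefault(key, {})
        if rec.sample in per_sample:
            raise ValidationError(
                f"duplicate counts for position {rec.position} "
                f"sample {rec.sample}"
            )
        per_sample[rec.sample] = rec

    if mode == "discovery":
        selected = [
            key
            for key, per_sample in grouped.items()
            if any(
                apply_discovery_filter(rec, thresholds)
                for rec in per_sample.values()
            )
        ]
        selected.sort()
    elif mode == "targeted":
        if panel is None:
            raise ConfigError("targeted mode requires a site panel")
        selected = _normalise_panel(panel)
    else:
        raise ConfigError(f"unknown calling mode {mode!r}")

    sites = []
    for pos, strand in selected:
        per_sample = grouped.get((pos, strand), {})
        eff = {
            sample: compute_efficiency(rec)
            for sample, rec in per_sample.items()
            if rec.coverage > 0
        }
        sites.append(
            EditingSite(position=pos, strand=strand, efficiency_by_sample=eff)
        )
    return sites


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

def _downstream_distance(position: int, gene: GeneModel) -> int | None:
    """Distance past the 3' end of the gene (>=1), or None if not 3' of it."""
    if gene.strand == "+":
        d = position - gene.gene_span[1]
    else:
        d = gene.gene_span[0] - position
    return d if d >= 1 else None


def _span_distance(position: int, gene: GeneModel) -> int:
    s, e = gene.gene_span
    if position < s:
        return s - position
    if position > e:
        return position - e
    return 0


def annotate_region(
    position: int,
    genes: Sequence[GeneModel],
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
    reference_length: int | None = None,
) -> tuple[str, str | None]:
    """Classify a plastome position and name its containing/nearest gene.

    Precedence: exonic (CDS) in any gene > intronic in any gene >
    within ``downstream_window`` nt 3' of a gene end (strand-aware) >
    intergenic, labelled with the nearest gene.
    """
    if reference_length is not None and not 1 <= position <= reference_length:
        raise RangeError(
            f"position {position} outside reference of length {reference_length}"
        )
    for gene in genes:
        if gene.exonic(position):
            return (REGION_CDS, gene.gene_id)
    for gene in genes:
        if gene.intronic(position):
            return (REGION_INTRON, gene.gene_id)
    downstream = [
        (d, gene.gene_id)
        for gene in genes
        if (d := _downstream_distance(position, gene)) is not None
        and d <= downstream_window
    ]
    if downstream:
        return (REGION_DOWNSTREAM, min(downstream)[1])
    if not genes:
        return (REGION_INTERGENIC, None)
    nearest = min(genes, key=lambda g: (_span_distance(position, g), g.gene_id))
    return (REGION_INTERGENIC, nearest.gene_id)


def codon_context(
    position: int, gene: GeneModel, reference: Reference
) -> tuple[str, int]:
    """Codon containing a CDS position, in transcript sense.

    Returns ``(codon, offset)`` with ``offset`` in {1, 2, 3} giving the
    position of the queried base within the codon. The gene's spliced
    transcript is assumed to be a reading frame starting at its first base.
    """
    t = gene.transcript_offset(position)  # 1-based in spliced transcript
    transcript = gene.transcript_sequence(reference)
    codon_start = ((t - 1) // 3) * 3
    codon = transcript[codon_start : codon_start + 3]
    if len(codon) != 3:
        raise ContractError(
            f"position {position} falls in an incomplete terminal codon of "
            f"gene {gene.gene_id}"
        )
    return codon, (t - 1) % 3 + 1


def _translate(codon: str) -> str:
    if codon in PLASTID_CODON_TABLE.stop_codons:
        return "*"
    return PLASTID_CODON_TABLE.forward_table[codon]


def predict_amino_acid_change(codon: str, edited_offset: int):
    """Consequence of C-to-U editing at ``edited_offset`` within ``codon``.

    Returns a ``(from_aa, to_aa)`` pair of three-letter residue names, or
    the :data:`UNCHANGED` label when the edit is synonymous. Translation
    uses the plastid (bacterial) genetic code; a stop codon is rendered
    ``Ter``.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ContractError(f"not a codon: {codon!r}")
    if edited_offset not in (1, 2, 3):
        raise ContractError(f"edited_offset must be 1, 2 or 3: {edited_offset}")
    if codon[edited_offset - 1] != "C":
        raise ContractError(
            f"codon {codon} has no C at offset {edited_offset}"
        )
    edited = codon[: edited_offset - 1] + "T" + codon[edited_offset:]
    aa_from = _translate(codon)
    aa_to = _translate(edited)
    if aa_from == aa_to:
        return UNCHANGED
    return (seq3(aa_from), seq3(aa_to))


def format_change(change) -> str:
    """Printed-style label for a substitution: ``'Ser-Leu'`` / ``'Unchanged'``."""
    if change == UNCHANGED:
        return UNCHANGED
    aa_from, aa_to = change
    return f"{aa_from}-{aa_to}"


def annotate_sites(
    sites: Sequence[EditingSite],
    genes: Sequence[GeneModel],
    reference: Reference,
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> list[EditingSite]:
    """Fill gene, region and amino-acid-change labels on called sites.

    For a CDS site the transcript-sense base must be the edited C; its codon
    context determines the substitution label.
    """
    annotated = []
    for site in sites:
        region, gene_id = annotate_region(
            site.position, genes, downstream_window, reference.length
        )
        change = None
        if region == REGION_CDS:
            gene = next(g for g in genes if g.gene_id == gene_id)
            codon, offset = codon_context(site.position, gene, reference)
            change = format_change(predict_amino_acid_change(codon, offset))
        annotated.append(
            EditingSite(
                position=site.position,
                strand=site.strand,
                gene_id=gene_id,
                region=region,
                change=change,
                efficiency_by_sample=dict(site.efficiency_by_sample),
            )
        )
    return annotated
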