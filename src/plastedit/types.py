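"""Core domain types shared across the pipeline.

Conventions used throughout the package:

* all plastome coordinates are 1-based and intervals are closed, matching the
  positions printed in published editing-site tables;
* strand symbols are ``+`` and ``-``;
* read counts and editing efficiencies are expressed in *transcript sense*:
  a C-to-U site on a minus-strand gene appears as G-to-A on the plus strand
  of the reference but is stored here as C/T;
* efficiencies are fractions in [0, 1] internally and are rendered as
  percentages only at output time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import RangeError, ValidationError

VALID_BASES = frozenset("ACGT")

REGION_CDS = "CDS"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"
REGION_DOWNSTREAM = "downstream"
REGIONS = (REGION_CDS, REGION_INTRON, REGION_INTERGENIC, REGION_DOWNSTREAM)

#: Label used for synonymous edits, matching the published table wording.
UNCHANGED = "Unchanged"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement of an ACGTN string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class Reference:
    """A plastome reference sequence (uppercase ACGTN alphabet)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("reference name must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValidationError(
                f"reference contains non-ACGTN characters: {sorted(bad)}"
            )
        if not seq:
            raise ValidationError("reference sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise RangeError(
                f"position {position} outside reference of length {self.length}"
            )
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence over the 1-based closed interval [start, end]."""
        if start < 1 or end > self.length:
            raise RangeError(
                f"[{start}, {end}] outside reference of length {self.length}"
            )
        if start > end:
            raise RangeError(f"empty interval [{start}, {end}]")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure on the plastome.

    ``exons`` are 1-based closed intervals stored in *genomic* order
    regardless of strand; gaps between consecutive exons are the introns.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        span = (int(self.gene_span[0]), int(self.gene_span[1]))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "gene_span", span)
        if span[0] > span[1]:
            raise ValidationError(f"gene {self.gene_id}: span end < start")
        if not exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in exons:
            if e < s:
                raise ValidationError(
                    f"gene {self.gene_id}: exon end {e} < start {s}"
                )
            if not (span[0] <= s and e <= span[1]):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{s}, {e}] outside gene span "
                    f"[{span[0]}, {span[1]}]"
                )
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Inter-exon gaps in genomic order (may be empty)."""
        gaps = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            gaps.append((e1 + 1, s2 - 1))
        return tuple(gaps)

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, position: int) -> bool:
        return self.gene_span[0] <= position <= self.gene_span[1]

    def exonic(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)

    def intronic(self, position: int) -> bool:
        return self.contains(position) and not self.exonic(position)

    def transcript_offset(self, position: int) -> int:
        """1-based position within the spliced transcript (5' -> 3')."""
        order = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        acc = 0
        for s, e in order:
            if s <= position <= e:
                within = (position - s) if self.strand == "+" else (e - position)
                return acc + within + 1
            acc += e - s + 1
        raise ValidationError(
            f"position {position} is not exonic in gene {self.gene_id}"
        )

    def transcript_sequence(self, reference: Reference) -> str:
        """Spliced transcript-sense sequence (DNA alphabet)."""
        parts = [reference.slice(s, e) for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript 3' end."""
        return self.gene_span[1] if self.strand == "+" else self.gene_span[0]


@dataclass(frozen=True)
class SiteCounts:
    """Reference/variant read counts at one position in one sample.

    Bases are transcript-sense: a C-to-U editing candidate has
    ``ref_base='C'`` and ``var_base='T'`` whatever the gene strand.
    """

    position: int
    strand: str
    ref_base: str
    var_base: str
    n_ref: int
    n_var: int
    sample: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r}")
        for base in (self.ref_base, self.var_base):
            if base not in VALID_BASES:
                raise ValidationError(f"invalid base {base!r}")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        for name, n in (("n_ref", self.n_ref), ("n_var", self.n_var)):
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise ValidationError(f"{name} must be an integer, got {n!r}")
            if n < 0:
                raise ValidationError(f"{name} must be non-negative, got {n}")

    @property
    def coverage(self) -> int:
        return self.n_ref + self.n_var

    def to_transcript_sense(self) -> "SiteCounts":
        """Convert a plus-strand pileup record on a minus-strand transcript.

        A minus-strand C-to-U site is observed as G-to-A on the plus strand
        of the reference; complementing both alleles (counts unchanged) gives
        the transcript-sense representation. Plus-strand records are returned
        unchanged.
        """
        if self.strand == "+":
            return self
        return SiteCounts(
            position=self.position,
            strand=self.strand,
            ref_base=complement_base(self.ref_base),
            var_base=complement_base(self.var_base),
            n_ref=self.n_ref,
            n_var=self.n_var,
            sample=self.sample,
        )


@dataclass
class FilterThresholds:
    """Discovery-filter thresholds: minimum reference and variant read
    counts plus an inclusive variant-frequency window."""

    min_ref: int = 2
    min_var: int = 3
    freq_lo: float = 0.1
    freq_hi: float = 0.9

    def __post_init__(self) -> None:
        if self.min_ref < 0 or self.min_var < 0:
            raise ValidationError("minimum counts must be >= 0")
        if not 0 <= self.freq_lo < self.freq_hi <= 1:
            raise ValidationError(
                f"need 0 <= freq_lo < freq_hi <= 1, got "
                f"[{self.freq_lo}, {self.freq_hi}]"
            )


@dataclass
class EditingSite:
    """A called or curated editing site.

    ``efficiency_by_sample`` maps sample label to an editing-efficiency
    fraction. A sample absent from the map is *missing* (no coverage /
    not measured); a stored 0.0 is a measured zero — this is the
    provenance distinction between "absent" and "measured zero".
    ``region`` and ``change`` may be ``None`` until the site is annotated;
    ``change`` is a printed-style label such as ``"Ser-Leu"`` or
    ``"Unchanged"`` and is only ever set for CDS sites.
    """

    position: int
    strand: str = "+"
    gene_id: str | None = None
    region: str | None = None
    change: str | None = None
    efficiency_by_sample: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r}")
        if self.region is not None and self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.change is not None and self.region != REGION_CDS:
            raise ValidationError(
                f"site {self.gene_id}-{self.position}: amino-acid change set "
                f"for non-CDS region {self.region!r}"
            )
        if self.region == REGION_CDS and self.change is None:
            raise ValidationError(
                f"site {self.gene_id}-{self.position}: CDS site without an "
                "amino-acid change label"
            )
        for sample, eff in self.efficiency_by_sample.items():
            if not 0.0 <= eff <= 1.0:
                raise ValidationError(
                    f"site {self.gene_id}-{self.position}, sample {sample}: "
                    f"efficiency {eff} outside [0, 1]"
                )

    @property
    def key(self) -> tuple[str | None, int]:
        return (self.gene_id, self.position)

    @property
    def coding(self) -> bool:
        return self.region == REGION_CDS

    @property
    def synonymous(self) -> bool | None:
        if self.change is None:
            return None
        return self.change == UNCHANGED


@dataclass
class EfficiencyTable:
    """Sites x samples matrix of editing efficiencies."""

    sites: list[EditingSite]
    samples: list[str]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample labels must be unique")
        seen: set[tuple[str | None, int]] = set()
        for site in self.sites:
            if site.key in seen:
                raise ValidationError(f"duplicated site key {site.key}")
            seen.add(site.key)
            unknown = set(site.efficiency_by_sample) - set(self.samples)
            if unknown:
                raise ValidationError(
                    f"site {site.key}: efficiencies for unknown samples "
                    f"{sorted(unknown)}"
                )
        self._index = {site.key: site for site in self.sites}

    def __len__(self) -> int:
        return len(self.sites)

    def site(self, gene_id: str | None, position: int) -> EditingSite:
        try:
            return self._index[(gene_id, position)]
        except KeyError:
            raise KeyError(f"no site ({gene_id}, {position}) in table") from None

    def efficiency(
        self, gene_id: str | None, position: int, sample: str
    ) -> float | None:
        """Efficiency fraction, or None when missing for that sample."""
        return self.site(gene_id, position).efficiency_by_sample.get(sample)

    def to_frame(self):
        """Efficiencies as a pandas DataFrame (NaN = missing), indexed by
        (gene, position), with region/change metadata columns."""
        import pandas as pd

        rows = []
        for s in self.sites:
            row = {"gene": s.gene_id, "position": s.position,
                   "region": s.region, "change": s.change}
            for sample in self.samples:
                row[sample] = s.efficiency_by_sample.get(sample, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows).set_index(["gene", "position"])
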