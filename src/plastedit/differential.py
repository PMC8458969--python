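"""Genotype x stage comparison of editing efficiencies.

A site's per-stage difference is expressed in percentage points,
``delta = 100 * (wild type - mutant)``. With the default threshold of 10
points (strict inequality — "more than 10%" of editing efficiency):

* stage 1: ``decreased`` iff delta_s1 > threshold, else ``unaffected``;
* stage 2, for sites decreased at stage 1: ``restored`` iff
  delta_s2 < threshold, else ``still_decreased``;
* stage 2, for sites unaffected at stage 1: ``newly_affected`` iff
  delta_s2 > threshold, else ``unaffected``.

The threshold is an absolute difference of efficiencies, not a relative
change — the only reading under which the published summary counts follow
from the published per-site table. A tie at exactly the threshold counts as
unaffected/restored (strict comparisons throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigError, MissingDataError
from .types import REGION_CDS, UNCHANGED, EfficiencyTable

CAT_DECREASED = "decreased"
CAT_UNAFFECTED = "unaffected"
CAT_RESTORED = "restored"
CAT_NEWLY_AFFECTED = "newly_affected"
CAT_STILL_DECREASED = "still_decreased"

S1_CATEGORIES = (CAT_DECREASED, CAT_UNAFFECTED)
S2_CATEGORIES = (
    CAT_RESTORED,
    CAT_NEWLY_AFFECTED,
    CAT_STILL_DECREASED,
    CAT_UNAFFECTED,
)

DEFAULT_THRESHOLD_POINTS = 10.0


@dataclass(frozen=True)
class SampleDesign:
    """Maps the four design roles to sample labels in a table."""

    wt_s1: str = "HD12-S1"
    wt_s2: str = "HD12-S2"
    mut_s1: str = "Gmpgl2-S1"
    mut_s2: str = "Gmpgl2-S2"

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.wt_s1, self.wt_s2, self.mut_s1, self.mut_s2)

    def stage(self, stage: int) -> tuple[str, str]:
        if stage == 1:
            return (self.wt_s1, self.mut_s1)
        if stage == 2:
            return (self.wt_s2, self.mut_s2)
        raise ConfigError(f"stage must be 1 or 2, got {stage}")


DEFAULT_DESIGN = SampleDesign()


@dataclass(frozen=True)
class ComparisonRecord:
    """Per-site comparison: deltas in percentage points and categories."""

    gene_id: str | None
    position: int
    delta_s1: float
    delta_s2: float
    category_s1: str
    category_s2: str

    @property
    def key(self) -> tuple[str | None, int]:
        return (self.gene_id, self.position)


def delta_points(
    table: EfficiencyTable,
    gene_id: str | None,
    position: int,
    stage: int,
    design: SampleDesign = DEFAULT_DESIGN,
) -> float:
    """Wild-type minus mutant editing efficiency, in percentage points."""
    wt_label, mut_label = design.stage(stage)
    site = table.site(gene_id, position)
    values = []
    for label in (wt_label, mut_label):
        if label not in site.efficiency_by_sample:
            raise MissingDataError(
                f"site ({gene_id}, {position}): no efficiency for sample "
                f"{label}"
            )
        values.append(site.efficiency_by_sample[label])
    return 100.0 * (values[0] - values[1])


def classify(
    table: EfficiencyTable,
    threshold_points: float = DEFAULT_THRESHOLD_POINTS,
    design: SampleDesign = DEFAULT_DESIGN,
) -> list[ComparisonRecord]:
    """Classify every site of a four-sample table at both stages."""
    missing = set(design.labels) - set(table.samples)
    if missing:
        raise ConfigError(
            f"table lacks required sample columns {sorted(missing)}"
        )
    records = []
    for site in table.sites:
        d1 = delta_points(table, site.gene_id, site.position, 1, design)
        d2 = delta_points(table, site.gene_id, site.position, 2, design)
        if d1 > threshold_points:
            cat1 = CAT_DECREASED
            cat2 = CAT_RESTORED if d2 < threshold_points else CAT_STILL_DECREASED
        else:
            cat1 = CAT_UNAFFECTED
            cat2 = (
                CAT_NEWLY_AFFECTED if d2 > threshold_points else CAT_UNAFFECTED
            )
        records.append(
            ComparisonRecord(
                gene_id=site.gene_id,
                position=site.position,
                delta_s1=d1,
                delta_s2=d2,
                category_s1=cat1,
                category_s2=cat2,
            )
        )
    return records


@dataclass
class ClassificationReport:
    """Summary of a genotype x stage comparison.

    ``s2_affected`` is the union of the still-decreased and newly affected
    categories: every site whose stage-2 efficiency is reduced beyond the
    threshold in the mutant.
    """

    n_sites: int
    n_coding: int
    n_noncoding: int
    coding_genes: tuple[str, ...]
    n_nonsynonymous: int
    substitution_types: tuple[str, ...]
    s1_decreased: tuple[tuple[str | None, int], ...]
    s2_restored: tuple[tuple[str | None, int], ...]
    s2_newly_affected: tuple[tuple[str | None, int], ...]
    s2_still_decreased: tuple[tuple[str | None, int], ...]
    s2_affected_genes: tuple[str, ...]
    category_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_coding_genes(self) -> int:
        return len(self.coding_genes)

    @property
    def s2_affected(self) -> tuple[tuple[str | None, int], ...]:
        return tuple(
            sorted(self.s2_still_decreased + self.s2_newly_affected)
        )

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_coding": self.n_coding,
            "n_noncoding": self.n_noncoding,
            "n_coding_genes": self.n_coding_genes,
            "coding_genes": list(self.coding_genes),
            "n_nonsynonymous": self.n_nonsynonymous,
            "substitution_types": list(self.substitution_types),
            "n_s1_decreased": len(self.s1_decreased),
            "n_s2_restored": len(self.s2_restored),
            "n_s2_newly_affected": len(self.s2_newly_affected),
            "n_s2_still_decreased": len(self.s2_still_decreased),
            "n_s2_affected": len(self.s2_affected),
            "n_s2_affected_genes": len(self.s2_affected_genes),
            "category_counts": dict(self.category_counts),
        }


def summarize(
    records: Sequence[ComparisonRecord], table: EfficiencyTable
) -> ClassificationReport:
    """Aggregate per-site records into the published-style summary counts."""
    coding = [s for s in table.sites if s.region == REGION_CDS]
    noncoding = [s for s in table.sites if s.region != REGION_CDS]
    coding_genes = tuple(
        sorted({s.gene_id for s in coding if s.gene_id is not None})
    )
    nonsyn = [s for s in coding if s.change != UNCHANGED]
    substitution_types = tuple(
        sorted({s.change for s in nonsyn if s.change is not None})
    )

    def keys(category_s1=None, category_s2=None):
        out = []
        for r in records:
            if category_s1 is not None and r.category_s1 != category_s1:
                continue
            if category_s2 is not None and r.category_s2 != category_s2:
                continue
            out.append(r.key)
        return tuple(sorted(out, key=lambda k: (str(k[0]), k[1])))

    s2_still = keys(category_s2=CAT_STILL_DECREASED)
    s2_new = keys(category_s2=CAT_NEWLY_AFFECTED)
    affected_genes = tuple(
        sorted({g for g, _ in s2_still + s2_new if g is not None})
    )
    category_counts = {
        f"s1_{CAT_DECREASED}": sum(
            r.category_s1 == CAT_DECREASED for r in records
        ),
        f"s1_{CAT_UNAFFECTED}": sum(
            r.category_s1 == CAT_UNAFFECTED for r in records
        ),
    }
    for cat in S2_CATEGORIES:
        category_counts[f"s2_{cat}"] = sum(
            r.category_s2 == cat for r in records
        )

    return ClassificationReport(
        n_sites=len(table),
        n_coding=len(coding),
        n_noncoding=len(noncoding),
        coding_genes=coding_genes,
        n_nonsynonymous=len(nonsyn),
        substitution_types=substitution_types,
        s1_decreased=keys(category_s1=CAT_DECREASED),
        s2_restored=keys(category_s2=CAT_RESTORED),
        s2_newly_affected=s2_new,
        s2_still_decreased=s2_still,
        s2_affected_genes=affected_genes,
        category_counts=category_counts,
    )
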