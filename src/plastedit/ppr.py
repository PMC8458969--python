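"""PPR-code target scoring for PLS-class editing factors.

A PLS-class PPR protein binds RNA with one nucleotide per P/L/S motif,
N- to C-terminal motifs pairing with the target 5' to 3'. Two residues per
motif — the amino acid at motif position 5 and at the motif's last position —
form an empirical recognition code mapping each motif to the nucleotide(s)
it can bind. Scoring a candidate edited C consists of aligning the motif
array to the sequence immediately upstream of the C and counting motifs
whose permitted set contains the paired nucleotide: the **match index**
``k/n`` over the protein's n binding motifs.

The alignment register places the 3'-most window nucleotide at ``offset``
relative to the edited C (default -4, the convention for E-class editing
factors in the code literature); it is configurable because published
figures often say only "upstream".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ContractError, FormatError, RangeError, ValidationError
from .types import GeneModel, Reference, revcomp

BINDING_CLASSES = ("P", "L", "S")
MOTIF_CLASSES = BINDING_CLASSES + ("E1", "E2", "E+")

_AA = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_OFFSET = -4


@dataclass(frozen=True)
class PPRMotif:
    """One PPR motif: class, protein span (1-based closed) and the two
    code-determining residues (position 5 and last position)."""

    motif_class: str
    start: int
    end: int
    aa5: str
    aa_last: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValidationError(f"unknown motif class {self.motif_class!r}")
        if self.end < self.start:
            raise ValidationError(
                f"motif span [{self.start}, {self.end}] reversed"
            )
        for aa in (self.aa5, self.aa_last):
            if aa not in _AA:
                raise ValidationError(f"not a standard residue: {aa!r}")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @property
    def binding(self) -> bool:
        return self.motif_class in BINDING_CLASSES


@dataclass(frozen=True)
class PPRProtein:
    """An ordered (N- to C-terminal) PPR motif array."""

    name: str
    motifs: tuple[PPRMotif, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "motifs", tuple(self.motifs))
        prev_end = 0
        seen_e = False
        for m in self.motifs:
            if m.start <= prev_end:
                raise ValidationError(
                    f"protein {self.name}: motif spans overlap or are unsorted"
                )
            prev_end = m.end
            if m.binding and seen_e:
                raise ValidationError(
                    f"protein {self.name}: P/L/S motif after an E-class motif"
                )
            if not m.binding:
                seen_e = True

    @property
    def binding_motifs(self) -> tuple[PPRMotif, ...]:
        return tuple(m for m in self.motifs if m.binding)

    @property
    def n_binding_motifs(self) -> int:
        return len(self.binding_motifs)

    def truncate(self, n_motifs: int) -> "PPRProtein":
        """First ``n_motifs`` motifs (models a truncated mutant protein)."""
        return PPRProtein(
            name=f"{self.name}[1:{n_motifs}]", motifs=self.motifs[:n_motifs]
        )


def extract_code(protein: PPRProtein) -> list[tuple[str, str]]:
    """(position-5, last) residue pairs over P/L/S motifs, N -> C order."""
    pairs = []
    for m in protein.binding_motifs:
        if m.span_length < 5:
            raise ContractError(
                f"motif [{m.start}, {m.end}] shorter than 5 residues has no "
                "position-5 residue"
            )
        pairs.append((m.aa5, m.aa_last))
    return pairs


@dataclass
class CodeTable:
    """Map from (position-5 aa, last aa) to permissible nucleotides.

    An empty set is only allowed for pairs explicitly marked as
    "no prediction"; residue pairs absent from the table altogether score
    as non-matching rather than erroring, because natural proteins contain
    uncharacterised combinations.
    """

    entries: dict[tuple[str, str], frozenset[str]]
    provenance: str = ""
    no_prediction: frozenset = frozenset()

    def __post_init__(self) -> None:
        clean = {}
        for pair, nucs in self.entries.items():
            nucs = frozenset(n.upper().replace("T", "U") for n in nucs)
            bad = nucs - set("ACGU")
            if bad:
                raise ValidationError(
                    f"pair {pair}: non-nucleotide symbols {sorted(bad)}"
                )
            if not nucs and pair not in self.no_prediction:
                raise ValidationError(
                    f"pair {pair}: empty set without a no-prediction flag"
                )
            clean[pair] = nucs
        self.entries = clean

    def permissible(self, pair: tuple[str, str]) -> frozenset[str]:
        return self.entries.get(pair, frozenset())

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "CodeTable":
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
        for col in ("aa5", "aa_last", "nucleotides"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column '{col}'")
        entries: dict[tuple[str, str], frozenset[str]] = {}
        no_pred = set()
        for row in df.itertuples(index=False):
            pair = (str(row.aa5), str(row.aa_last))
            nucs = str(row.nucleotides).strip()
            if nucs in (".", ""):
                no_pred.add(pair)
                entries[pair] = frozenset()
            else:
                entries[pair] = frozenset(nucs)
        return cls(
            entries=entries,
            provenance=provenance or str(path),
            no_prediction=frozenset(no_pred),
        )

    @classmethod
    def default(cls) -> "CodeTable":
        """The bundled replaceable code asset."""
        src = resources.files("plastedit").joinpath("data/ppr_code_table.tsv")
        with resources.as_file(src) as path:
            return cls.from_tsv(
                path, provenance="bundled two-residue code asset"
            )


@dataclass(frozen=True)
class TargetWindow:
    """The transcript-sense nucleotide window a motif array is aligned to.

    ``window`` is written 5'->3' in the RNA alphabet; its 3'-most base sits
    ``offset`` nucleotides from the edited C (offset < 0, i.e. strictly
    upstream)."""

    position: int
    strand: str
    window: str
    offset: int

    def __post_init__(self) -> None:
        if self.offset >= 0:
            raise ValidationError("window offset must be negative (upstream)")
        if not self.window:
            raise ValidationError("empty window")


def build_window(
    position: int,
    strand: str,
    reference: Reference,
    n: int,
    offset: int = DEFAULT_OFFSET,
) -> TargetWindow:
    """Extract the n-nucleotide transcript-sense window upstream of a C.

    The window's 3'-most base sits at transcript offset ``offset`` from the
    edited position; for minus-strand sites the plus-strand reference slice
    is reverse-complemented.
    """
    if n < 1:
        raise ContractError("window length must be >= 1")
    if offset >= 0:
        raise ContractError("offset must be negative (upstream of the C)")
    base = reference.base(position)
    sense = base if strand == "+" else revcomp(base)
    if sense != "C":
        raise ContractError(
            f"position {position} ({strand}) is not a transcript-sense C"
        )
    if strand == "+":
        end = position + offset
        start = end - n + 1
        if start < 1:
            raise RangeError(
                f"window for {position}+ extends past the reference start"
            )
        seq = reference.slice(start, end)
    else:
        start = position - offset
        end = start + n - 1
        if end > reference.length:
            raise RangeError(
                f"window for {position}- extends past the reference end"
            )
        seq = revcomp(reference.slice(start, end))
    return TargetWindow(
        position=position,
        strand=strand,
        window=seq.replace("T", "U"),
        offset=offset,
    )


def match_index(
    code: Sequence[tuple[str, str]],
    window: TargetWindow | str,
    table: CodeTable,
) -> tuple[int, int]:
    """Count motifs whose permitted nucleotides contain the paired base.

    Motif i (N->C) pairs with window nucleotide i (5'->3'). Returns
    ``(k, n)`` — the match index printed as ``k/n``.
    """
    seq = window.window if isinstance(window, TargetWindow) else window
    seq = seq.upper().replace("T", "U")
    if len(code) != len(seq):
        raise ContractError(
            f"code length {len(code)} != window length {len(seq)}"
        )
    k = sum(
        1 for pair, nuc in zip(code, seq) if nuc in table.permissible(pair)
    )
    return (k, len(code))


def scan_targets(
    protein: PPRProtein,
    reference: Reference,
    genes: Sequence[GeneModel],
    table: CodeTable | None = None,
    offset: int = DEFAULT_OFFSET,
) -> list[tuple[int, str, int, int, float]]:
    """Score every transcript-sense C inside annotated genes.

    Returns ``(position, strand, k, n, fraction)`` tuples sorted by
    descending match fraction, ties broken by ascending position. Positions
    whose window would run off the reference are skipped.
    """
    if table is None:
        table = CodeTable.default()
    code = extract_code(protein)
    n = len(code)
    if n == 0:
        return []
    seen: set[tuple[int, str]] = set()
    results = []
    for gene in genes:
        s, e = gene.gene_span
        for pos in range(s, e + 1):
            key = (pos, gene.strand)
            if key in seen:
                continue
            base = reference.base(pos)
            sense = base if gene.strand == "+" else revcomp(base)
            if sense != "C":
                continue
            seen.add(key)
            try:
                window = build_window(pos, gene.strand, reference, n, offset)
            except RangeError:
                continue
            k, total = match_index(code, window, table)
            results.append((pos, gene.strand, k, total, k / total))
    results.sort(key=lambda r: (-r[4], r[0]))
    return results


# ---------------------------------------------------------------------------
# Motif annotation I/O
# ---------------------------------------------------------------------------

def read_ppr_protein(path: str | Path, name: str | None = None) -> PPRProtein:
    """Read a motif annotation TSV
    (columns motif_index, class, start, end, aa5, aa_last)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    required = ["motif_index", "class", "start", "end", "aa5", "aa_last"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = df.assign(motif_index=df["motif_index"].astype(int))
    df = df.sort_values("motif_index").rename(columns={"class": "motif_class"})
    motifs = tuple(
        PPRMotif(
            motif_class=str(r.motif_class),
            start=int(r.start),
            end=int(r.end),
            aa5=str(r.aa5),
            aa_last=str(r.aa_last),
        )
        for r in df.itertuples(index=False)
    )
    return PPRProtein(name=name or Path(path).stem, motifs=motifs)


def write_ppr_protein(protein: PPRProtein, path: str | Path) -> None:
    lines = ["\t".join(["motif_index", "class", "start", "end", "aa5", "aa_last"])]
    for i, m in enumerate(protein.motifs, 1):
        lines.append(
            f"{i}\t{m.motif_class}\t{m.start}\t{m.end}\t{m.aa5}\t{m.aa_last}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_scan_results(
    results: Sequence[tuple[int, str, int, int, float]], path: str | Path
) -> None:
    lines = ["\t".join(["position", "strand", "matches", "motifs", "fraction"])]
    for pos, strand, k, n, frac in results:
        lines.append(f"{pos}\t{strand}\t{k}\t{n}\t{frac:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
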