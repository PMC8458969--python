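# Methods

## Scope and model

`plastedit` analyses C-to-U RNA editing in chloroplast transcripts from
per-site allele-count tables (the output of any pileup over aligned RNA-seq
reads; alignment itself is upstream of this package). Four analyses are
chained:

1. **Efficiency quantification.** The editing efficiency (editotype) at a
   site is the edited-read fraction `e = n_var / (n_ref + n_var)`, with
   counts expressed in transcript sense: a site on a minus-strand gene is
   observed as G→A on the plus strand of the reference and converted to
   C→T at ingest (`SiteCounts.to_transcript_sense`). Reads carrying third
   alleles are not part of the two-allele count table and are ignored —
   the standard editotype definition. Positions with zero coverage in a
   sample are reported *missing*, never 0: a stored 0.0 always means a
   measured zero.

2. **Discovery filter.** A position is a candidate editing site when, in at
   least one sample, `n_ref >= 2`, `n_var >= 3` and the variant frequency
   lies in the inclusive window `[0.1, 0.9]`. The three criteria are
   evaluated in that order and a failure reports the first violated one.
   The frequency window applies at discovery only; once a site is accepted
   its efficiency is reported in every covered sample, which is how a
   curated table can legitimately contain 0.00% and >90% entries. Because
   constitutively edited sites (>0.9 in every sample) can never enter via
   this filter, a *targeted* mode quantifies a supplied panel of known
   sites with no filtering — this is the mode the recovery analyses use.
   All four thresholds are configurable (`FilterThresholds`).

3. **Region and consequence annotation.** Positions are classified with
   precedence CDS (exonic in any gene) > intron (inside a gene span,
   outside exons) > downstream (within a strand-aware window 3′ of a gene
   end; default 200 nt, a configurable knob since published "downstream"
   labels come without distances) > intergenic (labelled with the nearest
   gene). For CDS sites the codon containing the edited C is read off the
   spliced transcript (frame anchored at the annotated CDS start) and both
   codons are translated with the plastid/bacterial genetic code
   (translation table 11); synonymous edits are labelled `Unchanged`,
   others `Xxx-Yyy` in three-letter residue names. An edit creating a stop
   codon is rendered `Ter`.

4. **Differential classification.** For the two-genotype × two-stage
   design, per-site differences are `delta = 100 × (wild type − mutant)`
   percentage points at each stage. With the default threshold of 10
   points: *decreased* at stage 1 iff `delta_s1 > 10` (strict); at stage 2
   a stage-1-decreased site is *restored* iff `delta_s2 < 10` (strict),
   else *still decreased*; a stage-1-unaffected site is *newly affected*
   iff `delta_s2 > 10`. "More than 10%" is read as an absolute difference
   of efficiencies, not a relative change — the only reading under which
   the published per-site table yields the published summary counts
   (20 decreased at S1; 5 restored and 5 newly affected at S2; 20 sites in
   12 genes affected at S2). Ties at exactly 10.00 points classify as
   unaffected/restored; the bundled data contain no exact tie (closest:
   10.25 points), so the convention is fixed by fiat and documented here.

## PPR-code target scoring

A PLS-class PPR editing factor is modelled as an ordered motif array
(P/L/S binding motifs, then optional E1/E2/E+ domains; a truncated mutant
protein is simply a truncated motif list). The two code-determining
residues per binding motif — position 5 and the motif's last position —
index an empirical code table mapping each residue pair to its permissible
nucleotides. The **match index** of a candidate edited C is `k/n`: motif i
(N→C) pairs with window nucleotide i (5′→3′) over the n-nucleotide window
upstream of the C, and `k` counts motifs whose permissible set contains the
paired base.

Register: the window's 3′-most base sits at transcript offset −4 from the
edited C, the convention of the two-residue-code literature for E-class
editing factors; since published alignment figures often say only
"upstream", the offset is a parameter. Residue pairs absent from the code
table score as non-matches (natural proteins contain uncharacterised
combinations); an explicitly empty "no prediction" entry is also allowed.
The bundled code asset carries the canonical published pair→nucleotide
combinations and is deliberately replaceable (plain TSV); the scoring
engine hard-codes nothing. Motif discovery from raw protein sequence is out
of scope — motif spans and residues are supplied as an annotation file,
keeping the module deterministic.

`scan_targets` scores every transcript-sense C inside annotated gene spans
and ranks by descending match fraction, ties broken by ascending position.
Set-membership scoring only; a probabilistic/weighted code is a documented
extension point, not implemented.

## Synthetic data

The generator replaces raw sequencing data. At a truth site with efficiency
`e` and coverage `m`, the variant count is drawn
`Binomial(m, e(1−ε) + (1−e)ε)` with a symmetric, position-independent error
rate ε (no published error model exists for the emulated experiment, so one
global knob); at non-edited Cs, `Binomial(m, ε)`. Coverage is fixed per
site (default) or negative-binomial with a dispersion knob — the emulated
study reports no coverage distribution, so fixed is the neutral choice.
Counts are emitted at every transcript-sense C (gene spans on their own
strand, the rest of the genome on the plus strand). Generation is a pure
function of `(config, seed)`; identical seeds give byte-identical
FASTA/GFF3/panel output.

Defaults describe the emulated study conditions: four samples (two
genotypes × two leaf stages), 43 sites, 2,000× coverage (deep plastid
transcript coverage typical of rRNA-depleted chloroplast RNA-seq), ε = 1e-3
(Illumina-like), ~50% of sites affected in the mutant with efficiency drops
of 0.15–0.8. Random toy plastomes place 12 genes on both strands
(300–900 nt CDS, intron probability 0.3).

`panel_from_table1()` instead builds, deterministically, a toy plastome
hosting the 43 curated sites: per-sample true efficiencies equal the
printed values; region classes reproduce the printed breakdown (38 CDS,
2 intron, 2 intergenic, 1 downstream); each coding site's codon context is
chosen to reproduce its printed substitution type (e.g. TCA edited at
offset 2 for Ser-Leu, CAT at offset 1 for His-Tyr, CTC at offset 3 for a
synonymous site); one multi-site gene (ndhB) sits on the minus strand so
strand arithmetic is exercised end to end. Printed genomic positions are
kept as site *labels* only — fabricating a 152-kb plastome coordinate
system would add nothing.

What the simulator does **not** model: read-level artifacts (FASTQ,
alignment error, strand bias, RNA degradation), base-quality structure,
position-dependent error, overlapping genes, RNA secondary structure, and
any correlation between sites. Passing recovery tests therefore
demonstrate correctness of the estimator and classifier under binomial
sampling — not robustness to alignment artifacts in real data.

## Recovery behaviour near the classification threshold

Re-estimation from one simulated replicate at 2,000× recovers efficiencies
to within a few binomial SDs (max absolute error ≈ 2–3 percentage points
over 43 × 4 values, reported by `scripts/acceptance.py`). The
*classification*, however, is a hard threshold at 10 points, and several
true deltas in the curated table sit within a fraction of one SD of it
(9.97, 10.25, 9.55, 9.39, 9.57 points; the delta SD at 2,000× is ≈ 0.8–1.6
points). Per-replicate exact reproduction of the (20, 5, 5) category
counts is therefore a coin-flip product across those borderline sites —
measured at ≈ 5% of replicates, consistent with the analytic product of
per-site correct-side probabilities (≈ 4%). This is a property of the data
and the threshold rule, not of the implementation: no unbiased estimator at
that coverage can classify a 9.97-point true delta to the correct side of
10 more than ~51% of the time. The acceptance script reports the measured
rate; the test suite asserts the idealised expectation and is expected to
flag it.

## Numerical and design choices

* Coordinates 1-based, intervals closed, matching published site tables.
* Efficiencies are fractions in [0, 1] internally; percentages (two
  decimals) exist only in report rendering. Machine TSVs store fractions at
  full float precision so write/read round trips are exact.
* The TSV dialect is UTF-8, tab-delimited, `#` comments, `.` for missing.
* Duplicate (gene, position) keys are a validation error, never merged.
* The curated-table loader normalises the two printed bare "0%" cells to
  0.0 like every other zero (the source table does not distinguish them)
  and asserts the 43-row / 38+5 region breakdown at load time.
* Sites validated by Sanger sequencing in the emulated study are not
  derivable from the efficiency table by any single threshold rule; they
  are not modelled. Segregation-ratio testing is likewise out of scope.
* Hypothesis-based property tests run derandomised; all simulations in
  tests use fixed seeds. Problem sizes (100 replicates at 2,000×, toy
  references ≤ 2 kb, a 101 × 101 filter grid) keep the whole suite under
  ~10 s while leaving every statistical check well-powered.

## Known limitations

* The filter interprets the loosely worded count thresholds ("≥2 reference
  reads, ≥3 variant reads") as minimum read counts, following the editing-
  detection literature the rule descends from; an alternative ratio
  reading can be swapped in via `FilterThresholds`.
* Codon frame is anchored at the annotated CDS start; 5′ UTR-containing
  gene models would need their exons trimmed to the CDS first.
* The PPR scan scores only Cs inside annotated gene spans (editing targets
  are transcribed), so unannotated transcripts are invisible to it.
* The bundled code table is a minimal canonical set; real-protein match
  indices depend on the code dataset used and should be computed with the
  user's preferred table (`scripts/external_validation.py`).
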