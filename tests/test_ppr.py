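"""PPR motif arrays, two-residue code extraction and match-index scoring."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastedit import (
    CodeTable,
    ContractError,
    GeneModel,
    PPRMotif,
    PPRProtein,
    Reference,
    ValidationError,
    build_window,
    extract_code,
    match_index,
    scan_targets,
)
from plastedit.errors import RangeError
from plastedit.types import revcomp


def motif(cls, i, aa5="T", aa_last="D", length=35):
    start = 1 + i * 40
    return PPRMotif(cls, start, start + length - 1, aa5, aa_last)


def protein(residues, name="toy"):
    return PPRProtein(
        name, tuple(motif("P", i, a5, al) for i, (a5, al) in enumerate(residues))
    )


TOY_TABLE = CodeTable(
    {("T", "D"): {"G"}, ("T", "N"): {"A"}, ("N", "D"): {"U"}}
)


class TestProteinModel:
    def test_extract_code_preserves_order(self):
        code = extract_code(protein([("T", "D"), ("T", "N"), ("N", "D")]))
        assert code == [("T", "D"), ("T", "N"), ("N", "D")]

    def test_seventeen_binding_motifs_give_seventeen_pairs(self):
        motifs = [motif("P", i) for i in range(17)]
        motifs += [motif("E1", 17), motif("E2", 18), motif("E+", 19)]
        p = PPRProtein("editing-factor", tuple(motifs))
        assert p.n_binding_motifs == 17
        assert len(extract_code(p)) == 17

    def test_e_motifs_are_excluded_from_the_code(self):
        p = PPRProtein("e-only", (motif("E1", 0), motif("E+", 1)))
        assert extract_code(p) == []

    def test_short_motif_span_is_a_contract_error(self):
        p = PPRProtein("bad", (PPRMotif("P", 1, 3, "T", "D"),))
        with pytest.raises(ContractError):
            extract_code(p)

    def test_binding_motif_after_e_domain_rejected(self):
        with pytest.raises(ValidationError):
            PPRProtein("bad", (motif("E1", 0), motif("P", 1)))

    def test_truncation_models_the_mutant_protein(self):
        motifs = tuple(motif("P", i) for i in range(17)) + (
            motif("E1", 17), motif("E2", 18), motif("E+", 19),
        )
        full = PPRProtein("factor", motifs)
        truncated = full.truncate(18)  # loses part of the C-terminal domains
        assert truncated.n_binding_motifs == 17
        assert len(truncated.motifs) == 18


class TestCodeTable:
    def test_default_asset_loads(self):
        table = CodeTable.default()
        assert table.permissible(("T", "D")) == frozenset("G")
        assert table.permissible(("N", "N")) == frozenset("CU")

    def test_unknown_pair_is_empty(self):
        assert TOY_TABLE.permissible(("W", "W")) == frozenset()

    def test_empty_set_requires_no_prediction_flag(self):
        with pytest.raises(ValidationError):
            CodeTable({("T", "D"): frozenset()})
        table = CodeTable(
            {("T", "D"): frozenset()}, no_prediction=frozenset({("T", "D")})
        )
        assert table.permissible(("T", "D")) == frozenset()

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "code.tsv"
        path.write_text("aa5\taa_last\tnucleotides\nT\tD\tG\nN\tN\tCU\nS\tS\t.\n")
        table = CodeTable.from_tsv(path)
        assert table.permissible(("N", "N")) == frozenset("CU")
        assert ("S", "S") in table.no_prediction


class TestBuildWindow:
    REF = Reference("r", "AAGGTTCCAAGGTTCCAAGGTTCCACGGT")

    def test_default_register_covers_minus_20_to_minus_4(self):
        ref = Reference("r", "ACGT" * 10 + "C" + "A" * 5)
        w = build_window(41, "+", ref, n=17, offset=-4)
        assert len(w.window) == 17
        # 3'-most base at position 41-4 = 37; window spans 21..37
        assert w.window == ref.slice(21, 37).replace("T", "U")

    def test_single_base_window_is_the_immediate_upstream_base(self):
        assert self.REF.base(26) == "C"
        w = build_window(26, "+", self.REF, n=1, offset=-1)
        assert w.window == self.REF.base(25).replace("T", "U")

    def test_minus_strand_window_is_reverse_complemented(self):
        # plant a transcript-sense C at plus position 10 on the minus strand
        ref = Reference("r", "AAAAAAAAAGTACGTACGTA")
        assert ref.base(10) == "G"  # revcomp G = C on the transcript
        w = build_window(10, "-", ref, n=5, offset=-1)
        assert w.window == revcomp(ref.slice(11, 15)).replace("T", "U")

    def test_window_past_reference_start_is_a_range_error(self):
        with pytest.raises(RangeError):
            build_window(26, "+", self.REF, n=30, offset=-4)

    def test_non_c_position_rejected(self):
        with pytest.raises(ContractError):
            build_window(1, "+", self.REF, n=1, offset=-1)  # an A


class TestMatchIndex:
    CODE = [("T", "D"), ("T", "N"), ("N", "D")]

    def test_hand_checked_toy(self):
        assert match_index(self.CODE, "GAA", TOY_TABLE) == (2, 3)

    def test_universal_table_matches_everything(self):
        table = CodeTable({pair: set("ACGU") for pair in self.CODE})
        assert match_index(self.CODE, "GAC", table) == (3, 3)

    def test_all_no_prediction_matches_nothing(self):
        table = CodeTable(
            {pair: frozenset() for pair in self.CODE},
            no_prediction=frozenset(self.CODE),
        )
        assert match_index(self.CODE, "GAU", table) == (0, 3)

    def test_length_mismatch_is_a_contract_error(self):
        with pytest.raises(ContractError):
            match_index(self.CODE, "GA", TOY_TABLE)

    @given(st.data())
    def test_monotone_under_table_growth(self, data):
        """Adding permitted nucleotides to any pair never lowers k."""
        pairs = [("T", "D"), ("T", "N"), ("N", "D"), ("N", "N")]
        base_sets = {
            p: set(data.draw(st.sets(st.sampled_from("ACGU")), label=str(p)))
            for p in pairs
        }
        grown = {
            p: base_sets[p]
            | set(data.draw(st.sets(st.sampled_from("ACGU")), label=f"+{p}"))
            for p in pairs
        }
        window = data.draw(
            st.text(alphabet="ACGU", min_size=4, max_size=4), label="window"
        )
        no_pred = frozenset(pairs)
        k0, _ = match_index(
            pairs, window, CodeTable(dict(base_sets), no_prediction=no_pred)
        )
        k1, _ = match_index(
            pairs, window, CodeTable(dict(grown), no_prediction=no_pred)
        )
        assert 0 <= k0 <= k1 <= 4


class TestScanTargets:
    def _brute_force(self, prot, reference, genes, table, offset):
        """Independent rescoring: direct loops over every C, no shared
        windowing arithmetic with the implementation under test."""
        code = [(m.aa5, m.aa_last) for m in prot.motifs if m.motif_class in "PLS"]
        n = len(code)
        hits = {}
        for gene in genes:
            for pos in range(gene.gene_span[0], gene.gene_span[1] + 1):
                plus = reference.sequence[pos - 1]
                sense = plus if gene.strand == "+" else revcomp(plus)
                if sense != "C" or (pos, gene.strand) in hits:
                    continue
                if gene.strand == "+":
                    lo = pos + offset - n + 1
                    hi = pos + offset
                    if lo < 1:
                        continue
                    window = reference.sequence[lo - 1 : hi]
                else:
                    lo = pos - offset
                    hi = lo + n - 1
                    if hi > reference.length:
                        continue
                    window = revcomp(reference.sequence[lo - 1 : hi])
                k = sum(
                    1
                    for pair, nuc in zip(code, window.replace("T", "U"))
                    if nuc in table.entries.get(pair, frozenset())
                )
                hits[(pos, gene.strand)] = (k, n)
        out = [(p, s, k, n, k / n) for (p, s), (k, n) in hits.items()]
        out.sort(key=lambda r: (-r[4], r[0]))
        return out

    def test_agrees_with_brute_force_on_random_references(self):
        import numpy as np

        rng = np.random.default_rng(2024)
        prot = protein([("T", "D"), ("T", "N"), ("N", "D"), ("N", "N"), ("T", "D")])
        table = CodeTable(
            {("T", "D"): {"G"}, ("T", "N"): {"A"}, ("N", "D"): {"U"},
             ("N", "N"): {"C", "U"}}
        )
        for _ in range(5):
            length = int(rng.integers(200, 2000))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            ref = Reference("r", seq)
            third = length // 3
            genes = [
                GeneModel("gp", "+", ((10, third),), (10, third)),
                GeneModel("gm", "-", ((third + 5, length - 5),),
                          (third + 5, length - 5)),
            ]
            assert scan_targets(prot, ref, genes, table) == self._brute_force(
                prot, ref, genes, table, -4
            )

    def test_planted_perfect_window_ranks_first(self):
        # code GAAUC must appear at offsets -8..-4 of the planted C
        code_pairs = [("T", "D"), ("T", "N"), ("T", "N"), ("N", "D"), ("N", "N")]
        table = CodeTable(
            {("T", "D"): {"G"}, ("T", "N"): {"A"}, ("N", "D"): {"U"},
             ("N", "N"): {"C"}}
        )
        target = "GAATC"
        seq = "T" * 40 + target + "TTT" + "C" + "T" * 40
        pos = 40 + 5 + 3 + 1  # the planted C
        ref = Reference("r", seq)
        genes = [GeneModel("g", "+", ((1, len(seq)),), (1, len(seq)))]
        results = scan_targets(protein(code_pairs), ref, genes, table)
        assert results[0][0] == pos
        assert results[0][2:] == (5, 5, 1.0)

    def test_ties_break_by_ascending_position(self):
        seq = "T" * 10 + "C" + "T" * 10 + "C" + "T" * 10
        ref = Reference("r", seq)
        genes = [GeneModel("g", "+", ((1, len(seq)),), (1, len(seq)))]
        results = scan_targets(
            protein([("T", "D")]), ref, genes, TOY_TABLE
        )
        assert [r[0] for r in results] == [11, 22]
        assert results[0][4] == results[1][4]

    def test_reference_without_c_yields_empty(self):
        ref = Reference("r", "ATG" * 20)
        genes = [GeneModel("g", "+", ((1, 60),), (1, 60))]
        assert scan_targets(protein([("T", "D")]), ref, genes, TOY_TABLE) == []

    def test_strand_consistency(self):
        """Scoring a minus-strand site equals scoring the mirrored
        plus-strand construction."""
        rng_seq = "ACGGTTCAGGATCCGGATTCAGCATCAGGT"
        ref_plus = Reference("p", rng_seq)
        ref_minus = Reference("m", revcomp(rng_seq))
        n = len(rng_seq)
        prot = protein([("T", "D"), ("N", "N"), ("T", "N")])
        plus_genes = [GeneModel("g", "+", ((1, n),), (1, n))]
        minus_genes = [GeneModel("g", "-", ((1, n),), (1, n))]
        plus_scores = {
            (p, k, t) for p, _, k, t, _ in
            scan_targets(prot, ref_plus, plus_genes, TOY_TABLE)
        }
        minus_scores = {
            (n + 1 - p, k, t) for p, _, k, t, _ in
            scan_targets(prot, ref_minus, minus_genes, TOY_TABLE)
        }
        assert plus_scores == minus_scores
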