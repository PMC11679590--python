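import numpy as np
import pytest

from amplityper.diagnostics import Alignment
from amplityper.fixtures import CI, RN, make_paper_panel, paper_primers
from amplityper.insilico_pcr import BindingModel, simulate_pcr
from amplityper.primer_design import (
    AssayPanel,
    DesignConstraints,
    DesignError,
    InfeasibleDesignError,
    PrimerCandidate,
    assemble_assay,
    cross_dimer_3prime_check,
    enumerate_candidates,
)
from amplityper.seqio import NucleotideSequence, PrimerRecord, PrimerRole
from oracles import brute_force_dimer_score

NO_QC = dict(gc_range=(0.0, 100.0), tm_range=(0.0, 500.0), max_homopolymer=50)


def toy_alignment(rows):
    return Alignment.from_sequences(
        [NucleotideSequence(f"r{i}", res, species=sp, allow_gaps=True)
         for i, (sp, res) in enumerate(rows)]
    )


class TestConstraints:
    def test_ranges_must_be_ordered(self):
        with pytest.raises(DesignError):
            DesignConstraints(length_range=(28, 18))
        with pytest.raises(DesignError):
            DesignConstraints(min_separation=0)

    def test_defaults_admit_the_published_primers(self):
        c = DesignConstraints()
        for p in paper_primers().values():
            if p.role is PrimerRole.BARCODING:
                continue  # the Folmer pair is not part of the diagnostic assay
            from amplityper.seqio import gc_content, max_homopolymer_run, wallace_tm
            seq = p.sequence.residues
            assert c.length_range[0] <= len(seq) <= c.length_range[1]
            assert c.gc_range[0] <= gc_content(seq) <= c.gc_range[1]
            assert c.tm_range[0] <= wallace_tm(seq) <= c.tm_range[1]
            assert max_homopolymer_run(seq) <= c.max_homopolymer


class TestEnumerateCandidates:
    def test_window_shorter_than_min_length_is_empty(self):
        a = toy_alignment([("s1", "ACGTACGTACGTACGTACGTACGTACGTAC")] * 2)
        assert enumerate_candidates(a, (1, 10), "forward",
                                    DesignConstraints(**NO_QC)) == []

    def test_candidate_count_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        row = "".join(rng.choice(list("ACGT"), 30))
        a = toy_alignment([("s1", row), ("s1", row)])
        c = DesignConstraints(length_range=(18, 22), **NO_QC)
        cands = enumerate_candidates(a, (1, 30), "forward", c, species="s1")
        expected = sum(30 - L + 1 for L in range(18, 23))
        assert len(cands) == expected
        assert [(x.start, x.end) for x in cands] == sorted(
            (x.start, x.end) for x in cands)

    def test_pinned_window_and_length_recover_published_forward(self, paper_alignment):
        c = DesignConstraints(length_range=(27, 27))
        (cand,) = enumerate_candidates(paper_alignment, (181, 207), "forward", c,
                                       species=CI)
        assert cand.primer.sequence.residues == "GGATTTGGTAATTGACTTGTACCTCTT"
        assert (cand.start, cand.end) == (181, 207)

    def test_reverse_strand_candidates_are_reverse_complements(self, paper_alignment):
        c = DesignConstraints(length_range=(23, 23))
        (cand,) = enumerate_candidates(paper_alignment, (357, 379), "reverse", c)
        assert cand.primer.sequence.residues == "CAGATCTACCACCATGAGCAATA"

    def test_window_outside_alignment_errors(self, paper_alignment):
        with pytest.raises(DesignError):
            enumerate_candidates(paper_alignment, (600, 700), "forward",
                                 DesignConstraints())


class TestAssembleAssay:
    def test_feasible_panel_on_fixture_respects_separation(self, paper_alignment):
        res = assemble_assay(paper_alignment, [CI, RN],
                             DesignConstraints(min_separation=50))
        assert res.panel.min_pairwise_separation >= 50
        sizes = res.panel.expected_sizes
        assert set(sizes) == {CI, RN}
        rev = res.panel.common_reverse
        for sp, fwd in res.panel.forwards.items():
            assert sizes[sp] == rev.end - fwd.start + 1

    def test_designed_sizes_are_reproduced_by_simulation(self, paper_panel):
        """Design/simulation consistency: in-silico PCR on each target's own
        barcode reproduces the panel's expected sizes exactly."""
        aln = paper_panel.alignment()
        res = assemble_assay(aln, [CI, RN])
        for sp, fwd in res.panel.forwards.items():
            (amp,) = simulate_pcr(fwd.primer, res.panel.common_reverse.primer,
                                  paper_panel.templates(sp)[0], BindingModel())
            assert amp.length == res.panel.expected_sizes[sp]

    def test_designed_forwards_do_not_amplify_non_targets(self, paper_panel):
        aln = paper_panel.alignment()
        res = assemble_assay(aln, [CI, RN])
        for sp, fwd in res.panel.forwards.items():
            for other in paper_panel.sequences:
                if other.species == sp:
                    continue
                amps = simulate_pcr(fwd.primer, res.panel.common_reverse.primer,
                                    other, BindingModel())
                assert amps == [], (sp, other.species)

    def test_result_invariant_to_row_order(self, paper_panel):
        aln = paper_panel.alignment()
        res = assemble_assay(aln, [CI, RN])
        shuffled = Alignment(tuple(reversed(aln.rows)))
        res2 = assemble_assay(shuffled, [CI, RN])
        assert res2.panel.expected_sizes == res.panel.expected_sizes
        assert res2.panel.common_reverse == res.panel.common_reverse
        assert res2.panel.forwards == res.panel.forwards

    def test_deterministic_across_calls(self, paper_alignment):
        a = assemble_assay(paper_alignment, [CI, RN])
        b = assemble_assay(paper_alignment, [CI, RN])
        assert a.panel == b.panel
        assert [p.expected_sizes for p in a.alternatives] == \
               [p.expected_sizes for p in b.alternatives]

    def test_single_species_cannot_discriminate(self, paper_alignment):
        with pytest.raises(DesignError):
            assemble_assay(paper_alignment, [CI])

    def test_infeasibility_reports_the_failing_constraint(self, paper_alignment):
        with pytest.raises(InfeasibleDesignError) as exc:
            assemble_assay(paper_alignment, [CI, RN],
                           DesignConstraints(min_separation=5000))
        assert "separation" in str(exc.value)
        assert exc.value.report["reverse_candidates"] > 0

    def test_panel_json_roundtrip(self, paper_alignment, tmp_path):
        panel = assemble_assay(paper_alignment, [CI, RN]).panel
        path = tmp_path / "panel.json"
        panel.to_json(path)
        back = AssayPanel.from_json(path)
        assert back.expected_sizes == panel.expected_sizes
        assert back.common_reverse.primer.sequence.residues == \
               panel.common_reverse.primer.sequence.residues


def test_panel_size_arithmetic_is_validated():
    rec = PrimerRecord("r", NucleotideSequence("r", "ACGTACGTACGTACGTACGTACG"),
                       PrimerRole.COMMON_REVERSE)
    rev = PrimerCandidate(rec, 357, 379, "reverse", 50.0, 66.0, 2)
    frec = PrimerRecord("f", NucleotideSequence("f", "A" * 27), PrimerRole.SPECIES_FORWARD,
                        "sp")
    fwd = PrimerCandidate(frec, 181, 207, "forward", 0.0, 54.0, 27)
    with pytest.raises(DesignError, match="reverse.end - forward.start"):
        AssayPanel(common_reverse=rev, forwards={"sp": fwd},
                   expected_sizes={"sp": 100})
    panel = AssayPanel(common_reverse=rev, forwards={"sp": fwd},
                       expected_sizes={"sp": 199})
    assert panel.expected_sizes["sp"] == 379 - 181 + 1 == 199


class TestSelectionSearch:
    """The subset-DP start selection must agree with exhaustive enumeration."""

    @staticmethod
    def _exhaustive(per_species, order, constraints):
        import itertools
        best_key, best = None, None
        for combo in itertools.product(*(sorted(per_species[sp]) for sp in order)):
            sep = min(abs(a - b) for a, b in itertools.combinations(combo, 2))
            if sep < constraints.min_separation:
                continue
            margin = min(per_species[sp][s].qc_margin(constraints)
                         for sp, s in zip(order, combo))
            key = (-sep, -margin, combo)
            if best_key is None or key < best_key:
                best_key, best = key, dict(zip(order, combo))
        return best

    @pytest.mark.parametrize("search_seed", range(10))
    def test_matches_exhaustive_product_on_small_instances(self, search_seed):
        from amplityper.primer_design import _best_selection
        rng = np.random.default_rng(search_seed)
        constraints = DesignConstraints(min_separation=int(rng.integers(1, 30)))
        order = [f"sp{i}" for i in range(int(rng.integers(2, 5)))]
        per_species = {}
        for sp in order:
            starts = rng.choice(np.arange(1, 200), size=int(rng.integers(1, 8)),
                                replace=False)
            cands = {}
            for s in starts:
                rec = PrimerRecord(f"{sp}_{s}", NucleotideSequence("p", "ACGTACGTACGTACGTAC"),
                                   PrimerRole.SPECIES_FORWARD, sp)
                gc = float(rng.choice([35.0, 45.0, 55.0]))
                cands[int(s)] = PrimerCandidate(rec, int(s), int(s) + 17, "forward",
                                                gc, 60.0, 2)
            per_species[sp] = cands
        got = _best_selection(per_species, order, constraints)
        expected = self._exhaustive(per_species, order, constraints)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            got_starts = {sp: c.start for sp, c in got.items()}
            import itertools
            def key(sel):
                starts = [sel[sp] for sp in order]
                sep = min(abs(a - b) for a, b in itertools.combinations(starts, 2))
                margin = min(per_species[sp][s].qc_margin(constraints)
                             for sp, s in sel.items())
                return (-sep, -margin)
            assert key(got_starts) == key(expected)


class TestCrossDimer:
    def _primer(self, name, seq):
        return PrimerRecord(name, NucleotideSequence(name, seq), PrimerRole.BARCODING)

    def test_fully_complementary_pair_fails(self):
        a = self._primer("a", "A" * 10)
        b = self._primer("b", "T" * 10)
        ok, score = cross_dimer_3prime_check(a, b, max_3prime_complementarity=3)
        assert not ok and score == 10

    @pytest.mark.parametrize("pair_seed", range(8))
    def test_score_matches_brute_force_search(self, pair_seed):
        rng = np.random.default_rng(pair_seed)
        x = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 26))))
        y = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 26))))
        _, score = cross_dimer_3prime_check(self._primer("x", x), self._primer("y", y))
        assert score == brute_force_dimer_score(x, y)

    def test_published_assay_pair_regression(self):
        primers = paper_primers()
        ok, score = cross_dimer_3prime_check(primers["MMRC_1955"], primers["MMRC_1964"])
        assert score == brute_force_dimer_score("CAGATCTACCACCATGAGCAATA",
                                                "GGATTTGGTAATTGACTTGTACCTCTT")
        assert (ok, score) == (True, 2)
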