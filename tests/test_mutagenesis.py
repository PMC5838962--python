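"""Mutant design: G4 disruption, loop controls, mutagenic primers."""

import pytest

from g4ltr import (
    design_g4_mutant,
    design_loop_control,
    gen_te_cohort,
    make_mutagenic_primer,
    scan,
)


def _hit(seq, params, strand="+"):
    hits = scan(seq, params, strands=strand)
    assert hits, "fixture sequence must contain a PQS"
    return hits[0]


class TestG4Mutant:
    def test_minimal_motif_bookkeeping(self, params):
        seq = "GGTGGTGGTGG"
        design = design_g4_mutant(seq, _hit(seq, params), params)
        assert design.mutant_seq == "GGTAATAATGG"

    def test_substitutions_confined_to_inner_runs(self, motifs, params):
        for name, seq in motifs.items():
            hit = _hit(seq, params)
            design = design_g4_mutant(seq, hit, params)
            inner = set()
            for run in hit.runs[1:3]:
                inner.update(range(run.start, run.end))
            assert {p for p, _f, _t in design.substitutions} <= inner, name
            assert all(f == "G" and t == "A" for _p, f, t in design.substitutions)

    def test_disruption_abolishes_detection(self, motifs, params):
        for name, seq in motifs.items():
            hit = _hit(seq, params)
            design = design_g4_mutant(seq, hit, params)
            surviving = [
                h
                for h in scan(design.mutant_seq, params, strands="both")
                if h.overlaps(hit.start, hit.end)
            ]
            assert surviving == [], name

    def test_mutant_has_no_hit_to_redesign(self, motifs, params):
        seq = motifs["Huck"]
        design = design_g4_mutant(seq, _hit(seq, params), params)
        assert scan(design.mutant_seq, params, strands="+") == []

    def test_minus_strand_hit_mutated_in_plus_coordinates(self, motifs, params):
        from g4ltr import reverse_complement

        seq = reverse_complement(motifs["Huck"])
        hit = _hit(seq, params, strand="-")
        design = design_g4_mutant(seq, hit, params)
        assert len(design.mutant_seq) == len(seq)
        # minus-strand G -> A reads as plus-strand C -> T
        assert all(f == "C" and t == "T" for _p, f, t in design.substitutions)
        assert [
            h
            for h in scan(design.mutant_seq, params, strands="both")
            if h.overlaps(hit.start, hit.end)
        ] == []

    def test_mismatched_sequence_rejected(self, motifs, params):
        hit = _hit(motifs["Huck"], params)
        with pytest.raises(ValueError, match="match"):
            design_g4_mutant("A" * len(motifs["Huck"]), hit, params)

    def test_planted_synthetic_motifs_all_disruptable(self, params):
        """Inner-run disruption removes every planted strict-tier motif.

        Random backgrounds hold plenty of two-tetrad GG clusters, so weak
        report-tier candidates can overlap the interval after mutation;
        verification therefore runs at the strict tier, the tier at which
        planted truth is defined."""
        records, truth = gen_te_cohort(
            n_families=12,
            length_dist=lambda rng: int(rng.integers(1500, 2500)),
            pqs_rate=1.0,
            seed=5,
        )
        by_id = {r.te_id: r for r in records}
        checked = 0
        for planted in truth.planted_pqs[:10]:
            te = by_id[planted.te_id]
            cand = [
                h
                for h in scan(te.sequence, params, strands=planted.strand, seq_id=te.te_id)
                if h.overlaps(planted.start, planted.end)
            ]
            design = design_g4_mutant(
                te.sequence, cand[0], params,
                verify_threshold=params.strict_threshold,
            )
            subs_pos = {p for p, _f, _t in design.substitutions}
            assert subs_pos and subs_pos <= set(range(planted.start, planted.end))
            checked += 1
        assert checked == 10


class TestLoopControl:
    def test_huck_cg_to_tc(self, motifs, params):
        seq = motifs["Huck"]
        hit = _hit(seq, params)
        design = design_loop_control(seq, hit, "CG", "TC", params)
        # the second loop AACGCA becomes AATCCA
        assert design.mutant_seq == "CGGGGATATAGGGGGAATCCAGGGACGCGGGGC"
        retained = scan(design.mutant_seq, params, strands="+")
        assert len(retained) == 1 and retained[0].score == hit.score

    def test_score_and_runs_preserved(self, motifs, params):
        seq = motifs["Gyma"]
        hit = _hit(seq, params)
        design = design_loop_control(seq, hit, "CG", "TC", params)
        (retained,) = scan(design.mutant_seq, params, strands="+")
        assert retained.score == hit.score
        assert retained.loops == hit.loops

    def test_absent_motif_rejected(self, motifs, params):
        with pytest.raises(ValueError, match="not found"):
            design_loop_control(
                motifs["Huck"], _hit(motifs["Huck"], params), "TTTT", "AAAA", params
            )

    def test_zero_length_loops_rejected(self, params):
        seq = "AGGTGGTGGTGGA"
        hit = _hit(seq, params)
        with pytest.raises(ValueError):
            design_loop_control(seq, hit, "CG", "TC", params)

    def test_unequal_motif_lengths_rejected(self, motifs, params):
        with pytest.raises(ValueError, match="length"):
            design_loop_control(
                motifs["Huck"], _hit(motifs["Huck"], params), "CG", "T", params
            )


class TestPrimer:
    def test_primer_length_unclipped(self, motifs, params):
        seq = "A" * 40 + motifs["Huck"] + "A" * 40
        hit = _hit(seq, params)
        design = design_g4_mutant(seq, hit, params)
        positions = [p for p, _f, _t in design.substitutions]
        span = max(positions) - min(positions) + 1
        primer = make_mutagenic_primer(seq, design, flank=15)
        assert len(primer) == span + 30

    def test_left_clipped_at_sequence_start(self, params):
        seq = "GGTGGTGGTGG" + "A" * 30
        design = design_g4_mutant(seq, _hit(seq, params), params)
        primer = make_mutagenic_primer(seq, design, flank=15)
        assert primer.startswith("GGT")  # clipped: nothing left of position 0
        assert len(primer) < (8 - 3 + 1) + 30 + 1

    def test_huck_primer_contains_both_mutated_runs(self, motifs, params):
        seq = "T" * 25 + motifs["Huck"] + "T" * 25
        design = design_g4_mutant(seq, _hit(seq, params), params)
        primer = make_mutagenic_primer(seq, design, flank=20)
        assert "AAAAA" in primer and "GGGG" in primer

    def test_short_flank_rejected(self, motifs, params):
        seq = motifs["Huck"]
        design = design_g4_mutant(seq, _hit(seq, params), params)
        with pytest.raises(ValueError):
            make_mutagenic_primer(seq, design, flank=5)
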