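"""Primer engine: screens, enumeration, pairing, ranking, specificity."""
from __future__ import annotations

import numpy as np
import pytest

from circseam import (
    CircRecord,
    DesignConfig,
    Dialect,
    FixtureSpec,
    JunctionTemplate,
    PlantedRepeat,
    design_primers,
    enumerate_candidates,
    linear_specificity_check,
    make_fixture,
    open_genome,
    pair_and_rank,
    parse_records,
    build_template,
    subsequence,
)
from circseam.primers import (
    PrimerCandidate,
    PrimerPair,
    hairpin_stem,
    max_homopolymer_run,
    self_dimer_scores,
)
from _oracles import (
    convergent_products_oracle,
    count_candidates_oracle,
    dimer_oracle,
    hairpin_oracle,
    homopolymer_oracle,
    valid_pairs_oracle,
)

BASES = np.array(list("ACGT"))


def random_template(seed: int, length: int = 400, gc: float = 0.5,
                    junction: int | None = None) -> JunctionTemplate:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(BASES[rng.choice(4, size=length, p=p)])
    j = junction if junction is not None else length // 2
    rec = CircRecord("ctg", 1000, 1000 + length, "+", f"t{seed}")
    return JunctionTemplate(rec, seq, j, j, length - j)


class TestStructureScreens:
    def test_poly_a_has_no_self_dimer(self):
        assert self_dimer_scores("A" * 15)[0] == 0

    def test_perfect_palindrome_scores_its_length(self):
        half = "ATGCATGC"
        pal = half + "GCATGCAT"  # revcomp(pal) == pal
        assert self_dimer_scores(pal)[0] == 16

    def test_scores_match_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(120):
            seq = "".join(BASES[rng.integers(0, 4, 19)])
            assert self_dimer_scores(seq) == dimer_oracle(seq)
            assert hairpin_stem(seq) == hairpin_oracle(seq)

    def test_hairpin_detects_planted_stem(self):
        # 6-bp stem, 4-nt loop, designed by hand
        seq = "GCGCGC" + "TTTT" + "GCGCGC"
        assert hairpin_stem(seq) >= 6

    def test_homopolymer_run(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            seq = "".join(BASES[rng.integers(0, 4, 25)])
            assert max_homopolymer_run(seq) == homopolymer_oracle(seq)


class TestEnumerateCandidates:
    def test_all_n_template_yields_nothing(self):
        rec = CircRecord("c", 0, 300, "+", "n")
        tpl = JunctionTemplate(rec, "N" * 300, 150, 150, 150)
        fwd, rev = enumerate_candidates(tpl, DesignConfig())
        assert fwd == [] and rev == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_exhaustive_filter_oracle(self, seed):
        tpl = random_template(seed, length=400, gc=0.5)
        cfg = DesignConfig()
        fwd, rev = enumerate_candidates(tpl, cfg)
        assert (len(fwd), len(rev)) == count_candidates_oracle(tpl.sequence, cfg)

    def test_candidates_respect_config_bounds(self):
        tpl = random_template(3, length=400, gc=0.6)
        cfg = DesignConfig()
        fwd, rev = enumerate_candidates(tpl, cfg)
        for cand in fwd + rev:
            assert cfg.min_len <= cand.length <= cfg.max_len
            assert cfg.tm_min <= cand.tm <= cfg.tm_max
            assert cfg.gc_min <= cand.gc <= cfg.gc_max
            assert max_homopolymer_run(cand.sequence) <= cfg.max_homopolymer

    def test_length_penalty_is_zero_at_optimum(self):
        tpl = random_template(4, length=400, gc=0.6)
        cfg = DesignConfig()
        fwd, rev = enumerate_candidates(tpl, cfg)
        nineteen = [c for c in fwd + rev if c.length == 19]
        assert nineteen, "expected some 19-mers on a 400-nt 60% GC template"
        for cand in nineteen:
            len_component = cand.penalty - cfg.w_tm * abs(
                cand.tm - cfg.tm_opt
            ) - cfg.w_gc * abs(cand.gc - 0.5)
            assert len_component == pytest.approx(0.0, abs=1e-12)


class TestPairAndRank:
    def test_product_entirely_left_of_junction_excluded(self):
        # junction at the far right edge: only products reaching the last
        # base can span it, everything fully left of it must be excluded
        tpl = random_template(8, length=400, gc=0.6, junction=399)
        cfg = DesignConfig(n_sets=10**6, product_min=50, product_max=120)
        fwd, rev = enumerate_candidates(tpl, cfg)
        pairs = pair_and_rank(fwd, rev, tpl, cfg)
        assert all(p.product_end == 400 for p in pairs)
        # plenty of size/Tm-valid combos end before the junction; prove
        # the junction constraint is what removed them
        unconstrained = sum(
            1
            for f in fwd
            for r in rev
            if cfg.product_min <= r.template_end - f.template_start <= cfg.product_max
            and r.template_start >= f.template_end
            and abs(f.tm - r.tm) <= cfg.max_tm_diff
        )
        assert unconstrained > len(pairs)

    def test_top_n_sets_returned_when_many_valid(self):
        tpl = random_template(9, length=400, gc=0.6)
        cfg_all = DesignConfig(n_sets=10**6)
        fwd, rev = enumerate_candidates(tpl, cfg_all)
        everything = pair_and_rank(fwd, rev, tpl, cfg_all)
        assert len(everything) >= 20
        top = pair_and_rank(fwd, rev, tpl, DesignConfig())
        assert len(top) == 4
        assert [p.pair_penalty for p in top] == sorted(
            p.pair_penalty for p in top
        )

    @pytest.mark.parametrize("seed", [10, 11, 12, 13])
    def test_valid_pair_set_matches_double_loop_oracle(self, seed):
        tpl = random_template(seed, length=450, gc=0.55)
        cfg = DesignConfig(n_sets=10**6)
        fwd, rev = enumerate_candidates(tpl, cfg)
        got = {
            (p.forward.sequence, p.forward.template_start,
             p.reverse.sequence, p.reverse.template_start)
            for p in pair_and_rank(fwd, rev, tpl, cfg)
        }
        assert got == valid_pairs_oracle(fwd, rev, tpl.junction_index, cfg)

    def test_reported_pair_invariants(self):
        cfg = DesignConfig()
        for seed in range(14, 20):
            tpl = random_template(seed, length=400, gc=0.6)
            for p in design_primers(tpl, cfg):
                assert p.product_size == p.product_end - p.product_start
                assert cfg.product_min <= p.product_size <= cfg.product_max
                assert p.product_start < tpl.junction_index < p.product_end
                assert p.product_start >= tpl.junction_index - cfg.product_max + 1
                assert p.tm_diff <= cfg.max_tm_diff
                assert p.spans_junction

    def test_deterministic_ranked_output(self):
        tpl = random_template(21, length=400, gc=0.6)
        a = design_primers(tpl, DesignConfig())
        b = design_primers(tpl, DesignConfig())
        assert a == b

    def test_relaxing_windows_never_loses_pairs(self):
        tight = DesignConfig(n_sets=10**6)
        wider_tm = DesignConfig(n_sets=10**6, tm_min=55.0, tm_max=65.0)
        wider_prod = DesignConfig(n_sets=10**6, product_min=120, product_max=250)
        for seed in (30, 31, 32):
            tpl = random_template(seed, length=450, gc=0.55)
            def n_pairs(cfg):
                fwd, rev = enumerate_candidates(tpl, cfg)
                return len(pair_and_rank(fwd, rev, tpl, cfg))
            base = n_pairs(tight)
            assert n_pairs(wider_tm) >= base
            assert n_pairs(wider_prod) >= base


class TestLinearSpecificity:
    def test_junction_pairs_divergent_on_clean_genome(self, std_fixture, std_genome):
        batch = parse_records(std_fixture.call_files[Dialect.BED])
        checked = 0
        for rec in batch:
            tpl = build_template(rec, std_genome)
            for pair in design_primers(tpl, DesignConfig()):
                ok, note = linear_specificity_check(pair, rec, std_genome)
                assert ok, note
                checked += 1
        assert checked > 0

    def test_planted_convergent_repeat_fails(self, tmp_path):
        spec = FixtureSpec(
            seed=2, n_circles=3, gc=0.6, contig_len=20_000, strands=("+",),
            planted_repeats=[PlantedRepeat(circle_index=0, distance=1000)],
        )
        fx = make_fixture(spec, tmp_path)
        genome = open_genome(fx.genome_fasta)
        rec = fx.records[0]
        tpl = build_template(rec, genome)
        pairs = design_primers(tpl, DesignConfig())
        assert pairs, "sabotaged circle should still yield junction pairs"
        failed = 0
        for pair in pairs:
            ok, note = linear_specificity_check(pair, rec, genome)
            # verify the verdict against the naive string-search oracle
            w_start = max(0, rec.start - 5000)
            w_end = min(genome.length(rec.chrom), rec.end + 5000)
            window = subsequence(genome, rec.chrom, w_start, w_end)
            oracle_hits = convergent_products_oracle(
                window,
                [pair.forward.sequence, pair.reverse.sequence],
                5000,
            )
            assert ok == (len(oracle_hits) == 0)
            failed += (not ok)
        assert failed >= 1

    def test_unmatched_primers_pass_with_note(self, toy_genome):
        cand = PrimerCandidate(
            sequence="GATTACAGATTACAG", template_start=0, length=15,
            orientation="forward", tm=60.0, gc=0.4, self_dimer_score=0,
            hairpin_score=0, penalty=0.0,
        )
        pair = PrimerPair(
            forward=cand, reverse=cand, product_start=0, product_end=160,
            product_size=160, spans_junction=True, tm_diff=0.0, pair_penalty=0.0,
        )
        rec = CircRecord("chrA", 1, 7, "+", "toy")
        ok, note = linear_specificity_check(pair, rec, toy_genome)
        assert ok
        assert "no exact primer matches" in note
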