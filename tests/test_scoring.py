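import itertools

import numpy as np
import pytest

import strainvar as sv
from strainvar.scoring import CooccurrenceIndex


def cand(gene, pos, alt="T", ref="C", count=10, depth=100, novel=False):
    return sv.CandidateVariant(gene, pos, ref, alt, count, depth, is_novel=novel)


class TestNovelty:
    def test_known_and_unknown_substitutions(self):
        db = sv.AlleleDatabase()
        db.add("g", "1", "ACCCCCCACC")
        db.add("g", "2", "ACCCCCCGCC")  # G at pos 7 is known
        cands = [cand("g", 7, alt="G"), cand("g", 7, alt="T")]
        sv.annotate_novelty(cands, db, {"g": 10})
        assert cands[0].is_novel is False
        assert cands[1].is_novel is True

    def test_only_same_length_alleles_consulted(self):
        db = sv.AlleleDatabase()
        db.add("g", "1", "ACCCCCCACC")
        db.add("g", "2", "ACCCCCCG")  # shorter: must be ignored
        cands = sv.annotate_novelty([cand("g", 7, alt="G")], db, {"g": 10})
        assert cands[0].is_novel is True

    def test_matches_bruteforce_scan(self, small_db):
        rng = np.random.default_rng(21)
        gene = small_db.gene_ids()[0]
        template = small_db.get(gene, "1").sequence
        cands = []
        for _ in range(40):
            pos = int(rng.integers(len(template)))
            alt = "ACGT"[int(rng.integers(4))]
            if alt == template[pos]:
                continue
            cands.append(cand(gene, pos, alt=alt, ref=template[pos]))
        sv.annotate_novelty(cands, small_db, {gene: len(template)})
        for c in cands:
            expected = not any(
                a.sequence[c.position] == c.alt_base
                for a in small_db.alleles(gene)
                if len(a.sequence) == len(template)
            )
            assert c.is_novel == expected


class TestProximityAndDensity:
    def test_within_window(self):
        cands = [cand("g", 10), cand("g", 14)]
        sv.annotate_proximity(cands)
        assert all(c.is_proximal for c in cands)

    def test_outside_window(self):
        cands = [cand("g", 10), cand("g", 16)]
        sv.annotate_proximity(cands)
        assert not any(c.is_proximal for c in cands)

    def test_same_position_alts_not_mutually_proximal(self):
        cands = [cand("g", 10, alt="T"), cand("g", 10, alt="G")]
        sv.annotate_proximity(cands)
        assert not any(c.is_proximal for c in cands)
        third = cand("g", 13, alt="A")
        sv.annotate_proximity(cands + [third])
        assert all(c.is_proximal for c in cands + [third])

    def test_density_window_counts(self):
        cands = [cand("g", p) for p in (100, 105, 112, 140)]
        sv.annotate_density(cands)
        by_pos = {c.position: c.density_M for c in cands}
        assert by_pos[105] == 2  # 100 and 112
        assert by_pos[140] == 0
        lone = [cand("g", 5)]
        sv.annotate_density(lone)
        assert lone[0].density_M == 0

    def test_flags_match_pairwise_bruteforce(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            positions = sorted(set(rng.integers(0, 200, size=12).tolist()))
            cands = [cand("g", int(p)) for p in positions]
            sv.annotate_proximity(cands)
            sv.annotate_density(cands)
            for c in cands:
                deltas = [abs(c.position - other.position) for other in cands
                          if other.position != c.position]
                assert c.is_proximal == any(d <= 5 for d in deltas)
                assert c.density_M == sum(d <= 15 for d in deltas)


def linked_read_set(gene="g", n_reads=100, length=200):
    """Reads over one gene where designated read indices carry alt bases."""
    template = "A" * length
    db = sv.AlleleDatabase()
    db.add(gene, "1", template)
    return db, template


def make_alignments(gene, length, n_reads, carriers):
    """carriers: {(pos, alt): set of read indices}."""
    records = []
    for i in range(n_reads):
        seq = ["A"] * length
        for (pos, alt), reads in carriers.items():
            if i in reads:
                seq[pos] = alt
        records.append(
            sv.AlignmentRecord(f"r{i}", gene, "1", 0, [(0, length)],
                               "".join(seq), None)
        )
    return records


class TestCooccurrence:
    def test_linked_pair_rewarded(self):
        carriers = {(10, "T"): set(range(10)), (50, "G"): set(range(10))}
        records = make_alignments("g", 200, 100, carriers)
        cands = [cand("g", 10, alt="T", ref="A", count=10),
                 cand("g", 50, alt="G", ref="A", count=10)]
        sv.annotate_cooccurrence(cands, records, maf=0.05)
        assert all(c.cooccurring for c in cands)
        assert cands[0].partners == {("g", 50, "G")}

    def test_disjoint_errors_not_rewarded(self):
        carriers = {(10, "T"): set(range(5)), (50, "G"): set(range(5, 10))}
        records = make_alignments("g", 200, 100, carriers)
        cands = [cand("g", 10, alt="T", ref="A", count=5),
                 cand("g", 50, alt="G", ref="A", count=5)]
        sv.annotate_cooccurrence(cands, records, maf=0.05)
        assert not any(c.cooccurring for c in cands)

    def test_partner_sets_match_read_intersection_oracle(self, small_db,
                                                          dual_strains):
        mix = sv.MixSpec(list(dual_strains), [0.92, 0.08], depth=150, seed=17)
        sample = sv.simulate_sample(mix, small_db, sv.ErrorModel.noise_free())
        top = sv.select_top_allele(sample.alignments, small_db)
        vmap = sv.build_variant_map(sample.alignments, top, small_db)
        cands = sv.extract_candidates(vmap, 0.05, 0.5)
        maf = 0.05
        sv.annotate_cooccurrence(cands, sample.alignments, maf)
        # brute-force oracle: per pair, intersect carrier and coverage read sets
        by_gene = {}
        for c in cands:
            by_gene.setdefault(c.gene_id, []).append(c)
        for gene_id, gene_cands in by_gene.items():
            recs = [r for r in sample.alignments if r.gene_id == gene_id]
            carrier = {}
            coverage = {}
            for c in gene_cands:
                carrier[c.key] = {
                    r.read_id for r in recs if r.base_at(c.position) == c.alt_base
                }
                coverage[c.key] = {
                    r.read_id for r in recs
                    if r.base_at(c.position) not in (None, "-")
                }
            for a in gene_cands:
                expected = set()
                for b in gene_cands:
                    if a.key == b.key:
                        continue
                    denom = len(coverage[a.key] & coverage[b.key])
                    joint = len(carrier[a.key] & carrier[b.key])
                    if denom > 0 and joint / denom > maf / 2:
                        expected.add(b.key)
                assert set(a.partners) == expected


class TestVariantThreshold:
    CLEAN_05 = sv.ParameterSet(maf=0.05, cor=0.459, ii=0.0497, pp=0.186,
                               np=2.009, dp=0.144)

    def test_no_flags_gives_maf(self):
        params = sv.ParameterSet(maf=0.05, cor=0.5, ii=0.1, pp=0.2, np=2.0, dp=0.1)
        assert sv.variant_threshold(cand("g", 5), params) == pytest.approx(0.05)

    def test_novel_only(self):
        params = sv.ParameterSet(maf=0.05, cor=0.5, ii=0.1, pp=0.2, np=2.0, dp=0.1)
        c = cand("g", 5, novel=True)
        assert sv.variant_threshold(c, params) == pytest.approx(0.15)

    def test_all_flags_in_listing_order(self):
        # ((0.05 + 0.05*2.0) * 1.2) + 0.05*0.1*2 - 0.05*0.5 = 0.165
        params = sv.ParameterSet(maf=0.05, cor=0.5, ii=0.1, pp=0.2, np=2.0, dp=0.1)
        c = cand("g", 5, novel=True)
        c.is_proximal = True
        c.density_M = 2
        c.cooccurring = True
        assert sv.variant_threshold(c, params) == pytest.approx(0.165)

    def test_floored_at_zero(self):
        params = sv.ParameterSet(maf=0.05, cor=30.0, ii=0.0, pp=0.0, np=0.0, dp=0.0)
        c = cand("g", 5)
        c.cooccurring = True
        assert sv.variant_threshold(c, params) == 0.0

    def test_monotonicity_in_each_parameter(self):
        c = cand("g", 5, novel=True)
        c.is_proximal = True
        c.density_M = 3
        c.cooccurring = True
        base = sv.ParameterSet(maf=0.05, cor=0.4, ii=0.1, pp=0.2, np=2.0, dp=0.1)
        t0 = sv.variant_threshold(c, base)
        for name, sign in (("np", 1), ("pp", 1), ("dp", 1), ("cor", -1)):
            bumped = sv.ParameterSet(**{**base.as_dict(), name: getattr(base, name) + 0.1})
            assert sign * (sv.variant_threshold(c, bumped) - t0) > 0

    def test_agrees_with_bruteforce_calculator(self):
        """Independent reimplementation agrees to 1e-12 on random draws."""
        def oracle(maf, np_, pp, dp, cor, novel, proximal, M, co):
            t = maf
            if novel:
                t = t + maf * np_
            if proximal:
                t = t * (1 + pp)
            t = t + maf * dp * M
            if co:
                t = t - maf * cor
            return max(t, 0.0)

        rng = np.random.default_rng(99)
        for _ in range(10_000):
            maf = rng.uniform(0.005, 0.2)
            vals = dict(cor=rng.uniform(0, 2), ii=rng.uniform(0, 0.5),
                        pp=rng.uniform(0, 1), np=rng.uniform(0, 5),
                        dp=rng.uniform(0, 1))
            params = sv.ParameterSet(maf=maf, **vals)
            c = cand("g", 5, novel=bool(rng.integers(2)))
            c.is_proximal = bool(rng.integers(2))
            c.density_M = int(rng.integers(0, 6))
            c.cooccurring = bool(rng.integers(2))
            expected = oracle(maf, vals["np"], vals["pp"], vals["dp"],
                              vals["cor"], c.is_novel, c.is_proximal,
                              c.density_M, c.cooccurring)
            assert abs(sv.variant_threshold(c, params) - expected) < 1e-12


class TestConverge:
    CLEAN_05 = sv.ParameterSet(maf=0.05, cor=0.459, ii=0.0497, pp=0.186,
                               np=2.009, dp=0.144)

    def test_empty_candidates_single_iteration(self):
        result = sv.converge([], self.CLEAN_05)
        assert result.final_variants == []
        assert result.iterations_run == 1
        assert result.converged

    def test_single_stable_candidate_two_iterations(self):
        c = cand("g", 50, count=6, depth=100)  # abundance 0.06, isolated
        result = sv.converge([c], self.CLEAN_05)
        assert [v.key for v in result.final_variants] == [c.key]
        assert result.iterations_run == 2

    def test_linked_pair_survives_noise_cluster(self):
        """Two co-occurring strain variants outlive four novel scattered errors.

        Expected outcome stepped by hand: iteration 1 drops all four novel
        errors (novelty + proximity + density push their thresholds to ~0.19
        against abundance 0.055) while the pair's thresholds stay below 0.07;
        iteration 2 confirms the stable count.
        """
        t1 = cand("g", 100, alt="T", ref="A", count=14, depth=200)
        t2 = cand("g", 107, alt="G", ref="A", count=14, depth=200)
        errors = [cand("g", p, alt="C", ref="A", count=11, depth=200, novel=True)
                  for p in (90, 94, 116, 120)]
        index = CooccurrenceIndex({(t1.key, t2.key): 0.07, (t2.key, t1.key): 0.07})
        result = sv.converge([t1, t2, *errors], self.CLEAN_05, index=index)
        assert result.keys() == {t1.key, t2.key}
        assert result.iterations_run == 2
        assert result.converged

    def test_zero_params_equal_plain_maf_threshold(self):
        rng = np.random.default_rng(12)
        from conftest import random_variant_map

        vmap, _ = random_variant_map(rng)
        cands = sv.extract_candidates(vmap, 0.05, 0.0)
        result = sv.converge(cands, sv.ParameterSet.zeros(0.05))
        expected = {c.key for c in cands if c.abundance >= 0.05}
        assert result.keys() == expected

    def test_retained_counts_non_increasing_and_terminates(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            cands = []
            n = int(rng.integers(0, 40))
            for i in range(n):
                depth = int(rng.integers(50, 300))
                count = int(rng.integers(3, max(4, depth // 4)))
                c = cand("g", int(rng.integers(0, 500)),
                         alt="ACGT"[int(rng.integers(4))], ref="N",
                         count=count, depth=depth,
                         novel=bool(rng.integers(2)))
                cands.append(c)
            params = sv.ParameterSet(
                maf=0.05, cor=float(rng.uniform(0, 1)),
                ii=float(rng.uniform(0, 0.3)), pp=float(rng.uniform(0, 0.5)),
                np=float(rng.uniform(0, 4)), dp=float(rng.uniform(0, 0.5)))
            result = sv.converge(cands, params, max_iter=100)
            counts = [s.retained_count for s in result.trace]
            assert all(a >= b for a, b in zip(counts, counts[1:]))
            assert result.iterations_run <= 100
            for v in result.final_variants:
                assert v.abundance >= result.final_thresholds[v.key]

    def test_scale_invariance_of_final_calls(self, small_db, dual_strains):
        """Doubling every pileup count leaves the final call set unchanged."""
        mix = sv.MixSpec(list(dual_strains), [0.94, 0.06], depth=150, seed=23)
        sample = sv.simulate_sample(mix, small_db, sv.ErrorModel())
        top = sv.select_top_allele(sample.alignments, small_db)
        vmap = sv.build_variant_map(sample.alignments, top, small_db)
        params = sv.lookup(0.05, "clean")
        params = sv.ParameterSet(maf=0.05, **{k: v for k, v in params.as_dict().items()
                                              if k != "maf"})

        def run(vm):
            # min_count=1 keeps the candidate universe fixed: the invariance
            # is abundance-space only, and doubling counts would otherwise
            # promote sub-floor cells into new candidates
            cands = sv.extract_candidates(vm, 0.05, params.cor, min_count=1)
            tl = {gp.gene_id: len(gp.template_seq) for gp in vm}
            sv.annotate_novelty(cands, small_db, tl)
            index = CooccurrenceIndex.build(cands, sample.alignments)
            return sv.converge(cands, params, index=index).keys()

        first = run(vmap)
        for gp in vmap:
            gp.counts *= 2
        assert run(vmap) == first
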