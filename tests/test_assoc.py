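"""Rank statistics, presence/absence contrast, and the local aligner."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from rhizoepc import assoc, synth
from rhizoepc._dna import mutate, random_dna, seq_to_array


def naive_H(values, labels):
    """Independent tie-corrected H (direct rank-sum formula)."""
    ranks = ss.rankdata(values)
    n = len(values)
    groups = {}
    for r, l in zip(ranks, labels):
        groups.setdefault(l, []).append(r)
    h = 12 / (n * (n + 1)) * sum(sum(g) ** 2 / len(g)
                                 for g in groups.values()) - 3 * (n + 1)
    _, c = np.unique(values, return_counts=True)
    tie = 1 - (c ** 3 - c).sum() / (n ** 3 - n)
    return h / tie if tie else 0.0


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = assoc.kruskal_wallis([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_tied(self):
        h, p = assoc.kruskal_wallis([5, 5, 5, 5], list("aabb"))
        assert (h, p) == (0.0, 1.0)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            assoc.kruskal_wallis([1, 2, 3], list("aaa"))

    @pytest.mark.parametrize("seed,sizes", [(0, (3, 3)), (1, (2, 3, 3)),
                                            (2, (4, 4)), (3, (2, 2, 2, 2))])
    def test_matches_scipy(self, seed, sizes):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=sum(sizes))
        labels = np.repeat(np.arange(len(sizes)), sizes)
        h, p = assoc.kruskal_wallis(values, labels)
        parts = np.split(values, np.cumsum(sizes)[:-1])
        h2, p2 = ss.kruskal(*parts)
        assert h == pytest.approx(h2)
        assert p == pytest.approx(p2)

    @pytest.mark.parametrize("seed,sizes,with_ties", [
        (4, (3, 3), False), (5, (2, 3, 3), False),
        (6, (4, 4), True), (7, (2, 2, 3), True)])
    def test_exact_matches_enumeration_oracle(self, seed, sizes, with_ties):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        values = rng.integers(0, 4 if with_ties else 1000, size=n).astype(float)
        labels = np.repeat([f"g{i}" for i in range(len(sizes))], sizes)
        h, p = assoc.kruskal_wallis(values, labels, method="exact")
        # independent oracle: iterate every distinct label permutation
        perms = set(itertools.permutations(labels))
        hs = [naive_H(values, perm) for perm in perms]
        p_oracle = np.mean([x >= h - 1e-12 for x in hs])
        assert h == pytest.approx(naive_H(values, labels))
        assert p == pytest.approx(p_oracle)


class TestDunnPosthoc:
    def test_identical_groups_share_letter(self):
        padj, _, letters = assoc.dunn_posthoc([1, 2, 3] * 3,
                                              list("aaabbbccc"))
        assert set(letters.values()) == {"a"}
        assert np.nanmin(padj.to_numpy()) == pytest.approx(1.0)

    def test_hand_example(self):
        """3 groups x 3 obs, no ties: z12 = (2-8)/sqrt(7.5*2/3) = -2.683."""
        values = [1, 2, 3, 10, 11, 12, 4, 5, 6]
        labels = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        padj, z, letters = assoc.dunn_posthoc(values, labels)
        assert z.loc["g1", "g2"] == pytest.approx(-6 / np.sqrt(7.5 * 2 / 3))
        praw = 2 * ss.norm.sf(abs(z.loc["g1", "g2"]))
        assert padj.loc["g1", "g2"] == pytest.approx(min(1.0, praw * 3))
        assert letters["g2"] == "a" and letters["g1"] == "b"
        assert set(letters["g3"]) == {"a", "b"}

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=12)
        labels = list("aaaabbbbcccc")
        padj, z, _ = assoc.dunn_posthoc(values, labels)
        for i, j in itertools.combinations("abc", 2):
            praw = 2 * ss.norm.sf(abs(z.loc[i, j]))
            assert padj.loc[i, j] >= praw - 1e-12

    def test_letters_consistent_with_decisions(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 6), rng.normal(8, 1, 6),
                                 rng.normal(16, 1, 6)])
        labels = ["lo"] * 6 + ["mid"] * 6 + ["hi"] * 6
        padj, _, letters = assoc.dunn_posthoc(values, labels)
        for i, j in itertools.combinations(sorted(set(labels)), 2):
            share = bool(set(letters[i]) & set(letters[j]))
            assert share == (padj.loc[i, j] >= 0.05)


class TestPoolSpecies:
    def test_counts_stack_per_cultivar(self):
        epc_mean = pd.DataFrame(np.arange(26).reshape(13, 2, order="F"),
                                index=[f"s{i}" for i in range(13)],
                                columns=["cvA", "cvB"], dtype=float)
        pooled = assoc.pool_species(epc_mean, {"cvA": "pea", "cvB": "pea"})
        assert (pooled["species"] == "pea").all()
        assert len(pooled) == 26

    def test_single_cultivar_identity(self):
        epc_mean = pd.DataFrame({"cvA": [1.0, 2.0]}, index=["s1", "s2"])
        pooled = assoc.pool_species(epc_mean, {"cvA": "pea"})
        assert pooled["epc"].tolist() == [1.0, 2.0]

    def test_pooled_median_matches_stacked_vector(self):
        rng = np.random.default_rng(3)
        epc_mean = pd.DataFrame(rng.uniform(0, 30, (6, 3)),
                                index=[f"s{i}" for i in range(6)],
                                columns=["c1", "c2", "c3"])
        mapping = {"c1": "pea", "c2": "pea", "c3": "lentil"}
        pooled = assoc.pool_species(epc_mean, mapping)
        pea = pooled.loc[pooled.species == "pea", "epc"]
        assert pea.median() == pytest.approx(
            np.median(epc_mean[["c1", "c2"]].to_numpy().ravel()))

    def test_unmapped_cultivar_errors(self):
        epc_mean = pd.DataFrame({"cvA": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="unmapped"):
            assoc.pool_species(epc_mean, {})


class TestRankStrains:
    def test_descending_with_ties_stable(self):
        epc_mean = pd.DataFrame({"H": [5.0, 9.0, 5.0, 1.0]},
                                index=["sB", "sA", "sC", "sD"])
        totals = pd.Series({"sB": 10, "sA": 50, "sC": 30, "sD": 5})
        assert assoc.rank_strains(epc_mean, "H", totals) == \
            ["sA", "sC", "sB", "sD"]
        # without totals ties fall back to label order
        assert assoc.rank_strains(epc_mean, "H") == ["sA", "sB", "sC", "sD"]

    def test_unknown_host_errors(self):
        with pytest.raises(KeyError):
            assoc.rank_strains(pd.DataFrame({"H": [1.0]}, index=["s"]), "X")


class TestContrastGenes:
    @staticmethod
    def _matrix(strains, carriers_by_gene):
        return pd.DataFrame({g: [s in c for s in strains]
                             for g, c in carriers_by_gene.items()},
                            index=strains)

    def test_constant_gene_never_candidate(self):
        strains = [f"s{i}" for i in range(10)]
        mat = self._matrix(strains, {"core": strains, "none": []})
        assert assoc.contrast_genes(strains, mat) == []

    def test_planted_gene_directions(self):
        strains = [f"s{i}" for i in range(12)]
        mat = self._matrix(strains, {"up": strains[:5], "down": strains[-5:],
                                     "noise": strains[3:8]})
        cands = assoc.contrast_genes(strains, mat, host="H")
        by_gene = {c.gene_id: c.direction for c in cands}
        assert by_gene == {"up": "present_in_top", "down": "absent_in_top"}

    def test_restricted_comparison(self):
        strains = [f"s{i}" for i in range(12)]
        subset = strains[2:10]
        mat = self._matrix(strains, {"g": subset[:4]})
        cands = assoc.contrast_genes(subset, mat, k_top=4, k_bottom=4)
        assert [c.gene_id for c in cands] == ["g"]
        assert cands[0].top_set == subset[:4]

    def test_k_too_large_errors(self):
        strains = [f"s{i}" for i in range(6)]
        mat = self._matrix(strains, {"g": strains[:3]})
        with pytest.raises(ValueError, match="exceeds"):
            assoc.contrast_genes(strains, mat, k_top=4, k_bottom=4)

    def test_overlapping_sets_error(self):
        strains = ["a", "b", "c", "d", "e", "f", "g", "h", "i", "a"]
        mat = self._matrix(sorted(set(strains)), {"g": ["a"]})
        with pytest.raises(ValueError, match="overlap"):
            assoc.contrast_genes(strains, mat)


class TestValidateCandidates:
    def test_planted_gene_significant(self):
        rng = np.random.default_rng(4)
        strains = [f"s{i}" for i in range(26)]
        carriers = strains[:13]
        epc_mean = pd.DataFrame(
            {"H": np.where([s in carriers for s in strains],
                           rng.uniform(8, 12, 26), rng.uniform(0, 1, 26))},
            index=strains)
        mat = pd.DataFrame({"g": [s in carriers for s in strains]},
                           index=strains)
        cand = assoc.ContrastCandidate("g", "H", "present_in_top")
        (res,) = assoc.validate_candidates([cand], epc_mean, mat)
        assert res.p < 0.05
        assert cand.validation_p == res.p

    def test_fixed_gene_flagged(self):
        strains = ["s1", "s2", "s3"]
        epc_mean = pd.DataFrame({"H": [1.0, 2.0, 3.0]}, index=strains)
        mat = pd.DataFrame({"g": [True, True, True]}, index=strains)
        (res,) = assoc.validate_candidates(
            [assoc.ContrastCandidate("g", "H", "present_in_top")],
            epc_mean, mat)
        assert np.isnan(res.p) and "undefined" in res.note

    def test_single_noncarrier_warns_but_runs(self):
        rng = np.random.default_rng(5)
        strains = [f"s{i}" for i in range(26)]
        epc_mean = pd.DataFrame({"H": rng.uniform(0, 10, 26)}, index=strains)
        mat = pd.DataFrame({"g": [s != "s0" for s in strains]}, index=strains)
        with pytest.warns(UserWarning, match="single"):
            (res,) = assoc.validate_candidates(
                [assoc.ContrastCandidate("g", "H", "present_in_top")],
                epc_mean, mat)
        assert res.n == {"carrier": 25, "noncarrier": 1}


def brute_force_best_segment(query, subject):
    """Oracle: best ungapped segment over all diagonals (exhaustive
    Kadane), scored +1 match / -2 mismatch."""
    q, s = seq_to_array(query), seq_to_array(subject)
    best = None
    for d in range(-(len(q) - 1), len(s)):
        q0, s0 = max(0, -d), max(0, d)
        span = min(len(q) - q0, len(s) - s0)
        if span <= 0:
            continue
        sc = np.where(q[q0:q0 + span] == s[s0:s0 + span], 1, -2)
        cur, cur_start, top = 0, 0, (-1, 0, 0)
        for i, v in enumerate(sc):
            if cur <= 0:
                cur, cur_start = int(v), i
            else:
                cur += int(v)
            if cur > top[0]:
                top = (cur, cur_start, i + 1)
        score, a, b = top
        if score <= 0:
            continue
        matches = int((q[q0 + a:q0 + b] == s[s0 + a:s0 + b]).sum())
        cand = (score, matches / (b - a), (b - a) / len(q))
        if best is None or cand[0] > best[0]:
            best = cand
    return best


class TestLocalAlign:
    def test_self_alignment(self):
        seq = random_dna(np.random.default_rng(6), 40)
        hit = assoc.local_align(seq, seq)
        assert hit.identity == 1.0 and hit.coverage == 1.0
        assert hit.score == len(seq)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            assoc.local_align("", "ACGT" * 10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        """Query embedded at 10% substitutions: identity ~0.9, coverage
        ~1.0, and score/identity/coverage equal the exhaustive oracle."""
        rng = np.random.default_rng(seed)
        gene = random_dna(rng, 150)
        subject = (random_dna(rng, 25) + mutate(gene, 0.10, rng)
                   + random_dna(rng, 25))
        hit = assoc.local_align(gene, subject)
        score, identity, coverage = brute_force_best_segment(gene, subject)
        assert hit.score == score
        assert hit.identity == pytest.approx(identity)
        assert hit.coverage == pytest.approx(coverage)
        assert 0.82 <= hit.identity <= 0.98
        assert hit.coverage > 0.9

    def test_unrelated_sequences_below_thresholds(self):
        rng = np.random.default_rng(7)
        assert not assoc.check_presence(random_dna(rng, 1000),
                                        random_dna(rng, 1000))


class TestCheckPresence:
    def test_identical_gene_present(self):
        rng = np.random.default_rng(8)
        gene = random_dna(rng, 200)
        genome = random_dna(rng, 400) + gene + random_dna(rng, 400)
        assert assoc.check_presence(gene, genome)

    def test_sixty_percent_decoy_absent(self):
        rng = np.random.default_rng(9)
        gene = random_dna(rng, 300)
        genome = random_dna(rng, 300) + mutate(gene, 0.4, rng) \
            + random_dna(rng, 300)
        assert not assoc.check_presence(gene, genome)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(10)
        gene = random_dna(rng, 200)
        genome = random_dna(rng, 100) + mutate(gene, 0.2, rng) \
            + random_dna(rng, 100)
        grid = [0.5, 0.7, 0.9, 0.99]
        for i_lo, i_hi in itertools.combinations(grid, 2):
            for c_lo, c_hi in itertools.combinations(grid, 2):
                if assoc.check_presence(gene, genome, i_hi, c_hi):
                    assert assoc.check_presence(gene, genome, i_lo, c_lo)

    def test_reproduces_pangenome_truth(self, small_panel):
        pg = synth.simulate_pangenome(small_panel, n_genes=5, n_planted=2,
                                      seed=11)
        matrix = assoc.presence_matrix_from_genomes(pg.gene_sequences,
                                                    pg.genomes)
        called = matrix.matrix.loc[pg.presence.index, pg.presence.columns]
        assert called.equals(pg.presence)


class TestBidirectionalBestHits:
    def test_identical_sets_perfect_pairing(self):
        rng = np.random.default_rng(12)
        genes = {f"g{i}": random_dna(rng, 120) for i in range(4)}
        pairs = assoc.bidirectional_best_hits(genes, genes)
        assert pairs == [(g, g) for g in sorted(genes)]

    def test_orphan_unpaired(self):
        rng = np.random.default_rng(13)
        shared = {f"g{i}": random_dna(rng, 120) for i in range(3)}
        a = dict(shared, orphan=random_dna(rng, 120))
        b = {k: mutate(v, 0.05, rng) for k, v in shared.items()}
        pairs = assoc.bidirectional_best_hits(a, b)
        assert ("orphan" not in dict(pairs)) and len(pairs) == 3

    def test_symmetry_and_exhaustive_oracle(self):
        rng = np.random.default_rng(14)
        ancestors = [random_dna(rng, 150) for _ in range(4)]
        a = {f"a{i}": mutate(anc, 0.03, rng)
             for i, anc in enumerate(ancestors)}
        b = {f"b{i}": mutate(anc, 0.03, rng)
             for i, anc in enumerate(rng.permutation(ancestors))}
        pairs = assoc.bidirectional_best_hits(a, b)
        swapped = assoc.bidirectional_best_hits(b, a)
        assert sorted((y, x) for x, y in pairs) == swapped

        # exhaustive all-vs-all oracle
        def score(x, y):
            hit = assoc.local_align(x, y)
            return hit.score if hit else -1

        oracle = []
        for an, aseq in a.items():
            best_b = min(sorted(b), key=lambda bn: (-score(aseq, b[bn]), bn))
            back = min(sorted(a), key=lambda an2: (-score(b[best_b], a[an2]),
                                                   an2))
            if back == an:
                oracle.append((an, best_b))
        assert pairs == sorted(oracle)
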