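"""lincRNA identification, locus clustering and positional statistics."""

import numpy as np
import pytest

import layerizer as lz
from layerizer.lincrna import (
    Locus,
    orf_fraction,
    read_gtf,
    write_gtf,
)


def _tx(tid, gene, chrom, exons, strand="+", biotype="unknown", label="noncoding"):
    return lz.TranscriptModel(transcript_id=tid, gene_id=gene, chrom=chrom,
                              strand=strand, exons=list(exons), biotype=biotype,
                              coding_label=label)


def _coding(tid, gene, chrom, exons, strand="+"):
    return _tx(tid, gene, chrom, exons, strand, biotype="protein_coding",
               label="coding")


class TestTerritoryExpansion:
    def test_one_base_exonic_overlap_expands(self):
        gene = _coding("t1", "gA", "chr1", [(1000, 1200), (1500, 1700)])
        novel = _tx("t2", "novel", "chr1", [(1199, 1300), (2500, 2600)])
        terr = lz.expand_coding_genes([gene, novel], {"gA"})
        assert terr["gA"] == ("chr1", 1000, 2600)

    def test_intron_only_overlap_does_not_expand(self):
        gene = _coding("t1", "gA", "chr1", [(1000, 1200), (1500, 1700)])
        novel = _tx("t2", "novel", "chr1", [(1250, 1300), (1350, 1400)])
        terr = lz.expand_coding_genes([gene, novel], {"gA"})
        assert terr["gA"] == ("chr1", 1000, 1700)

    def test_no_novel_transcripts_territory_is_span(self):
        gene = _coding("t1", "gA", "chr1", [(1000, 1200), (1500, 1700)])
        terr = lz.expand_coding_genes([gene], {"gA"})
        assert terr["gA"] == ("chr1", 1000, 1700)


class TestCandidateIdentification:
    def toy_set(self):
        """Ten transcripts exercising every filter; the retained set below is
        derived by hand from the rules."""
        coding = _coding("c1", "gA", "chr1", [(1000, 1200), (1500, 1700)])
        txs = [
            coding,
            _tx("mono", "n1", "chr1", [(5000, 5400)]),                       # monoexonic
            _tx("short", "n2", "chr1", [(6000, 6100), (6200, 6290)]),        # 190 bp
            _tx("boundary", "n3", "chr1", [(7000, 7100), (7200, 7300)]),     # exactly 200 bp
            _tx("good1", "n4", "chr1", [(8000, 8150), (8300, 8400)]),        # 250 bp, keep
            _tx("in_territory", "n5", "chr1", [(1100, 1250), (1400, 1460)]), # hits gA exon
            _tx("coding_like", "n6", "chr1", [(9000, 9200), (9300, 9500)],
                label="coding"),
            _tx("unlabeled", "n7", "chr1", [(11000, 11200), (11300, 11500)],
                label="unset"),
            _tx("good2", "n8", "chr2", [(100, 300), (400, 600)], strand="-"),
            _tx("near_territory", "n9", "chr1", [(1800, 1950), (2100, 2250)]),
        ]
        return txs

    def test_toy_retained_set_matches_hand_derivation(self):
        txs = self.toy_set()
        terr = lz.expand_coding_genes(txs, {"gA"})
        kept = lz.identify_lincrna_candidates(txs, terr, {"gA"})
        assert {t.transcript_id for t in kept} == {"good1", "good2", "near_territory"}

    def test_length_threshold_is_strict(self):
        txs = self.toy_set()
        terr = lz.expand_coding_genes(txs, {"gA"})
        kept = {t.transcript_id for t in lz.identify_lincrna_candidates(txs, terr, {"gA"})}
        assert "boundary" not in kept  # exactly 200 bp is not "longer than"


class TestLocusClustering:
    def test_transitive_closure(self):
        a = _tx("a", "a", "chr1", [(100, 200), (900, 1000)])
        b = _tx("b", "b", "chr1", [(950, 1050), (1900, 2000)])
        c = _tx("c", "c", "chr1", [(1950, 2050), (2900, 3000)])
        loci = lz.cluster_loci([a, b, c])
        assert len(loci) == 1
        assert set(loci[0].member_ids) == {"a", "b", "c"}

    def test_opposite_strands_cluster(self):
        a = _tx("a", "a", "chr1", [(100, 200), (400, 500)], strand="+")
        b = _tx("b", "b", "chr1", [(450, 550), (700, 800)], strand="-")
        assert len(lz.cluster_loci([a, b])) == 1

    def test_intronic_overlap_clusters(self):
        """Sharing only an intronic base still merges loci (span overlap)."""
        a = _tx("a", "a", "chr1", [(100, 200), (900, 1000)])
        b = _tx("b", "b", "chr1", [(400, 500), (600, 700)])  # inside a's intron
        assert len(lz.cluster_loci([a, b])) == 1

    def test_touching_spans_stay_separate(self):
        a = _tx("a", "a", "chr1", [(100, 200), (400, 500)])
        b = _tx("b", "b", "chr1", [(500, 600), (700, 800)])  # half-open: no shared base
        assert len(lz.cluster_loci([a, b])) == 2

    def test_matches_quadratic_union_find_on_random_transcripts(self):
        rng = np.random.default_rng(6)
        txs = []
        for i in range(200):
            chrom = f"chr{1 + int(rng.integers(2))}"
            start = int(rng.integers(0, 50_000))
            e1 = (start, start + int(rng.integers(50, 500)))
            gap = int(rng.integers(50, 2_000))
            e2 = (e1[1] + gap, e1[1] + gap + int(rng.integers(50, 500)))
            txs.append(_tx(f"t{i:03d}", f"t{i:03d}", chrom, [e1, e2],
                           strand="+-"[int(rng.integers(2))]))
        loci = lz.cluster_loci(txs)
        # quadratic oracle: union-find over all overlapping span pairs
        parent = {t.transcript_id: t.transcript_id for t in txs}
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for i, t1 in enumerate(txs):
            for t2 in txs[i + 1:]:
                if t1.chrom != t2.chrom:
                    continue
                if t1.span[0] < t2.span[1] and t2.span[0] < t1.span[1]:
                    parent[find(t1.transcript_id)] = find(t2.transcript_id)
        oracle = {}
        for t in txs:
            oracle.setdefault(find(t.transcript_id), set()).add(t.transcript_id)
        assert sorted(map(sorted, (set(l.member_ids) for l in loci))) == \
            sorted(map(sorted, oracle.values()))

    def test_reclustering_is_idempotent(self):
        a = _tx("a", "a", "chr1", [(100, 200), (900, 1000)])
        b = _tx("b", "b", "chr1", [(950, 1050), (1900, 2000)])
        first = lz.cluster_loci([a, b])
        second = lz.cluster_loci([a, b])
        assert first == second

    def test_every_candidate_in_exactly_one_locus(self, small_atlas):
        coding = {t.gene_id for t in small_atlas.transcripts
                  if t.biotype == "protein_coding"}
        terr = lz.expand_coding_genes(small_atlas.transcripts, coding)
        cands = lz.identify_lincrna_candidates(small_atlas.transcripts, terr, coding)
        loci = lz.cluster_loci(cands)
        members = [m for l in loci for m in l.member_ids]
        assert sorted(members) == sorted(t.transcript_id for t in cands)


class TestGTFRoundTrip:
    def test_coordinates_preserved(self, small_atlas, tmp_path):
        path = tmp_path / "t.gtf"
        write_gtf(path, small_atlas.transcripts)
        back = read_gtf(path)
        orig = {t.transcript_id: t for t in small_atlas.transcripts}
        assert set(orig) == {t.transcript_id for t in back}
        for t in back:
            assert t.exons == orig[t.transcript_id].exons
            assert t.strand == orig[t.transcript_id].strand
            assert t.biotype == orig[t.transcript_id].biotype


class TestAdjacencyEnrichment:
    def _layout(self, rng, n_genes=60, n_loci=20, beside_patterned=None):
        positions = {}
        loci = []
        patterned = set()
        pos = 1000
        for i in range(n_genes):
            gid = f"g{i:03d}"
            positions[gid] = ("chr1", pos, pos + 500)
            is_pat = i % 3 == 0
            if is_pat:
                patterned.add(gid)
            if beside_patterned is not None and len(loci) < n_loci:
                if is_pat == beside_patterned:
                    loci.append(Locus(locus_id=f"l{len(loci)}", member_ids=(),
                                      chrom="chr1", span=(pos + 600, pos + 800)))
            pos += 5000
        if beside_patterned is None:
            starts = rng.choice(n_genes, size=n_loci, replace=False)
            for k, i in enumerate(sorted(starts)):
                base = 1000 + i * 5000
                loci.append(Locus(locus_id=f"l{k}", member_ids=(), chrom="chr1",
                                  span=(base + 600, base + 800)))
        return positions, loci, patterned

    def test_random_labels_fold_near_one(self):
        rng = np.random.default_rng(3)
        positions, loci, _pat = self._layout(rng, n_genes=600, n_loci=150)
        patterned = {g for g in positions if rng.random() < 1 / 3}
        fold, p = lz.adjacency_enrichment(patterned, positions, loci,
                                          n_perm=2000, seed=4)
        assert abs(fold - 1.0) < 0.1

    def test_loci_planted_beside_patterned_genes(self):
        rng = np.random.default_rng(3)
        positions, loci, patterned = self._layout(rng, beside_patterned=True)
        fold, p = lz.adjacency_enrichment(patterned, positions, loci,
                                          n_perm=2000, seed=4)
        assert fold > 1.3
        assert p < 0.01

    def test_p_respects_estimator_floor(self):
        rng = np.random.default_rng(3)
        positions, loci, patterned = self._layout(rng, beside_patterned=True)
        _fold, p = lz.adjacency_enrichment(patterned, positions, loci,
                                           n_perm=200, seed=4)
        assert p >= 1 / 201

    def test_too_few_patterned_errors(self):
        rng = np.random.default_rng(3)
        positions, loci, _pat = self._layout(rng)
        with pytest.raises(ValueError):
            lz.adjacency_enrichment({"g000"}, positions, loci)


class TestNeighborCorrelation:
    def test_proportional_profiles_have_unit_rho(self):
        from scipy import stats

        a = np.array([1, 2, 3, 4, 5, 6, 7.0])
        assert abs(stats.spearmanr(a, 2 * a).statistic) == pytest.approx(1.0)
        stat, p = lz.neighbor_correlation_test(
            [(a, 2 * a)] * 3, [(a, np.array([2, 1, 4, 3, 6, 5, 7.0]))] * 3)
        assert np.isfinite(stat)

    def test_power_on_coexpressed_patterned_pairs(self):
        rng = np.random.default_rng(12)
        pat, unpat = [], []
        for _ in range(50):
            shared = rng.normal(0, 1, 7)
            pat.append((shared + rng.normal(0, 0.3, 7),
                        shared + rng.normal(0, 0.3, 7)))
            unpat.append((rng.normal(0, 1, 7), rng.normal(0, 1, 7)))
        _stat, p = lz.neighbor_correlation_test(pat, unpat)
        assert p < 0.05

    def test_null_p_uniform_over_replicates(self):
        from scipy import stats

        rng = np.random.default_rng(14)
        ps = []
        for _ in range(200):
            g1 = [(rng.normal(0, 1, 7), rng.normal(0, 1, 7)) for _ in range(10)]
            g2 = [(rng.normal(0, 1, 7), rng.normal(0, 1, 7)) for _ in range(10)]
            ps.append(lz.neighbor_correlation_test(g1, g2)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_pairs_errors(self):
        a = np.arange(7.0)
        with pytest.raises(ValueError):
            lz.neighbor_correlation_test([(a, a)] * 2, [(a, a)] * 5)


class TestIntervalOverlap:
    def test_saturating_features_give_fold_one(self):
        sizes = {"chr1": 10_000}
        queries = [("chr1", i * 500, i * 500 + 100) for i in range(10)]
        features = [("chr1", 0, 10_000)]
        fold, _p = lz.interval_overlap_enrichment(queries, features, sizes,
                                                  n_shuffles=200, seed=1)
        assert fold == 1.0

    def test_planted_queries_in_sparse_features(self):
        sizes = {"chr1": 1_000_000}
        features = [("chr1", 100_000 + i * 1_000, 100_200 + i * 1_000)
                    for i in range(30)]
        queries = [("chr1", 100_050 + i * 1_000, 100_150 + i * 1_000)
                   for i in range(30)]
        fold, p = lz.interval_overlap_enrichment(queries, features, sizes,
                                                 n_shuffles=500, seed=2)
        assert fold > 5
        assert p == pytest.approx(1 / 501)

    def test_interval_longer_than_chromosome_errors(self):
        with pytest.raises(ValueError):
            lz.interval_overlap_enrichment([("chr1", 0, 2_000)], [], {"chr1": 1_000})

    def test_label_swap_symmetry_on_dense_fixture(self):
        rng = np.random.default_rng(9)
        sizes = {"chr1": 100_000}
        qs = [("chr1", int(s), int(s) + 200)
              for s in rng.integers(0, 99_800, size=60)]
        fs = [("chr1", int(s), int(s) + 200)
              for s in rng.integers(0, 99_800, size=60)]
        f1, _ = lz.interval_overlap_enrichment(qs, fs, sizes, n_shuffles=400, seed=3)
        f2, _ = lz.interval_overlap_enrichment(fs, qs, sizes, n_shuffles=400, seed=4)
        assert abs(f1 - f2) / max(f1, f2) < 0.2


class TestORFHeuristic:
    def test_no_start_codon_fraction_zero(self):
        assert orf_fraction("CCCCCCCCCCCC") == 0.0

    def test_known_orf(self):
        seq = "AAAATGAAACCCTAGAAAA"  # ORF: ATG AAA CCC TAG = 12 bases
        assert orf_fraction(seq) == pytest.approx(12 / len(seq))
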