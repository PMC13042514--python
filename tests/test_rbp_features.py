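"""RBP-binding-context feature encoding and its brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import exonic_bases_5to3, random_transcript
from reading_m6a.annotation import GenomicInterval, TranscriptModel, Transcriptome
from reading_m6a.m6a_sites import M6ASite
from reading_m6a.readouts import ExonEvent
from reading_m6a.rbp_features import (
    RBPBindingSite,
    RBPTrack,
    assemble_features,
    drach_vocabulary,
    feature_sets,
    kmer_features,
    m6a_rbp_distance_summary,
    nearest_rbp,
    variability_metrics,
)


def _track(rbp, triples, chrom="chr1", strand="+"):
    return RBPTrack(rbp, [
        RBPBindingSite(rbp, GenomicInterval(chrom, s, e, strand), sc)
        for s, e, sc in triples
    ])


def brute_nearest_genome(triples, pos):
    """Enumerate every covered base of every interval."""
    best = None
    for s, e, sc in triples:
        d = min(abs(pos - b) for b in range(s, e))
        if best is None or (d, -sc, s) < best[:3]:
            best = (d, -sc, s, sc)
    return (math.nan, math.nan) if best is None else (best[0], best[3])


class TestNearestRbp:
    def test_worked_example(self):
        track = _track("X", [(950, 960, 5.0), (1100, 1110, 8.0)])
        anchor = M6ASite("chr1", 1000, "+")
        d, sc = nearest_rbp(track, anchor, "genome")
        assert (d, sc) == (41.0, 5.0)  # nearest covered bases 959 and 1100

    def test_anchor_inside_site(self):
        track = _track("X", [(990, 1010, 3.0)])
        assert nearest_rbp(track, M6ASite("chr1", 1000, "+"), "genome") == (0.0, 3.0)

    def test_empty_track_missing_sentinel(self):
        d, sc = nearest_rbp(_track("X", []), M6ASite("chr1", 1000, "+"), "genome")
        assert math.isnan(d) and math.isnan(sc)

    def test_matches_brute_force_genome_space(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            triples = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                triples.append((s, s + int(rng.integers(1, 30)),
                                float(rng.integers(0, 100))))
            track = _track("X", triples)
            pos = int(rng.integers(0, 5200))
            got = nearest_rbp(track, M6ASite("chr1", pos, "+"), "genome")
            expected = brute_nearest_genome(triples, pos)
            assert got[0] == expected[0]
            # score must belong to some site at the winning distance
            at_min = {sc for s, e, sc in triples
                      if min(abs(pos - b) for b in range(s, e)) == got[0]}
            assert got[1] in at_min

    def test_matches_brute_force_transcript_space(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 100:
            tx = random_transcript(rng, max_exons=6, max_len=2000, coding=False)
            txome = Transcriptome({tx.transcript_id: tx})
            bases = exonic_bases_5to3(tx)
            tindex = {b: i for i, b in enumerate(bases)}
            lo, hi = tx.exons[0].start, tx.exons[-1].end
            triples = []
            for _ in range(int(rng.integers(1, 30))):
                s = int(rng.integers(max(0, lo - 200), hi + 200))
                triples.append((s, s + int(rng.integers(1, 40)),
                                float(rng.integers(0, 100))))
            track = _track("X", triples, strand=tx.strand)
            anchor_g = bases[int(rng.integers(len(bases)))]
            anchor = M6ASite(tx.chrom, anchor_g, tx.strand, gene_ids=(tx.gene_id,))
            got_d, _ = nearest_rbp(track, anchor, "transcript", txome)
            # oracle: exonic covered bases mapped through the enumeration index
            t_anchor = tindex[anchor_g]
            best = math.inf
            for s, e, _sc in triples:
                tpos = [tindex[b] for b in range(s, e) if b in tindex]
                if tpos:
                    best = min(best, min(abs(t_anchor - t) for t in tpos))
            expected = math.nan if math.isinf(best) else float(best)
            if math.isnan(expected):
                assert math.isnan(got_d)
            else:
                assert got_d == expected
            checked += 1


class TestDistanceSummary:
    def test_single_site_degenerate(self):
        track = _track("X", [(0, 10, 1.0)])
        sites = [M6ASite("chr1", 100, "+")]
        mn, mx = m6a_rbp_distance_summary(sites, track, "genome")
        assert mn == mx == 91.0

    def test_min_max_over_sites(self):
        track = _track("X", [(0, 10, 1.0)])
        sites = [M6ASite("chr1", 19, "+"), M6ASite("chr1", 509, "+")]
        assert m6a_rbp_distance_summary(sites, track, "genome") == (10.0, 500.0)

    def test_no_rbp_sites_both_missing(self):
        mn, mx = m6a_rbp_distance_summary([M6ASite("chr1", 5, "+")],
                                          _track("X", []), "genome")
        assert math.isnan(mn) and math.isnan(mx)


class TestKmerFeatures:
    def test_overlapping_count(self):
        out = kmer_features("GGACTGGACT", [7], ["GGACT"], flank=100)
        d, c = out["GGACT"]
        assert c == 2.0      # occurrence starts 0 and 5
        assert d == 2.0      # |7 - 5|

    def test_absent_kmer_missing_distance(self):
        d, c = kmer_features("AAAA", [0], ["GGACT"])["GGACT"]
        assert math.isnan(d) and c == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        vocab = drach_vocabulary()[:6]
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 400))))
            sites = sorted(rng.choice(len(seq), size=int(rng.integers(1, 4)),
                                      replace=False).tolist())
            out = kmer_features(seq, sites, vocab, flank=25)
            for km in vocab:
                occs = [i for i in range(len(seq) - 4) if seq[i:i + 5] == km]
                if not occs:
                    assert math.isnan(out[km][0]) and out[km][1] == 0.0
                    continue
                exp_d = min(abs(t - o) for t in sites for o in occs)
                exp_c = max(sum(t - 25 <= o <= t + 25 for o in occs) for t in sites)
                assert out[km] == (float(exp_d), float(exp_c))


class TestAssembly:
    @pytest.fixture()
    def setup(self, small_sim):
        _, data = small_sim
        by_gene = {}
        for s in data["truth"].m6a_sites:
            for g in s.gene_ids:
                by_gene.setdefault(g, []).append(s)
        return data, by_gene

    def test_gene_level_shape_contract(self, setup):
        data, by_gene = setup
        genes = sorted(by_gene)[:10]
        feats = assemble_features(
            genes, by_gene, data["rbp_tracks"][:3], data["txome"],
            data["tx_sequences"], expression=data["expression"],
            dependency=data["dependency"], level="gene")
        rbp_cols = [c for c in feats.columns if c.startswith("rbp:")]
        assert len(rbp_cols) == 3 * 6
        assert any(c.startswith("expression:") for c in feats.columns)
        assert "dependency:score" in feats.columns
        assert len(feats) == len(genes)

    def test_deterministic_byte_identical(self, setup):
        data, by_gene = setup
        genes = sorted(by_gene)[:8]
        kw = dict(m6a_by_gene=by_gene, tracks=data["rbp_tracks"][:3],
                  txome=data["txome"], tx_sequences=data["tx_sequences"],
                  expression=data["expression"], dependency=data["dependency"])
        a = assemble_features(genes, **kw).to_csv()
        b = assemble_features(genes, **kw).to_csv()
        assert a == b

    def test_unknown_gene_in_tables_masked_not_dropped(self, setup):
        data, by_gene = setup
        genes = sorted(by_gene)[:4]
        expr = data["expression"].drop(index=genes[0])
        feats = assemble_features(genes, by_gene, data["rbp_tracks"][:2],
                                  data["txome"], data["tx_sequences"],
                                  expression=expr, dependency=data["dependency"])
        assert genes[0] in feats.index
        assert feats.loc[genes[0]].filter(like="expression:").isna().all()

    def _exon_events(self, data, by_gene, shift=0):
        events = {}
        for g in sorted(by_gene)[:12]:
            tx = data["txome"].rep_transcript(g)
            exon = tx.exons[0]
            iv = GenomicInterval(exon.chrom, exon.start + shift,
                                 exon.end + shift, exon.strand)
            events[f"SE_{g}"] = ExonEvent(f"SE_{g}", g, iv, {}, {}, 2.0, 1.0)
        return events

    def test_exon_level_schema_excludes_gene_only_sets(self, setup):
        data, by_gene = setup
        events = self._exon_events(data, by_gene)
        feats = assemble_features(list(events), by_gene, data["rbp_tracks"][:3],
                                  data["txome"], data["tx_sequences"],
                                  expression=data["expression"],
                                  dependency=data["dependency"],
                                  level="exon", exon_events=events)
        assert len(feats) > 0
        assert not any(c.startswith(("expression:", "dependency:"))
                       for c in feats.columns)
        assert not any(c.endswith(("mind_g", "maxd_g", "mind_t", "maxd_t"))
                       for c in feats.columns)

    def test_exon_beyond_10kb_excluded(self, setup):
        data, by_gene = setup
        g = sorted(by_gene)[0]
        far = GenomicInterval("chr1", 10**7, 10**7 + 100, "+")
        events = {"far": ExonEvent("far", g, far, {}, {}, 2.0, 1.0)}
        feats = assemble_features(["far"], by_gene, data["rbp_tracks"][:2],
                                  data["txome"], data["tx_sequences"],
                                  level="exon", exon_events=events)
        assert len(feats) == 0

    def test_feature_set_partition_covers_all_columns(self, setup):
        data, by_gene = setup
        genes = sorted(by_gene)[:6]
        feats = assemble_features(genes, by_gene, data["rbp_tracks"][:3],
                                  data["txome"], data["tx_sequences"],
                                  expression=data["expression"],
                                  dependency=data["dependency"])
        part = feature_sets(feats.columns)
        assert sorted(c for cols in part.values() for c in cols) == \
               sorted(feats.columns)
        assert len(part) == 11


class TestVariabilityMetrics:
    def test_worked_examples(self):
        out = variability_metrics(
            {"g1": {"a": 100, "b": 100, "c": 100}, "g2": {"a": 50, "b": 150}},
            {"g1": {"a": 1.0, "b": 1.0}})
        assert out.loc["g1", "cv_distance"] == 0.0
        assert out.loc["g2", "cv_distance"] == pytest.approx(np.sqrt(5000) / 100)
        assert out.loc["g1", "sd_log2fc"] == 0.0

    def test_single_cell_type_and_zero_mean_flagged(self):
        out = variability_metrics({"g": {"a": 100}, "h": {"a": 0, "b": 0}}, {})
        assert math.isnan(out.loc["g", "cv_distance"])
        assert math.isnan(out.loc["h", "cv_distance"])
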