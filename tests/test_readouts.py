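"""Half-life, translation-efficiency, and exon-inclusion readouts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import reading_m6a as rm
from reading_m6a import synthetic as syn
from reading_m6a.readouts import (
    CountMatrix,
    ExonEvent,
    NormalizationError,
    SampleInfo,
    bh_fdr,
    classify_halflife,
    classify_splicing,
    compute_psi,
    ercc_normalize,
    fit_decay,
    te_change,
)


def _matrix(values, sample_specs):
    samples = [SampleInfo(*s) for s in sample_specs]
    df = pd.DataFrame(values, columns=[s.sample for s in samples])
    return CountMatrix(df, samples)


def _decay_matrix(gene_rows, ercc_rows, conditions=("shControl",)):
    """One replicate per (condition, time) from literal per-time values."""
    specs, cols = [], {}
    for cond in conditions:
        for t in (0, 3, 6):
            name = f"{cond}_t{t}"
            specs.append((name, cond, float(t), 1))
            cols[name] = [v[cond][t] for v in gene_rows.values()] + \
                         [e[cond][t] for e in ercc_rows.values()]
    df = pd.DataFrame(cols, index=list(gene_rows) + list(ercc_rows))
    return CountMatrix(df, [SampleInfo(*s) for s in specs])


class TestErccNormalize:
    def test_ratio_identity(self):
        # gene 100 over ERCC 10,000 equals gene 200 over ERCC 20,000
        cm = _matrix({}, [("s1", "c", 0.0, 1), ("s2", "c", 0.0, 2)])
        cm.counts = pd.DataFrame({"s1": [100, 10_000], "s2": [200, 20_000]},
                                 index=["g", "ERCC-1"])
        norm = ercc_normalize(cm)
        assert norm.counts.loc["g", "s1"] == norm.counts.loc["g", "s2"] == 0.01

    def test_uniform_scaling_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, size=(30, 2)),
                              index=[f"g{i}" for i in range(28)] + ["ERCC-1", "ERCC-2"],
                              columns=["a", "b"])
        cm = _matrix({}, [("a", "c", 0.0, 1), ("b", "c", 0.0, 2)])
        cm.counts = counts
        scaled = cm.counts.copy()
        scaled["a"] *= 4  # deeper library
        cm2 = _matrix({}, [("a", "c", 0.0, 1), ("b", "c", 0.0, 2)])
        cm2.counts = scaled
        pd.testing.assert_frame_equal(ercc_normalize(cm).counts,
                                      ercc_normalize(cm2).counts)

    def test_zero_ercc_rejected(self):
        cm = _matrix({}, [("a", "c", 0.0, 1)])
        cm.counts = pd.DataFrame({"a": [5, 0]}, index=["g", "ERCC-1"])
        with pytest.raises(NormalizationError):
            ercc_normalize(cm)


class TestFitDecay:
    def test_exact_exponential(self):
        cm = _decay_matrix(
            {"g": {"shControl": {0: 1000, 3: 500, 6: 250}}},
            {"ERCC-1": {"shControl": {0: 100, 3: 100, 6: 100}}})
        norm = ercc_normalize(cm)
        est, _ = fit_decay(norm, "shControl", delta=1.0)
        e = est[0]
        assert e.k3 == pytest.approx(1 / 3)
        assert e.k6 == pytest.approx(1 / 3)
        assert e.k == pytest.approx(1 / 3)
        assert e.half_life == pytest.approx(3.0)

    def test_delta_cancels_ratio(self):
        cm = _decay_matrix(
            {"g": {"shControl": {0: 1000, 3: 500, 6: 250}}},
            {"ERCC-1": {"shControl": {0: 100, 3: 100, 6: 100}}})
        est, _ = fit_decay(ercc_normalize(cm), "shControl", delta=2.0)
        assert est[0].k3 == pytest.approx(0.0)

    def test_negative_k_for_growing_gene(self):
        cm = _decay_matrix(
            {"g": {"shControl": {0: 100, 3: 200, 6: 400}}},
            {"ERCC-1": {"shControl": {0: 100, 3: 100, 6: 100}}})
        est, _ = fit_decay(ercc_normalize(cm), "shControl", delta=1.0)
        assert est[0].k3 == pytest.approx(-1 / 3)
        assert not math.isfinite(est[0].half_life)

    def test_zero_a0_skipped_with_reason(self):
        cm = _decay_matrix(
            {"g": {"shControl": {0: 0, 3: 10, 6: 10}}},
            {"ERCC-1": {"shControl": {0: 100, 3: 100, 6: 100}}})
        est, skipped = fit_decay(ercc_normalize(cm), "shControl")
        assert est == [] and skipped == [("g", "A0=0")]


class TestClassifyHalflife:
    def _est(self, gene, cond, hl):
        from reading_m6a.readouts import DecayEstimate
        k = 1.0 / hl
        return DecayEstimate(gene, cond, k, k, k, hl, 1.0, 1.0)

    @pytest.mark.parametrize("hl_c,hl_k,expected", [
        (2.0, 3.0, "HL_down"),   # ratio 2/3 <= 1/1.5
        (3.0, 3.0, "none"),
        (4.5, 3.0, "HL_up"),     # ratio exactly 1.5, boundary inclusive
    ])
    def test_thresholds(self, hl_c, hl_k, expected):
        calls = classify_halflife([self._est("g", "c", hl_c)],
                                  [self._est("g", "k", hl_k)])
        assert calls[0].category == expected

    def test_infinite_half_life_gets_reason(self):
        calls = classify_halflife([self._est("g", "c", math.inf)],
                                  [self._est("g", "k", 3.0)])
        assert calls[0].category == "none" and calls[0].reason


class TestTeChange:
    def _pair(self, rpf_vals, rna_vals, n_rep=2):
        genes = [f"g{i}" for i in range(len(rpf_vals["shControl"][0]))]
        out = []
        for vals in (rpf_vals, rna_vals):
            specs, cols = [], {}
            for cond, reps in vals.items():
                for r, col in enumerate(reps, 1):
                    name = f"{cond}_r{r}"
                    specs.append((name, cond, 0.0, r))
                    cols[name] = col
            cm = CountMatrix(pd.DataFrame(cols, index=genes),
                             [SampleInfo(*s) for s in specs])
            out.append(cm)
        return out

    def test_identity_no_calls(self):
        reps = [[100, 200, 300]] * 2
        rpf, rna = self._pair({"shControl": reps, "shMETTL3": reps},
                              {"shControl": reps, "shMETTL3": reps})
        res = te_change(rpf, rna)
        assert all(t.log2fc == 0 and t.direction == "none" for t in res)

    def test_uniform_rpf_doubling_is_compositionally_invisible(self):
        base = [[100, 200, 300], [110, 190, 310]]
        doubled = [[2 * v for v in rep] for rep in base]
        rpf, rna = self._pair({"shControl": doubled, "shMETTL3": base},
                              {"shControl": base, "shMETTL3": base})
        res = te_change(rpf, rna)
        for t in res:
            assert t.log2fc == pytest.approx(0.0, abs=1e-12)

    def test_planted_te_power(self):
        # 4x planted TE shifts, 6 replicates, deep counts: near-complete recovery
        genes = [f"G{i:04d}" for i in range(400)]
        cfg = rm.SimulationConfig(seed=13, n_genes=400, te_replicates=6, depth=500.0)
        truth = syn.plant_te_psi_truth(cfg, genes)
        rpf, rna = syn.gen_te_experiment(cfg, truth)
        res = {t.gene_id: t for t in te_change(rpf, rna)}
        planted = [g for g in genes if truth.te_label[g] != "none"]
        hits = sum(res[g].direction == truth.te_label[g] for g in planted)
        assert hits / len(planted) >= 0.95


class TestPsi:
    def test_worked_example(self):
        assert compute_psi(60, 20, 2, 1) == pytest.approx(0.6)

    @pytest.mark.parametrize("i,s,expected", [(5, 0, 1.0), (0, 5, 0.0)])
    def test_boundaries(self, i, s, expected):
        assert compute_psi(i, s, 2, 1) == expected

    def test_undefined_flagged(self):
        with pytest.raises(ValueError):
            compute_psi(0, 0, 2, 1)

    def test_matches_closed_form_on_grid(self):
        for i in range(51):
            for s in range(51):
                if i == s == 0:
                    continue
                for li, ls in ((1.0, 1.0), (2.0, 1.0), (3.5, 2.0)):
                    expected = (i / li) / (i / li + s / ls)
                    assert compute_psi(i, s, li, ls) == pytest.approx(expected, abs=1e-12)


def fisher_two_sided_enumeration(a, b, c, d):
    """Hypergeometric enumeration oracle for the 2x2 two-sided exact test."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, row1, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestClassifySplicing:
    def _events(self, tables, li=2.0, ls=1.0):
        evs = []
        for eid, (ic, sc, ik, sk) in tables.items():
            evs.append(ExonEvent(eid, "g", None,
                                 {"c_r1": ic, "k_r1": ik},
                                 {"c_r1": sc, "k_r1": sk}, li, ls))
        return evs, {"shControl": ["c_r1"], "shMETTL3": ["k_r1"]}

    def test_identity_no_calls(self):
        evs, cond = self._events({"e1": (50, 50, 50, 50), "e2": (30, 10, 30, 10)})
        calls = classify_splicing(evs, cond)
        assert all(c.category == "none" for c in calls)

    def test_strong_shift_called_up(self):
        evs, cond = self._events({"e": (90, 10, 50, 50)}, li=1.0, ls=1.0)
        calls = classify_splicing(evs, cond)
        c = calls[0]
        assert c.effect_size == pytest.approx(0.4)
        assert c.category == "PSI_up"
        assert c.significance < 1e-8

    def test_effect_size_gate_blocks_small_dpsi(self):
        # large counts, tiny delta-Psi, minuscule p: still no call
        evs, cond = self._events({"e": (5200, 4800, 4800, 5200)}, li=1.0, ls=1.0)
        calls = classify_splicing(evs, cond)
        assert abs(calls[0].effect_size) < 0.1
        assert calls[0].significance < 1e-6
        assert calls[0].category == "none"

    def test_fisher_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 50, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            oracle = fisher_two_sided_enumeration(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(oracle, abs=1e-10)


class TestBhFdr:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_monotone_in_input_order_statistics(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q >= p - 1e-15) & (q <= 1.0)).all()
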