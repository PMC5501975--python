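"""Generator determinism, ground-truth bookkeeping and calibration."""

import numpy as np
import pytest
from scipy.special import logit

from mirmeta.seeds import find_seed_sites, site_sequence
from mirmeta.simulate import (
    CohortSimConfig,
    SimConfigError,
    simulate_additive_combination,
    simulate_cohorts,
    simulate_dose_response,
    simulate_utrs,
)

MIR21 = "UAGCUUAUCAGACUGAUGUUGA"


class TestCohortSim:
    def test_invalid_configs_rejected(self):
        with pytest.raises(SimConfigError):
            CohortSimConfig(n_genes=10, n_planted_targets=11)
        with pytest.raises(SimConfigError):
            CohortSimConfig(noise_sd=0.0)
        with pytest.raises(SimConfigError):
            CohortSimConfig(n_tumor=5, n_normal=5, n_matched=6)
        with pytest.raises(SimConfigError):
            CohortSimConfig(frac_decoy_down=1.5)

    def test_determinism(self):
        cfg = CohortSimConfig(name="c", n_genes=40, seed=7, n_tumor=6, n_normal=6,
                              n_matched=4)
        a, ta = simulate_cohorts([cfg])
        b, tb = simulate_cohorts([cfg])
        assert a[0].mrna.equals(b[0].mrna)
        assert a[0].mirna.equals(b[0].mirna)
        assert ta.planted_target_ids == tb.planted_target_ids

    def test_truth_classes_disjoint(self):
        cfg = CohortSimConfig(
            name="c", n_genes=100, n_planted_targets=10, seed=2,
            frac_decoy_down=0.2, frac_decoy_corr=0.2,
        )
        _, truth = simulate_cohorts([cfg])
        assert len(truth.planted_target_ids) == 10
        assert not truth.planted_target_ids & truth.decoy_down_ids
        assert not truth.planted_target_ids & truth.decoy_corr_ids
        assert not truth.decoy_down_ids & truth.decoy_corr_ids

    def test_shared_truth_across_cohorts(self):
        cfgs = [CohortSimConfig(name=f"c{i}", n_genes=60, seed=5 + i) for i in range(2)]
        cohorts, truth = simulate_cohorts(cfgs, shared_truth=True)
        assert list(cohorts[0].mrna.index) == list(cohorts[1].mrna.index)
        assert truth.planted_target_ids <= set(cohorts[0].mrna.index)

    def test_null_model_mean_log2fold_zero(self):
        """With zero shift and slope, gene log2folds average to 0."""
        folds = []
        for seed in range(200):
            cfg = CohortSimConfig(
                name="c", n_genes=5, n_planted_targets=1, n_tumor=5, n_normal=5,
                n_matched=4, mirna_tumor_shift=0.0, target_slope=0.0,
                noise_sd=1.0, seed=seed,
            )
            (cohort,), _ = simulate_cohorts([cfg])
            tum = cohort.mrna[cohort.tumor_samples].mean(axis=1)
            norm = cohort.mrna[cohort.normal_samples].mean(axis=1)
            folds.extend((tum - norm).tolist())
        folds = np.asarray(folds)
        se = folds.std(ddof=1) / np.sqrt(folds.size)
        assert abs(folds.mean()) <= 3 * se

    def test_near_deterministic_coupling(self):
        """Tiny noise: the planted target is almost perfectly
        anticorrelated with the miRNA on matched samples."""
        cfg = CohortSimConfig(
            name="c", n_genes=10, n_planted_targets=1, n_tumor=10, n_normal=10,
            n_matched=10, mirna_tumor_shift=2.0, target_slope=-1.0,
            noise_sd=0.01, frac_decoy_down=0.0, frac_decoy_corr=0.0, seed=1,
            matched_mode="pooled",  # tumor+normal span makes coupling dominate
        )
        (cohort,), truth = simulate_cohorts([cfg])
        g = next(iter(truth.planted_target_ids))
        matched = sorted(cohort.matched)
        r = np.corrcoef(
            cohort.mirna[matched], cohort.mrna.loc[g, matched]
        )[0, 1]
        assert r < -0.99

    def test_decoy_structure(self):
        """Down-decoys shift without coupling; corr-decoys couple
        without net shift."""
        cfg = CohortSimConfig(
            name="c", n_genes=200, n_planted_targets=0, n_tumor=200, n_normal=200,
            n_matched=150, mirna_tumor_shift=2.0, target_slope=-1.0,
            noise_sd=0.5, frac_decoy_down=0.1, frac_decoy_corr=0.1, seed=4,
        )
        (cohort,), truth = simulate_cohorts([cfg])
        tum, norm = cohort.tumor_samples, cohort.normal_samples
        down = sorted(truth.decoy_down_ids)
        corr = sorted(truth.decoy_corr_ids)
        fold_down = (
            cohort.mrna.loc[down, tum].mean(axis=1)
            - cohort.mrna.loc[down, norm].mean(axis=1)
        ).mean()
        fold_corr = (
            cohort.mrna.loc[corr, tum].mean(axis=1)
            - cohort.mrna.loc[corr, norm].mean(axis=1)
        ).mean()
        assert fold_down < -1.5  # true shift -2 with n=200 per arm
        assert abs(fold_corr) < 0.5


class TestUtrSim:
    def test_planted_8mer_found_at_recorded_interval(self):
        records, truth = simulate_utrs(
            ["g1", "g2"], MIR21, {"g1": ["8mer"]}, length=100, seed=3
        )
        (site,) = truth["g1"]
        seq = str(records[0].seq)
        found = find_seed_sites(seq, MIR21, site_types=("8mer",))
        assert [(s.start, s.end) for s in found] == [(site["start"], site["end"])]
        assert truth["g2"] == []

    def test_no_extra_equal_or_higher_stringency_sites(self):
        records, truth = simulate_utrs(
            [f"g{i}" for i in range(30)],
            MIR21,
            {f"g{i}": ["7mer-m8"] for i in range(30)},
            length=150,
            gc_fraction=0.3,
            seed=9,
        )
        for rec in records:
            found = find_seed_sites(str(rec.seq), MIR21, site_types=("8mer", "7mer-m8"))
            intervals = [(t["start"], t["end"]) for t in truth[rec.id]]
            for s in found:
                assert any(s.start >= a and s.end <= b for a, b in intervals)

    def test_determinism_bytes(self):
        a, _ = simulate_utrs(["g1"], MIR21, {"g1": ["6mer"]}, seed=7)
        b, _ = simulate_utrs(["g1"], MIR21, {"g1": ["6mer"]}, seed=7)
        assert str(a[0].seq) == str(b[0].seq)

    def test_site_longer_than_sequence_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_utrs(["g1"], MIR21, {"g1": ["8mer"]}, length=9)

    def test_spontaneous_8mer_rate_matches_markov_oracle(self):
        """Empty-plan UTRs carry spontaneous 8mers at the rate predicted
        by an exact KMP-automaton Markov computation."""
        pattern = site_sequence(MIR21, "8mer")
        gc = 0.4
        probs = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}

        # exact P(pattern appears in an i.i.d. sequence of length L)
        def occurrence_prob(L):
            k = len(pattern)
            # failure links (KMP)
            fail = [0] * k
            for i in range(1, k):
                j = fail[i - 1]
                while j and pattern[i] != pattern[j]:
                    j = fail[j - 1]
                fail[i] = j + 1 if pattern[i] == pattern[j] else 0
            # state = matched prefix length, k absorbing
            dist = np.zeros(k + 1)
            dist[0] = 1.0
            trans = np.zeros((k, k + 1))
            for state in range(k):
                for base, pb in probs.items():
                    j = state
                    while j and base != pattern[j]:
                        j = fail[j - 1]
                    nxt = j + 1 if base == pattern[j] else 0
                    trans[state, nxt] += pb
            for _ in range(L):
                nxt = np.zeros(k + 1)
                nxt[: k + 1] = dist[:k] @ trans
                nxt[k] += dist[k]
                dist = nxt
            return dist[k]

        n, length = 4000, 200
        gene_ids = [f"g{i}" for i in range(n)]
        records, _ = simulate_utrs(gene_ids, MIR21, {}, length=length,
                                   gc_fraction=gc, seed=13)
        frac = np.mean([pattern in str(r.seq) for r in records])
        expected = occurrence_prob(length)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= 3 * se + 1e-9


class TestDoseResponseSim:
    def test_median_effect_definition(self):
        s = simulate_dose_response(m=2.0, Dm=7.0, doses=[7.0])
        assert s.fa[0] == pytest.approx(0.5)

    def test_closed_form(self):
        s = simulate_dose_response(m=1.0, Dm=10.0, doses=[100.0])
        assert s.fa[0] == pytest.approx(10 / 11)

    def test_determinism_and_logit_noise(self):
        a = simulate_dose_response(1.0, 10.0, [1, 5, 20], noise_sd=0.05, seed=6)
        b = simulate_dose_response(1.0, 10.0, [1, 5, 20], noise_sd=0.05, seed=6)
        np.testing.assert_array_equal(a.fa, b.fa)
        assert np.all((a.fa > 0) & (a.fa < 1))
        clean = simulate_dose_response(1.0, 10.0, [1, 5, 20]).fa
        np.testing.assert_allclose(
            logit(a.fa) - logit(clean),
            np.random.default_rng(6).normal(0, 0.05, 3),
        )

    def test_invalid_params(self):
        with pytest.raises(SimConfigError):
            simulate_dose_response(m=-1.0, Dm=10.0, doses=[1.0])
        with pytest.raises(SimConfigError):
            simulate_dose_response(m=1.0, Dm=0.0, doses=[1.0])
        with pytest.raises(SimConfigError):
            simulate_dose_response(m=1.0, Dm=1.0, doses=[])

    def test_additive_combination_empty_grid_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_additive_combination((1, 10), (1, 20), [], ratio=1.0)

    def test_additive_points_lie_on_loewe_line(self):
        combo = simulate_additive_combination(
            (1.3, 12.0), (0.8, 44.0), [0.25, 0.5, 0.75], ratio=0.5
        )
        for (d1, d2), fa in zip(combo.doses, combo.fa):
            dx1 = 12.0 * (fa / (1 - fa)) ** (1 / 1.3)
            dx2 = 44.0 * (fa / (1 - fa)) ** (1 / 0.8)
            assert d1 / dx1 + d2 / dx2 == pytest.approx(1.0, rel=1e-12)
            assert d2 / d1 == pytest.approx(0.5, rel=1e-12)
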