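import numpy as np
import pandas as pd
import pytest

from _oracles import ztest_oracle
from hdcminer.enrichment import (
    CountTable,
    DAResult,
    EmptyResultError,
    EnrichCriteria,
    FilterParams,
    builtin_da,
    filter_table,
    flag_enriched,
    hsb_enrichment_test,
    p_to_label,
    two_proportion_ztest,
)
from hdcminer.synthetic_data import AbundanceSimSpec, simulate_abundance


def _table(counts: dict, conditions: dict, study="s1") -> CountTable:
    df = pd.DataFrame(counts)
    meta = pd.DataFrame(
        {"study": study, "condition": pd.Series(conditions)},
    )
    meta.index.name = "sample_id"
    return CountTable(counts=df, sample_meta=meta)


class TestFilterTable:
    def test_sample_depth_boundary(self):
        counts = {"ok": [1_000_000], "low": [999_999]}
        t = _table(counts, {"ok": "control", "low": "control"})
        out = filter_table(t)
        assert list(out.counts.columns) == ["ok"]

    def test_all_samples_removed_is_error(self):
        t = _table({"a": [10]}, {"a": "control"})
        with pytest.raises(EmptyResultError):
            filter_table(t)

    def test_rare_taxon_thresholds(self):
        # taxon at 0.02% in 1/6 samples (~17% >= 10%) kept; 0.005% everywhere dropped
        n_samples = 6
        total = 2_000_000
        rows = {}
        rows["abundant"] = [total - 500] * n_samples
        rows["sometimes"] = [400] + [50] * (n_samples - 1)  # 0.02% once
        rows["always_rare"] = [100] * n_samples  # 0.005%
        counts = pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)]).T
        t = CountTable(
            counts=counts,
            sample_meta=pd.DataFrame(
                {"study": "x", "condition": "control"}, index=counts.columns
            ),
        )
        out = filter_table(t)
        assert set(out.counts.index) == {"abundant", "sometimes"}

    def test_toy_table_against_bruteforce(self):
        # 10 species x 6 samples with one planted rare taxon
        rng = np.random.default_rng(5)
        counts = rng.integers(10_000, 900_000, size=(10, 6)).astype(np.int64)
        counts[7] = 30  # planted rare taxon, far below 0.01% everywhere
        scale = np.maximum(1, (1_100_000 / counts.sum(0))).astype(np.int64)
        counts = counts * scale[None, :]
        species = [f"sp{i}" for i in range(10)]
        samples = [f"m{i}" for i in range(6)]
        t = CountTable(
            counts=pd.DataFrame(counts, index=species, columns=samples),
            sample_meta=pd.DataFrame({"study": "x", "condition": "control"}, index=samples),
        )
        params = FilterParams()
        out = filter_table(t, params)
        # independent brute-force re-application of the two rules
        keep_samples = [j for j in range(6) if counts[:, j].sum() >= params.min_library_size]
        expected = []
        for i in range(10):
            n_ok = 0
            for j in keep_samples:
                if counts[i, j] / counts[:, j].sum() >= params.rare_rel_abundance:
                    n_ok += 1
            if n_ok / len(keep_samples) >= params.rare_sample_fraction:
                expected.append(species[i])
        assert list(out.counts.index) == expected
        assert len(expected) == 9


def da(species, method, effect, q, direction="disease"):
    return DAResult(species_id=species, method=method, effect=effect, qvalue=q,
                    direction=direction)


class TestFlagEnriched:
    def test_criteria_branches_hand_counted(self):
        results = [
            da("d_at_boundary", "deseq2_like", 1.0, 0.01),   # effect not strictly > 1
            da("d_pass", "deseq2_like", 1.5, 0.04),
            da("d_q_boundary", "deseq2_like", 1.5, 0.05),    # q not strictly < 0.05
            da("d_control", "deseq2_like", 3.0, 0.001, "control"),
            da("m_pass", "maaslin2_like", 0.25, 0.04),
            da("m_at_boundary", "maaslin2_like", 0.2, 0.01),
            da("l_q_too_big", "lefse_like", 3.0, 0.01),      # needs q < 0.001
            da("l_pass", "lefse_like", 2.5, 0.0005),
            da("l_at_boundary", "lefse_like", 2.0, 0.0005),
        ]
        assert flag_enriched(results) == {"d_pass", "m_pass", "l_pass"}

    def test_hmp2_variant_thresholds(self):
        results = [
            da("d_small_fc", "deseq2_like", 0.6, 0.04),
            da("d_at_half", "deseq2_like", 0.5, 0.04),
            da("m_small_coef", "maaslin2_like", 0.1, 0.04),
            da("m_zero", "maaslin2_like", 0.0, 0.04),
        ]
        assert flag_enriched(results, study="HMP2") == {"d_small_fc", "m_small_coef"}
        assert flag_enriched(results, study="other") == set()

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        results = [
            da(f"s{i}", "deseq2_like", float(rng.normal(1, 1)), float(rng.random()))
            for i in range(100)
        ]
        base = flag_enriched(results)
        relaxed = EnrichCriteria()
        relaxed.base["deseq2_like"] = type(relaxed.base["deseq2_like"])(0.5, 0.2)
        assert base <= flag_enriched(results, relaxed)

    def test_unknown_method_is_error(self):
        with pytest.raises(KeyError):
            flag_enriched([da("x", "mystery", 2.0, 0.01)])


class TestTwoProportionZtest:
    def test_equal_proportions(self):
        z, p = two_proportion_ztest(5, 10, 50, 100)
        assert z == 0.0
        assert p == 0.5

    def test_extreme_separation(self):
        _, p = two_proportion_ztest(10, 10, 0, 100)
        assert p < 1e-6

    def test_derived_example(self):
        z, p = two_proportion_ztest(12, 40, 30, 400)
        assert z == pytest.approx(4.335277142399527, abs=1e-12)
        assert p == pytest.approx(7.2788297184024416e-06, rel=1e-9)

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_ztest(0, 10, 0, 20) == (0.0, 0.5)
        assert two_proportion_ztest(10, 10, 20, 20) == (0.0, 0.5)

    def test_matches_oracle_on_full_small_grid(self):
        for n1 in (5, 10, 40, 100):
            for n2 in (5, 10, 40, 100):
                for x1 in range(n1 + 1):
                    for x2 in range(n2 + 1):
                        z, _ = two_proportion_ztest(x1, n1, x2, n2)
                        assert abs(z - ztest_oracle(x1, n1, x2, n2)) <= 1e-10

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n1, n2 = rng.integers(1, 50, 2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            z12, _ = two_proportion_ztest(int(x1), int(n1), int(x2), int(n2))
            z21, _ = two_proportion_ztest(int(x2), int(n2), int(x1), int(n1))
            assert z12 == pytest.approx(-z21, abs=1e-12)

    def test_zero_group_size_is_error(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(0, 0, 1, 10)


class TestPToLabel:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.05, "*"),
            (0.051, "n.s."),
            (0.01, "**"),
            (0.001, "***"),
            (1e-4, "****"),
            (1e-5, "****"),
            (0.3, "n.s."),
        ],
    )
    def test_boundaries(self, p, label):
        assert p_to_label(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p_to_label(1.2)


class TestBuiltinDa:
    def test_constant_species_is_null(self):
        counts = {f"m{i}": [2_000_000, 1_000_000] for i in range(8)}
        conditions = {f"m{i}": ("control" if i < 4 else "disease") for i in range(8)}
        t = _table(counts, conditions)
        results = {r.species_id: r for r in builtin_da(t)}
        # both species have constant relative abundance across samples
        for r in results.values():
            assert r.effect == pytest.approx(0.0)
            assert r.qvalue >= 0.05

    def test_single_condition_is_error(self):
        t = _table({"m1": [10, 10], "m2": [10, 10]}, {"m1": "control", "m2": "control"})
        with pytest.raises(ValueError):
            builtin_da(t)

    def test_planted_eightfold_increase_detected(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = AbundanceSimSpec(
                n_species=20, n_hsb=1, fraction_hsb_affected=1.0,
                fraction_other_affected=0.0, dispersion=0.1, baseline_sigma=0.5,
                planted_fold_change=8.0, seed=seed,
            )
            table, truth = simulate_abundance(spec)
            enriched = flag_enriched(builtin_da(filter_table(table)))
            hits += truth.affected_species[0] in enriched
        assert hits / n_rep >= 0.95

    def test_permuted_labels_control_false_positives(self):
        spec = AbundanceSimSpec(planted_fold_change=1.0, seed=42)
        table, _ = simulate_abundance(spec)
        rng = np.random.default_rng(0)
        fractions = []
        for _ in range(200):
            perm = rng.permutation(len(table.sample_meta))
            meta = table.sample_meta.copy()
            meta["condition"] = table.sample_meta["condition"].to_numpy()[perm]
            shuffled = CountTable(counts=table.counts, sample_meta=meta)
            results = builtin_da(shuffled)
            fractions.append(np.mean([r.qvalue < 0.05 for r in results]))
        assert np.mean(fractions) <= 0.05


class TestHsbEnrichmentTest:
    def test_counts_and_overlap_variants(self):
        universe = {f"s{i}" for i in range(10)}
        hsb = {"s0", "s1", "s2"}
        enriched = {"s0", "s1", "s5"}
        r = hsb_enrichment_test(enriched, hsb, universe)
        assert (r.x_hsb, r.n_hsb, r.x_all, r.n_all) == (2, 3, 3, 10)
        r2 = hsb_enrichment_test(enriched, hsb, universe, overlap=False)
        assert (r2.x_hsb, r2.n_hsb, r2.x_all, r2.n_all) == (2, 3, 1, 7)

    def test_hsb_outside_universe_rejected(self):
        with pytest.raises(Exception):
            hsb_enrichment_test(set(), {"zz"}, {"s1"})
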