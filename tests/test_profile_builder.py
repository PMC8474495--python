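import numpy as np
import pandas as pd
import pytest

from microcore.expression_stats import (
    DeltaPercentileTable,
    PercentileProfile,
    delta_percentile,
    percentile_rank,
)
from microcore.profile_builder import (
    TriangleTable,
    build_core_profile,
    microglia_unique,
    top_decile,
    triangle_fractions,
    venn_partition,
)


def _profile(values, cohort="c"):
    return PercentileProfile(cohort=cohort, percentiles=pd.Series(values, dtype=float))


def _delta(values):
    return DeltaPercentileTable("a", "b", pd.Series(values, dtype=float))


def _triangle(rows):
    df = pd.DataFrame(rows, columns=["pct_tissue", "pct_c1", "pct_c2"]).astype(float)
    df.index = df.index.astype(str) if not isinstance(rows, dict) else df.index
    return TriangleTable(fractions=df)


class TestTopDecile:
    def test_101_distinct_means(self):
        means = pd.Series(np.arange(101.0)[::-1], index=[f"g{i}" for i in range(101)])
        top = top_decile(percentile_rank(means))
        assert top.genes == {f"g{i}" for i in range(10)}

    def test_degenerate_cutoffs(self):
        p = _profile({"a": 0.0, "b": 50.0, "c": 100.0})
        assert top_decile(p, cutoff=0).genes == set()
        assert top_decile(p, cutoff=100.1).genes == {"a", "b", "c"}


class TestSetOps:
    def test_microglia_unique(self):
        assert microglia_unique({"a", "b", "c"}, {"b"}) == {"a", "c"}
        assert microglia_unique({"a"}, {"x"}) == {"a"}
        assert microglia_unique({"a"}, {"a", "b"}) == set()

    def test_venn_partition(self):
        v = venn_partition({1, 2, 3}, {2, 3, 4})
        assert (len(v.a_only), len(v.shared), len(v.b_only)) == (1, 2, 1)
        v2 = venn_partition({1, 2}, {1, 2})
        assert v2.counts == {"a_only": 0, "shared": 2, "b_only": 0}

    def test_venn_against_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = set(rng.integers(0, 100, rng.integers(0, 100)).tolist())
            b = set(rng.integers(0, 100, rng.integers(0, 100)).tolist())
            v = venn_partition(a, b)
            # element-wise membership oracle
            assert v.a_only == {x for x in a | b if x in a and x not in b}
            assert v.b_only == {x for x in a | b if x in b and x not in a}
            assert v.shared == {x for x in a | b if x in a and x in b}
            assert v.a_only | v.shared | v.b_only == a | b
            assert len(v.a_only) + len(v.shared) + len(v.b_only) == len(a | b)


class TestTriangle:
    def test_fractions(self):
        t = triangle_fractions(
            pd.Series({"g": 0.0, "h": 2.0}),
            pd.Series({"g": 5.0, "h": 2.0}),
            pd.Series({"g": 5.0, "h": 2.0}),
        )
        np.testing.assert_allclose(t.fractions.loc["g"], [0, 50, 50])
        np.testing.assert_allclose(t.fractions.loc["h"], [100 / 3] * 3)
        np.testing.assert_allclose(t.fractions.sum(axis=1), 100, rtol=1e-12)

    def test_scale_invariance(self):
        a = pd.Series({"g": 1.0, "h": 3.0})
        b = pd.Series({"g": 2.0, "h": 1.0})
        c = pd.Series({"g": 3.0, "h": 0.5})
        t1 = triangle_fractions(a, b, c)
        t7 = triangle_fractions(7 * a, 7 * b, 7 * c)
        pd.testing.assert_frame_equal(t1.fractions, t7.fractions)

    def test_all_zero_gene_dropped(self):
        t = triangle_fractions(
            pd.Series({"g": 0.0, "z": 0.0}),
            pd.Series({"g": 1.0, "z": 0.0}),
            pd.Series({"g": 1.0, "z": 0.0}),
        )
        assert "z" not in t.fractions.index
        assert t.n_dropped_all_zero == 1


class TestBuildCoreProfile:
    def test_boundary_inequalities(self):
        """Δ = 19.9 with 61% retained; Δ = 20 exactly and 60% exactly
        excluded (strict inequalities)."""
        delta = _delta({"keep": 19.9, "at20": 20.0, "at60": 5.0})
        tri = TriangleTable(
            fractions=pd.DataFrame(
                {
                    "pct_tissue": [39.0, 10.0, 40.0],
                    "pct_c1": [30.0, 45.0, 30.0],
                    "pct_c2": [31.0, 45.0, 30.0],
                },
                index=["keep", "at20", "at60"],
            )
        )
        prof = build_core_profile(
            de_enriched={"keep", "at20", "at60"},
            shared_top=set(),
            c2_only_top=set(),
            delta=delta,
            triangle=tri,
        )
        assert prof.genes == {"keep"}
        row = prof.flags.loc["keep"]
        assert row["in_de_enriched"] and row["delta_lt_threshold"]
        assert row["microglia_fraction_ge_threshold"]

    def test_union_then_filter_and_order_invariance(self):
        delta = _delta({"a": 1.0, "b": 1.0, "c": 1.0})
        tri = TriangleTable(
            fractions=pd.DataFrame(
                {"pct_tissue": [5.0] * 3, "pct_c1": [50.0] * 3, "pct_c2": [45.0] * 3},
                index=["a", "b", "c"],
            )
        )
        p1 = build_core_profile({"a"}, {"b"}, {"c"}, delta, tri)
        p2 = build_core_profile({"c"}, {"a"}, {"b"}, delta, tri)
        assert p1.genes == p2.genes == {"a", "b", "c"}

    def test_no_filters_returns_covered_candidates(self):
        delta = _delta({"a": 99.0, "b": 1.0})
        tri = TriangleTable(
            fractions=pd.DataFrame(
                {"pct_tissue": [90.0, 5.0], "pct_c1": [5.0, 90.0], "pct_c2": [5.0, 5.0]},
                index=["a", "b"],
            )
        )
        prof = build_core_profile(
            {"a", "b"}, set(), set(), delta, tri,
            delta_max=np.inf, microglia_min_pct=0.0,
        )
        assert prof.genes == {"a", "b"}

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(50)]
        delta = _delta(dict(zip(genes, rng.uniform(0, 40, 50))))
        frac = rng.uniform(0, 100, 50)
        tri = TriangleTable(
            fractions=pd.DataFrame(
                {
                    "pct_tissue": 100 - frac,
                    "pct_c1": frac / 2,
                    "pct_c2": frac / 2,
                },
                index=genes,
            )
        )
        cands = set(genes)
        prev = None
        for dmax, mgmin in [(30, 40), (20, 60), (10, 80)]:
            cur = build_core_profile(
                cands, set(), set(), delta, tri,
                delta_max=dmax, microglia_min_pct=mgmin,
            ).genes
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_empty_candidates_warn_not_raise(self):
        prof = build_core_profile(set(), set(), set(), _delta({}), _triangle({}))
        assert prof.genes == set()

    def test_planted_recovery_small_sim(self):
        """50 planted genes (high in both microglia cohorts, near zero in
        tissue) among 500 nulls: all planted retained, <= 2 nulls."""
        from microcore.differential import de_test_builtin, filter_enriched
        from microcore.io_formats import CountTable

        rng = np.random.default_rng(123)
        n, n_planted = 550, 50
        genes = [f"g{i}" for i in range(n)]
        base = rng.lognormal(4, 1, n)
        mean_t = base.copy()
        mean_t[:n_planted] *= 0.01  # planted nearly absent in tissue
        mean_m = base.copy()
        mean_m[:n_planted] *= 16
        r = 10.0

        def draw(mean):
            return rng.negative_binomial(r, r / (r + mean[:, None]), (n, 5))

        samples = {}
        cohort_of = {}
        draws = {}
        for cohort, mean in [("t", mean_t), ("c1", mean_m), ("c2", mean_m)]:
            mat = draw(mean)
            draws[cohort] = mat
            for j in range(5):
                sid = f"{cohort}_{j}"
                samples[sid] = mat[:, j]
                cohort_of[sid] = cohort
        ct = CountTable(
            counts=pd.DataFrame(samples, index=genes), cohort_of=cohort_of
        )
        de_set = filter_enriched(de_test_builtin(ct, "c1", "t"))
        mt, m1, m2 = (
            pd.Series(draws[c].mean(axis=1), index=genes) for c in ("t", "c1", "c2")
        )
        p1, p2, pt = (percentile_rank(m, cohort=c) for m, c in
                      [(m1, "c1"), (m2, "c2"), (mt, "t")])
        delta = delta_percentile(p1, p2)
        tri = triangle_fractions(mt, m1, m2)
        shared = (top_decile(p1).genes - top_decile(pt).genes) & (
            top_decile(p2).genes - top_decile(pt).genes
        )
        c2only = (top_decile(p2).genes - top_decile(pt).genes) - shared
        prof = build_core_profile(de_set, shared, c2only, delta, tri)
        planted = set(genes[:n_planted])
        # brute-force filter oracle over the same candidates
        expect = {
            g
            for g in (de_set | shared | c2only)
            if delta.delta[g] < 20
            and tri.fractions.loc[g, ["pct_c1", "pct_c2"]].sum() > 60
        }
        assert prof.genes == expect
        assert planted <= prof.genes
        assert len(prof.genes - planted) <= 2
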