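"""Age strata, discretization, the discrete K-S statistic and the co-profiling network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from isap import (
    GeneSetCollection,
    assign_strata,
    build_co_profiling_network,
    compute_cross_tissue_deltas,
    discretize,
    enrich_top_delta_genes,
    ks_statistic,
    select_tissues,
    shared_go_terms,
)
from isap.cross_tissue import tissue_degree_summary
from isap.experiments import planted_cohort_config
from isap.simulate import generate_cohort


def _meta(tissues, ages):
    return pd.DataFrame({"tissue": tissues, "age": ages},
                        index=[f"s{i}" for i in range(len(ages))])


class TestStrata:
    def test_boundaries_inclusive(self):
        meta = _meta(["t"] * 5, [50, 50.5, 59.9, 60, 40])
        s = assign_strata(meta)
        assert s.young == ["s0", "s4"] and s.old == ["s3"] and s.excluded == ["s1", "s2"]

    def test_strict_min_per_group_excludes_boundary_tissue(self):
        # young=3 exactly -> excluded under the strict "more than 3" reading
        ages_a = [40] * 3 + [70] * 10
        ages_b = [40] * 4 + [70] * 4
        meta = _meta(["A"] * 13 + ["B"] * 8, ages_a + ages_b)
        meta2 = pd.concat([meta, _meta(["C"] * 8, [40] * 4 + [70] * 4).set_axis(
            [f"c{i}" for i in range(8)])])
        assert select_tissues(meta2, min_per_group=3, strict=True) == ["B", "C"]
        assert select_tissues(meta2, min_per_group=3, strict=False) == ["A", "B", "C"]

    def test_too_few_tissues_raises(self):
        meta = _meta(["A"] * 4, [40, 41, 70, 71])
        with pytest.raises(ValueError):
            select_tissues(meta)

    def test_seven_tissues_give_twentyone_pairs(self):
        tissues = [t for t in "ABCDEFG" for _ in range(10)]
        ages = ([40] * 5 + [70] * 5) * 7
        ok = select_tissues(_meta(tissues, ages), min_per_group=3, strict=True)
        assert len(ok) == 7
        assert len(ok) * (len(ok) - 1) // 2 == 21


class TestDiscretize:
    def test_three_bands(self):
        assert list(discretize([-2, 0, 2], mean=0, sd=1)) == [-1, 0, 1]

    def test_boundary_goes_to_middle_band(self):
        assert list(discretize([-1.0, 1.0], mean=0, sd=1)) == [0, 0]

    def test_gaussian_band_frequencies(self, rng):
        x = rng.standard_normal(10_000)
        d = discretize(x, float(x.mean()), float(x.std(ddof=1)))
        for level, expected in ((-1, 0.1587), (0, 0.6827), (1, 0.1587)):
            freq = np.mean(d == level)
            se = np.sqrt(expected * (1 - expected) / x.size)
            assert abs(freq - expected) < 3 * se + 1e-3

    def test_zero_sd_gives_all_middle(self):
        assert not discretize([1, 2, 3], mean=2, sd=0).any()


class TestKsStatistic:
    def test_identical_samples_give_zero(self):
        assert ks_statistic([-1, 0, 1], [-1, 0, 1]) == 0

    def test_disjoint_support_gives_one(self):
        assert ks_statistic([-1, -1], [1, 1, 1]) == 1

    def test_hand_cdf_example(self):
        assert ks_statistic([-1, -1, 0, 1], [0, 0, 1, 1]) == 0.5

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_statistic([], [0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=30),
           st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=30))
    def test_symmetric_and_matches_reference(self, a, b):
        assert ks_statistic(a, b) == ks_statistic(b, a)
        assert abs(ks_statistic(a, b) - ks_2samp(a, b, method="asymp").statistic) < 1e-12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=20),
           st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=20))
    def test_invariant_under_monotone_relabeling(self, a, b):
        relabel = {-1: 10, 0: 20, 1: 300}
        assert ks_statistic(a, b) == ks_statistic([relabel[x] for x in a],
                                                  [relabel[x] for x in b])


@pytest.fixture(scope="module")
def planted():
    ds = generate_cohort(planted_cohort_config(seed=1))
    markers = ["gene_0010", "gene_0020", "gene_0030", "gene_0031"]
    deltas = compute_cross_tissue_deltas(ds, markers)
    return ds, markers, deltas


class TestCoProfilingNetwork:

    def test_planted_edge_exceeds_threshold(self, planted):
        ds, markers, deltas = planted
        edges = build_co_profiling_network(ds, markers, delta_threshold=0.95, deltas=deltas)
        top = edges.iloc[0]
        assert {top["marker_a"], top["marker_b"]} == {"gene_0010", "gene_0020"}
        assert top["delta"] > 0.95

    def test_stable_pairs_have_small_delta(self, planted):
        _, _, deltas = planted
        stable = deltas[~deltas["marker_a"].isin(["gene_0010", "gene_0020"])
                        & ~deltas["marker_b"].isin(["gene_0010", "gene_0020"])]
        assert stable["delta"].max() < 0.5

    def test_zero_threshold_keeps_every_pair(self, planted):
        ds, markers, deltas = planted
        edges = build_co_profiling_network(ds, markers, delta_threshold=-1, deltas=deltas)
        n_tissues = len({*deltas["tissue_a"], *deltas["tissue_b"]})
        expected = (n_tissues * (n_tissues - 1) // 2) * len(markers) ** 2
        assert len(edges) == len(deltas) == expected

    def test_edge_count_monotone_in_threshold(self, planted):
        ds, markers, deltas = planted
        counts = [len(build_co_profiling_network(ds, markers, delta_threshold=t, deltas=deltas))
                  for t in (0.0, 0.5, 0.95)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_degree_summary_counts_partner_tissues(self):
        edges = pd.DataFrame([
            {"tissue_a": "A", "marker_a": "x", "tissue_b": "B", "marker_b": "y",
             "ks_young": 0, "ks_old": 1, "delta": 1},
            {"tissue_a": "A", "marker_a": "x", "tissue_b": "C", "marker_b": "y",
             "ks_young": 0, "ks_old": 1, "delta": 1},
        ])
        deg = tissue_degree_summary(edges)
        assert deg.iloc[0]["tissue"] == "A" and deg.iloc[0]["degree"] == 2


class TestSharedTermsAndTopDelta:
    def _edges(self, delta):
        return pd.DataFrame([{"tissue_a": "A", "marker_a": "g1", "tissue_b": "B",
                              "marker_b": "g2", "ks_young": 0.0, "ks_old": delta,
                              "delta": delta}])

    def test_shared_terms_are_the_set_intersection(self):
        coll = GeneSetCollection(
            sets={"T1": ("", ["g1"]), "T2": ("", ["g1", "g2"]), "T3": ("", ["g1", "g2"]),
                  "T4": ("", ["g2"])},
            universe=["g1", "g2", "g3"])
        out = shared_go_terms(self._edges(1.0), coll)
        assert out.iloc[0]["shared_terms"] == ["T2", "T3"]
        assert out.iloc[0]["n_shared"] == 2

    def test_unmapped_endpoint_gives_empty_set(self):
        coll = GeneSetCollection(sets={"T": ("", ["g1", "g2"])}, universe=["g1", "g2"])
        edges = self._edges(1.0)
        edges.loc[0, "marker_a"] = "probe_0001"
        out = shared_go_terms(edges, coll, probe_gene_map={})
        assert out.iloc[0]["n_shared"] == 0

    def test_all_deltas_below_cut_give_empty_table(self):
        coll = GeneSetCollection(sets={"T": ("", ["g1", "g2"])}, universe=["g1", "g2"])
        assert enrich_top_delta_genes(self._edges(0.2), coll, delta_cut=0.85).empty

    def test_qualifying_edge_queries_its_genes(self):
        coll = GeneSetCollection(sets={"T": ("", ["g1", "g2"])}, universe=["g1", "g2", "g3"])
        table = enrich_top_delta_genes(self._edges(0.9), coll, delta_cut=0.85)
        assert table.iloc[0]["n"] == 2 and table.iloc[0]["k"] == 2
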