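import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrofish.acgh import call_aberrations
from thyrofish.core import Segment
from thyrofish.genome import GenomicRegion
from thyrofish.markers import (
    RankedRegion,
    build_region_matrix,
    minimal_common_region,
    rank_regions,
    select_minimal_markers,
)
from thyrofish.segmentation import NoiseEstimate

from .conftest import make_probes
from .oracles import minimum_set_cover_size, wilcoxon_exact_bruteforce


def seg(chrom, istart, iend, mean, probes):
    return Segment(
        chrom, int(probes.starts[istart]), int(probes.ends[iend - 1]),
        mean, iend - istart, istart, iend,
    )


def segs_with_break(probes, cut, means=(0.0, 0.0), chrom="1"):
    n = 100
    return [
        seg(chrom, 0, cut, means[0], probes),
        seg(chrom, cut, n, means[1], probes),
    ]


class TestBuildRegionMatrix:
    def test_identical_breakpoints_two_regions(self):
        probes = make_probes(n_per_chrom=100, chroms=("1",))
        segments = {
            "A": segs_with_break(probes, 50),
            "B": segs_with_break(probes, 50),
        }
        m = build_region_matrix(segments, {"A": [], "B": []}, probes)
        assert len(m.regions) == 2
        assert m.region_probes == [(0, 50), (50, 100)]

    def test_union_of_breakpoints(self):
        probes = make_probes(n_per_chrom=100, chroms=("1",))
        segments = {
            "A": segs_with_break(probes, 50),
            "B": segs_with_break(probes, 70),
        }
        m = build_region_matrix(segments, {"A": [], "B": []}, probes)
        assert m.region_probes == [(0, 50), (50, 70), (70, 100)]

    def test_no_calls_all_normal(self):
        probes = make_probes(n_per_chrom=100, chroms=("1",))
        segments = {"A": segs_with_break(probes, 30)}
        m = build_region_matrix(segments, {"A": []}, probes)
        assert (m.states == 0).all()

    def test_states_and_values_inherited_from_covering_call(self):
        probes = make_probes(n_per_chrom=100, chroms=("1",))
        a_segs = segs_with_break(probes, 50, means=(-0.6, 0.0))
        b_segs = segs_with_break(probes, 70, means=(0.0, 0.0))
        calls = {
            "A": call_aberrations(a_segs, NoiseEstimate(0.0)),
            "B": [],
        }
        m = build_region_matrix({"A": a_segs, "B": b_segs}, calls, probes)
        ia = m.sample_ids.index("A")
        # region (0,50) and (50,70): A's first segment covers (0,50) only
        assert m.states[ia, 0] == -1
        assert m.values[ia, 0] == pytest.approx(-0.6)
        assert m.states[ia, 1] == 0


class TestRankRegions:
    def make_matrix(self, cfa_vals, cftc_vals):
        n = len(cfa_vals) + len(cftc_vals)
        values = np.array(cfa_vals + cftc_vals, dtype=float).reshape(n, 1)
        states = np.sign(values).astype(np.int8)
        ids = [f"A{i}" for i in range(len(cfa_vals))] + [
            f"C{i}" for i in range(len(cftc_vals))
        ]
        from thyrofish.markers import RegionMatrix

        return (
            RegionMatrix(
                [GenomicRegion("1", 0, 100)], ids, values, states, [(0, 1)]
            ),
            {i: ("cFA" if i.startswith("A") else "cFTC") for i in ids},
        )

    def test_exact_p_for_separated_groups(self):
        m, labels = self.make_matrix([1, 2, 3], [4, 5, 6])
        (r,) = rank_regions(m, labels, on="values")
        assert r.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        m, labels = self.make_matrix([1.0, 1.0], [1.0, 1.0])
        (r,) = rank_regions(m, labels, on="values")
        assert r.p_value == 1.0

    @settings(max_examples=25)
    @given(data=st.data())
    def test_matches_enumeration_oracle_small_groups(self, data):
        """Exact p equals full enumeration over label assignments for
        tie-free groups of size <= 8."""
        n1 = data.draw(st.integers(2, 8))
        n2 = data.draw(st.integers(2, 8))
        pool = data.draw(
            st.lists(
                st.integers(-50, 50), min_size=n1 + n2, max_size=n1 + n2,
                unique=True,
            )
        )
        x, y = [float(v) for v in pool[:n1]], [float(v) for v in pool[n1:]]
        m, labels = self.make_matrix(x, y)
        (r,) = rank_regions(m, labels, on="values")
        assert r.p_value == pytest.approx(wilcoxon_exact_bruteforce(x, y))

    @given(seed=st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 6).tolist()
        y = (rng.normal(0.5, 1, 7)).tolist()
        m1, labels = self.make_matrix(x, y)
        m2, _ = self.make_matrix(
            list(np.exp(x)), list(np.exp(y))
        )
        (r1,) = rank_regions(m1, labels, on="values")
        (r2,) = rank_regions(m2, labels, on="values")
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_direction_and_coverage(self):
        m, labels = self.make_matrix([0, 0, 0], [0, -1, -1])
        (r,) = rank_regions(m, labels, on="states")
        assert r.direction == "loss"
        assert r.coverage == {"C1", "C2"}
        assert r.all_cfa_normal


def ranked(region_idx, p, coverage, all_cfa_normal=True, chrom="1", start=0):
    return RankedRegion(
        GenomicRegion(chrom, start + 1, start + 100),
        region_idx, p, "loss", frozenset(coverage), all_cfa_normal,
    )


class TestSelectMinimalMarkers:
    def test_single_candidate_covering_all(self):
        r = ranked(0, 0.001, {"c1", "c2", "c3"})
        assert select_minimal_markers([r]) == [r]

    def test_greedy_matches_set_cover_on_toy_instance(self):
        a = ranked(0, 0.01, {"1", "2", "3"})
        b = ranked(1, 0.02, {"3", "4"}, start=100)
        c = ranked(2, 0.03, {"4"}, start=200)
        sel = select_minimal_markers([a, b, c])
        assert sel == [a, b]
        assert minimum_set_cover_size(
            {"1", "2", "3", "4"},
            [set(a.coverage), set(b.coverage), set(c.coverage)],
        ) == 2

    def test_non_clean_and_insignificant_filtered(self):
        dirty = ranked(0, 0.001, {"1", "2"}, all_cfa_normal=False)
        weak = ranked(1, 0.2, {"1", "2"}, start=100)
        good = ranked(2, 0.01, {"1"}, start=200)
        sel = select_minimal_markers([dirty, weak, good])
        assert sel == [good]
        assert all(r.all_cfa_normal for r in sel)

    def test_tie_breaks_by_p_then_genome_order(self):
        a = ranked(0, 0.02, {"1", "2"}, chrom="2")
        b = ranked(1, 0.01, {"1", "2"}, chrom="5")
        c = ranked(2, 0.01, {"1", "2"}, chrom="3")
        sel = select_minimal_markers([a, b, c])
        assert sel[0] is c  # smallest p first, then earlier chromosome

    def test_empty_candidates_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_minimal_markers([ranked(0, 0.9, {"1"})]) == []
        assert "no significant" in caplog.text

    @settings(max_examples=30)
    @given(data=st.data())
    def test_greedy_equals_exhaustive_minimum_set_cover(self, data):
        """On instances of <= 12 candidate regions whose coverage sets are
        disjoint or nested (the carrier structure union-breakpoint grids
        produce), the greedy pick achieves the same coverage with the same
        number of regions as the optimal minimum set cover found by
        exhaustive search."""
        n_roots = data.draw(st.integers(1, 4))
        cands = []
        next_case, j = 0, 0
        for _ in range(n_roots):
            root = {f"c{next_case + i}" for i in range(data.draw(st.integers(0, 4)))}
            next_case += len(root)
            family = [root] + data.draw(
                st.lists(
                    st.sets(st.sampled_from(sorted(root)) if root else st.nothing()),
                    max_size=2,
                )
            )
            for cov in family:
                if j < 12:
                    cands.append(ranked(j, 0.001 * (j + 1), cov, start=100 * j))
                    j += 1
        sel = select_minimal_markers(cands)
        covered = set().union(*(set(r.coverage) for r in sel), set())
        coverable = set().union(*(set(r.coverage) for r in cands), set())
        assert covered == coverable  # greedy always reaches full coverage
        optimum = minimum_set_cover_size(
            coverable, [set(r.coverage) for r in cands]
        )
        assert len(sel) == optimum


class TestMinimalCommonRegion:
    def test_single_sample_own_interval(self):
        iv = GenomicRegion("1", 10, 100)
        out = minimal_common_region([iv])
        assert (out.start, out.end) == (10, 100)

    def test_pairwise_intersection(self):
        out = minimal_common_region(
            [GenomicRegion("1", 0, 100), GenomicRegion("1", 50, 150)]
        )
        assert (out.start, out.end) == (50, 100)

    def test_jittered_carriers_containment(self):
        rng = np.random.default_rng(0)
        carriers = [
            GenomicRegion("1", int(rng.integers(0, 5)) * 100,
                          34_000 + int(rng.integers(0, 5)) * 100)
            for _ in range(5)
        ]
        mcr = minimal_common_region(carriers)
        for iv in carriers:
            assert iv.start <= mcr.start and mcr.end <= iv.end

    def test_disjoint_intervals_error_lists_samples(self):
        with pytest.raises(ValueError, match="1:0-10.*1:20-30"):
            minimal_common_region(
                [GenomicRegion("1", 0, 10), GenomicRegion("1", 20, 30)]
            )

    def test_cross_chromosome_error(self):
        with pytest.raises(ValueError, match="different chromosomes"):
            minimal_common_region(
                [GenomicRegion("1", 0, 10), GenomicRegion("2", 0, 10)]
            )
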