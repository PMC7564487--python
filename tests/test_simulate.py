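import numpy as np
import pytest

from thyrofish.fish import classify_nucleus, classify_ploidy, score_case
from thyrofish.genome import GenomicRegion
from thyrofish.simulate import (
    CnvEvent,
    CohortDesign,
    FishSimConfig,
    SimConfig,
    expected_log2,
    make_probe_set,
    marker_event,
    simulate_cohort,
    simulate_di,
    simulate_fish_case,
    simulate_profile,
    simulate_training_cohort,
)


class TestExpectedLog2:
    def test_no_change_is_zero(self):
        for purity in (0.1, 0.5, 1.0):
            assert expected_log2(2, 2, purity) == 0.0

    def test_single_copy_loss_closed_form(self):
        assert expected_log2(1, 2, 0.8) == pytest.approx(np.log2(0.6))

    def test_male_whole_x_gain_closed_form(self):
        # one extra X copy on a one-copy male baseline
        assert expected_log2(2, 1, 0.8) == pytest.approx(np.log2(1.8))

    def test_zero_baseline_is_domain_error(self):
        with pytest.raises(ValueError):
            expected_log2(2, 0, 0.8)


@pytest.fixture(scope="module")
def grid(genome_module):
    return make_probe_set(
        genome_module, spacing=2_000_000, chromosomes=["1", "22", "X"], seed=0
    )


@pytest.fixture(scope="module")
def genome_module():
    from thyrofish.genome import load_default_genome

    return load_default_genome()


def clean_config(**kw):
    defaults = dict(noise_sd=0.0, gc_bias=0.0, dye_offset=0.0, purity=0.8, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateProfile:
    def test_no_events_no_noise_all_zero(self, grid):
        prof = simulate_profile(grid, [], clean_config(), "female", seed=1)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_whole_x_gain_female(self, grid, genome_module):
        ev = marker_event(genome_module, "X", "female")
        prof = simulate_profile(grid, [ev], clean_config(), "female", seed=1)
        x_mask = grid.chromosomes == "X"
        np.testing.assert_allclose(
            prof.values[x_mask], np.log2(2.8 / 2), atol=1e-12
        )
        np.testing.assert_array_equal(prof.values[~x_mask], 0.0)

    def test_deterministic_for_fixed_seed(self, grid, genome_module):
        cfg = SimConfig(noise_sd=0.12, seed=5)
        ev = marker_event(genome_module, "1p", "female")
        a = simulate_profile(grid, [ev], cfg, "female", seed=3)
        b = simulate_profile(grid, [ev], cfg, "female", seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_profile(grid, [ev], cfg, "female", seed=4)
        assert not np.array_equal(a.values, c.values)

    def test_overlapping_events_rejected(self, grid):
        e1 = CnvEvent(GenomicRegion("1", 0, 2_000_000), 1)
        e2 = CnvEvent(GenomicRegion("1", 1_000_000, 3_000_000), 3)
        with pytest.raises(ValueError, match="overlapping"):
            simulate_profile(grid, [e1, e2], clean_config(), "female", seed=0)

    def test_gc_bias_and_dye_offset_enter_linearly(self, grid):
        cfg = clean_config(gc_bias=0.5, dye_offset=0.3)
        prof = simulate_profile(grid, [], cfg, "female", seed=0)
        expected = 0.5 * (grid.gc - grid.gc.mean()) + 0.3
        np.testing.assert_allclose(prof.values, expected, atol=1e-12)


@pytest.fixture(scope="module")
def cohort(genome_module):
    grid = make_probe_set(genome_module, spacing=2_000_000, seed=0)
    return simulate_training_cohort(grid, genome_module, clean_config())


class TestTrainingCohort:
    def test_class_sizes(self, cohort):
        _, _, phenotypes = cohort
        labels = [p.label for p in phenotypes]
        assert labels.count("cFA") == 33 and labels.count("cFTC") == 33

    def test_marker_counts_and_overlap_structure(self, cohort):
        _, truth, phenotypes = cohort
        cftc = {p.sample_id for p in phenotypes if p.label == "cFTC"}
        marker_sets = {}
        for sid in cftc:
            markers = set()
            for ev in truth[sid]:
                if ev.region.chromosome == "1" and ev.tumor_cn == 1:
                    markers.add("1p")
                elif ev.region.chromosome == "22" and ev.tumor_cn == 1:
                    markers.add("22q")
                elif ev.region.chromosome == "X" and ev.tumor_cn > 1:
                    markers.add("X")
            marker_sets[sid] = markers
        carriers = {s for s, m in marker_sets.items() if m}
        # 21 alterations in 18 distinct patients
        assert len(carriers) == 18
        assert sum(len(m) for m in marker_sets.values()) == 21
        counts = {
            m: sum(m in ms for ms in marker_sets.values())
            for m in ("1p", "22q", "X")
        }
        assert counts == {"1p": 5, "22q": 8, "X": 8}
        # 16 single-, 1 double-, 1 triple-positive (inclusion-exclusion)
        sizes = sorted(len(marker_sets[s]) for s in carriers)
        assert sizes == [1] * 16 + [2, 3]

    def test_cfa_marker_negative(self, cohort):
        _, truth, phenotypes = cohort
        for p in phenotypes:
            if p.label != "cFA":
                continue
            for ev in truth[p.sample_id]:
                assert ev.region.chromosome not in ("1", "22", "X")

    def test_background_recur_in_both_classes(self, cohort):
        _, truth, phenotypes = cohort
        label = {p.sample_id: p.label for p in phenotypes}
        cfa_bg = set()
        cftc_bg = set()
        for sid, events in truth.items():
            for ev in events:
                if ev.region.chromosome in ("1", "22", "X"):
                    continue
                (cfa_bg if label[sid] == "cFA" else cftc_bg).add(
                    ev.region.chromosome
                )
        assert cftc_bg  # complex cFTC exist
        assert cftc_bg <= cfa_bg  # nothing outside the markers is cFTC-only

    def test_all_frequencies_zero_gives_flat_profiles(self, genome_module):
        grid = make_probe_set(
            genome_module, spacing=5_000_000, chromosomes=["1", "22"], seed=0
        )
        design = CohortDesign(
            prefix="Z", n_cfa=2, n_cftc=2, carriers={}, n_complex_cfa=0,
            cfa_females=1, cftc_females=1,
        )
        profiles, truth, _ = simulate_cohort(
            grid, genome_module, clean_config(), design
        )
        assert len(profiles) == 4
        for prof in profiles:
            np.testing.assert_array_equal(prof.values, 0.0)
        assert all(not ev for ev in truth.values())

    def test_bit_identical_reruns(self, genome_module):
        grid = make_probe_set(
            genome_module, spacing=5_000_000, chromosomes=["1", "22", "X"],
            seed=0,
        )
        cfg = SimConfig(noise_sd=0.12, seed=9)
        a, _, _ = simulate_training_cohort(grid, genome_module, cfg)
        b, _, _ = simulate_training_cohort(grid, genome_module, cfg)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.values, pb.values)


class TestSimulateFishCase:
    def test_all_normal_when_fraction_zero(self):
        cfg = FishSimConfig(aberrant_fraction=0.0, failure_rate=0.0, seed=1)
        case = simulate_fish_case(
            {"P1": "1p-loss"}, cfg, "female", seed=0
        )
        assert all(
            (n.target, n.control) == (2, 2) for n in case.nuclei["P1"]
        )

    def test_forced_x_gain_pattern(self):
        cfg = FishSimConfig(
            aberrant_fraction=1.0, failure_rate=0.0, contamination=0.0, seed=1
        )
        case = simulate_fish_case({"PXY": "X-gain"}, cfg, "female", seed=0)
        assert all(
            (n.target, n.control) == (3, 0) for n in case.nuclei["PXY"]
        )

    def test_aberrant_count_matches_binomial_oracle(self):
        cfg_kw = dict(
            n_nuclei=200, aberrant_fraction=0.6, failure_rate=0.0,
            contamination=0.1,
        )
        p = 0.6 * (1 - 0.1)
        fractions = []
        for seed in range(100):
            case = simulate_fish_case(
                {"P1": "1p-loss"}, FishSimConfig(seed=7, **cfg_kw),
                "female", seed=seed,
            )
            aberrant = sum(
                1 for n in case.nuclei["P1"] if (n.target, n.control) == (1, 2)
            )
            assert 0 <= aberrant <= 200  # binomial support
            fractions.append(aberrant / 200)
        se = np.sqrt(p * (1 - p) / (200 * 100))
        assert abs(np.mean(fractions) - p) < 3 * se

    def test_case_scores_positive_end_to_end(self):
        cfg = FishSimConfig(seed=3)
        case = simulate_fish_case(
            {"P22": "22q-loss"}, cfg, "male", seed=11, case_id="C1"
        )
        res = score_case(case)
        assert res.panels["P22"].call == "positive"
        assert res.panels["P1"].call == "negative"
        assert res.call == "positive"


class TestSimulateDi:
    @pytest.mark.parametrize(
        "cls", ["diploid", "aneuploid", "haploid", "tetraploid", "multiploid"]
    )
    def test_round_trip_identity(self, cls):
        for seed in range(200):
            dis = simulate_di(cls, seed=seed)
            assert classify_ploidy(dis) == cls

    def test_diploid_interval(self):
        for seed in range(50):
            (di,) = simulate_di("diploid", seed=seed)
            assert 0.9 <= di <= 1.1

    def test_tetraploid_interval(self):
        for seed in range(50):
            (di,) = simulate_di("tetraploid", seed=seed)
            assert 1.8 <= di <= 2.2

    def test_multiploid_two_distinct_indices(self):
        dis = simulate_di("multiploid", seed=4)
        assert len(dis) == 2
        assert abs(dis[0] - dis[1]) > 0.05

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            simulate_di("octoploid", seed=0)
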