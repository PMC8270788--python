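import numpy as np
import pytest

from hicarch import synthetic_data as sd
from hicarch.domain_metrics import DITrack, InsulationTrack, insulation_score
from hicarch.tad_consensus import (
    Domain,
    DomainSet,
    call_domains_insulation,
    compare_domain_sets,
    filter_domains,
    low_density_filter,
    merge_domain_sets,
    read_domain_bed,
    write_domain_bed,
)

from conftest import make_matrix

BS = 10_000


def ins_track(values, block=5):
    return InsulationTrack(np.asarray(values, dtype=float), block)


def dset(intervals, source="x"):
    return DomainSet(
        [Domain("chrT", s * BS, e * BS, source=(source,)) for s, e in intervals], BS
    )


class TestInsulationCaller:
    def test_monotone_track_empty(self):
        track = ins_track(np.linspace(0, 1, 50))
        with pytest.warns(UserWarning):
            out = call_domains_insulation(track, BS, "chrT")
        assert len(out) == 0

    def test_two_close_minima_both_reported(self):
        v = np.zeros(40)
        v[10] = -1.0
        v[13] = -1.0
        v[11:13] = -0.2
        out = call_domains_insulation(ins_track(v), BS, "chrT", min_depth=0.3,
                                      min_size_bins=1)
        starts = [d.start // BS for d in out]
        assert starts == [10]
        assert out[0].end // BS == 13

    def test_min_size_filter(self):
        v = np.zeros(60)
        v[[10, 12, 40]] = -1.0
        out = call_domains_insulation(ins_track(v), BS, "chrT", min_depth=0.5,
                                      min_size_bins=5)
        assert [(d.start // BS, d.end // BS) for d in out] == [(12, 40)]

    def test_recovers_planted_borders(self):
        hits, total = 0, 0
        from hicarch.matrix_core import apply_normalization, compute_normalization

        for seed in range(5):
            spec = sd.default_fixture(seed=seed)
            m, truth = sd.simulate_contact_matrix(spec)
            vec = compute_normalization(m, "balanced")
            ins = insulation_score(apply_normalization(m, vec), 40)
            called = call_domains_insulation(ins, BS, "chrT")
            borders = sorted({d.start // BS for d in called} | {d.end // BS for d in called})
            for b in truth.borders:
                total += 1
                hits += any(abs(b - c) <= 2 for c in borders)
        assert hits / total >= 0.9


class TestMerge:
    def test_single_set_identity(self):
        a = dset([(10, 30), (40, 60)])
        track = ins_track(np.zeros(100))
        merged = merge_domain_sets([a], track)
        assert [(d.start, d.end) for d in merged] == [(d.start, d.end) for d in a]

    def test_border_moves_to_lowest_insulation(self):
        v = np.zeros(200)
        v[100] = -0.2
        v[103] = 0.1
        a = dset([(50, 100)])
        b = dset([(50, 103)], source="y")
        merged = merge_domain_sets([a, b], ins_track(v))
        assert [(d.start // BS, d.end // BS) for d in merged] == [(50, 100)]
        assert merged[0].source == ("x", "y")

    def test_three_callers_one_merged_domain(self):
        v = np.zeros(200)
        v[80] = -0.5
        v[120] = -0.4
        sets = [
            dset([(80, 120)], "a"),
            dset([(79, 121)], "b"),
            dset([(81, 119)], "c"),
        ]
        merged = merge_domain_sets(sets, ins_track(v))
        assert len(merged) == 1
        assert (merged[0].start // BS, merged[0].end // BS) == (80, 120)
        assert merged[0].source == ("a", "b", "c")

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=300)
        sets = [dset([(10, 55), (57, 90), (92, 140)], "a"),
                dset([(12, 54), (58, 141)], "b")]
        once = merge_domain_sets(sets, ins_track(v))
        twice = merge_domain_sets([once, once], ins_track(v))
        assert [(d.start, d.end) for d in twice] == [(d.start, d.end) for d in once]

    def test_grid_mismatch_rejected(self):
        a = dset([(10, 30)])
        b = DomainSet([Domain("chrT", 0, 50_000)], 25_000)
        with pytest.raises(ValueError):
            merge_domain_sets([a, b], ins_track(np.zeros(100)))


class TestFilters:
    def _matrix_with_block(self, fold, s=30, e=50, n=100):
        dense = np.full((n, n), 2.0)
        dense[s:e, s:e] *= fold
        return make_matrix(dense)

    def test_low_diamond_removed(self):
        # fold f gives DS = f/(1+f); 1.2222 -> 0.55
        m = self._matrix_with_block(0.55 / 0.45)
        out = filter_domains(dset([(30, 50)]), m)  # 200 kb
        assert len(out) == 0
        assert "diamond" in out.provenance["removed"][0]["reason"]

    def test_small_domain_removed(self):
        m = self._matrix_with_block(4.0, s=30, e=39)  # DS 0.8, 90 kb
        out = filter_domains(dset([(30, 39)]), m)
        assert len(out) == 0
        assert "size" in out.provenance["removed"][0]["reason"]

    def test_passing_domain_retained(self):
        m = self._matrix_with_block(0.7 / 0.3, s=30, e=45)  # DS 0.7, 150 kb
        out = filter_domains(dset([(30, 45)]), m)
        assert len(out) == 1
        assert np.isclose(out[0].diamond, 0.7)

    def test_output_subset_and_commutation(self):
        rng = np.random.default_rng(2)
        dense = rng.random((200, 200)) * 5 + 1
        dense = (dense + dense.T) / 2
        m = make_matrix(dense)
        cands = dset([(20, 40), (50, 58), (60, 100), (120, 170)])
        by_score = filter_domains(cands, m, ds_min=0.4, min_size=0)
        then_size = filter_domains(by_score, m, ds_min=0.0, min_size=100_000)
        by_size = filter_domains(cands, m, ds_min=0.0, min_size=100_000)
        then_score = filter_domains(by_size, m, ds_min=0.4, min_size=0)
        assert [(d.start, d.end) for d in then_size] == [(d.start, d.end) for d in then_score]
        keys = {(d.start, d.end) for d in cands}
        assert {(d.start, d.end) for d in then_size} <= keys

    def test_low_density_uniform_none_removed(self):
        m = make_matrix(np.ones((100, 100)))
        cands = dset([(10, 30), (40, 60), (70, 90)])
        out = low_density_filter(cands, m)
        assert len(out) == 3

    def test_low_density_zero_region_removed(self):
        dense = np.ones((100, 100))
        dense[40:60, :] = 0
        dense[:, 40:60] = 0
        m = make_matrix(dense)
        cands = dset([(10, 30), (42, 58), (70, 90)])
        out = low_density_filter(cands, m, floor_quantile=0.4)
        assert [(d.start // BS, d.end // BS) for d in out] == [(10, 30), (70, 90)]

    def test_zero_quantile_identity(self):
        m = make_matrix(np.ones((100, 100)))
        cands = dset([(10, 30)])
        assert len(low_density_filter(cands, m, floor_quantile=0.0)) == 1


class TestCompare:
    def test_identical_sets_all_match(self):
        a = dset([(10, 40), (50, 90)])
        rep = compare_domain_sets(a, dset([(10, 40), (50, 90)], "y"), 0.9)
        assert rep.matched == 2 and rep.unique_a == 0 and rep.unique_b == 0
        assert np.isclose(rep.mean_jaccard, 1.0)

    def test_shift_15_of_100_unmatched_at_09(self):
        a = dset([(100, 200)])
        b = dset([(115, 215)], "y")
        rep = compare_domain_sets(a, b, 0.9)
        assert rep.matched == 0

    def test_shift_15_of_100_matched_at_07(self):
        a = dset([(100, 200)])
        b = dset([(115, 215)], "y")
        rep = compare_domain_sets(a, b, 0.7)
        assert rep.matched == 1


class TestBedIO:
    def test_round_trip(self, tmp_path):
        a = dset([(10, 40), (50, 90)])
        p = tmp_path / "d.bed"
        write_domain_bed(a, p)
        back = read_domain_bed(p, BS)
        assert [(d.start, d.end) for d in back] == [(d.start, d.end) for d in a]

    def test_duplicate_domains_rejected(self):
        with pytest.raises(ValueError):
            DomainSet([Domain("chrT", 0, BS), Domain("chrT", 0, BS)], BS)
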