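"""DP alignment against an exhaustive oracle; guide tree; common-ion
quantitation and misalignment flagging."""

import itertools
import math

import numpy as np
import pytest

from gcmskit.align import (
    AlignmentParams,
    AlignmentTable,
    align_all,
    align_pair,
    area_matrix,
    build_guide_tree,
    common_ion_quantify,
    peak_similarity,
    read_alignment_csv,
    write_alignment_csv,
)
from gcmskit.core import MassSpectrum
from gcmskit.peaks import Peak, make_uid
from gcmskit.simulate import jittered_peak_lists


def make_peak(rt: float, spectrum: dict[float, float], area: float = 1.0) -> Peak:
    masses = sorted(spectrum)
    spec = MassSpectrum(masses, [spectrum[m] for m in masses])
    ion_areas = {m: area * spectrum[m] / sum(spectrum.values()) for m in masses}
    return Peak(
        uid=make_uid(spec, rt), rt=rt, spectrum=spec, ion_areas=ion_areas, area=area
    )


def random_peak_list(rng: np.random.Generator, n: int) -> list[Peak]:
    rts = np.sort(rng.uniform(0.0, 40.0, size=n))
    out = []
    for rt in rts:
        masses = rng.choice(np.arange(50, 120), size=4, replace=False).astype(float)
        spectrum = {float(m): float(v) for m, v in zip(masses, rng.uniform(10, 1000, 4))}
        out.append(make_peak(float(rt), spectrum))
    return out


def brute_force_min_cost(a, b, params: AlignmentParams) -> float:
    """Enumerate every monotone matching (order-preserving pairing of equal-
    size subsets) and return the minimum total alignment cost."""
    sim = [[peak_similarity(p, q, params.D) for q in b] for p in a]
    best = math.inf
    na, nb = len(a), len(b)
    for k in range(min(na, nb) + 1):
        for ia in itertools.combinations(range(na), k):
            for ib in itertools.combinations(range(nb), k):
                cost = sum(1.0 - sim[i][j] for i, j in zip(ia, ib))
                cost += params.gap * (na + nb - 2 * k)
                best = min(best, cost)
    return best


def table_cost(table: AlignmentTable, params: AlignmentParams) -> float:
    """Total cost of a two-experiment alignment table as produced by DP."""
    cost = 0.0
    for pa, pb in table.rows:
        if pa is not None and pb is not None:
            cost += 1.0 - peak_similarity(pa, pb, params.D)
        else:
            cost += params.gap
    return cost


def matching(table: AlignmentTable) -> set[tuple[str, str]]:
    return {
        (pa.uid, pb.uid)
        for pa, pb in table.rows
        if pa is not None and pb is not None
    }


class TestPeakSimilarity:
    def test_identical_peaks_score_one(self):
        p = make_peak(10.0, {60.0: 100.0, 70.0: 50.0})
        assert peak_similarity(p, p) == pytest.approx(1.0)

    def test_orthogonal_spectra_score_zero_any_rt(self):
        p = make_peak(10.0, {60.0: 100.0})
        q = make_peak(10.0, {61.0: 100.0})
        assert peak_similarity(p, q) == 0.0
        assert peak_similarity(p, make_peak(500.0, {61.0: 100.0})) == 0.0

    def test_rt_modulation_closed_form(self):
        D = 2.5
        p = make_peak(10.0, {60.0: 100.0, 70.0: 50.0})
        q = make_peak(10.0 + D, {60.0: 100.0, 70.0: 50.0})
        assert peak_similarity(p, q, D) == pytest.approx(math.exp(-0.5))

    def test_symmetry_and_zero_spectrum_error(self):
        p = make_peak(10.0, {60.0: 100.0, 70.0: 50.0})
        q = make_peak(12.0, {60.0: 30.0, 75.0: 90.0})
        assert peak_similarity(p, q) == pytest.approx(peak_similarity(q, p))
        empty = Peak(uid="x", rt=1.0, spectrum=MassSpectrum([50.0], [0.0]))
        with pytest.raises(ValueError):
            peak_similarity(p, empty)


class TestAlignPair:
    def test_identical_lists_align_diagonally(self):
        a = [make_peak(10.0 * k, {60.0 + k: 100.0, 80.0: 50.0}) for k in range(4)]
        table = align_pair(a, a)
        assert table.n_positions == 4
        assert all(pa is not None and pb is not None for pa, pb in table.rows)

    def test_uniform_shift_of_half_D_still_matches(self):
        params = AlignmentParams(D=2.5, gap=0.30)
        a = [make_peak(20.0 * k + 10, {60.0 + k: 100.0, 80.0: 40.0}) for k in range(5)]
        b = [
            make_peak(p.rt + 0.5 * params.D, dict(p.member_ions())) for p in a
        ]
        table = align_pair(a, b, params)
        assert len(matching(table)) == 5

    def test_missing_middle_peak_creates_one_gap(self):
        a = [make_peak(10.0, {60.0: 9.0}), make_peak(20.0, {70.0: 9.0}),
             make_peak(30.0, {80.0: 9.0})]
        b = [a[0], a[2]]
        table = align_pair(a, b)
        gaps = [row for row in table.rows if row[1] is None]
        assert table.n_positions == 3 and len(gaps) == 1
        assert gaps[0][0].rt == 20.0

    def test_empty_list_gives_all_gap_rows(self):
        b = [make_peak(5.0, {60.0: 1.0})]
        table = align_pair([], b)
        assert table.n_positions == 1 and table.rows[0][0] is None

    def test_optimal_cost_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        params = AlignmentParams(D=2.5, gap=0.30)
        for _ in range(60):
            a = random_peak_list(rng, int(rng.integers(1, 6)))
            b = random_peak_list(rng, int(rng.integers(1, 6)))
            table = align_pair(a, b, params)
            assert table_cost(table, params) == pytest.approx(
                brute_force_min_cost(a, b, params), abs=1e-9
            )

    def test_symmetric_matchings(self):
        rng = np.random.default_rng(23)
        params = AlignmentParams()
        for _ in range(20):
            a = random_peak_list(rng, 4)
            b = random_peak_list(rng, 5)
            ab = matching(align_pair(a, b, params))
            ba = {(x, y) for y, x in matching(align_pair(b, a, params))}
            assert ab == ba

    def test_columns_preserve_elution_order(self):
        rng = np.random.default_rng(29)
        table = align_pair(random_peak_list(rng, 6), random_peak_list(rng, 6))
        for col in range(2):
            rts = [row[col].rt for row in table.rows if row[col] is not None]
            assert rts == sorted(rts)


class TestGuideTreeAndProgressive:
    def test_two_experiments_single_merge(self):
        rng = np.random.default_rng(3)
        lists = [random_peak_list(rng, 3) for _ in range(2)]
        assert build_guide_tree(lists) == [(0, 1)]

    def test_identical_pair_merges_first(self):
        rng = np.random.default_rng(31)
        base = random_peak_list(rng, 4)
        other = random_peak_list(rng, 4)
        tree = build_guide_tree([other, base, list(base)])
        assert tuple(sorted(tree[0])) == (1, 2)

    def test_identical_experiments_fully_occupied(self):
        rng = np.random.default_rng(5)
        base = random_peak_list(rng, 5)
        table = align_all([list(base) for _ in range(4)])
        assert table.n_positions == 5
        assert all(table.occupancy(k) == 4 for k in range(5))

    def test_each_peak_appears_exactly_once(self):
        lists, _ = jittered_peak_lists(8, 4, jitter_sd=0.8, seed=2)
        table = align_all(lists)
        for col, plist in enumerate(lists):
            seen = [row[col].uid for row in table.rows if row[col] is not None]
            assert sorted(seen) == sorted(p.uid for p in plist)
            assert len(seen) == len(plist)

    def test_recovery_at_small_jitter_and_degradation(self):
        D = 2.5
        accs = []
        for sigma in (D / 3, D, 2 * D):
            lists, labels = jittered_peak_lists(10, 5, jitter_sd=sigma, seed=7)
            table = align_all(lists, AlignmentParams(D=D))
            total = correct = 0
            for row in table.rows:
                comps = set()
                for col, peak in enumerate(row):
                    if peak is None:
                        continue
                    comps.add(labels[col][lists[col].index(peak)])
                full = len([p for p in row if p is not None])
                total += full
                if len(comps) == 1 and full == 5:
                    correct += full
            accs.append(correct / total)
        assert accs[0] == 1.0
        assert accs[0] >= accs[1] >= accs[2]
        assert accs[2] < 1.0

    def test_min_peaks_drops_sparse_rows(self):
        a = [make_peak(10.0, {60.0: 5.0}), make_peak(30.0, {70.0: 5.0})]
        b = [make_peak(10.2, {60.0: 5.0})]
        table = align_all([a, b], AlignmentParams(min_peaks=2))
        assert table.n_positions == 1
        assert table.occupancy(0) == 2


class TestQuantitation:
    def three_member_row(self):
        specs = [
            {149.0: 1000.0, 61.0: 820.0, 77.0: 300.0, 90.0: 100.0, 105.0: 50.0},
            {149.0: 900.0, 61.0: 700.0, 77.0: 350.0, 91.0: 120.0, 106.0: 60.0},
            {149.0: 1100.0, 62.0: 800.0, 77.0: 250.0, 92.0: 110.0, 107.0: 40.0},
        ]
        return [make_peak(100.0 + 0.1 * k, s, area=10.0 + k) for k, s in enumerate(specs)]

    def test_shared_top_ion_selected_with_areas(self):
        row = self.three_member_row()
        table = AlignmentTable(("e0", "e1", "e2"), (tuple(row),))
        result = common_ion_quantify(table, n_top=5)
        assert result.common_ions[0] == 149.0
        assert not result.misaligned[0]
        assert all(a is not None and a > 0 for a in result.areas[0])

    def test_disjoint_top_sets_flagged_misaligned(self):
        p = make_peak(10.0, {50.0: 9.0, 51.0: 5.0})
        q = make_peak(10.1, {70.0: 9.0, 71.0: 5.0})
        table = AlignmentTable(("e0", "e1"), ((p, q),))
        result = common_ion_quantify(table, n_top=5)
        assert result.misaligned == (True,)
        assert result.common_ions == (None,)
        assert result.areas[0] == (None, None)

    def test_single_member_position_uses_own_top_ion(self):
        p = make_peak(10.0, {50.0: 9.0, 51.0: 5.0})
        table = AlignmentTable(("e0", "e1"), ((p, None),))
        result = common_ion_quantify(table)
        assert result.common_ions[0] == 50.0
        assert result.areas[0][0] == pytest.approx(p.ion_areas[50.0])
        assert result.areas[0][1] is None

    def test_consistent_ion_across_cells(self):
        lists, _ = jittered_peak_lists(6, 3, jitter_sd=0.5, seed=11)
        table = align_all(lists)
        result = common_ion_quantify(table)
        for k in range(table.n_positions):
            if result.misaligned[k] or result.common_ions[k] is None:
                continue
            ion = result.common_ions[k]
            for peak, a in zip(table.rows[k], result.areas[k]):
                if peak is not None:
                    assert ion in peak.top_ions(5)
                    assert a == pytest.approx(peak.ion_areas[ion])


class TestAlignmentOutput:
    def test_area_matrix_shape_and_gaps(self):
        a = [make_peak(10.0, {60.0: 5.0}, area=2.0), make_peak(30.0, {70.0: 5.0}, area=3.0)]
        b = [make_peak(10.2, {60.0: 5.0}, area=4.0)]
        table = align_all([a, b])
        df = area_matrix(table)
        assert df.shape == (2, 3)  # rt_s + 2 experiments
        assert df["exp0"].tolist() == [2.0, 3.0]
        assert np.isnan(df["exp1"].iloc[1])

    def test_csv_round_trip_with_na_gaps(self, tmp_path):
        lists, _ = jittered_peak_lists(5, 3, jitter_sd=0.5, seed=13)
        lists[1] = lists[1][:-1]  # force one gap
        table = align_all(lists)
        result = common_ion_quantify(table)
        areas_path, meta_path = write_alignment_csv(table, result, tmp_path / "aln")
        text = areas_path.read_text()
        assert "NA" in text
        again = read_alignment_csv(areas_path)
        df = area_matrix(table)
        np.testing.assert_allclose(
            again[df.columns[1:]].to_numpy(float),
            df[df.columns[1:]].to_numpy(float),
        )
        header = meta_path.read_text().splitlines()[0]
        assert header == "uid,rt_s,occupancy,common_ion,misaligned"
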