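"""Chip projection, focal-distribution grids, peaks, and peak matching."""

import math

import numpy as np
import pytest

from colourgame.chip_projection import (
    ChipGrid,
    Peak,
    PeakSet,
    find_peaks,
    focal_distribution,
    peak_to_peak_distance,
    project_many,
    project_to_chip,
    select_top_peaks,
    stimulus_multiplicity,
)
from colourgame.focal_analysis import EmergentLanguage, LanguageSet
from colourgame.stimuli import StimulusSet


def _projection_oracle(lab, array):
    """Independent exhaustive application of the two-step rule."""
    L, a, b = lab
    r = min(range(10), key=lambda rr: abs(array.row_L[rr] - L))
    ach = int(array.achromatic_idx[r])
    chips = array.chrom_idx[r]
    if chips[0] < 0:
        return ach
    theta = math.atan2(b, a)
    best, best_d = None, None
    for idx in chips:
        d = abs(math.atan2(array.labs[idx, 2], array.labs[idx, 1]) - theta) % (2 * math.pi)
        d = min(d, 2 * math.pi - d)
        if best_d is None or d < best_d:
            best, best_d = int(idx), d
    radius = math.hypot(a, b)
    if abs(math.hypot(array.labs[best, 1], array.labs[best, 2]) - radius) <= radius:
        return best
    return ach


class TestProjection:
    def test_all_chips_self_project(self, synthetic_array):
        got = project_many(synthetic_array.labs, synthetic_array)
        np.testing.assert_array_equal(got, np.arange(330))

    def test_achromatic_point_hits_grey_chip(self, synthetic_array):
        r = 4
        lab = [synthetic_array.row_L[r], 0.0, 0.0]
        assert project_to_chip(lab, synthetic_array) == synthetic_array.achromatic_idx[r]

    def test_matches_exhaustive_two_step_oracle(self, synthetic_array):
        rng = np.random.default_rng(61)
        labs = np.column_stack(
            [rng.uniform(0, 100, 100), rng.uniform(-70, 70, 100), rng.uniform(-70, 70, 100)]
        )
        got = project_many(labs, synthetic_array)
        expect = [_projection_oracle(lab, synthetic_array) for lab in labs]
        np.testing.assert_array_equal(got, expect)


class TestFocalDistribution:
    def test_no_languages_gives_zero_grid(self, synthetic_array, clustered_stimuli):
        grid = focal_distribution(None, clustered_stimuli, synthetic_array)
        assert grid.values.sum() == 0.0

    def test_unit_mass_on_single_chip(self, synthetic_array):
        chip = int(synthetic_array.chrom_idx[4, 10])
        lab = synthetic_array.labs[chip]
        stim = StimulusSet(lab[None, :], label="synthetic")
        langs = LanguageSet([EmergentLanguage("a", lab[None, :])])
        grid = focal_distribution(langs, stim, synthetic_array)
        assert grid.values[chip] == pytest.approx(1.0)
        assert grid.values.sum() == pytest.approx(1.0)

    def test_hand_enumerated_toy_set(self, synthetic_array):
        """5 languages on known chips; per-chip value = languages / multiplicity."""
        rng = np.random.default_rng(62)
        chips = [int(synthetic_array.chrom_idx[2, 5]), int(synthetic_array.chrom_idx[6, 20])]
        # two stimuli on chip A, one on chip B
        stim = StimulusSet(
            synthetic_array.labs[[chips[0], chips[0], chips[1]]] + [[0, 1e-4, 0], [0, 0, 1e-4], [0, 0, 0]],
            label="synthetic",
        )
        mult = stimulus_multiplicity(stim, synthetic_array)
        assert mult[chips[0]] == 2 and mult[chips[1]] == 1
        langs = LanguageSet(
            [EmergentLanguage(str(i), synthetic_array.labs[chips[0]][None]) for i in range(3)]
            + [EmergentLanguage(str(i + 3), synthetic_array.labs[chips[1]][None]) for i in range(2)]
        )
        grid = focal_distribution(langs, stim, synthetic_array)
        assert grid.values[chips[0]] == pytest.approx(3 / 2)
        assert grid.values[chips[1]] == pytest.approx(2 / 1)
        assert grid.values.sum() == pytest.approx(3 / 2 + 2)
        _ = rng

    def test_mass_identity(self, synthetic_array, clustered_stimuli):
        """sum(value * multiplicity) equals the number of (language, chip) hits."""
        rng = np.random.default_rng(63)
        langs = LanguageSet(
            [
                EmergentLanguage(
                    str(i),
                    np.column_stack(
                        [rng.uniform(20, 90, 4), rng.uniform(-50, 50, 4), rng.uniform(-50, 50, 4)]
                    ),
                )
                for i in range(5)
            ]
        )
        grid = focal_distribution(langs, clustered_stimuli, synthetic_array)
        mult = stimulus_multiplicity(clustered_stimuli, synthetic_array)
        hits = 0
        for lang in langs.languages:
            proj = np.unique(project_many(lang.foci, synthetic_array))
            hits += sum(1 for c in proj if mult[c] > 0)
        assert np.sum(grid.values * mult) == pytest.approx(hits)


def _peaks_oracle(g, wrap):
    out = []
    rows, cols = g.shape
    for r in range(1, rows - 1):
        for c in range(cols) if wrap else range(1, cols - 1):
            neigh = [g[r - 1, c], g[r + 1, c], g[r, (c - 1) % cols], g[r, (c + 1) % cols]]
            if all(g[r, c] > v for v in neigh):
                out.append((c, r + 1, g[r, c]))
    return out


def _grid_from(synthetic_array, chrom):
    vals = np.zeros(330)
    vals[synthetic_array.chrom_idx[1:9].ravel()] = chrom.ravel()
    return ChipGrid(synthetic_array, vals)


class TestFindPeaks:
    def test_constant_grid_has_no_peaks(self, synthetic_array):
        grid = _grid_from(synthetic_array, np.ones((8, 40)))
        assert find_peaks(grid) == []

    def test_single_interior_spike(self, synthetic_array):
        chrom = np.zeros((8, 40))
        chrom[3, 17] = 1.0
        grid = _grid_from(synthetic_array, chrom)
        peaks = find_peaks(grid)
        assert peaks == [Peak(h=17, l=4, value=1.0)]

    def test_border_rows_never_peak(self, synthetic_array):
        chrom = np.zeros((8, 40))
        chrom[0, 5] = 9.0
        chrom[7, 5] = 9.0
        assert find_peaks(_grid_from(synthetic_array, chrom)) == []

    @pytest.mark.parametrize("wrap", [True, False])
    def test_matches_brute_force_on_random_grids(self, synthetic_array, wrap):
        rng = np.random.default_rng(64)
        for _ in range(200):
            chrom = rng.uniform(0, 1, (8, 40))
            grid = _grid_from(synthetic_array, chrom)
            got = [(p.h, p.l, p.value) for p in find_peaks(grid, hue_wrap=wrap)]
            assert got == _peaks_oracle(chrom, wrap)

    def test_wrap_mode_sees_seam_peaks(self, synthetic_array):
        chrom = np.zeros((8, 40))
        chrom[3, 0] = 1.0  # spike on the hue seam
        grid = _grid_from(synthetic_array, chrom)
        assert len(find_peaks(grid, hue_wrap=True)) == 1
        assert find_peaks(grid, hue_wrap=False) == []


class TestSelectTopPeaks:
    def _six(self):
        return [Peak(h, 4, v) for h, v in zip(range(6), [5, 3, 9, 1, 7, 2])]

    def test_wcs_mode_keeps_four(self):
        ps = select_top_peaks(self._six(), source="wcs")
        assert len(ps) == 4
        assert [p.value for p in ps.peaks] == [9, 7, 5, 3]

    def test_emergent_mode_subtracts_black_and_white(self):
        ps = select_top_peaks(self._six(), source="emergent", mean_categories=6.0)
        assert ps.n_requested == 4

    def test_floor_at_one(self):
        ps = select_top_peaks(self._six(), source="emergent", mean_categories=2.0)
        assert ps.n_requested == 1

    def test_fewer_peaks_than_requested_flags_truncation(self):
        ps = select_top_peaks(self._six()[:2], source="wcs")
        assert ps.truncated and len(ps) == 2

    def test_ties_break_by_row_then_column(self):
        peaks = [Peak(9, 5, 1.0), Peak(2, 3, 1.0), Peak(1, 3, 2.0), Peak(5, 2, 1.0)]
        ps = select_top_peaks(peaks, source="emergent", mean_categories=5.0)
        expect = sorted(peaks, key=lambda p: (-p.value, p.l, p.h))[:3]
        assert ps.peaks == expect

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            select_top_peaks([], source="wcs")


def _p2p_oracle(P, Q):
    def d(p, q):
        return math.hypot(p[0] - q[0], p[1] - q[1])

    wp = len(P) / (len(P) + len(Q))
    wq = len(Q) / (len(P) + len(Q))
    return wp * sum(min(d(p, q) for q in Q) for p in P) + wq * sum(
        min(d(p, q) for p in P) for q in Q
    )


class TestPeakToPeakDistance:
    def test_identical_sets_have_zero_distance(self):
        ps = PeakSet([Peak(3, 4, 2.0), Peak(10, 2, 1.0)], n_requested=2)
        assert peak_to_peak_distance(ps, ps) == 0.0

    def test_singletons_at_grid_distance_five(self):
        p = PeakSet([Peak(0, 2, 1.0)], n_requested=1)
        q = PeakSet([Peak(3, 6, 1.0)], n_requested=1)
        assert peak_to_peak_distance(p, q) == pytest.approx(5.0)

    def test_matches_double_loop_oracle_and_symmetry(self):
        rng = np.random.default_rng(65)
        for _ in range(50):
            P = [Peak(int(h), int(l), 1.0) for h, l in rng.integers(0, 30, (3, 2))]
            Q = [Peak(int(h), int(l), 1.0) for h, l in rng.integers(0, 30, (4, 2))]
            got = peak_to_peak_distance(P, Q)
            assert got == pytest.approx(
                _p2p_oracle([(p.h, p.l) for p in P], [(q.h, q.l) for q in Q]), abs=1e-9
            )
            assert got == pytest.approx(peak_to_peak_distance(Q, P), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            peak_to_peak_distance([], [Peak(1, 2, 1.0)])
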