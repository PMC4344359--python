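import math

import numpy as np
import pandas as pd
import pytest

from stillmerge.geometry import Beam, MosaicModel, crystal_from_cell
from stillmerge.merge_qc import (
    l_test,
    merge,
    nz_test,
    per_lattice_cutoff,
    resolution_shells,
    semi_dataset_stats,
    shell_i_over_sigma,
    unique_indices_in_range,
    wilson_moment,
)
from stillmerge.postrefine import Frame, Observation


def _bare_frame(frame_id, cell, point_group, obs_rows, G=1.0, B=0.0):
    """Frame from (hkl, I, sigma) rows; crystal in the reference orientation."""
    mos = MosaicModel(4000.0, math.radians(0.2))
    crystal = crystal_from_cell(cell, point_group, mos)
    obs = [
        Observation(hkl=tuple(h), I_raw=float(i), sigma=float(s),
                    d=crystal.d_spacing(h))
        for h, i, s in obs_rows
    ]
    return Frame(frame_id=frame_id, crystal=crystal, beam=Beam(1.269),
                 observations=obs, G=G, B=B)


CELL = (20.0, 21.0, 22.0, 90.0, 90.0, 90.0)


class TestPerLatticeCutoff:
    def _frame(self, i_over_sigma_by_d):
        rows = [((h, k, l), ios * 1.0, 1.0) for (h, k, l), ios in i_over_sigma_by_d]
        return _bare_frame("f", CELL, "P 1", rows)

    def test_all_shells_pass_unchanged(self, noisy_data):
        _, _, frames, _ = noisy_data
        f = frames[0]
        out = per_lattice_cutoff(f, threshold=1e-6)
        assert len(out.observations) == len(f.observations)

    def test_threshold_none_is_identity(self, noisy_data):
        _, _, frames, _ = noisy_data
        f = frames[0]
        assert per_lattice_cutoff(f, None) is f

    def test_truncates_at_first_failing_shell(self):
        """A frame whose high-resolution half has mean I/sigma far below
        threshold loses everything beyond the cutoff shell."""
        mos = MosaicModel(4000.0, math.radians(0.2))
        crystal = crystal_from_cell(CELL, "P 1", mos)
        rows = []
        for l in range(1, 10):
            hkl = (0, 0, l)
            d = crystal.d_spacing(hkl)
            ios = 10.0 if d >= 2.5 else 0.2
            rows.append((hkl, ios, 1.0))
        f = _bare_frame("f", CELL, "P 1", rows)
        out = per_lattice_cutoff(f, threshold=0.5, n_bins=5)
        assert len(out.observations) < len(f.observations)
        assert all(o.d >= 2.5 for o in out.observations)

    def test_too_few_bins_rejected(self, noisy_data):
        _, _, frames, _ = noisy_data
        with pytest.raises(ValueError):
            per_lattice_cutoff(frames[0], 0.5, n_bins=1)


class TestMerge:
    def test_multiplicity_counts_frames(self):
        frames = [
            _bare_frame(f"f{i}", CELL, "P 1", [((1, 2, 3), 10.0, 1.0)])
            for i in range(10)
        ]
        merged = merge(frames, "P 1", use_partiality=False)
        assert len(merged.table) == 1
        assert merged.table["multiplicity"].iloc[0] == 10

    def test_unweighted_mean_of_duplicates(self):
        frames = [
            _bare_frame("a", CELL, "P 1", [((1, 2, 3), 10.0, 1.0)]),
            _bare_frame("b", CELL, "P 1", [((1, 2, 3), 14.0, 1.0)]),
        ]
        merged = merge(frames, "P 1", use_partiality=False)
        assert merged.table["I"].iloc[0] == pytest.approx(12.0)

    def test_complete_single_frame(self):
        full = unique_indices_in_range(CELL, "P 1", 25.0, 3.0)
        rows = [((int(h), int(k), int(l)), 10.0, 1.0) for h, k, l in full]
        f = _bare_frame("f", CELL, "P 1", rows)
        merged = merge([f], "P 1", d_range=(25.0, 3.0), anomalous=False,
                       use_partiality=False)
        assert merged.completeness == pytest.approx(1.0)
        assert (merged.table["multiplicity"] == 1).all()

    def test_permutation_invariant(self, noisy_data):
        _, _, frames, _ = noisy_data
        m1 = merge(frames, "P 21 21 21", use_partiality=False)
        m2 = merge(frames[::-1], "P 21 21 21", use_partiality=False)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_friedel_separation_flag(self):
        frames = [
            _bare_frame("a", CELL, "P 1", [((1, 2, 3), 10.0, 1.0), ((-1, -2, -3), 20.0, 1.0)]),
        ]
        anom = merge(frames, "P 1", anomalous=True, use_partiality=False)
        coll = merge(frames, "P 1", anomalous=False, use_partiality=False)
        assert len(anom.table) == 2 and len(coll.table) == 1
        assert coll.table["I"].iloc[0] == pytest.approx(15.0)

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            merge([], "P 1")

    def test_sigma_floor_from_scatter(self):
        """Discrepant duplicates inflate the merged sigma above the purely
        propagated estimate."""
        frames = [
            _bare_frame("a", CELL, "P 1", [((1, 2, 3), 10.0, 0.1)]),
            _bare_frame("b", CELL, "P 1", [((1, 2, 3), 30.0, 0.1)]),
        ]
        merged = merge(frames, "P 1", use_partiality=False)
        propagated = math.sqrt(0.1**2 + 0.1**2) / 2
        assert merged.table["sigma"].iloc[0] > propagated


class TestSemiDatasetStats:
    def test_identical_halves(self):
        rows = [((0, 0, l), 10.0 * l, 1.0) for l in range(1, 8)]
        frames = [_bare_frame("a", CELL, "P 1", rows), _bare_frame("b", CELL, "P 1", rows)]
        cc, rs = semi_dataset_stats(frames, "P 1", split_seed=0, use_partiality=False)
        assert cc == pytest.approx(1.0)
        assert rs == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_correlation(self):
        """Two half-datasets with independent Gaussian noise on a common
        truth have expected correlation var(T) / (var(T) + sigma_half^2)."""
        rng = np.random.default_rng(99)
        full = unique_indices_in_range(CELL, "P 1", 25.0, 3.0)
        n_rep, n_frames, sigma = 50, 10, 40.0
        truth = rng.exponential(100.0, size=len(full))
        expected = np.var(truth) / (np.var(truth) + sigma**2 / (n_frames // 2))
        ccs = []
        for rep in range(n_rep):
            frames = []
            for i in range(n_frames):
                vals = truth + rng.normal(0, sigma, size=len(full))
                rows = [((int(h), int(k), int(l)), v, sigma)
                        for (h, k, l), v in zip(full, vals)]
                frames.append(_bare_frame(f"f{i}", CELL, "P 1", rows))
            cc, _ = semi_dataset_stats(frames, "P 1", split_seed=rep,
                                       anomalous=False, use_partiality=False)
            ccs.append(cc)
        assert np.mean(ccs) == pytest.approx(expected, abs=0.05)

    def test_uncorrelated_halves_near_zero(self):
        rng = np.random.default_rng(17)
        full = unique_indices_in_range(CELL, "P 1", 25.0, 3.0)
        frames = []
        for i in range(10):
            vals = rng.exponential(100.0, size=len(full))
            rows = [((int(h), int(k), int(l)), v, 1.0) for (h, k, l), v in zip(full, vals)]
            frames.append(_bare_frame(f"f{i}", CELL, "P 1", rows))
        cc, _ = semi_dataset_stats(frames, "P 1", split_seed=0, anomalous=False,
                                   use_partiality=False)
        assert abs(cc) < 3.0 / math.sqrt(len(full))

    def test_single_frame_rejected(self):
        f = _bare_frame("a", CELL, "P 1", [((1, 2, 3), 10.0, 1.0)])
        with pytest.raises(ValueError):
            semi_dataset_stats([f], "P 1")


class TestWilsonMoment:
    def test_constant_is_one(self):
        assert wilson_moment([5.0] * 10) == pytest.approx(1.0)

    def test_acentric_exponential(self):
        rng = np.random.default_rng(1)
        assert wilson_moment(rng.exponential(1.0, 100_000)) == pytest.approx(2.0, abs=0.05)

    def test_centric_chi_square(self):
        """The centric Wilson law is a scaled one-degree chi-square, whose
        second-moment ratio is the fourth Gaussian moment: 3."""
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(100_000) ** 2
        assert wilson_moment(draws) == pytest.approx(3.0, abs=0.1)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            wilson_moment([1.0])


class TestLTest:
    def test_constant_intensities_zero(self):
        res = l_test(np.full(500, 7.0), n_pairs=2000, seed=0)
        assert res.mean_abs_l == 0.0

    def test_exponential_moments(self):
        rng = np.random.default_rng(3)
        res = l_test(rng.exponential(1.0, 200_000), n_pairs=100_000, seed=0)
        assert res.mean_abs_l == pytest.approx(0.5, abs=0.01)
        assert res.mean_l2 == pytest.approx(1.0 / 3.0, abs=0.01)
        assert res.max_dev < 0.02

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            l_test(np.array([1.0, 2.0, 3.0, 4.0]), n_pairs=10, seed=0)


def _merged_from_arrays(I, d, centric, sigma=None):
    from stillmerge.merge_qc import MergedSet

    n = len(I)
    tab = pd.DataFrame({
        "h": np.arange(n), "k": np.zeros(n, int), "l": np.zeros(n, int),
        "sign": np.ones(n, int), "d": d, "I": I,
        "sigma": sigma if sigma is not None else np.ones(n),
        "multiplicity": np.ones(n, int), "centric": centric,
    })
    return MergedSet(table=tab, point_group="P 1", cell=(1, 1, 1, 90, 90, 90),
                     d_range=(float(np.max(d)), float(np.min(d))),
                     completeness=1.0, n_frames=1, anomalous=False)


class TestNZTest:
    def test_exponential_single_shell(self):
        rng = np.random.default_rng(4)
        I = rng.exponential(1.0, 100_000)
        merged = _merged_from_arrays(I, np.full(len(I), 3.0), np.zeros(len(I), bool))
        res = nz_test(merged, n_shells=1)
        assert res.max_dev_acentric < 0.01

    def test_constant_data_closed_form(self):
        """All z equal to 1: the sup-difference between a unit step at 1 and
        1 - exp(-z) is max(1 - 1/e, 1/e) = 0.632."""
        I = np.full(1000, 42.0)
        merged = _merged_from_arrays(I, np.full(len(I), 3.0), np.zeros(len(I), bool))
        res = nz_test(merged, n_shells=1)
        assert res.max_dev_acentric == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_absent_centric_class(self):
        rng = np.random.default_rng(5)
        I = rng.exponential(1.0, 500)
        merged = _merged_from_arrays(I, np.full(len(I), 3.0), np.zeros(len(I), bool))
        res = nz_test(merged, n_shells=1)
        assert res.max_dev_centric is None


class TestShellIOverSigma:
    def test_constant_ratio(self):
        d = np.linspace(2.5, 20, 500)
        merged = _merged_from_arrays(np.full(500, 10.0), d, np.zeros(500, bool),
                                     sigma=np.ones(500))
        tab = shell_i_over_sigma(merged, n_shells=5)
        assert np.allclose(tab["i_over_sigma"].dropna(), 10.0)

    def test_linear_in_inverse_sigma(self):
        d = np.linspace(2.5, 20, 500)
        rng = np.random.default_rng(6)
        I = rng.exponential(50, 500)
        m1 = _merged_from_arrays(I, d, np.zeros(500, bool), sigma=np.ones(500))
        m2 = _merged_from_arrays(I, d, np.zeros(500, bool), sigma=2 * np.ones(500))
        t1 = shell_i_over_sigma(m1, 5)["i_over_sigma"].to_numpy()
        t2 = shell_i_over_sigma(m2, 5)["i_over_sigma"].to_numpy()
        assert np.allclose(t1, 2 * t2, equal_nan=True)

    def test_monotone_decrease_on_simulated_data(self, noisy_data):
        """Resolution-dependent signal decay in the generator shows up as a
        decreasing I/sigma profile of the merged set."""
        _, _, frames, _ = noisy_data
        merged = merge(frames, "P 21 21 21", use_partiality=False)
        tab = shell_i_over_sigma(merged, n_shells=6)
        vals = tab.loc[tab["shell"] >= 0, "i_over_sigma"].dropna().to_numpy()
        assert vals[0] > vals[-1]
        assert np.corrcoef(np.arange(len(vals)), vals)[0, 1] < 0


class TestResolutionShells:
    def test_equal_volume_edges(self):
        d = np.linspace(2.0, 20.0, 1000)
        idx, edges = resolution_shells(d, 10)
        s3 = 1.0 / edges**3
        widths = np.diff(s3)
        assert np.allclose(widths, widths[0])

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            resolution_shells(np.array([2.0, 3.0]), 1)
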