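"""Piezo-class decomposition: intersection match and transport bounds.

The transport bounds are verified against an exact linear-program oracle:
minimize / maximize the upward-moved mass over all transport plans between
the two residual histograms (marginal constraints, non-negative flows).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog

from piezolab.autoradiography import ActivityHistogram, paired_histograms
from piezolab.classification import classify, match_tolerant, transport_bounds
from piezolab.synthetic import SyntheticConfig, gen_paired_community


def hist(counts, width=0.17, anchor=-2.0):
    counts = np.asarray(counts, dtype=int)
    edges = anchor + width * np.arange(len(counts) + 1)
    return ActivityHistogram(edges=edges, counts=counts, n_active=int(counts.sum()),
                             width=width, anchor=anchor)


def lp_up_bounds(res_in, res_atm):
    """Oracle: exact min and max of upward-moved mass via linear programming."""
    n = len(res_in)
    idx = [(i, j) for i in range(n) for j in range(n)]
    c = np.array([1.0 if j > i else 0.0 for i, j in idx])
    a_eq, b_eq = [], []
    for i in range(n):  # row sums = source masses
        a_eq.append([1.0 if ii == i else 0.0 for ii, _ in idx])
        b_eq.append(res_in[i])
    for j in range(n):  # column sums = target masses
        a_eq.append([1.0 if jj == j else 0.0 for _, jj in idx])
        b_eq.append(res_atm[j])
    lo = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    hi = linprog(-c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert lo.success and hi.success
    return lo.fun, -hi.fun


class TestMatchTolerant:
    def test_identical_histograms(self):
        h = hist([3, 5, 2])
        tol, ri, ra = match_tolerant(h, h)
        assert tol == pytest.approx(1.0)
        assert np.allclose(ri, 0) and np.allclose(ra, 0)

    def test_disjoint_histograms(self):
        tol, ri, ra = match_tolerant(hist([5, 0, 0]), hist([0, 0, 5]))
        assert tol == 0.0
        assert ri.sum() == pytest.approx(1.0) and ra.sum() == pytest.approx(1.0)

    def test_hand_example_per_bin_minima(self):
        # p_in = (0.6, 0.4, 0), p_atm = (0.5, 0, 0.5) → tolerant 0.5
        tol, ri, ra = match_tolerant(hist([6, 4, 0]), hist([5, 0, 5]))
        assert tol == pytest.approx(0.5)
        assert ri == pytest.approx([0.1, 0.4, 0.0])
        assert ra == pytest.approx([0.0, 0.0, 0.5])
        # at each bin at most one residual is nonzero; totals equal
        assert np.all(np.minimum(ri, ra) == 0)
        assert ri.sum() == pytest.approx(ra.sum())

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            match_tolerant(hist([1, 2]), hist([1, 2, 3]))
        with pytest.raises(ValueError):
            match_tolerant(hist([1, 2]), hist([1, 2], anchor=-1.83))


class TestTransportBounds:
    def test_empty_residuals(self):
        assert transport_bounds(np.zeros(4), np.zeros(4)) == (0, 0, 0, 0)

    def test_single_forced_upward_move(self):
        up_min, up_max, down_min, down_max = transport_bounds(
            np.array([0.2, 0, 0]), np.array([0, 0, 0.2])
        )
        assert (up_min, up_max) == (pytest.approx(0.2), pytest.approx(0.2))
        assert (down_min, down_max) == (0.0, 0.0)

    def test_mixed_forced_moves(self):
        # b1→b3 up, b5→b3 down; both forced
        up_min, up_max, down_min, down_max = transport_bounds(
            np.array([0.1, 0, 0, 0, 0.1]), np.array([0, 0, 0.2, 0, 0])
        )
        assert up_min == pytest.approx(0.1) and up_max == pytest.approx(0.1)
        assert down_min == pytest.approx(0.1) and down_max == pytest.approx(0.1)

    def test_unequal_totals_rejected(self):
        with pytest.raises(ValueError):
            transport_bounds(np.array([0.3, 0.0]), np.array([0.0, 0.2]))

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_linear_program_oracle(self, data):
        """Boundary formula equals the exact LP optimum on 0.1-grid residuals."""
        n_bins = data.draw(st.integers(2, 5))
        total = data.draw(st.integers(1, 10))
        cuts_i = sorted(data.draw(st.lists(st.integers(0, total), min_size=n_bins - 1,
                                           max_size=n_bins - 1)))
        cuts_a = sorted(data.draw(st.lists(st.integers(0, total), min_size=n_bins - 1,
                                           max_size=n_bins - 1)))
        to_masses = lambda cuts: np.diff([0] + cuts + [total]) / 10.0
        p_in, p_atm = to_masses(cuts_i), to_masses(cuts_a)
        # remove the per-bin overlap, as match_tolerant would
        both = np.minimum(p_in, p_atm)
        res_in, res_atm = p_in - both, p_atm - both
        up_min, up_max, down_min, down_max = transport_bounds(res_in, res_atm)
        lo, hi = lp_up_bounds(res_in, res_atm)
        m = res_in.sum()
        assert up_min == pytest.approx(lo, abs=1e-7)
        assert up_max == pytest.approx(hi, abs=1e-7)
        assert down_min == pytest.approx(m - hi, abs=1e-7)
        assert down_max == pytest.approx(m - lo, abs=1e-7)


class TestClassify:
    def test_tolerant_only_zero_noise_community(self):
        """With only tolerant cells the two conditions share every latent uptake."""
        cfg = SyntheticConfig(seed=2, n_active_cells=300, halo_noise_cv=0.0,
                              class_fractions=(1.0, 0.0, 0.0))
        _, truth = gen_paired_community(cfg, 2)
        assert np.allclose(truth.u_atm_amol_d, truth.u_insitu_amol_d)
        # a fully matched pair of histograms classifies as 100% tolerant
        u = truth.u_insitu_amol_d.to_numpy()[:300]
        res = classify(*paired_histograms(u, u))
        assert res.tolerant == pytest.approx(1.0)
        assert res.sensitive_max == 0.0 and res.philic_max == 0.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = 10 ** rng.normal(-1.3, 0.5, 400)
        b = 10 ** rng.normal(-0.9, 0.6, 500)
        h_in, h_atm = paired_histograms(a, b)
        fwd, rev = classify(h_in, h_atm), classify(h_atm, h_in)
        assert fwd.tolerant == pytest.approx(rev.tolerant)
        assert (fwd.sensitive_min, fwd.sensitive_max) == pytest.approx(
            (rev.philic_min, rev.philic_max)
        )
        assert (fwd.philic_min, fwd.philic_max) == pytest.approx(
            (rev.sensitive_min, rev.sensitive_max)
        )

    def test_sum_rules_on_random_histograms(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a = 10 ** rng.normal(rng.uniform(-2, 0), rng.uniform(0.2, 0.8), 200)
            b = 10 ** rng.normal(rng.uniform(-2, 0), rng.uniform(0.2, 0.8), 300)
            res = classify(*paired_histograms(a, b))
            m = res.moved_mass
            assert m == pytest.approx(1 - res.tolerant, abs=1e-9)
            assert res.sensitive_min + res.philic_max == pytest.approx(m, abs=1e-9)
            assert res.sensitive_max + res.philic_min == pytest.approx(m, abs=1e-9)

    def test_anchor_shift_invariance(self):
        """Shifting both anchors by a whole number of bins changes nothing."""
        rng = np.random.default_rng(5)
        a = 10 ** rng.normal(-1.3, 0.5, 400)
        b = 10 ** rng.normal(-0.8, 0.5, 400)
        h_in, h_atm = paired_histograms(a, b)
        res1 = classify(h_in, h_atm)
        w = h_in.width
        shift = 3
        pad = lambda h: ActivityHistogram(
            edges=np.concatenate([h.edges[0] - w * np.arange(shift, 0, -1), h.edges]),
            counts=np.concatenate([np.zeros(shift, int), h.counts]),
            n_active=h.n_active, width=w, anchor=h.anchor - shift * w,
        )
        res2 = classify(pad(h_in), pad(h_atm))
        for attr in ("tolerant", "sensitive_min", "sensitive_max", "philic_min", "philic_max"):
            assert getattr(res1, attr) == pytest.approx(getattr(res2, attr), abs=1e-12)
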