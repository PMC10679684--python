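import numpy as np
import pytest

from mea3d.geometry import ElectrodeAddress
from mea3d.synchrony import SynchronyMatrix, SynchronyParams, pairwise_matrix
from mea3d.treatments import (
    TreatmentSeries,
    classify_edges,
    edge_fractions_wrt_bic,
    synchrony_shift_fit,
    synchrony_shift_fits,
    track_edges,
    vehicle_fold_change,
)


def matrix_from_scores(scores):
    """Symmetric SynchronyMatrix over n electrodes of probe 1 (n <= 8)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    addresses = [ElectrodeAddress(1, 1, e) for e in range(1, n + 1)]
    sym = scores.copy()
    iu = np.triu_indices(n, 1)
    sym[(iu[1], iu[0])] = sym[iu]
    np.fill_diagonal(sym, np.nan)
    return SynchronyMatrix(sym, addresses)


def upper(n, entries):
    """Build an n x n upper-triangular score array from {(i, j): score}."""
    m = np.full((n, n), np.nan)
    for (i, j), v in entries.items():
        m[i, j] = v
    return m


class TestVehicleFoldChange:
    def test_chem_ratio_over_vehicle_ratio(self):
        # chem 0.5x baseline, vehicle 0.25x baseline -> fold 2
        assert vehicle_fold_change(0.5, 1.0, [0.25]) == pytest.approx(2.0)

    def test_vehicle_evaluated_against_itself_is_one(self):
        ratios = [0.8, 1.1, 1.3]
        mean = np.mean(ratios)
        for r in [mean]:
            assert vehicle_fold_change(r, 1.0, ratios) == pytest.approx(1.0)

    def test_equal_chem_and_vehicle_ratio_is_one(self):
        assert vehicle_fold_change(0.7, 1.0, [0.7]) == pytest.approx(1.0)

    def test_zero_baseline_gives_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(vehicle_fold_change(0.5, 0.0, [1.0]))
        with pytest.warns(UserWarning):
            assert np.isnan(vehicle_fold_change(0.5, 1.0, [0.0]))


class TestClassifyEdges:
    def test_threshold_boundary(self):
        m = matrix_from_scores(upper(3, {(0, 1): 0.40, (0, 2): 0.39, (1, 2): 0.75}))
        edges = classify_edges(m)
        by_pair = {(r.i, r.j): r.category for r in edges.itertuples()}
        assert by_pair[(0, 1)] == "high"   # score exactly at 0.40
        assert by_pair[(0, 2)] == "low"
        assert by_pair[(1, 2)] == "high"

    def test_silent_electrode_forces_inactive(self):
        m = matrix_from_scores(upper(3, {(0, 1): 0.9}))  # (0,2),(1,2) missing
        edges = classify_edges(m)
        cats = edges.set_index(["i", "j"])["category"]
        assert cats.loc[(0, 2)] == "inactive"
        assert cats.loc[(1, 2)] == "inactive"

    def test_section_labels_and_within_flag(self):
        m = matrix_from_scores(upper(4, {(0, 1): 0.5, (0, 2): 0.5, (2, 3): 0.5}))
        edges = classify_edges(m).set_index(["i", "j"])
        assert bool(edges.loc[(0, 1), "within_section"])   # electrodes 1,2: bottom
        assert not bool(edges.loc[(0, 2), "within_section"])  # bottom vs middle1


def hand_series():
    """4-electrode series with hand-enumerable category flips.

    Edges (i, j) over electrodes 0..3 (=> 6 edges).  Baseline: edge (0,1)
    high, (0,2) low, rest inactive.  BIC: all 6 active, (0,1),(2,3) high.
    AP5: (2,3) drops to low, (1,3) inactive.  CNQX: only (0,1) survives, low.
    """
    base = upper(4, {(0, 1): 0.6, (0, 2): 0.2})
    bic = upper(4, {(0, 1): 0.7, (0, 2): 0.3, (0, 3): 0.1, (1, 2): 0.2,
                    (1, 3): 0.35, (2, 3): 0.45})
    ap5 = upper(4, {(0, 1): 0.55, (0, 2): 0.25, (0, 3): 0.05, (1, 2): 0.1,
                    (2, 3): 0.30})
    cnqx = upper(4, {(0, 1): 0.15})
    return TreatmentSeries({
        "baseline": matrix_from_scores(base),
        "BIC": matrix_from_scores(bic),
        "AP5+BIC": matrix_from_scores(ap5),
        "CNQX+AP5+BIC": matrix_from_scores(cnqx),
    })


class TestEdgeFractions:
    def test_fractions_match_hand_count(self):
        frac = edge_fractions_wrt_bic(hand_series())
        # 6 edges active under BIC
        assert frac.loc["baseline"].tolist() == pytest.approx([1 / 6, 1 / 6, 4 / 6])
        assert frac.loc["BIC"].tolist() == pytest.approx([2 / 6, 4 / 6, 0.0])
        assert frac.loc["AP5+BIC"].tolist() == pytest.approx([1 / 6, 4 / 6, 1 / 6])
        assert frac.loc["CNQX+AP5+BIC"].tolist() == pytest.approx(
            [0.0, 1 / 6, 5 / 6]
        )

    def test_unchanged_categories_reproduce_bic_fractions(self):
        bic = matrix_from_scores(upper(3, {(0, 1): 0.5, (0, 2): 0.2, (1, 2): 0.9}))
        series = TreatmentSeries({c: bic for c in
                                  ("baseline", "BIC", "AP5+BIC", "CNQX+AP5+BIC")})
        frac = edge_fractions_wrt_bic(series)
        assert (frac.loc["baseline"] == frac.loc["BIC"]).all()

    def test_half_inactivated_after_cnqx(self):
        bic = matrix_from_scores(upper(3, {(0, 1): 0.5, (0, 2): 0.2, (1, 2): 0.9}))
        cnqx = matrix_from_scores(upper(3, {(0, 1): 0.5}))
        series = TreatmentSeries({"baseline": bic, "BIC": bic,
                                  "AP5+BIC": bic, "CNQX+AP5+BIC": cnqx})
        frac = edge_fractions_wrt_bic(series)
        assert frac.loc["CNQX+AP5+BIC", "inactive"] == pytest.approx(2 / 3)

    def test_no_bic_active_edges_errors(self):
        empty = matrix_from_scores(upper(3, {}))
        series = TreatmentSeries({c: empty for c in
                                  ("baseline", "BIC", "AP5+BIC", "CNQX+AP5+BIC")})
        with pytest.raises(ValueError):
            edge_fractions_wrt_bic(series)


class TestShiftFit:
    def test_identity_data_gives_unit_slope_zero_intercept(self):
        x = np.linspace(0.1, 0.9, 20)
        fit = synchrony_shift_fit(x, x)
        assert fit["slope"] == pytest.approx(1.0, abs=1e-12)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_response(self):
        x = np.linspace(0.1, 0.9, 20)
        fit = synchrony_shift_fit(x, np.full_like(x, 0.4))
        assert fit["slope"] == pytest.approx(0.0, abs=1e-12)
        assert fit["intercept"] == pytest.approx(0.4, abs=1e-12)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 100)
        y = 0.3 * x + 0.1 + rng.normal(0, 0.05, 100)
        fit = synchrony_shift_fit(x, y)
        # normal equations solved independently
        sx, sy, sxx, sxy, n = x.sum(), y.sum(), (x * x).sum(), (x * y).sum(), 100
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        assert fit["slope"] == pytest.approx(slope, abs=1e-12)
        assert fit["intercept"] == pytest.approx(intercept, abs=1e-12)

    def test_fewer_than_two_common_edges_is_missing(self):
        fit = synchrony_shift_fit([0.5, np.nan], [np.nan, 0.4])
        assert np.isnan(fit["slope"]) and fit["n"] == 0

    def test_grouped_fits_cover_within_and_between(self):
        fits = synchrony_shift_fits(hand_series())
        assert set(fits) == {"baseline", "AP5+BIC", "CNQX+AP5+BIC"}
        assert set(fits["baseline"]) == {"within", "between"}
        per_sec = synchrony_shift_fits(hand_series(), grouping="per_section")
        assert set(per_sec["baseline"]) == {"bottom", "middle1", "middle2", "top"}


class TestTrackEdges:
    def test_transition_flags(self):
        table = track_edges(hand_series()).set_index(["i", "j"])
        # (1,2): inactive at baseline, active under BIC -> became_active
        assert bool(table.loc[(1, 2), "became_active"])
        # (0,2): active at baseline, inactive by CNQX -> became_inactive
        assert bool(table.loc[(0, 2), "became_inactive"])
        # (0,1): active throughout -> no flags
        assert not bool(table.loc[(0, 1), "became_active"])
        assert not bool(table.loc[(0, 1), "became_inactive"])
        assert table.loc[(0, 1), "score_BIC"] == pytest.approx(0.7)

    def test_bic_boosted_bottom_coupling_raises_bottom_edge_scores(self, layout):
        from mea3d.synthetic import CultureConfig, TreatmentEffect, simulate_recording

        cfg = CultureConfig(between_coupling=0.0)
        eff = TreatmentEffect(coupling={"BIC": (1.4, 1.0, 1.0, 1.0)})
        params = SynchronyParams(normalize=False)
        recs = {
            cond: simulate_recording(cfg, condition=cond, effects=eff,
                                     seed=13, duration=200.0, layout=layout)
            for cond in ("baseline", "BIC", "AP5+BIC", "CNQX+AP5+BIC")
        }
        series = TreatmentSeries({c: pairwise_matrix(r, params)
                                  for c, r in recs.items()})
        table = track_edges(series)
        bottom = table[table.within_section & (table.section_i == "bottom")]
        assert bottom["score_BIC"].mean() > bottom["score_baseline"].mean()
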