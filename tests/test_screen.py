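"""Plate QC, normalization, hit calling, EC50 fits and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from mapshift import screen
from mapshift import synthetic_data as sd

from conftest import small_config


def _wells(rows):
    defaults = dict(plate_id="p1", well="W01", well_type="compound",
                    compound_id="c1", concentration_um=10.0, n_cells=2000,
                    response=10.0)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestQc:
    def test_cell_count_boundary(self):
        wells = _wells([{"n_cells": 499}, {"n_cells": 500}])
        out = screen.qc_wells(wells)
        assert out["n_cells"].tolist() == [500]

    def test_all_pass_is_identity(self):
        wells = _wells([{"n_cells": 600}, {"n_cells": 700}])
        pd.testing.assert_frame_equal(screen.qc_wells(wells), wells)

    def test_counting_mixed_fixture(self, rng):
        n_cells = np.full(96, 1000)
        low = rng.choice(96, size=7, replace=False)
        n_cells[low] = rng.integers(0, 500, size=7)
        wells = _wells([{"n_cells": int(c), "well": f"W{i}"} for i, c in enumerate(n_cells)])
        assert len(screen.qc_wells(wells)) == 89


class TestNormalize:
    def test_media_mean_arithmetic(self):
        wells = _wells(
            [{"well_type": "media", "response": r} for r in (4.0, 5.0, 6.0)]
            + [{"response": 10.0}]
        )
        out = screen.normalize_plate(wells)
        assert out.loc[out["well_type"] == "compound", "normalized_response"].iloc[0] == pytest.approx(2.0)
        assert out.loc[out["well_type"] == "media", "normalized_response"].mean() == pytest.approx(1.0)

    def test_all_equal_to_media_gives_ones(self):
        wells = _wells(
            [{"well_type": "media", "response": 5.0}, {"response": 5.0}]
        )
        out = screen.normalize_plate(wells)
        assert np.allclose(out["normalized_response"], 1.0)

    def test_plate_effect_removed_exactly(self):
        base = [{"well_type": "media", "response": 5.0},
                {"response": 15.0, "compound_id": "c1"}]
        doubled = [{**r, "plate_id": "p2", "response": r["response"] * 2} for r in base]
        out = screen.normalize_plate(_wells(base + doubled))
        by_plate = out[out["well_type"] == "compound"].set_index("plate_id")
        assert by_plate.loc["p1", "normalized_response"] == pytest.approx(
            by_plate.loc["p2", "normalized_response"]
        )

    def test_plate_without_media_excluded(self):
        wells = _wells(
            [{"well_type": "media", "response": 5.0}, {"response": 15.0},
             {"plate_id": "p2", "response": 7.0}]
        )
        out = screen.normalize_plate(wells)
        assert out.attrs["excluded_plates"] == ["p2"]
        assert set(out["plate_id"]) == {"p1"}


class TestPrimaryHits:
    def _plate(self, fold):
        return _wells(
            [{"well_type": "media", "response": 5.0},
             {"well_type": "vehicle", "response": 5.0},
             {"response": 5.0 * fold, "compound_id": "c1"}]
        )

    @pytest.mark.parametrize("fold,expected", [(2.0, True), (1.99, False)])
    def test_twofold_boundary_inclusive(self, fold, expected):
        out = screen.call_primary_hits(screen.normalize_plate(self._plate(fold)))
        assert bool(out.loc["c1", "hit"]) is expected

    def test_planted_enhancers_all_recovered(self, rng):
        rows = [{"well_type": "media", "response": 5.0, "well": "M"},
                {"well_type": "vehicle", "response": 5.0, "well": "V"}]
        truth = {}
        for i in range(400):
            hit = i < 20  # 5% planted enhancers at fold 3
            fold = 3.0 if hit else 1.0
            truth[f"c{i}"] = hit
            rows.append({"compound_id": f"c{i}", "well": f"W{i}",
                         "response": 5.0 * fold * rng.normal(1, 0.1)})
        out = screen.call_primary_hits(screen.normalize_plate(_wells(rows)))
        called = set(out.index[out["hit"]])
        assert {c for c, h in truth.items() if h} <= called
        false = [c for c in called if not truth[c]]
        assert len(false) <= 4  # <=1% false at CV 10%


def four_pl(conc, bottom=1.0, top=3.0, ec50=10.0, hill=2.5):
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) * conc**hill / (conc**hill + ec50**hill)


class TestEc50:
    CONC = np.array(screen.DOSE_SERIES_UM)

    def test_noiseless_logistic_recovered(self):
        responses = four_pl(self.CONC)
        fit = screen.fit_ec50(self.CONC, responses)
        assert fit.censored is None
        assert 9.0 <= fit.ec50_um <= 11.0

    def test_flat_series_censored_above_max(self):
        fit = screen.fit_ec50(self.CONC, np.ones(6))
        assert fit.ec50_um is None
        assert fit.censored == "above_max"

    def test_saturated_from_lowest_dose_flagged_below_min(self):
        responses = four_pl(self.CONC, ec50=0.1)
        fit = screen.fit_ec50(self.CONC, responses)
        assert fit.censored == "below_min"
        assert fit.ec50_um <= 1.25

    def test_unsaturated_curve_flagged_not_plateaued(self):
        responses = four_pl(self.CONC, ec50=60.0, top=5.0)
        fit = screen.fit_ec50(self.CONC, responses)
        assert fit.not_plateaued

    def test_duplicates_averaged(self, rng):
        conc = np.repeat(self.CONC, 2)
        responses = four_pl(conc) * rng.normal(1, 0.05, conc.size)
        fit = screen.fit_ec50(conc, responses)
        assert fit.ec50_um == pytest.approx(10.0, rel=0.35)

    def test_recovery_median_relative_error(self, rng):
        """100 simulated compounds at 10% response noise: median absolute
        relative EC50 error stays within 15%."""
        errors = []
        for _ in range(100):
            ec50 = float(np.exp(rng.uniform(np.log(2), np.log(30))))
            conc = np.repeat(self.CONC, 2)
            responses = four_pl(conc, top=rng.uniform(2.5, 5.0), ec50=ec50)
            responses = responses * rng.normal(1, 0.1, conc.size)
            fit = screen.fit_ec50(conc, responses)
            if fit.ec50_um is not None:
                errors.append(abs(fit.ec50_um - ec50) / ec50)
        assert len(errors) >= 90
        assert np.median(errors) <= 0.15

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4"):
            screen.fit_ec50([1, 2, 4], [1, 2, 3])


def brute_force_fisher_two_sided(table: np.ndarray) -> float:
    """Enumerate all tables with the same margins; two-sided p sums the
    probabilities of tables at most as probable as the observed one."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = (
        comb(col1, a, exact=True)
        * comb(n - col1, row1 - a, exact=True)
        / comb(n, row1, exact=True)
    )
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_x = (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )
        if p_x <= p_obs * (1 + 1e-12):
            total += p_x
    return total


class TestEnrichment:
    def test_perfect_association_closed_form(self):
        frame = pd.DataFrame(
            {"active": [True] * 10 + [False] * 10,
             "primary_target": ["t1"] * 10 + ["t2"] * 10}
        )
        out = screen.enrichment_fisher(frame).set_index("primary_target")
        expected = 2 / comb(20, 10, exact=True)
        assert out.loc["t1", "p"] == pytest.approx(expected, rel=1e-9)
        assert out.loc["t1", "p"] == pytest.approx(1.082e-5, rel=1e-3)

    def test_matches_brute_force_enumeration_small_margins(self):
        """All 2x2 tables with margins <= 12 against an exhaustive
        hypergeometric enumeration."""
        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            table = np.array([[a, b], [c, d]])
            _, p = stats.fisher_exact(table)
            assert p == pytest.approx(
                brute_force_fisher_two_sided(table), rel=1e-9, abs=1e-12
            )

    def test_independent_annotation_p_uniform(self, rng):
        pvals = []
        for _ in range(200):
            frame = pd.DataFrame(
                {"active": rng.random(60) < 0.3,
                 "primary_target": np.where(rng.random(60) < 0.5, "t1", "t2")}
            )
            out = screen.enrichment_fisher(frame)
            pvals.append(out["p"].iloc[0])
        # exact-test p-values are super-uniform (conservative)
        assert (np.array(pvals) < 0.05).mean() <= 0.07

    def test_single_shared_target_degenerate(self):
        frame = pd.DataFrame(
            {"active": [True, False, True], "primary_target": ["t1"] * 3}
        )
        out = screen.enrichment_fisher(frame)
        assert np.isnan(out["odds_ratio"].iloc[0])


class TestFlagsAndSummary:
    @pytest.mark.parametrize(
        "pka,logp,expected",
        [(7.0, 3.0, True), (6.0, 3.0, False), (7.0, 2.0, False),
         (11.0, 2.01, True), (6.5, 2.01, True), (11.01, 3.0, False)],
    )
    def test_lysosomotropic_rule(self, pka, logp, expected):
        assert screen.lysosomotropic_flag(pka, logp) is expected

    def test_missing_property_is_unknown(self):
        assert screen.lysosomotropic_flag(None, 3.0) is None
        assert screen.lysosomotropic_flag(np.nan, 3.0) is None

    def test_study_summary_numbers(self):
        assert screen.summarize_screen(37, 32, 786) == (86, 4)

    def test_full_validation(self):
        assert screen.summarize_screen(10, 10, 100) == (100, 10)

    def test_zero_hits_degenerate(self):
        assert screen.summarize_screen(0, 0, 100) == (0, 0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            screen.summarize_screen(5, 10, 100)


@pytest.fixture(scope="module")
def truth():
    return sd.generate_screen(sd.SimulationConfig(), seed=8)


class TestGeneratedScreen:
    def test_plate_layout_controls_present(self, truth):
        counts = truth.primary.groupby(["plate_id", "well_type"]).size().unstack()
        assert (counts["media"] == 3).all()
        assert (counts["vehicle"] == 3).all()
        assert (counts["enhancer_control"] == 3).all()
        assert (counts["inhibitor_control"] == 3).all()

    def test_strong_true_hits_called_in_primary(self, truth):
        normalized = screen.normalize_plate(screen.qc_wells(truth.primary))
        called = screen.call_primary_hits(normalized)
        strong = truth.compounds[
            truth.compounds["true_hit"]
            & (truth.compounds["true_ec50_um"] < 10.0)
            & (truth.compounds["max_fold"] > 3.5)
        ].index
        recovered = called.loc[strong, "hit"]
        assert recovered.mean() >= 0.9

    def test_secondary_ec50_recovery(self, truth):
        normalized = screen.normalize_plate(screen.qc_wells(truth.secondary))
        compounds = normalized[normalized["well_type"] == "compound"]
        errors = []
        for compound_id, sub in compounds.groupby("compound_id"):
            true_ec50 = truth.compounds.loc[compound_id, "true_ec50_um"]
            if not truth.compounds.loc[compound_id, "true_hit"]:
                continue
            fit = screen.fit_ec50(
                sub["concentration_um"], sub["normalized_response"], compound_id
            )
            if fit.ec50_um is not None and fit.censored is None:
                errors.append(abs(fit.ec50_um - true_ec50) / true_ec50)
        assert len(errors) >= 20
        assert np.median(errors) <= 0.2
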