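"""Tracer arithmetic: ratio/atom%/delta conversions and incorporation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import foramtracer as ft
from foramtracer.errors import DegenerateLabelError, InvalidInputError


@pytest.mark.parametrize("ratio, expected", [
    (0.0112372, 1.1112328),   # VPDB: natural 13C abundance
    (1.0, 50.0),              # symmetric half/half mixture
    (0.0036765, 0.3663004),   # atmospheric N2: natural 15N abundance
])
def test_ratio_to_atom_percent_reference_points(ratio, expected):
    assert ft.ratio_to_atom_percent(ratio) == pytest.approx(expected, abs=5e-6)


@pytest.mark.parametrize("delta, expected", [
    (0.0, 0.0112372),         # at the standard the ratio is the standard's
    (1000.0, 0.0224744),      # +1000 permil doubles the ratio
])
def test_delta_to_ratio_vpdb(delta, expected):
    assert ft.delta_to_ratio(delta, ft.VPDB) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad_call", [
    lambda: ft.ratio_to_atom_percent(0.0),
    lambda: ft.ratio_to_atom_percent(-0.1),
    lambda: ft.delta_to_ratio(-1000.0, ft.VPDB),
    lambda: ft.atom_percent_to_ratio(100.0),
    lambda: ft.excess(0.0, 1.0),
])
def test_conversion_domain_errors(bad_call):
    with pytest.raises(InvalidInputError):
        bad_call()


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(min_value=1e-6, max_value=10.0, allow_nan=False))
def test_ratio_atom_percent_round_trip(r):
    assert ft.atom_percent_to_ratio(ft.ratio_to_atom_percent(r)) == pytest.approx(r, rel=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.floats(min_value=-999.0, max_value=5000.0))
def test_delta_ratio_round_trip(delta):
    assert ft.ratio_to_delta(ft.delta_to_ratio(delta, ft.AIR_N2), ft.AIR_N2) \
        == pytest.approx(delta, abs=1e-9)


@pytest.mark.parametrize("sample, background, expected", [
    (1.30, 1.11, 0.19),
    (2.5, 2.5, 0.0),
    (5.00, 1.11123, 3.88877),
])
def test_excess_is_plain_subtraction(sample, background, expected):
    assert ft.excess(sample, background) == pytest.approx(expected, rel=1e-12)


def _incorp(atom_sample, total, background=1.0, food=51.0, n=10, dw=100.0):
    return ft.incorporation(sample_id="s", element="C", atom_pct_sample=atom_sample,
                            total_element_ug=total, n_individuals=n,
                            dry_weight_ug=dw, background_atom_pct=background,
                            food_atom_pct=food)


class TestIncorporation:
    def test_control_sample_yields_zero(self):
        rec = _incorp(atom_sample=1.0, total=10.0)
        assert rec.i_iso_ug == 0.0
        assert rec.i_phyto_ug == 0.0
        assert rec.fraction_of_total_pct == 0.0

    def test_pure_label_limit_identity(self):
        # food at 100 atom% against ~zero background: I_phyto == I_iso
        rec = ft.incorporation(sample_id="s", element="C", atom_pct_sample=5.0,
                               total_element_ug=10.0, n_individuals=1,
                               dry_weight_ug=100.0, background_atom_pct=1e-9,
                               food_atom_pct=100.0)
        assert rec.i_phyto_ug == pytest.approx(rec.i_iso_ug, rel=1e-7)

    def test_worked_example(self):
        # TOC 10 ug, E = 1 atom%, food excess 50 atom% -> I_iso 0.1 ug, pC 0.2 ug
        rec = _incorp(atom_sample=2.0, total=10.0, background=1.0, food=51.0)
        assert rec.excess_clamped == pytest.approx(1.0, rel=1e-12)
        assert rec.i_iso_ug == pytest.approx(0.1, rel=1e-12)
        assert rec.i_phyto_ug == pytest.approx(0.2, rel=1e-12)
        assert rec.per_individual_ug == pytest.approx(0.02, rel=1e-12)
        assert rec.fraction_of_total_pct == pytest.approx(2.0, rel=1e-12)

    def test_negative_excess_preserved_but_clamped(self):
        rec = _incorp(atom_sample=0.9, total=10.0)
        assert rec.excess_raw == pytest.approx(-0.1, rel=1e-9)
        assert rec.excess_clamped == 0.0
        assert rec.i_phyto_ug == 0.0

    def test_degenerate_label_rejected(self):
        with pytest.raises(DegenerateLabelError):
            _incorp(atom_sample=2.0, total=10.0, background=5.0, food=4.0)

    def test_grid_matches_direct_formula(self):
        # brute-force oracle: three-line direct evaluation over a parameter grid
        for e in (0.01, 0.5, 2.0, 10.0, 40.0):
            for total in (0.5, 5.0, 50.0):
                for food_excess in (10.0, 50.0, 96.9):
                    bg = 1.0
                    rec = _incorp(atom_sample=bg + e, total=total,
                                  background=bg, food=bg + food_excess)
                    i_iso = e / 100.0 * total
                    i_phyto = i_iso / (food_excess / 100.0)
                    assert rec.i_iso_ug == pytest.approx(i_iso, rel=1e-12)
                    assert rec.i_phyto_ug == pytest.approx(i_phyto, rel=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(e=st.floats(min_value=0.01, max_value=50.0),
       total=st.floats(min_value=0.1, max_value=100.0),
       k=st.floats(min_value=0.1, max_value=10.0))
def test_incorporation_linear_in_total_and_monotone_in_excess(e, total, k):
    bg = 1.0
    rec = _incorp(atom_sample=bg + e, total=total, background=bg, food=98.0)
    scaled = _incorp(atom_sample=bg + e, total=k * total, background=bg, food=98.0)
    assert scaled.i_phyto_ug == pytest.approx(k * rec.i_phyto_ug, rel=1e-9)
    bigger = _incorp(atom_sample=bg + min(e * 1.5, 98.0), total=total,
                     background=bg, food=98.0)
    assert bigger.i_phyto_ug > rec.i_phyto_ug


class TestBatchAndTransformer:
    def test_batch_cardinality_and_loop_oracle(self, default_samples):
        samples, _ = default_samples
        bg = {"C": ft.natural_background("C"), "N": ft.natural_background("N")}
        out = ft.batch_incorporation(samples, bg, ft.FoodSource())
        assert len(out) == 2 * len(samples)
        # row-by-row oracle
        for _, row in samples.iterrows():
            rec = ft.incorporation(
                sample_id=row.sample_id, element="C",
                atom_pct_sample=row.atom13C_pct, total_element_ug=row.TOC_ug,
                n_individuals=int(row.n_individuals), dry_weight_ug=row.dry_weight_ug,
                background_atom_pct=bg["C"], food_atom_pct=98.0)
            got = out[(out.sample_id == row.sample_id) & (out.element == "C")]
            assert got["i_phyto_ug"].iloc[0] == pytest.approx(rec.i_phyto_ug, rel=1e-12)

    def test_all_controls_yield_zero(self):
        bg = {"C": 1.1, "N": 0.37}
        df = pd.DataFrame({
            "sample_id": ["c1", "c2"], "treatment": ["control"] * 2,
            "day": [0, 0], "size_fraction": ["mixed"] * 2,
            "n_individuals": [10, 10], "dry_weight_ug": [100.0, 90.0],
            "TOC_ug": [10.0, 9.0], "TN_ug": [2.0, 1.8],
            "atom13C_pct": [1.1, 1.1], "atom15N_pct": [0.37, 0.37],
        })
        out = ft.batch_incorporation(df, bg, ft.FoodSource())
        assert (out["i_phyto_ug"] == 0.0).all()

    def test_transformer_learns_background_from_controls(self):
        df = pd.DataFrame({
            "sample_id": ["c1", "c2", "s1"],
            "treatment": ["control", "control", "single_pulse"],
            "day": [0, 0, 2], "size_fraction": ["mixed"] * 3,
            "n_individuals": [10, 10, 10], "dry_weight_ug": [100.0] * 3,
            "TOC_ug": [10.0] * 3, "TN_ug": [2.0] * 3,
            "atom13C_pct": [1.2, 1.4, 5.0], "atom15N_pct": [0.4, 0.5, 2.0],
        })
        tr = ft.TracerIncorporation(background="controls").fit(df)
        assert tr.background_atom_pct_["C"] == pytest.approx(1.3)
        assert tr.background_atom_pct_["N"] == pytest.approx(0.45)
        assert tr.n_controls_ == 2
        # sklearn-style params round trip
        assert ft.TracerIncorporation().set_params(**tr.get_params()).get_params() \
            == tr.get_params()

    def test_transformer_natural_background_default(self):
        tr = ft.TracerIncorporation().fit(pd.DataFrame())
        assert tr.background_atom_pct_["C"] == pytest.approx(1.1112328, abs=5e-6)
        assert tr.background_atom_pct_["N"] == pytest.approx(0.3663004, abs=5e-6)
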