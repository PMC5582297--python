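"""PSM filtering, reporter QC, protein summation, folds, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oftquant.proteomics_quant import (
    CHANNELS,
    bh_fdr,
    differential_abundance,
    filter_psms,
    normalize_channels,
    reporter_qc,
    reporter_qc_mask,
    signed_fold,
    sum_to_protein,
)


def _psm_row(peptide, proteins, mass_error, intensities):
    row = {"peptide_id": peptide, "protein_ids": proteins, "mass_error_ppm": mass_error}
    row.update(dict(zip(CHANNELS, intensities)))
    return row


def _table(rows):
    return pd.DataFrame(rows)


class TestIdentificationFilters:
    def test_mass_error_and_uniqueness_rules(self):
        rows = [
            _psm_row("p1", "A", 25.0, [1000] * 10),   # mass error too high
            _psm_row("p2", "A;B", 5.0, [1000] * 10),  # ambiguous mapping
            _psm_row("p3", "A", -19.9, [1000] * 10),  # kept (absolute value)
            _psm_row("p4", "A", 20.0, [1000] * 10),   # boundary: not < 20
        ]
        kept = filter_psms(_table(rows))
        assert list(kept["peptide_id"]) == ["p3"]


class TestReporterQc:
    def test_all_500_is_boundary_drop(self):
        df = _table([_psm_row("p", "A", 0.0, [500.0] * 10)])
        assert not reporter_qc_mask(df).iloc[0]

    def test_extremes_excluded_before_mean(self):
        intens = [1e6] + [600.0] * 8 + [0.0]
        df = _table([_psm_row("p", "A", 0.0, intens)])
        assert reporter_qc_mask(df).iloc[0]  # trimmed mean 600 > 500

    def test_all_zero_dropped(self):
        df = _table([_psm_row("p", "A", 0.0, [0.0] * 10)])
        assert not reporter_qc_mask(df).iloc[0]

    def test_tie_drops_single_instance_each(self):
        # eight 501s with min/max ties: trimmed mean is 501 > 500 -> keep
        intens = [501.0] * 10
        assert reporter_qc_mask(_table([_psm_row("p", "A", 0.0, intens)])).iloc[0]


class TestSumToProtein:
    def test_single_psm_passthrough(self):
        df = _table([_psm_row("p1", "A", 0.0, list(range(10)))])
        tab = sum_to_protein(df)
        assert list(tab.loc["A", CHANNELS]) == list(range(10))
        assert tab.loc["A", "peptide_count"] == 1

    def test_two_psms_sum_elementwise(self):
        df = _table(
            [
                _psm_row("p1", "A", 0.0, [1.0] * 10),
                _psm_row("p2", "A", 0.0, [2.0] * 10),
                _psm_row("p3", "B", 0.0, [5.0] * 10),
            ]
        )
        tab = sum_to_protein(df)
        assert (tab.loc["A", CHANNELS] == 3.0).all()
        assert tab.loc["A", "peptide_count"] == 2
        assert tab.loc["B", "peptide_count"] == 1

    def test_empty_input_gives_empty_table(self):
        tab = sum_to_protein(_table([]).reindex(columns=["peptide_id", "protein_ids"]))
        assert len(tab) == 0


class TestNormalization:
    def test_equal_totals_is_identity(self):
        tab = sum_to_protein(_table([_psm_row("p", "A", 0.0, [100.0] * 10)]))
        out = normalize_channels(tab)
        assert np.allclose(out[CHANNELS], tab[CHANNELS])

    def test_doubled_channel_restored(self, rng):
        vals = rng.uniform(100, 1000, size=(20, 10))
        tab = pd.DataFrame(vals, columns=CHANNELS)
        tab["peptide_count"] = 1
        doubled = tab.copy()
        doubled["c3"] = doubled["c3"] * 2.0
        out = normalize_channels(doubled)
        totals = out[CHANNELS].sum(axis=0)
        assert np.allclose(totals, totals.mean(), rtol=1e-9)
        base = normalize_channels(tab)
        ratio = out[CHANNELS].to_numpy() / base[CHANNELS].to_numpy()
        assert np.allclose(ratio, ratio[0, 0])  # restored up to global scale

    def test_zero_channel_total_rejected(self):
        tab = pd.DataFrame(np.zeros((3, 10)), columns=CHANNELS)
        with pytest.raises(ValueError, match="total"):
            normalize_channels(tab)


class TestSignedFold:
    @pytest.mark.parametrize(
        "ratio,expected", [(1.5, 1.5), (1.0, 1.0), (1 / 1.2, -1.2), (0.5, -2.0)]
    )
    def test_convention(self, ratio, expected):
        assert signed_fold(ratio) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            signed_fold(0.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_reciprocal_symmetry(self, r):
        assert abs(signed_fold(r)) == pytest.approx(abs(signed_fold(1.0 / r)), rel=1e-9)
        assert abs(signed_fold(r)) >= 1.0


def _naive_bh(p):
    """O(m^2) step-up oracle straight from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 1.0])
        assert np.allclose(q, [0.04, 0.04, 0.04, 1.0])

    def test_matches_naive_oracle_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            q = bh_fdr(p)
            assert np.allclose(q, _naive_bh(p), atol=0, rtol=0)
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, q_sm)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(0, 1, 100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert q.max() <= 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDifferentialAbundance:
    def _null_table(self, rng, n=50):
        vals = rng.lognormal(8, 1, size=(n, 10))
        tab = pd.DataFrame(vals, columns=CHANNELS, index=[f"P{i}" for i in range(n)])
        tab["peptide_count"] = 2
        return tab

    def test_swapping_groups_negates_folds_keeps_p(self, rng):
        tab = self._null_table(rng)
        res = differential_abundance(tab, normalize=False)
        swapped = tab.copy()
        swapped[CHANNELS] = tab[[*CHANNELS[5:], *CHANNELS[:5]]].to_numpy()
        res_sw = differential_abundance(swapped, normalize=False)
        # continuous data: ratio is never exactly 1, so folds negate strictly
        assert np.allclose(res["fold"], -res_sw["fold"])
        assert np.allclose(res["p"], res_sw["p"])

    def test_protein_order_permutation_equivariance(self, rng):
        tab = self._null_table(rng)
        perm = tab.sample(frac=1.0, random_state=1)
        res = differential_abundance(tab).sort_index()
        res_p = differential_abundance(perm).sort_index()
        assert np.allclose(res["fold"], res_p["fold"])
        assert np.allclose(res["q"], res_p["q"])

    def test_zero_intensity_pseudocount_flagged(self, rng):
        tab = self._null_table(rng, n=5)
        tab.iloc[0, tab.columns.get_loc("c1")] = 0.0
        res = differential_abundance(tab, normalize=False)
        assert bool(res["pseudocount_used"].iloc[0])
        assert not res["pseudocount_used"].iloc[1:].any()
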