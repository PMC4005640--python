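"""ALEX stream splitting, burst search, ratios, crosstalk and γ calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfluor.alex import (
    AlternationScheme,
    BurstTable,
    CalibrationError,
    CorrectionFactors,
    PhotonStream,
    accurate_E,
    calibrate_gamma,
    correct_counts,
    es_histogram_2d,
    estimate_crosstalk,
    find_bursts,
    raw_es,
    split_streams,
)
from smfluor.synthetic import InstrumentModel, SpeciesModel, simulate_alex_experiment

IDEAL = InstrumentModel(Lk_true=0.0, Dir_true=0.0, gamma_true=1.0,
                        bg_rate_donor_kHz=0.0, bg_rate_acceptor_kHz=0.0)


def make_table(*counts):
    """BurstTable from (F_Dex_Dem, F_Dex_Aem, F_Aex_Aem) tuples."""
    rows = [
        {"t_start": 1000.0 * i, "t_end": 1000.0 * i + 500.0,
         "F_Dex_Dem": c[0], "F_Dex_Aem": c[1], "F_Aex_Aem": c[2], "F_Aex_Dem": 0}
        for i, c in enumerate(counts)
    ]
    return BurstTable(df=pd.DataFrame(rows))


class TestAlternationScheme:
    def test_default_duty_fraction(self):
        assert AlternationScheme().duty_fraction == pytest.approx(0.40)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            AlternationScheme(dex_window=(0, 60), aex_window=(50, 90))

    def test_window_outside_period_rejected(self):
        with pytest.raises(ValueError):
            AlternationScheme(aex_window=(50, 120))


class TestSplitStreams:
    def make_stream(self, times, dets):
        return PhotonStream(np.array(times, dtype=np.int64),
                            np.array(dets, dtype=np.int8))

    def test_window_and_detector_combinations(self):
        stream = self.make_stream([10, 155, 245], [0, 1, 0])
        labels = split_streams(stream)
        assert list(labels) == ["Dex_Dem", "Aex_Aem", "off_window"]

    def test_gap_photon_is_off_window(self):
        assert split_streams(self.make_stream([45], [0]))[0] == "off_window"

    def test_aex_donor_detector(self):
        assert split_streams(self.make_stream([55], [0]))[0] == "Aex_Dem"


class TestFindBursts:
    def test_empty_stream(self):
        stream = PhotonStream(np.array([], dtype=np.int64), np.array([], dtype=np.int8))
        assert len(find_bursts(stream)) == 0

    def test_planted_cluster_found_exactly(self):
        """60 donor photons inside 1 ms (60 kHz ≫ 3 kHz) form exactly one burst."""
        times = sorted(100 * cycle + offset
                       for cycle in range(10)
                       for offset in (5, 10, 15, 20, 25, 30))
        stream = PhotonStream(np.array(times, dtype=np.int64),
                              np.zeros(60, dtype=np.int8))
        table = find_bursts(stream)
        assert len(table) == 1
        assert table.df["F_Dex_Dem"].iloc[0] == 60

    def test_subthreshold_background_yields_no_bursts(self):
        rng = np.random.default_rng(123)
        times = np.unique(rng.integers(0, 10_000_000, size=10_000))  # ~1 kHz for 10 s
        stream = PhotonStream(times.astype(np.int64),
                              rng.integers(0, 2, size=times.size).astype(np.int8))
        assert len(find_bursts(stream)) == 0

    def test_recall_on_planted_bursts(self):
        """Simulated bursts well above threshold are recovered nearly completely."""
        species = [SpeciesModel(true_E=0.5, label_state="dual", fraction=1.0)]
        stream, truth = simulate_alex_experiment(species, IDEAL, 300, seed=21)
        table = find_bursts(stream)
        found = 0
        for _, row in truth.iterrows():
            hit = ((table.df["t_start"] <= row.t_end)
                   & (table.df["t_end"] >= row.t_start))
            found += int(hit.any())
        assert found / len(truth) >= 0.99

    def test_invalid_parameters(self):
        stream = PhotonStream(np.array([1], dtype=np.int64), np.array([0], dtype=np.int8))
        with pytest.raises(ValueError):
            find_bursts(stream, rate_threshold_kHz=0.0)
        with pytest.raises(ValueError):
            find_bursts(stream, smoothing_window_ms=-1.0)


class TestRawES:
    @pytest.mark.parametrize(
        ("counts", "e_expected", "s_expected"),
        [
            ((50, 50, 0), 0.5, 1.0),
            ((10, 30, 40), 0.75, 0.5),
            ((80, 0, 20), 0.0, 0.8),
        ],
    )
    def test_known_ratios(self, counts, e_expected, s_expected):
        table = raw_es(make_table(counts))
        assert table.df["E_raw"].iloc[0] == pytest.approx(e_expected)
        assert table.df["S_raw"].iloc[0] == pytest.approx(s_expected)

    def test_zero_denominator_flagged_not_dropped(self):
        table = raw_es(make_table((0, 0, 40)))
        assert len(table) == 1
        assert not table.df["defined"].iloc[0]
        assert np.isnan(table.df["E_raw"].iloc[0])


class TestCorrectCounts:
    def test_zero_factors_identity(self):
        table = raw_es(make_table((60, 40, 50)))
        corrected = correct_counts(table, CorrectionFactors(Lk=0.0, Dir=0.0))
        assert corrected.df["E_corr"].iloc[0] == table.df["E_raw"].iloc[0]
        assert corrected.df["S_corr"].iloc[0] == table.df["S_raw"].iloc[0]

    def test_donor_only_exact_cancellation(self):
        table = make_table((100, 10, 0))
        corrected = correct_counts(table, CorrectionFactors(Lk=0.10, Dir=0.0))
        assert corrected.df["F_fret_corr"].iloc[0] == 0.0
        assert corrected.df["E_corr"].iloc[0] == 0.0

    def test_arithmetic(self):
        table = make_table((100, 50, 50))
        corrected = correct_counts(table, CorrectionFactors(Lk=0.1, Dir=0.1))
        assert corrected.df["F_fret_corr"].iloc[0] == pytest.approx(35.0)
        assert corrected.df["E_corr"].iloc[0] == pytest.approx(35.0 / 135.0)

    def test_floor_at_zero(self):
        table = make_table((100, 5, 100))
        corrected = correct_counts(table, CorrectionFactors(Lk=0.2, Dir=0.2))
        assert corrected.df["F_fret_corr"].iloc[0] == 0.0


class TestAccurateE:
    def test_gamma_one_reduces_to_proximity_ratio(self):
        table = correct_counts(make_table((60, 40, 50)), CorrectionFactors())
        out = accurate_E(table, CorrectionFactors(gamma=1.0))
        assert out.df["E_acc"].iloc[0] == pytest.approx(out.df["E_corr"].iloc[0])

    def test_zero_fret_count(self):
        table = correct_counts(make_table((60, 0, 50)), CorrectionFactors())
        out = accurate_E(table, CorrectionFactors(gamma=0.9))
        assert out.df["E_acc"].iloc[0] == 0.0

    def test_arithmetic(self):
        table = correct_counts(make_table((40, 60, 0)), CorrectionFactors())
        out = accurate_E(table, CorrectionFactors(gamma=0.75))
        assert out.df["E_acc"].iloc[0] == pytest.approx(60.0 / 90.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        d=st.integers(min_value=1, max_value=200),
        a=st.integers(min_value=0, max_value=200),
        da=st.integers(min_value=1, max_value=50),
        gamma=st.floats(min_value=0.5, max_value=2.0),
    )
    def test_monotone_in_acceptor_count(self, d, a, da, gamma):
        """E_acc never decreases when F_Dex_Aem grows with all else fixed."""
        factors = CorrectionFactors(Lk=0.05, Dir=0.05, gamma=gamma)
        lo = accurate_E(correct_counts(make_table((d, a, 50)), factors), factors)
        hi = accurate_E(correct_counts(make_table((d, a + da, 50)), factors), factors)
        e_lo, e_hi = lo.df["E_acc"].iloc[0], hi.df["E_acc"].iloc[0]
        assert e_hi >= e_lo - 1e-12


@pytest.fixture(scope="module")
def contaminant_run():
    instrument = InstrumentModel(Lk_true=0.10, Dir_true=0.08, gamma_true=1.0,
                                 bg_rate_donor_kHz=0.0, bg_rate_acceptor_kHz=0.0)
    species = [
        SpeciesModel(true_E=0.0, label_state="donor_only", fraction=0.5,
                     brightness_Aex=0.0),
        SpeciesModel(true_E=0.0, label_state="acceptor_only", fraction=0.5),
    ]
    stream, _ = simulate_alex_experiment(species, instrument, 1500, seed=17)
    return raw_es(find_bursts(stream))


class TestEstimateCrosstalk:
    def test_leakage_recovery(self, contaminant_run):
        Lk, _ = estimate_crosstalk(contaminant_run)
        assert Lk == pytest.approx(0.10, abs=0.01)

    def test_direct_excitation_recovery(self, contaminant_run):
        _, Dir = estimate_crosstalk(contaminant_run)
        assert Dir == pytest.approx(0.08, abs=0.01)

    def test_ideal_instrument_no_crosstalk(self):
        species = [
            SpeciesModel(true_E=0.0, label_state="donor_only", fraction=0.5,
                         brightness_Aex=0.0),
            SpeciesModel(true_E=0.0, label_state="acceptor_only", fraction=0.5),
        ]
        stream, _ = simulate_alex_experiment(species, IDEAL, 600, seed=19)
        Lk, Dir = estimate_crosstalk(raw_es(find_bursts(stream)))
        assert Lk == pytest.approx(0.0, abs=0.01)
        assert Dir == pytest.approx(0.0, abs=0.01)

    def test_missing_subpopulation_raises(self):
        species = [SpeciesModel(true_E=0.0, label_state="donor_only", fraction=1.0,
                                brightness_Aex=0.0)]
        stream, _ = simulate_alex_experiment(species, IDEAL, 200, seed=23)
        with pytest.raises(CalibrationError):
            estimate_crosstalk(raw_es(find_bursts(stream)))


class TestCalibrateGamma:
    def test_single_standard_rejected(self):
        table = correct_counts(raw_es(make_table((50, 50, 50))), CorrectionFactors())
        with pytest.raises(CalibrationError):
            calibrate_gamma([table])

    def test_indistinguishable_standards_rejected(self):
        t = correct_counts(raw_es(make_table(*[(50, 50, 50)] * 30)), CorrectionFactors())
        with pytest.raises(CalibrationError):
            calibrate_gamma([t, t])


class TestStoichiometryDiscrimination:
    def test_species_separate_in_S(self, free_run, free_table):
        """Donor-only bursts sit at S>0.85, acceptor-only at S<0.15."""
        _, truth = free_run
        df = free_table.df
        donor_only = df[df["S_raw"] > 0.85]
        acceptor_only = df[df["S_raw"] < 0.15]
        exp_donor = 0.15 * len(truth)
        exp_acceptor = 0.10 * len(truth)
        assert len(donor_only) == pytest.approx(exp_donor, rel=0.25)
        assert len(acceptor_only) == pytest.approx(exp_acceptor, rel=0.25)


class TestEsHistogram2d:
    def test_single_burst_single_cell(self):
        table = raw_es(make_table((50, 50, 100)))
        counts, _, _ = es_histogram_2d(table)
        assert counts.sum() == 1
        assert np.count_nonzero(counts) == 1

    def test_counts_conserved(self, free_table):
        counts, _, _ = es_histogram_2d(free_table)
        assert counts.sum() == free_table.df["defined"].sum()

    def test_two_modes_in_E(self, free_run, free_table):
        """The two dual species appear as separate E modes in the mid-S band."""
        counts, e_edges, s_edges = es_histogram_2d(free_table, bin_E=0.05, bin_S=0.05)
        mid = (s_edges[:-1] >= 0.3) & (s_edges[:-1] < 0.8)
        profile = counts[:, mid].sum(axis=1)
        e_centers = 0.5 * (e_edges[:-1] + e_edges[1:])
        # modes near the raw proximity ratios of the two dual species
        top2 = e_centers[np.argsort(profile)[::-1][:4]]
        assert any(abs(top2 - 0.75) < 0.1)
        assert any(abs(top2 - 0.55) < 0.15)
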