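import numpy as np
import pandas as pd
import pytest

from weanling import mixing
from weanling.mixing import (
    MixingConfigError,
    MixingConstraints,
    build_mixing_model,
    default_source_table,
    fit_mixing,
    read_sources,
    write_sources,
)


@pytest.fixture(scope="module")
def two_sources():
    return pd.DataFrame(
        {
            "name": ["A", "B"],
            "d13C_mean": [-26.0, -14.0],
            "d13C_sd": [0.1, 0.1],
            "d15N_mean": [4.0, 10.0],
            "d15N_sd": [0.1, 0.1],
            "protein_conc_mean": [1.0, 1.0],
            "protein_conc_sd": [0.01, 0.01],
            "offset_d13C_mean": [4.8, 4.8],
            "offset_d13C_sd": [0.1, 0.1],
            "offset_d15N_mean": [5.5, 5.5],
            "offset_d15N_sd": [0.1, 0.1],
        }
    )


class TestSourceTable:
    def test_demo_preset_contents(self):
        df = default_source_table("roman_italy_demo")
        names = set(df["name"])
        assert {"marine fish", "C4 cereals", "human milk"} <= names
        assert len(df) == 5
        sd_cols = [c for c in df.columns if c.endswith("_sd")]
        assert (df[sd_cols] >= 0).all().all()
        assert (df["protein_conc_mean"] > 0).all()

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="roman_italy_demo"):
            default_source_table("atlantis")

    def test_csv_round_trip_identical(self, tmp_path):
        df = default_source_table()
        path = tmp_path / "sources.csv"
        write_sources(df, path)
        back = read_sources(path)
        pd.testing.assert_frame_equal(back, df)


class TestBuildModel:
    def test_milk_required_when_bins_precede_cessation(self, two_sources):
        constraints = MixingConstraints(cessation_age=2.0)
        with pytest.raises(MixingConfigError, match="human milk"):
            build_mixing_model(two_sources, constraints,
                               np.array([[0.75, 1.25]]))

    def test_milk_rejected_when_all_bins_after_cessation(self):
        sources = default_source_table()
        constraints = MixingConstraints(cessation_age=2.0)
        with pytest.raises(MixingConfigError, match="post-cessation"):
            build_mixing_model(sources, constraints, np.array([[3.0, 3.5]]))

    def test_constraints_validation(self):
        with pytest.raises(ValueError):
            MixingConstraints(cessation_age=0.3, milk_exclusive_until=0.5)

    def test_cessation_age_moves_first_zero_bin(self):
        """Shifting the cessation age relabels exactly the bins at or
        beyond it, leaving earlier bins' structure unchanged."""
        sources = default_source_table()
        bins = np.array([[0.25, 0.75], [0.75, 1.25], [1.25, 1.75],
                         [1.75, 2.25], [2.25, 2.75]])
        m1 = build_mixing_model(
            sources, MixingConstraints(cessation_age=1.25), bins
        )
        m2 = build_mixing_model(
            sources, MixingConstraints(cessation_age=2.25), bins
        )
        np.testing.assert_array_equal(m1.zero_milk_bins,
                                      [False, False, True, True, True])
        np.testing.assert_array_equal(m2.zero_milk_bins,
                                      [False, False, False, False, True])
        np.testing.assert_array_equal(m1.free_milk_bins[:2],
                                      m2.free_milk_bins[:2])


class TestFitMixing:
    def test_pure_endmember_identified(self, two_sources):
        """A consumer sitting exactly on source A's signature + offset is
        attributed to A."""
        consumer = pd.DataFrame(
            {"bin_start": [1.0], "bin_end": [1.5],
             "d13C": [-26.0 + 4.8], "d15N": [4.0 + 5.5]}
        )
        model = build_mixing_model(two_sources, None, np.array([[1.0, 1.5]]))
        est = fit_mixing(model, consumer, seed=1)
        assert est.draws.mean(axis=0)[0, 0] >= 0.9

    def test_symmetric_sources_exchangeable(self, two_sources):
        """Identical sources are statistically indistinguishable: the
        posterior splits evenly within Monte Carlo error."""
        sym = two_sources.copy()
        sym.loc[1, ["d13C_mean", "d15N_mean"]] = sym.loc[
            0, ["d13C_mean", "d15N_mean"]
        ].to_numpy()
        consumer = pd.DataFrame(
            {"bin_start": [1.0], "bin_end": [1.5],
             "d13C": [-26.0 + 4.8], "d15N": [4.0 + 5.5]}
        )
        model = build_mixing_model(sym, None, np.array([[1.0, 1.5]]))
        est = fit_mixing(model, consumer, seed=2)
        np.testing.assert_allclose(est.draws.mean(axis=0)[0], 0.5, atol=0.05)

    def test_simplex_closure_every_draw(self, two_sources):
        consumer = pd.DataFrame(
            {"bin_start": [1.0], "bin_end": [1.5],
             "d13C": [-18.0], "d15N": [12.0]}
        )
        model = build_mixing_model(two_sources, None, np.array([[1.0, 1.5]]))
        est = fit_mixing(model, consumer, seed=3)
        assert np.abs(est.draws.sum(axis=2) - 1.0).max() < 1e-9
        assert (est.draws >= 0).all()

    def test_milk_constraints_hold_in_every_draw(self):
        """Exclusive, monotone-declining, and post-cessation-zero milk
        structure is exact, not approximate."""
        sources = default_source_table()
        sources = sources[sources["name"].isin(
            ["C3 plants", "terrestrial animals", "human milk"]
        )].reset_index(drop=True)
        bins = np.array([[0.25, 0.5], [0.5, 1.0], [1.0, 1.5], [1.5, 2.0],
                         [2.0, 2.5]])
        constraints = MixingConstraints(cessation_age=2.0)
        model = build_mixing_model(sources, constraints, bins)
        milk_sig = sources[sources["name"] == "human milk"]
        d13 = float(milk_sig["d13C_mean"].iloc[0] + 4.8)
        d15 = float(milk_sig["d15N_mean"].iloc[0] + 5.5)
        fm = np.array([1.0, 0.8, 0.5, 0.2, 0.0])
        veg = np.array([-25.5 + 4.8, 3.5 + 5.5])
        consumer = pd.DataFrame(
            {"bin_start": bins[:, 0], "bin_end": bins[:, 1],
             "d13C": fm * d13 + (1 - fm) * veg[0],
             "d15N": fm * d15 + (1 - fm) * veg[1]}
        )
        est = fit_mixing(model, consumer, seed=4)
        mi = model.milk_index
        milk = est.draws[:, :, mi]
        assert (milk[:, 0] >= 0.95).all()  # exclusive bin
        assert (np.diff(milk, axis=1) <= 1e-12).all()  # descendant trend
        assert (milk[:, -1] == 0.0).all()  # post-cessation zero

    def test_mismatched_bins_rejected(self, two_sources):
        model = build_mixing_model(two_sources, None, np.array([[1.0, 1.5]]))
        consumer = pd.DataFrame(
            {"bin_start": [2.0], "bin_end": [2.5], "d13C": [-20.0],
             "d15N": [10.0]}
        )
        with pytest.raises(ValueError, match="bins"):
            fit_mixing(model, consumer, seed=5)
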