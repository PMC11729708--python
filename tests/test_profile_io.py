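import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weanling import profile_io, synthetic
from weanling.profile_io import (
    QCCriteria,
    SchemaError,
    ValidationError,
    cn_atomic_ratio,
    qc_filter,
    read_increments,
    write_table,
)


class TestCnAtomicRatio:
    @pytest.mark.parametrize(
        "pct_C, pct_N, expected",
        [
            (42.0, 15.0, 3.266),  # hand arithmetic (42/12.011)/(15/14.007)
            (12.011, 14.007, 1.0),  # definition identity
            (24.022, 14.007, 2.0),  # doubling linearity
        ],
    )
    def test_known_values(self, pct_C, pct_N, expected):
        assert cn_atomic_ratio(pct_C, pct_N) == pytest.approx(expected, abs=1e-3)

    @given(st.floats(0.01, 1000.0), st.floats(0.01, 1000.0), st.floats(0.001, 50.0))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, c, n, k):
        assert cn_atomic_ratio(k * c, k * n) == pytest.approx(
            cn_atomic_ratio(c, n), rel=1e-9
        )

    @pytest.mark.parametrize("c, n", [(0.0, 10.0), (10.0, -1.0)])
    def test_nonpositive_rejected(self, c, n):
        with pytest.raises(ValueError):
            cn_atomic_ratio(c, n)


class TestReadWrite:
    def test_round_trip_preserves_values(self, tmp_path):
        cohort, _ = synthetic.generate_cohort(
            {"s": {"mu_cessation": 2.0, "sd_cessation": 0.3, "n": 2}}, seed=3
        )
        path = tmp_path / "cohort.csv"
        write_table(cohort, path, header_comment="round trip")
        back = read_increments(path)
        for col in ("d13C", "d15N", "pct_C", "pct_N", "position_end_mm"):
            np.testing.assert_allclose(
                back[col].to_numpy(), cohort[col].to_numpy(), atol=1e-9
            )

    def test_schema_mapping_and_missing_column(self, tmp_path, weaning_profile):
        renamed = weaning_profile.rename(columns={"d15N": "δ15N (AIR)"})
        path = tmp_path / "renamed.csv"
        renamed.to_csv(path, index=False)
        back = read_increments(path, schema={"d15N": "δ15N (AIR)"})
        np.testing.assert_allclose(back["d15N"], weaning_profile["d15N"])
        with pytest.raises(SchemaError, match="d15N"):
            read_increments(path)

    def test_position_order_violation_names_individual(
        self, tmp_path, weaning_profile
    ):
        bad = weaning_profile.copy()
        # swap the positions of increments 2 and 3 without renumbering
        cols = ["position_start_mm", "position_end_mm"]
        i2, i3 = bad.index[1], bad.index[2]
        bad.loc[i2, cols], bad.loc[i3, cols] = (
            bad.loc[i3, cols].to_numpy(),
            bad.loc[i2, cols].to_numpy(),
        )
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="SYN1"):
            read_increments(path)

    def test_gap_in_increment_index_rejected(self, weaning_profile):
        bad = weaning_profile.copy()
        bad.loc[bad.index[-1], "increment_index"] = 99
        with pytest.raises(ValidationError, match="contiguous"):
            profile_io.validate_increments(bad)


class TestQcFilter:
    def _profile(self, cn, pct_C, pct_N, n=10):
        return pd.DataFrame(
            {
                "individual_id": "X1",
                "site": "s",
                "tooth": "M1",
                "increment_index": np.arange(1, n + 1),
                "position_start_mm": np.arange(n, dtype=float),
                "position_end_mm": np.arange(1, n + 1, dtype=float),
                "d13C": -19.0,
                "d15N": 10.0,
                "pct_C": pct_C,
                "pct_N": pct_N,
            }
        )

    def test_all_within_bounds_retained(self):
        report = qc_filter(self._profile(3.2, 40.0, 14.0))
        assert report.increments["qc_pass"].all()
        assert report.retained_ids == ["X1"]

    def test_all_outside_bounds_excluded(self):
        # C:N atomic 4.5 with adequate elemental content
        pct_N = 14.0
        pct_C = 4.5 * pct_N * 12.011 / 14.007
        report = qc_filter(self._profile(None, pct_C, pct_N))
        assert not report.increments["qc_pass"].any()
        assert report.individuals["status"].tolist() == ["excluded"]

    def test_poorly_preserved_individual_excluded_wholesale(self):
        """A profile with 60% failing increments is dropped as a whole,
        the way a badly preserved archaeological sample is."""
        truth = synthetic.SyntheticTruth(seed=5, degrade=True)
        df, _ = synthetic.generate_individual(truth, "degraded-01")
        report = qc_filter(df)
        n_fail = int((~report.increments["qc_pass"]).sum())
        assert n_fail / len(df) == pytest.approx(0.6, abs=0.05)
        assert report.individuals["status"].tolist() == ["excluded"]

    def test_idempotent_and_order_independent(self, weaning_profile):
        rep1 = qc_filter(weaning_profile)
        shuffled = weaning_profile.sample(frac=1.0, random_state=0)
        rep2 = qc_filter(shuffled)
        assert (
            rep1.individuals["status"].tolist()
            == rep2.individuals["status"].tolist()
        )
        merged = rep2.increments.sort_values("increment_index")
        assert (
            merged["qc_pass"].to_numpy()
            == rep1.increments["qc_pass"].to_numpy()
        ).all()

    def test_empty_profile_rejected(self, weaning_profile):
        with pytest.raises(ValidationError):
            qc_filter(weaning_profile.iloc[0:0])

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            QCCriteria(cn_atomic_min=3.6, cn_atomic_max=2.9)
        with pytest.raises(ValueError):
            QCCriteria(max_failed_fraction=1.5)
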