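import numpy as np
import pandas as pd
import pytest

from stcmix import (
    Direction,
    GeneratorConfig,
    LogisticCRC,
    Treatment,
    TrueScenario,
    fit_ll4,
    hypoactivity_effect,
    max_effect_from_fit,
    mean_multiplier,
    percent_change,
    simulate_dataset,
    standardize_hyperactivity,
    to_crc_dataset,
    truncate_at_peak,
)
from stcmix.exceptions import (
    DegenerateControlError,
    IngestionError,
    NormalizationError,
    ParameterError,
)


def records_from(counts_by_conc, experiment="E1"):
    rows = []
    for conc, counts in counts_by_conc.items():
        for i, c in enumerate(counts):
            rows.append(
                {
                    "substance": "s",
                    "concentration_um": conc,
                    "embryo_id": f"{experiment}-{conc}-{i}",
                    "stc_per_min": float(c),
                    "replicate": "r1",
                    "experiment": experiment,
                }
            )
    return pd.DataFrame(rows)


class TestPercentChange:
    def test_basic_arithmetic(self):
        rec = records_from({0.0: [6, 6], 1.0: [9, 9]})
        out = percent_change(rec)
        assert out["percent_change"].iloc[0] == pytest.approx(50.0)

    def test_no_change_is_zero(self):
        rec = records_from({0.0: [5, 7], 1.0: [7, 5]})
        out = percent_change(rec)
        assert out["percent_change"].iloc[0] == pytest.approx(0.0)

    def test_experiments_kept_separate(self):
        rec = pd.concat(
            [
                records_from({0.0: [6], 1.0: [9]}, experiment="E1"),
                records_from({0.0: [4], 1.0: [4]}, experiment="E2"),
            ]
        )
        out = percent_change(rec).set_index("experiment")
        assert out.loc["E1", "percent_change"] == pytest.approx(50.0)
        assert out.loc["E2", "percent_change"] == pytest.approx(0.0)

    def test_missing_controls_raise(self):
        rec = records_from({1.0: [9, 9]})
        with pytest.raises(NormalizationError):
            percent_change(rec)

    def test_zero_control_mean_raises(self):
        rec = records_from({0.0: [0, 0], 1.0: [9]})
        with pytest.raises(DegenerateControlError):
            percent_change(rec)

    def test_empty_table_rejected(self):
        with pytest.raises(IngestionError):
            percent_change(pd.DataFrame())

    def test_matches_generator_truth_within_sampling_error(self):
        """Per-concentration percent changes track the programmed effect curve.

        The tolerance is the Monte-Carlo standard error of a dish mean,
        computed from the generator's own count distribution at large n.
        """
        crc = LogisticCRC(slope_b=1.5, inflection_e=2.0)
        t = Treatment("s", ((1.0, crc),), (0.0, 0.5, 2.0, 8.0))
        cfg = GeneratorConfig(
            seed=11, n_embryos_per_dish=400, n_replicates=1, n_experiments=1,
            experiment_effect_sd=0.0,
        )
        df = simulate_dataset(TrueScenario((t,)), cfg)
        out = percent_change(df).set_index("concentration_um")
        for conc in (0.5, 2.0, 8.0):
            true_pc = 100.0 * (mean_multiplier(t, conc) - 1.0)
            mu = 6.0 * mean_multiplier(t, conc)
            # sd of the percent-change estimate from NB counts, 400 embryos
            sd_pt = 100.0 / 6.0 * np.sqrt(
                (mu + 0.05 * mu**2) / 400 + (mu / 6.0) ** 2 * (6.0 + 0.05 * 36.0) / 400
            )
            assert abs(out.loc[conc, "percent_change"] - true_pc) < 4 * sd_pt


class TestStandardization:
    @pytest.mark.parametrize(
        "raw, m, expected",
        [
            (41.0, 82.0, 50.0),  # half of a partial maximum maps to 50
            (24.0, 48.0, 50.0),
            (33.0, 100.0, 33.0),  # full-effect substance: identity
        ],
    )
    def test_divisor_scaling(self, raw, m, expected):
        assert standardize_hyperactivity(raw, m) == pytest.approx(expected)

    @pytest.mark.parametrize("m", [0.0, -5.0, np.nan])
    def test_invalid_divisor_rejected(self, m):
        with pytest.raises(ParameterError):
            standardize_hyperactivity(50.0, m)

    def test_order_preserving(self):
        vals = np.array([3.0, 18.0, 44.0, 61.0, 80.0])
        out = standardize_hyperactivity(vals, 82.0)
        assert np.all(np.argsort(out) == np.argsort(vals))

    def test_max_effect_from_fitted_ceiling(self):
        from stcmix import CrcDataset, ll4_effect

        truth = LogisticCRC(slope_b=1.7, inflection_e=2.0, ceiling_d=82.0)
        conc = np.geomspace(0.2, 50, 8)
        fit = fit_ll4(
            CrcDataset(conc, ll4_effect(conc, truth)), fix_ceiling=False
        )
        assert max_effect_from_fit(fit) == pytest.approx(82.0, rel=1e-5)

    def test_max_effect_rejects_hypoactivity_curve(self):
        crc = LogisticCRC(slope_b=1.0, inflection_e=1.0, direction=Direction.HYPOACTIVITY)
        with pytest.raises(ParameterError):
            max_effect_from_fit(crc)


class TestHypoactivity:
    def test_sign_convention(self):
        assert hypoactivity_effect(-40.0) == pytest.approx(40.0)

    def test_clamped_at_full_suppression(self):
        with pytest.warns(RuntimeWarning):
            out = hypoactivity_effect(np.array([-120.0, -30.0]))
        assert out[0] == pytest.approx(100.0)
        assert out[1] == pytest.approx(30.0)


class TestPoolingAndTruncation:
    def test_pooled_fit_invariant_to_experiment_relabeling(self):
        crc = LogisticCRC(slope_b=1.5, inflection_e=2.0)
        t = Treatment("s", ((1.0, crc),), (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0))
        df = simulate_dataset(TrueScenario((t,)), GeneratorConfig(seed=5))
        norm1 = percent_change(df)
        relabeled = df.copy()
        relabeled["experiment"] = relabeled["experiment"].map({"E1": "B", "E2": "A"})
        norm2 = percent_change(relabeled)
        f1 = fit_ll4(to_crc_dataset(norm1, Direction.HYPERACTIVITY))
        f2 = fit_ll4(to_crc_dataset(norm2, Direction.HYPERACTIVITY))
        assert f1.inflection_e == pytest.approx(f2.inflection_e, rel=1e-6)

    def test_truncation_drops_declining_limb(self):
        norm = pd.DataFrame(
            {
                "experiment": "E1",
                "concentration_um": [0.5, 1.0, 2.0, 4.0, 8.0],
                "percent_change": [10.0, 30.0, 60.0, 40.0, -20.0],
                "se_percent": 5.0,
                "n_embryos": 40,
            }
        )
        out = truncate_at_peak(norm)
        assert out["concentration_um"].max() == 2.0
        assert len(out) == 3
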