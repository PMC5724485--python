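import numpy as np
import pytest

from trajarea.config import GeneratorConfig, InstrumentSpec, default_config, simple_config
from trajarea.generator import generate_trial

from conftest import null_default_config


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = default_config(seed=5)
        assert generate_trial(cfg) == generate_trial(cfg)

    def test_seed_override(self):
        cfg = default_config(seed=5)
        a = generate_trial(cfg, seed=9)
        b = generate_trial(cfg, seed=9)
        c = generate_trial(cfg, seed=10)
        assert a == b
        assert a != c


class TestInvariants:
    def test_schema_invariants(self, default_dataset):
        df = default_dataset.df
        assert df["participant_id"].is_unique
        maci = df.filter(like="maci_")
        assert ((maci >= 1) & (maci <= 7) | maci.isna()).all().all()
        dcma = df.filter(like="dcma_")
        assert ((dcma >= 0) & (dcma <= 1) | dcma.isna()).all().all()
        ages = df[["age_9", "age_15", "age_27", "age_39"]].to_numpy()
        assert (np.diff(ages, axis=1) > 0).all()

    def test_counts_are_nonnegative_integers(self, default_dataset):
        for col in ("aosi_9", "aosi_15", "ados_27", "ados_39"):
            vals = default_dataset.df[col].dropna()
            assert (vals >= 0).all()
            assert np.allclose(vals, np.round(vals))

    def test_no_all_missing_baseline(self, default_dataset):
        base = default_dataset.df[["aosi_9", "maci_att_9", "maci_nondir_9",
                                   "mullen_rl_9", "mullen_el_9",
                                   "vineland_comm_9", "vineland_soc_9"]]
        assert not base.isna().all(axis=1).any()

    def test_allocation(self, default_dataset):
        counts = default_dataset.df["arm"].value_counts()
        assert counts["intervention"] == 28
        assert counts["control"] == 26


class TestConfigValidation:
    def test_non_pd_correlation_rejected(self):
        with pytest.raises(ValueError, match="score.*not positive-definite"):
            simple_config(rho=1.0)

    def test_nonzero_baseline_effect_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            simple_config(effect_curve=(0.1, 0, 0, 0))

    def test_missingness_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="missingness"):
            simple_config(missingness={"control": {39: 1.4}})

    def test_diagnostic_probs_must_sum_to_one(self):
        cfg = simple_config()
        cfg.diagnostic_probs["control"] = (0.5, 0.4, 0.3)
        with pytest.raises(ValueError, match="diagnostic"):
            cfg.validate()

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            GeneratorConfig.from_dict({"bogus_knob": 1})

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = simple_config(effect_curve=(0, -0.2, -0.4, -0.1), seed=3)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        cfg2 = GeneratorConfig.from_yaml(path)
        assert generate_trial(cfg) == generate_trial(cfg2)


class TestNullConfiguration:
    def test_zero_effect_zero_arm_difference(self):
        # null configuration: identical moments, zero curve -> every outcome's
        # arm difference within 3 Monte-Carlo SEs of 0
        cfg = null_default_config(n_per_arm={"intervention": 10000, "control": 10000}, seed=21)
        df = generate_trial(cfg).df
        grouped = df.groupby("arm")
        for col in df.columns:
            if df[col].dtype.kind != "f" or col.startswith(("age_", "ados_module")):
                continue
            m = grouped[col].mean()
            s = grouped[col].std()
            n = grouped[col].count()
            diff = m["intervention"] - m["control"]
            se = np.sqrt(s["intervention"] ** 2 / n["intervention"] + s["control"] ** 2 / n["control"])
            assert abs(diff) < 3 * se, f"{col}: arm diff {diff:.4f} exceeds 3 SE {3 * se:.4f}"


@pytest.fixture(scope="module")
def big():
    return generate_trial(default_config(n_per_arm={"intervention": 10000, "control": 10000}, seed=1)).df


class TestCalibration:
    def test_ados_27_control_cell(self, big):
        sub = big.loc[big.arm == "control", "ados_27"].dropna()
        assert abs(sub.mean() - 6.32) < 0.5
        assert abs(sub.std() - 6.79) < 0.7

    def test_normal_family_cells_converge(self, big):
        # pure-normal instruments must hit configured moments within 3 MC SEs
        # (plus a small allowance for 2-decimal rounding)
        cfg = default_config()
        inst = next(i for i in cfg.instruments if i.name == "mullen_rl")
        for arm in ("control", "intervention"):
            for t in inst.times:
                vals = big.loc[big.arm == arm, f"mullen_rl_{t}"].dropna()
                n = len(vals)
                target_m, target_s = inst.means[arm][t], inst.sds[arm][t]
                assert abs(vals.mean() - target_m) < 3 * target_s / np.sqrt(n) + 0.01
                assert abs(vals.std() - target_s) < 3 * target_s / np.sqrt(2 * n) + 0.01

    def test_count_family_cells_converge(self, big):
        # lognormal map is moment-matched; integer rounding adds a small bias bound
        cfg = default_config()
        inst = next(i for i in cfg.instruments if i.name == "aosi")
        for arm in ("control", "intervention"):
            for t in inst.times:
                vals = big.loc[big.arm == arm, f"aosi_{t}"].dropna()
                n = len(vals)
                target_m, target_s = inst.means[arm][t], inst.sds[arm][t]
                assert abs(vals.mean() - target_m) < 3 * target_s / np.sqrt(n) + 0.1
                assert abs(vals.std() - target_s) < 3 * target_s / np.sqrt(2 * n) + 0.2

    def test_missingness_fraction(self):
        cfg = simple_config(n_per_arm=2500, seed=8,
                            missingness={"control": {39: 0.2}, "intervention": {39: 0.2}})
        df = generate_trial(cfg).df
        frac = df["score_39"].isna().mean()
        assert abs(frac - 0.2) < 0.02  # binomial SE bound

    def test_effect_curve_shifts_latent_mean(self):
        cfg = simple_config(effect_curve=(0, -0.5, 0, 0), n_per_arm=8000, seed=4, missingness={})
        df = generate_trial(cfg).df
        g = df.groupby("arm")["score_15"]
        d_emp = (g.mean()["intervention"] - g.mean()["control"]) / 10.0
        assert abs(d_emp + 0.5) < 0.05

    def test_diagnostic_probabilities(self):
        cfg = default_config(n_per_arm={"intervention": 20000, "control": 20000}, seed=2)
        df = generate_trial(cfg).df
        frac = (
            df[df.arm == "intervention"]["diagnostic_outcome"].value_counts(normalize=True)
        )
        assert abs(frac["ASD"] - 4 / 27) < 0.01
        assert abs(frac["typical"] - 16 / 27) < 0.015


class TestMnarKnob:
    def test_off_by_default(self):
        assert simple_config().mnar_strength == 0.0

    def test_positive_strength_links_missingness_to_outcome(self):
        base = dict(n_per_arm=4000, seed=77,
                    missingness={"control": {39: 0.3}, "intervention": {39: 0.3}})
        cfg = simple_config(**base)
        cfg.mnar_strength = 2.0
        df = generate_trial(cfg).df
        # under MNAR, observed values at the affected occasion are shifted
        # relative to the full latent distribution (here: high scores missing)
        observed_mean = df["score_39"].dropna().mean()
        assert observed_mean < 50 - 0.5
        cfg0 = simple_config(**base)
        df0 = generate_trial(cfg0).df
        assert abs(df0["score_39"].dropna().mean() - 50) < 0.5
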