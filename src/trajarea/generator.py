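"""Synthetic two-arm trial generator.

Outcomes are drawn on a latent standard-normal scale — correlated across
occasions within a latent group, shifted by the standardized treatment
effect curve in the intervention arm — then pushed through a monotone
per-family map onto the instrument's observed scale.  Missingness is a
missed-visit indicator per arm x occasion (MAR given arm and occasion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from trajarea.config import ARMS, GeneratorConfig
from trajarea.dataset import TrialDataset

DIAGNOSTIC_LEVELS = ("typical", "atypical", "ASD")


def _map_family(z: np.ndarray, family: str, mean: float, sd: float, scale_range) -> np.ndarray:
    if family == "count":
        # moment-matched lognormal: E=mean, SD=sd before integer rounding
        sig2 = np.log1p(sd**2 / mean**2)
        mu = np.log(mean) - sig2 / 2
        return np.round(np.exp(mu + np.sqrt(sig2) * z))
    if family == "scale":
        lo, hi = scale_range
        return np.round(np.clip(mean + sd * z, lo, hi), 1)
    if family == "proportion":
        # delta-method calibration on the logit scale
        return np.round(expit(logit(mean) + sd / (mean * (1 - mean)) * z), 4)
    if family == "normal":
        return np.round(mean + sd * z, 2)
    raise ValueError(f"unknown family {family!r}")


def generate_trial(config: GeneratorConfig, seed: int | None = None) -> TrialDataset:
    """Generate one synthetic trial; identical (config, seed) reproduces it bit-for-bit.

    Parameters
    ----------
    config
        Validated generator configuration; ``config.seed`` is used unless
        ``seed`` overrides it.
    """
    config.validate()
    gaps = np.diff(config.occasion_times)
    if config.age_jitter >= gaps.min() / 2:
        raise ValueError(
            f"age_jitter {config.age_jitter} too large for minimum occasion gap {gaps.min()}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)

    frames = []
    offset = 0
    for arm in ARMS:
        n = config.n_per_arm[arm]
        cols: dict[str, np.ndarray] = {}
        cols["participant_id"] = np.array([f"P{offset + i + 1:03d}" for i in range(n)])
        cols["arm"] = np.repeat(arm, n)
        cols["centre"] = rng.choice(config.centre_levels, size=n, p=[1 - config.centre_prob, config.centre_prob])
        cols["maternal_education"] = 1 + rng.choice(len(config.education_probs), size=n, p=config.education_probs)
        cols["ethnicity"] = rng.binomial(1, config.ethnicity_prob, size=n)
        for t in config.occasion_times:
            cols[f"age_{t}"] = np.round(t + rng.uniform(-config.age_jitter, config.age_jitter, size=n), 1)

        # one correlated latent draw per latent group, shared by its instruments
        latent: dict[tuple[str, float], np.ndarray] = {}
        for group in dict.fromkeys(inst.latent_group for inst in config.instruments):
            times = config.group_times(group)
            corr = config.group_correlation(group)
            z = rng.standard_normal((n, len(times))) @ np.linalg.cholesky(corr).T
            if arm == "intervention":
                z = z + np.array([config.effect_at(t) for t in times])
            for j, t in enumerate(times):
                latent[(group, t)] = z[:, j]

        for inst in config.instruments:
            for t in inst.times:
                cols[f"{inst.name}_{t}"] = _map_family(
                    latent[(inst.latent_group, t)], inst.family,
                    inst.means[arm][t], inst.sds[arm][t], inst.scale_range,
                )
            if inst.name == "ados":
                module = rng.choice([1.0, 2.0], size=n, p=[0.6, 0.4])
                for t in inst.times:
                    cols[f"ados_module_{t}"] = module.copy()
                    module = np.minimum(module + rng.binomial(1, 0.4, size=n), 3.0)

        # missed-visit missingness; MAR given arm x occasion by default.
        # mnar_strength > 0 tilts the miss probability on the logit scale by
        # the participant's mean latent score at that occasion (optional MNAR
        # sensitivity knob, off by default).
        outcome_cols_at = {
            t: [c for c in cols if c not in ("participant_id", "arm", "centre", "maternal_education", "ethnicity")
                and not c.startswith("age_") and c.endswith(f"_{t}")]
            for t in config.occasion_times
        }
        baseline = config.occasion_times[0]
        for t in config.occasion_times:
            p = config.missingness.get(arm, {}).get(t, 0.0)
            if p <= 0 or not outcome_cols_at[t]:
                continue
            if config.mnar_strength:
                zbar = np.mean(
                    [latent[key] for key in latent if key[1] == t], axis=0
                )
                p_i = expit(logit(p) + config.mnar_strength * zbar)
                missed = (rng.uniform(size=n) < p_i)
            else:
                missed = rng.binomial(1, p, size=n).astype(bool)
            keep_first = t == baseline  # never blank an entire baseline visit
            for j, c in enumerate(outcome_cols_at[t]):
                if keep_first and j == 0:
                    continue
                vals = np.asarray(cols[c], dtype=float)
                vals[missed] = np.nan
                cols[c] = vals

        cols["diagnostic_outcome"] = rng.choice(DIAGNOSTIC_LEVELS, size=n, p=config.diagnostic_probs[arm])
        frames.append(pd.DataFrame(cols))
        offset += n

    df = pd.concat(frames, ignore_index=True)
    for c in df.columns:
        if df[c].dtype.kind in "if" and c not in ("maternal_education", "ethnicity"):
            df[c] = df[c].astype(float)
    df["maternal_education"] = df["maternal_education"].astype(np.int64)
    df["ethnicity"] = df["ethnicity"].astype(np.int64)
    dataset = TrialDataset(df)
    dataset.validate()
    return dataset
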