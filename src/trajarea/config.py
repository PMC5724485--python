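"""Generator configuration: instruments, arms, missingness, covariates.

Defaults are calibrated to the published per-arm summary statistics of a
54-infant two-arm trial assessed at 9, 15, 27 and 39 months, with a
symptom-instrument switch after 15 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

ARMS = ("control", "intervention")

#: Instrument families and the monotone map from the latent normal scale:
#:   count      — moment-matched lognormal, rounded to nearest integer >= 0
#:   scale      — normal clipped to [1, 7], rounded to 1 decimal
#:   proportion — logit-mean/delta-method-sd normal passed through a logistic
#:   normal     — untransformed normal, rounded to 1 decimal
FAMILIES = ("count", "scale", "proportion", "normal")


@dataclass
class InstrumentSpec:
    """One outcome instrument measured at a subset of occasions.

    ``means`` / ``sds`` give the target observed-scale mean and SD per arm
    and occasion time.  Instruments sharing ``latent_group`` draw from one
    latent process over the union of their occasion times, so conceptually
    continuous measures stay correlated across an instrument switch.
    """

    name: str
    family: str
    times: tuple
    means: dict
    sds: dict
    latent_group: str = ""
    scale_range: tuple = (1.0, 7.0)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"instrument {self.name!r}: unknown family {self.family!r}")
        self.times = tuple(self.times)
        if not self.latent_group:
            self.latent_group = self.name
        for arm in ARMS:
            for d, what in ((self.means, "means"), (self.sds, "sds")):
                if arm not in d:
                    raise ValueError(f"instrument {self.name!r}: missing {what} for arm {arm!r}")
                missing = [t for t in self.times if t not in d[arm]]
                if missing:
                    raise ValueError(
                        f"instrument {self.name!r}: {what}[{arm!r}] lacks times {missing}"
                    )
        for arm in ARMS:
            for t in self.times:
                if self.sds[arm][t] <= 0:
                    raise ValueError(f"instrument {self.name!r}: sd must be > 0 at {arm}/{t}")
                if self.family == "proportion" and not 0 < self.means[arm][t] < 1:
                    raise ValueError(
                        f"instrument {self.name!r}: proportion mean must be in (0,1) at {arm}/{t}"
                    )
                if self.family == "count" and self.means[arm][t] <= 0:
                    raise ValueError(
                        f"instrument {self.name!r}: count mean must be > 0 at {arm}/{t}"
                    )


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic two-arm trial.

    ``latent_effect_curve`` is a standardized treatment effect added to the
    intervention arm's latent scores, one value per occasion time, zero at
    baseline by randomization.  ``correlations`` maps a latent group name to
    either an exchangeable correlation coefficient or a full cross-occasion
    correlation matrix (list of lists) over that group's occasion times.
    """

    n_per_arm: dict = field(default_factory=lambda: {"intervention": 28, "control": 26})
    occasion_times: tuple = (9, 15, 27, 39)
    latent_effect_curve: tuple = (0.0, 0.0, 0.0, 0.0)
    instruments: list = field(default_factory=list)
    correlations: dict = field(default_factory=dict)
    default_correlation: float = 0.4
    missingness: dict = field(
        default_factory=lambda: {
            "control": {9: 0.0, 15: 0.0, 27: 1 / 26, 39: 2 / 26},
            "intervention": {9: 0.0, 15: 1 / 28, 27: 5 / 28, 39: 1 / 28},
        }
    )
    diagnostic_probs: dict = field(
        default_factory=lambda: {
            "control": (16 / 26, 8 / 26, 2 / 26),
            "intervention": (16 / 27, 7 / 27, 4 / 27),
        }
    )
    centre_levels: tuple = ("manchester", "london")
    centre_prob: float = 0.5
    education_probs: tuple = (0.10, 0.20, 0.40, 0.30)
    ethnicity_prob: float = 0.85
    age_jitter: float = 1.5
    mnar_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.occasion_times = tuple(self.occasion_times)
        self.latent_effect_curve = tuple(float(v) for v in self.latent_effect_curve)
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if len(self.latent_effect_curve) != len(self.occasion_times):
            raise ValueError("latent_effect_curve must have one value per occasion time")
        if self.latent_effect_curve[0] != 0.0:
            raise ValueError(
                "latent_effect_curve must be 0 at the baseline occasion "
                f"(got {self.latent_effect_curve[0]} at t={self.occasion_times[0]})"
            )
        if list(self.occasion_times) != sorted(set(self.occasion_times)):
            raise ValueError("occasion_times must be strictly increasing")
        for arm in ARMS:
            if self.n_per_arm.get(arm, 0) <= 0:
                raise ValueError(f"n_per_arm[{arm!r}] must be a positive integer")
            probs = self.diagnostic_probs[arm]
            if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-8:
                raise ValueError(f"diagnostic_probs[{arm!r}] must be 3 probabilities summing to 1")
            for t, p in self.missingness.get(arm, {}).items():
                if not 0 <= p <= 1:
                    raise ValueError(f"missingness[{arm!r}][{t}]={p} outside [0, 1]")
        for inst in self.instruments:
            bad = [t for t in inst.times if t not in self.occasion_times]
            if bad:
                raise ValueError(f"instrument {inst.name!r}: times {bad} not in occasion_times")
        for group in {inst.latent_group for inst in self.instruments}:
            self.group_correlation(group)  # raises if not PD
        if abs(sum(self.education_probs) - 1) > 1e-8:
            raise ValueError("education_probs must sum to 1")

    # -- derived structure ------------------------------------------------

    def group_times(self, group: str) -> tuple:
        times = sorted({t for inst in self.instruments if inst.latent_group == group for t in inst.times})
        return tuple(times)

    def group_correlation(self, group: str) -> np.ndarray:
        """Cross-occasion latent correlation matrix for one latent group.

        Raises ValueError (naming the group) if the configured matrix is not
        symmetric positive-definite.
        """
        times = self.group_times(group)
        m = len(times)
        spec = self.correlations.get(group, self.default_correlation)
        if np.isscalar(spec):
            rho = float(spec)
            mat = np.full((m, m), rho)
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(spec, dtype=float)
            if mat.shape != (m, m):
                raise ValueError(
                    f"correlation matrix for group {group!r} has shape {mat.shape}, "
                    f"expected {(m, m)} for times {times}"
                )
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ValueError(f"correlation matrix for group {group!r} is not symmetric")
        eigvals = np.linalg.eigvalsh(mat)
        if eigvals.min() <= 1e-10:
            raise ValueError(
                f"correlation matrix for group {group!r} is not positive-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        return mat

    def effect_at(self, time) -> float:
        return self.latent_effect_curve[self.occasion_times.index(time)]

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["instruments"] = [asdict(i) for i in self.instruments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        insts = d.pop("instruments", None)
        base = default_config()
        if insts is not None:
            d["instruments"] = [
                i if isinstance(i, InstrumentSpec) else _instrument_from_dict(i) for i in insts
            ]
        else:
            d["instruments"] = base.instruments
        for key in ("missingness", "diagnostic_probs", "n_per_arm"):
            if key in d:
                d[key] = {arm: _intkeys(v) if key == "missingness" else v for arm, v in d[key].items()}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _intkeys(d: dict) -> dict:
    return {int(k): v for k, v in d.items()}


def _instrument_from_dict(d: dict) -> InstrumentSpec:
    d = dict(d)
    for key in ("means", "sds"):
        d[key] = {arm: _intkeys(v) for arm, v in d[key].items()}
    return InstrumentSpec(**d)


def _per_arm(control: dict, intervention: dict) -> dict:
    return {"control": control, "intervention": intervention}


def default_config(**overrides) -> GeneratorConfig:
    """Trial-calibrated default: 28/26 split, four occasions, full battery."""
    instruments = [
        InstrumentSpec(
            "aosi", "count", (9, 15),
            means=_per_arm({9: 9.08, 15: 7.31}, {9: 10.04, 15: 5.93}),
            sds=_per_arm({9: 5.32, 15: 5.83}, {9: 4.60, 15: 4.05}),
            latent_group="symptoms",
        ),
        InstrumentSpec(
            "ados", "count", (27, 39),
            means=_per_arm({27: 6.32, 39: 5.13}, {27: 4.13, 39: 3.96}),
            sds=_per_arm({27: 6.79, 39: 5.03}, {27: 3.61, 39: 3.68}),
            latent_group="symptoms",
        ),
        InstrumentSpec(
            "maci_att", "scale", (9, 15, 27),
            means=_per_arm({9: 3.65, 15: 4.19, 27: 4.21}, {9: 3.39, 15: 4.22, 27: 4.74}),
            sds=_per_arm({9: 1.29, 15: 1.13, 27: 1.44}, {9: 1.26, 15: 1.05, 27: 1.63}),
            latent_group="child_dyadic",
        ),
        InstrumentSpec(
            "maci_nondir", "scale", (9, 15, 27),
            means=_per_arm({9: 3.73, 15: 3.92, 27: 4.29}, {9: 3.50, 15: 4.67, 27: 5.00}),
            sds=_per_arm({9: 1.43, 15: 1.32, 27: 1.73}, {9: 1.48, 15: 1.24, 27: 1.65}),
            latent_group="parent_dyadic",
        ),
        InstrumentSpec(
            "dcma_init", "proportion", (27, 39),
            means=_per_arm({27: 0.47, 39: 0.44}, {27: 0.57, 39: 0.50}),
            sds=_per_arm({27: 0.20, 39: 0.14}, {27: 0.23, 39: 0.18}),
            latent_group="child_dyadic",
        ),
        InstrumentSpec(
            "dcma_sync", "proportion", (27, 39),
            means=_per_arm({27: 0.46, 39: 0.45}, {27: 0.48, 39: 0.43}),
            sds=_per_arm({27: 0.19, 39: 0.10}, {27: 0.18, 39: 0.14}),
            latent_group="parent_dyadic",
        ),
        InstrumentSpec(
            "mullen_rl", "normal", (9, 15, 27, 39),
            means=_per_arm(
                {9: 50.38, 15: 43.04, 27: 48.92, 39: 50.75},
                {9: 49.89, 15: 36.89, 27: 50.57, 39: 50.30},
            ),
            sds=_per_arm(
                {9: 9.30, 15: 12.11, 27: 13.68, 39: 13.59},
                {9: 9.03, 15: 7.13, 27: 12.64, 39: 12.61},
            ),
        ),
        InstrumentSpec(
            "mullen_el", "normal", (9, 15, 27, 39),
            means=_per_arm(
                {9: 55.04, 15: 49.77, 27: 47.36, 39: 50.88},
                {9: 53.54, 15: 46.52, 27: 49.96, 39: 50.33},
            ),
            sds=_per_arm(
                {9: 9.99, 15: 11.13, 27: 13.96, 39: 12.35},
                {9: 11.27, 15: 8.69, 27: 12.23, 39: 12.37},
            ),
        ),
        InstrumentSpec(
            "vineland_comm", "normal", (9, 15, 27, 39),
            means=_per_arm(
                {9: 92.68, 15: 98.76, 27: 99.76, 39: 95.92},
                {9: 91.78, 15: 93.42, 27: 100.48, 39: 98.27},
            ),
            sds=_per_arm(
                {9: 16.18, 15: 14.74, 27: 16.29, 39: 16.47},
                {9: 18.54, 15: 11.05, 27: 11.97, 39: 12.33},
            ),
        ),
        InstrumentSpec(
            "vineland_soc", "normal", (9, 15, 27, 39),
            means=_per_arm(
                {9: 99.92, 15: 97.76, 27: 98.28, 39: 94.54},
                {9: 94.93, 15: 99.27, 27: 98.04, 39: 95.27},
            ),
            sds=_per_arm(
                {9: 10.33, 15: 13.11, 27: 15.78, 39: 13.73},
                {9: 16.26, 15: 12.04, 27: 10.94, 39: 13.80},
            ),
        ),
    ]
    cfg = dict(instruments=instruments)
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def simple_config(
    effect_curve=(0.0, 0.0, 0.0, 0.0),
    n_per_arm=None,
    rho: float = 0.5,
    missingness: dict | None = None,
    seed: int = 0,
) -> GeneratorConfig:
    """Minimal one-instrument config for calibration studies.

    A single untransformed normal outcome ``score`` (mean 50, SD 10 in both
    arms) at all four occasions; ``effect_curve`` is the standardized
    treatment effect per occasion.  Useful for parameter-recovery, null
    calibration and bootstrap-coverage simulations where instrument maps
    would only add noise.
    """
    inst = InstrumentSpec(
        "score", "normal", (9, 15, 27, 39),
        means=_per_arm({t: 50.0 for t in (9, 15, 27, 39)}, {t: 50.0 for t in (9, 15, 27, 39)}),
        sds=_per_arm({t: 10.0 for t in (9, 15, 27, 39)}, {t: 10.0 for t in (9, 15, 27, 39)}),
    )
    kwargs = dict(
        instruments=[inst],
        latent_effect_curve=tuple(effect_curve),
        default_correlation=rho,
        seed=seed,
    )
    if n_per_arm is not None:
        if np.isscalar(n_per_arm):
            n_per_arm = {"intervention": int(n_per_arm), "control": int(n_per_arm)}
        kwargs["n_per_arm"] = n_per_arm
    if missingness is not None:
        kwargs["missingness"] = missingness
    return GeneratorConfig(**kwargs)
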