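"""Per-occasion regression specification."""

from __future__ import annotations

from dataclasses import dataclass, field

from trajarea.dataset import timed_columns
from trajarea.transforms import VALID_TRANSFORMS


@dataclass
class OccasionSpec:
    """One assessment occasion and its treatment-effect regression.

    ``baseline_column`` is the pre-randomization measure covaried for; it must
    refer to an occasion strictly earlier than ``time`` when its name carries
    a ``_<time>`` suffix.  ``covariate_columns`` are the additional adjustment
    covariates (centre, age-at-assessment, ethnicity, education).  String
    covariates are expanded to indicator codes at design-building time.
    """

    label: str
    time: float
    outcome_column: str
    transform: str = "identity"
    baseline_column: str | None = None
    covariate_columns: tuple = field(default_factory=tuple)
    treatment_column: str = "arm"
    sd_stratum_column: str | None = None

    def __post_init__(self):
        self.covariate_columns = tuple(self.covariate_columns)
        if self.transform not in VALID_TRANSFORMS:
            raise ValueError(f"occasion {self.label!r}: unknown transform {self.transform!r}")
        if not self.treatment_column:
            raise ValueError(f"occasion {self.label!r}: treatment_column is required")
        if self.baseline_column:
            timed = timed_columns([self.baseline_column])
            if self.baseline_column in timed:
                _, btime = timed[self.baseline_column]
                if btime >= self.time:
                    raise ValueError(
                        f"occasion {self.label!r}: baseline column {self.baseline_column!r} "
                        f"(t={btime}) must be strictly earlier than t={self.time}"
                    )

    @classmethod
    def from_dict(cls, d: dict) -> "OccasionSpec":
        d = dict(d)
        d.setdefault("label", f"{d.get('outcome', d.get('outcome_column', 'occ'))}")
        if "outcome" in d:
            d["outcome_column"] = d.pop("outcome")
        if "baseline" in d:
            d["baseline_column"] = d.pop("baseline")
        if "covariates" in d:
            d["covariate_columns"] = tuple(d.pop("covariates"))
        if "sd_stratum" in d:
            d["sd_stratum_column"] = d.pop("sd_stratum")
        return cls(**d)
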