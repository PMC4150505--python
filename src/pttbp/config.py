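"""Run-level configuration shared by the pipeline stages and the CLI."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = ["RunConfig", "PTTV_CONVENTIONS", "FIT_SCOPES"]

PTTV_CONVENTIONS = ("differences_of_5_ptt", "5_differences")
FIT_SCOPES = ("pooled", "leave_one_out")
POPULATION_DESIGNS = ("subject_intercepts", "plain")


@dataclass
class RunConfig:
    """Tunables of the estimation pipeline with their protocol defaults.

    ``pttv_convention`` picks how many successive differences feed PTTV for
    a window parameter W: ``differences_of_5_ptt`` takes the W values of the
    feature window itself (W − 1 differences, the default); ``5_differences``
    extends the variability window by one beat so W differences are used.
    ``population_fit_scope`` controls whether a subject's own sessions enter
    the pooled regression that fixes the compensation constants c and d
    (``pooled``) or are held out (``leave_one_out``, the honest-evaluation
    default).  ``population_design`` chooses that regression's design:
    ``subject_intercepts`` (default) absorbs between-subject BP offsets with
    one intercept per subject, so c and d are identified from within-subject
    session contrasts; ``plain`` is a single shared intercept.
    """

    window_W: int = 5
    filter_window_ms: float = 10.0
    fs_hz: float = 250.0
    pttv_convention: str = "differences_of_5_ptt"
    fluctuation_cv_threshold: float = 0.2
    population_fit_scope: str = "leave_one_out"
    population_design: str = "subject_intercepts"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_W < 3:
            raise ValueError("window_W must be at least 3")
        if self.filter_window_ms <= 0 or self.fs_hz <= 0:
            raise ValueError("filter_window_ms and fs_hz must be positive")
        if self.fluctuation_cv_threshold <= 0:
            raise ValueError("fluctuation_cv_threshold must be positive")
        if self.pttv_convention not in PTTV_CONVENTIONS:
            raise ValueError(f"pttv_convention must be one of {PTTV_CONVENTIONS}")
        if self.population_fit_scope not in FIT_SCOPES:
            raise ValueError(f"population_fit_scope must be one of {FIT_SCOPES}")
        if self.population_design not in POPULATION_DESIGNS:
            raise ValueError(
                f"population_design must be one of {POPULATION_DESIGNS}"
            )

    @property
    def pttv_window(self) -> int | None:
        """Window length passed to the feature stage (None = same as W)."""
        return None if self.pttv_convention == "differences_of_5_ptt" else (
            self.window_W + 1
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
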