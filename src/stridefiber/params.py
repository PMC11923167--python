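"""Analysis parameters with published defaults.

Every numeric threshold used by the pipeline lives here so a whole analysis
is reproducible from a single YAML file.  Defaults are the values used for
the head-fixed treadmill assay, the open-field optogenetics assay, and the
stimulation-locked photometry analysis; individual assays override the ones
they need.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, model_validator


class AnalysisParams(BaseModel):
    """All tunable thresholds of the pipeline.

    Units are given per field.  ``dff`` quantities are fractions internally;
    thresholds expressed in percent are marked as such.
    """

    # -- treadmill movement/rest segmentation -------------------------------
    move_threshold: float = 0.25  # cm/s, movement vs rest binarization
    min_move_dur: float = 0.5  # s, shorter movement periods are discarded
    min_move_mean_vel: float = 0.5  # cm/s, slower movement periods discarded
    min_rest_dur: float = 0.8  # s, shorter rests are absorbed into movement

    # -- open-field ambulation / immobility ---------------------------------
    ambulation_threshold: float = 2.0  # cm/s
    ambulation_min_dur: float = 0.5  # s, bouts must last strictly longer
    ambulation_min_sep: float = 0.5  # s, closer bouts are merged
    immobility_threshold: float = 0.02  # motion-index fraction (<2% pixel change)

    # -- trial state classification around stimulation ----------------------
    state_window: float = 0.5  # s preceding the anchor
    ambulatory_threshold: float = 2.0  # cm/s, every sample strictly above
    quiescent_threshold: float = 1.5  # cm/s, every sample strictly below
    stim_velocity_window: float = 1.0  # s, pre/post means around the anchor

    # -- dF/F normalization --------------------------------------------------
    f0_window: float = 5.0  # s, sliding-percentile baseline window
    f0_percentile: float = 10.0  # percent
    f0_window_align: Literal["centered", "trailing"] = "centered"
    butter_order: int = 2
    butter_corner: float = 3.0  # Hz, low-pass corner for the reference
    ransac_max_trials: int = 100
    qc_max_dff: float = 1.5  # percent, session max dF/F must exceed this
    qc_max_corr: float = 0.6  # Pearson r(signal, reference) must stay below

    # -- event-aligned timing metrics ----------------------------------------
    peak_window: tuple[float, float] = (-1.0, 1.0)  # s around the anchor
    slope_window: tuple[float, float] = (-0.5, 0.0)  # s before offset
    rise_baseline_window: tuple[float, float] = (-1.0, -0.5)  # s before onset
    rise_window_len: float = 0.020  # s, sliding-window length (20 ms)
    rise_step: float = 0.002  # s, sliding-window step (2 ms)
    rise_alpha: float = 0.05
    rise_consecutive: int = 5
    rise_search_end: float = 0.5  # s, sliding search stops at this lag

    # -- stimulation-locked photometry windows -------------------------------
    stim_baseline_window: float = 5.0  # s preceding onset
    stim_elevation_window: tuple[float, float] = (0.5, 1.0)  # s post onset
    stim_reduction_window: float = 1.0  # s before offset
    stim_post_window: tuple[float, float] = (4.0, 9.0)  # s post offset

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "AnalysisParams":
        for name in (
            "min_move_dur",
            "min_rest_dur",
            "ambulation_min_dur",
            "ambulation_min_sep",
            "state_window",
            "stim_velocity_window",
            "f0_window",
            "stim_baseline_window",
            "stim_reduction_window",
            "rise_window_len",
            "rise_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.f0_percentile < 100:
            raise ValueError("f0_percentile must be in (0, 100)")
        if not self.quiescent_threshold < self.ambulatory_threshold:
            raise ValueError(
                "quiescent_threshold must be below ambulatory_threshold "
                "(the gap guarantees the two state labels are exclusive)"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
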