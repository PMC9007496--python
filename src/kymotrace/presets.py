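"""Canonical simulation scenes used for validation and calibration.

These configurations pin down, in one place, the scenes behind the package's
recovery and calibration studies:

* :func:`recovery_scene` — k well-separated constant-velocity vesicles in a
  photobleached segment at spot SNR ≈ 5–6, for count/direction/velocity
  recovery checks.
* :func:`calibration_config` / :func:`calibration_design` — the compact
  transport scene used for the Monte-Carlo type-I-error and power studies of
  the full pipeline (simulate → kymograph → events → Tau screen → t-test).
  The field is kept small (10 x 140 px around a 13 µm neurite) so thousands
  of full acquisitions stay cheap; the acquisition regime itself (50 s at
  100 ms/frame) is never scaled down.
* :func:`calcium_recovery_config` — the calcium regime (60 s at 250 ms,
  240 samples) with three transients and ~1% noise for metric recovery.

SNR here means spot amplitude over the background noise SD inside the
bleached segment (shot noise of the attenuated background plus read noise).
"""

from __future__ import annotations

from dataclasses import replace

from .events import EventParams
from .experiment import ExperimentDesign
from .simulate import CalciumSimConfig, TransportSimConfig, staggered_vesicle_specs

__all__ = [
    "recovery_scene",
    "calibration_config",
    "calibration_design",
    "power_design",
    "calcium_recovery_config",
]


def recovery_scene(k: int, seed: int, pauses: bool = False) -> TransportSimConfig:
    """Transport scene with ``k`` staggered, non-overlapping vesicle runs.

    Vesicle ``i`` enters every 8 s from alternating ends at 1.8–2.2 µm/s, so
    at most one vesicle is mid-segment at a time and ground-truth matching is
    unambiguous. Background 150 bleached to 15 gives a noise SD of ~4.4
    counts inside the segment; amplitude 25 puts the spots at SNR ≈ 5.7.
    """
    cfg = TransportSimConfig(seed=seed)
    specs = staggered_vesicle_specs(
        k,
        cfg.path_length_um,
        first_direction="anterograde" if seed % 2 == 0 else "retrograde",
    )
    return replace(
        cfg,
        vesicle_specs=specs,
        n_vesicles=k,
        pause_prob_per_frame=0.05 if pauses else 0.0,
    )


def calibration_config(mean_vesicles: float = 8.0, seed: int = 0) -> TransportSimConfig:
    """Compact transport scene for Monte-Carlo pipeline calibration.

    The per-animal vesicle count is Poisson(``mean_vesicles``) and entry
    times are uniform over the stream, giving realistic animal-to-animal
    dispersion in detected event counts.
    """
    return TransportSimConfig(
        field_shape=(10, 140),
        path=((5.0, 4.0), (5.0, 135.0)),
        bleach_window_um=(1.5, 12.0),
        n_vesicles=int(round(mean_vesicles)),
        poisson_vesicle_count=True,
        seed=seed,
    )


def _event_params() -> EventParams:
    return EventParams()


def calibration_design(n_per_group: int = 4, seed: int = 0) -> ExperimentDesign:
    """Identical-group (null) transport experiment design."""
    cfg = calibration_config()
    return ExperimentDesign(
        label_a="control",
        label_b="treated",
        n_animals_a=n_per_group,
        n_animals_b=n_per_group,
        config_a=cfg,
        config_b=cfg,
        seed=seed,
        comparison_metric="n_events",
        event_params=_event_params(),
    )


def power_design(n_per_group: int = 12, seed: int = 0) -> ExperimentDesign:
    """Transport design with a halved group-B vesicle rate (effect present)."""
    return ExperimentDesign(
        label_a="control",
        label_b="treated",
        n_animals_a=n_per_group,
        n_animals_b=n_per_group,
        config_a=calibration_config(mean_vesicles=8.0),
        config_b=calibration_config(mean_vesicles=4.0),
        seed=seed,
        comparison_metric="n_events",
        event_params=_event_params(),
    )


def calcium_recovery_config(seed: int) -> CalciumSimConfig:
    """Calcium regime with 3 transients and noise at 1% of baseline."""
    return CalciumSimConfig(n_transients=3, noise_sd=1.0, seed=seed)
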