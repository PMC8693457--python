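"""End-to-end simulation study: distorted flow -> heading estimates -> PSE.

One *trial* is a (run, condition, lateral offset, vertical heading angle)
cell: a fresh random patch set is drawn for the cell, the flow field is
built (distorted or not), the subspace estimator returns a heading, and the
estimate is converted to an up/down answer.  Patch sets are shared across
conditions within a cell -- the same geometry, different distortion -- so
condition contrasts are paired.  Child seeds derive from the master seed and
the cell index only, making every table byte-reproducible and insensitive to
which conditions are requested.

The default protocol: 50 runs x (3 conditions x 2 lateral offsets x 15
vertical angles) = 50 x 90 trial cells; vertical angles -3.5..3.5 deg in 0.5
steps; FoV radius 55 deg; candidate grid 70 x 20 deg at 0.25 deg steps (a
coarser step is configurable for desk-scale work).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distortion import DistortionField
from .flow import MotionScenario, build_flow_field
from .heading import HeadingGrid, estimate_heading, patch_residual_surfaces, sample_patches
from .psychophysics import FitError, aggregate_responses, delta_pse, fit_psychometric, heading_to_answer
from .synthetic import SyntheticLens, distortion_for_gaze, synthesize_pal

__all__ = ["SimulationConfig", "build_distortion_fields", "run_simulation",
           "fit_trial_table", "fov_sweep"]

logger = logging.getLogger(__name__)

_CONDITIONS = ("undistorted", "central", "peripheral")


def _default_angles() -> tuple[float, ...]:
    return tuple(np.round(np.arange(-3.5, 3.51, 0.5), 6))


@dataclass(frozen=True)
class SimulationConfig:
    """Full protocol description; defaults are the study conditions."""

    runs: int = 50
    n_patches: int = 50
    vectors_per_patch: int = 10
    vertical_angles: tuple = field(default_factory=_default_angles)
    lateral_offsets: tuple = (-20.0, 20.0)
    conditions: tuple = _CONDITIONS
    grid_step: float = 0.25
    fov_radius: float = 55.0
    fov_radii: tuple = (40.0, 45.0, 50.0, 55.0)
    master_seed: int = 0
    speed: float = 2.0
    eye_height: float = 1.8
    gaze_depression: float = 20.0
    lens: SyntheticLens = field(default_factory=SyntheticLens)
    peripheral_gaze: tuple = (20.0, -20.0)

    def __post_init__(self):
        angles = np.asarray(self.vertical_angles, dtype=float)
        if not np.allclose(np.sort(angles), -np.sort(angles)[::-1]):
            raise ValueError("vertical angle list must be symmetric about 0")
        unknown = set(self.conditions) - set(_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        # Grid-step compatibility (the grid itself re-checks the spans).
        HeadingGrid(step=self.grid_step, gaze_depression=self.gaze_depression)
        if any(r > self.fov_radius for r in self.fov_radii):
            raise ValueError("effective FoV radii cannot exceed the maximum FoV")

    @property
    def n_combinations(self) -> int:
        """Heading x condition combinations evaluated per run."""
        return (len(self.conditions) * len(self.lateral_offsets)
                * len(self.vertical_angles))

    @property
    def expected_rows(self) -> int:
        return self.runs * self.n_combinations

    def scenario(self, offset: float, angle: float) -> MotionScenario:
        return MotionScenario(
            speed=self.speed, heading_azimuth_world=offset,
            heading_vertical_world=angle, eye_height=self.eye_height,
            gaze_depression=self.gaze_depression)

    def heading_grid(self) -> HeadingGrid:
        return HeadingGrid(step=self.grid_step,
                           gaze_depression=self.gaze_depression)


def build_distortion_fields(config: SimulationConfig) -> dict:
    """Synthesize the per-condition distortion fields from the config's lens."""
    fields: dict[str, DistortionField | None] = {}
    model = synthesize_pal(config.lens)
    for condition in config.conditions:
        if condition == "undistorted":
            fields[condition] = None
        elif condition == "central":
            fields[condition] = distortion_for_gaze(model, (0.0, 0.0))
        elif condition == "peripheral":
            fields[condition] = distortion_for_gaze(model, config.peripheral_gaze)
    return fields


def _cell_seed(config: SimulationConfig, run: int, offset_idx: int,
               angle_idx: int) -> np.random.SeedSequence:
    # Counter-based child seeds: independent of which conditions are requested.
    return np.random.SeedSequence(
        (int(config.master_seed), run, offset_idx, angle_idx))


def _iter_cells(config: SimulationConfig):
    for run in range(config.runs):
        for offset_idx, offset in enumerate(config.lateral_offsets):
            for angle_idx, angle in enumerate(config.vertical_angles):
                yield run, offset_idx, float(offset), angle_idx, float(angle)


def run_simulation(config: SimulationConfig,
                   fields: dict | None = None) -> pd.DataFrame:
    """Execute the full protocol; one row per trial.

    ``fields`` maps condition name to a DistortionField (None for
    undistorted); when omitted the synthetic lens from the config is used.
    """
    if fields is None:
        fields = build_distortion_fields(config)
    missing = [c for c in config.conditions if c != "undistorted"
               and fields.get(c) is None]
    if missing:
        raise ValueError(f"no distortion field for conditions {missing}")
    grid = config.heading_grid()
    rows = []
    for run, offset_idx, offset, angle_idx, angle in _iter_cells(config):
        scenario = config.scenario(offset, angle)
        patches = sample_patches(
            config.fov_radius, config.n_patches, scenario,
            _cell_seed(config, run, offset_idx, angle_idx),
            n_points=config.vectors_per_patch)
        for condition in config.conditions:
            flow = build_flow_field(scenario, patches, fields.get(condition),
                                    condition=condition,
                                    fov_radius=config.fov_radius)
            est, _ = estimate_heading(flow, grid)
            if est.n_ties > 1:
                logger.info("tie at run=%d cond=%s offset=%g angle=%g: %d nodes",
                            run, condition, offset, angle, est.n_ties)
            rows.append(dict(
                run=run, condition=condition, lateral_offset=offset,
                vertical_angle=angle, fov_radius=config.fov_radius,
                est_azimuth=est.azimuth, est_elevation=est.elevation,
                est_vertical_world=est.world_vertical,
                residual=est.residual, n_patches=est.n_patches,
                n_ties=est.n_ties, answer=heading_to_answer(est)))
        logger.debug("run %d cell (%g, %g) done", run, offset, angle)
    return pd.DataFrame(rows)


def fit_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, fov_radius) psychometric fits of a trial table."""
    rows = []
    reference: dict[float, float] = {}
    for (condition, radius), sub in trials.groupby(["condition", "fov_radius"]):
        table = aggregate_responses(
            zip(sub["vertical_angle"], sub["answer"]))
        try:
            fit = fit_psychometric(table)
            rows.append(dict(condition=condition, fov_radius=radius,
                             pse=fit.pse, spread=fit.spread, lapse=fit.lapse,
                             converged=fit.converged, n_trials=fit.n_trials,
                             flag=""))
            if condition == "undistorted":
                reference[radius] = fit.pse
        except FitError as exc:
            logger.warning("fit failed for %s @ %g deg: %s", condition, radius, exc)
            rows.append(dict(condition=condition, fov_radius=radius,
                             pse=np.nan, spread=np.nan, lapse=np.nan,
                             converged=False, n_trials=float(len(sub)),
                             flag=str(exc)))
    frame = pd.DataFrame(rows)
    frame["delta_pse"] = [
        row.pse - reference[row.fov_radius]
        if row.condition != "undistorted" and row.fov_radius in reference
        else (0.0 if row.condition == "undistorted" and np.isfinite(row.pse)
              else np.nan)
        for row in frame.itertuples()]
    return frame.sort_values(["fov_radius", "condition"]).reset_index(drop=True)


def fov_sweep(config: SimulationConfig,
              fields: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-estimate headings under shrinking effective FoV radii.

    Patches are sampled once per cell at the maximum FoV; for each effective
    radius the patches whose points do not all fit inside are dropped (the
    retained sets are nested across radii) and the heading is re-estimated
    from the retained per-patch residual surfaces.  Returns (trial table
    with one row per trial x radius, per-condition PSE/delta-PSE table).
    """
    if fields is None:
        fields = build_distortion_fields(config)
    grid = config.heading_grid()
    radii = sorted(config.fov_radii)
    rows = []
    for run, offset_idx, offset, angle_idx, angle in _iter_cells(config):
        scenario = config.scenario(offset, angle)
        patches = sample_patches(
            config.fov_radius, config.n_patches, scenario,
            _cell_seed(config, run, offset_idx, angle_idx),
            n_points=config.vectors_per_patch)
        for condition in config.conditions:
            flow = build_flow_field(scenario, patches, fields.get(condition),
                                    condition=condition,
                                    fov_radius=config.fov_radius)
            surfaces = patch_residual_surfaces(flow, grid)
            for radius in radii:
                est, _ = estimate_heading(flow, grid, fov_radius=radius,
                                          surfaces=surfaces)
                rows.append(dict(
                    run=run, condition=condition, lateral_offset=offset,
                    vertical_angle=angle, fov_radius=float(radius),
                    est_azimuth=est.azimuth, est_elevation=est.elevation,
                    est_vertical_world=est.world_vertical,
                    residual=est.residual, n_patches=est.n_patches,
                    n_ties=est.n_ties, answer=heading_to_answer(est)))
    trials = pd.DataFrame(rows)
    return trials, fit_trial_table(trials)
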