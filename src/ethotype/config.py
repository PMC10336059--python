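"""Configuration types for the simulators and the arena geometry.

All spatial quantities are in pixels; the tracking camera's calibration
(1 cm = 16.7 px by default) converts to centimetres only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidConfigError(ValueError):
    """A configuration violates one of its invariants."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of one behavioral arena.

    The refuge is an axis-aligned rectangle ``(x0, y0, x1, y1)``; a fish
    inside it is invisible to the tracker, so absence of a detection is
    operationally equivalent to refuge occupancy.  ``object_point`` and
    ``conspecific_point`` are the centroids of the novel object and of the
    companion aquarium used by the exploration and sociability tests.
    """

    width_px: float = 1000.0
    height_px: float = 830.0
    refuge_region: tuple[float, float, float, float] = (0.0, 0.0, 150.0, 150.0)
    object_point: tuple[float, float] | None = (500.0, 415.0)
    conspecific_point: tuple[float, float] | None = (1000.0, 415.0)
    px_per_cm: float = 16.7

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidConfigError("arena dimensions must be positive")
        if self.px_per_cm <= 0:
            raise InvalidConfigError("px_per_cm must be positive")
        x0, y0, x1, y1 = self.refuge_region
        if not (x0 < x1 and y0 < y1):
            raise InvalidConfigError("refuge_region must have positive extent")
        if x0 < 0 or y0 < 0 or x1 > self.width_px or y1 > self.height_px:
            raise InvalidConfigError("refuge_region must lie inside the arena")

    @property
    def refuge_center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.refuge_region
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass(frozen=True)
class MovementConfig:
    """Parameters of the correlated random walk emitted by the simulator.

    Turning angles are Von Mises(``turn_mu_rad``, ``turn_kappa``); step
    lengths are exponential with mean ``step_mean_px`` (the tracking data
    constrain only turning angles, so any positive step-length law is
    admissible; exponential needs a single parameter).  Refuge occupancy is
    a two-state Markov chain with per-second entry/exit probabilities.
    ``duration_s`` is 3600 for the 1-h tests and 7200 for activity.

    ``bias_point``/``bias_strength`` optionally pull headings toward a
    stimulus (taxis toward a novel object or conspecific); at the default
    strength 0 the walk is an unbiased correlated random walk.
    """

    step_mean_px: float = 10.0
    turn_mu_rad: float = 0.0
    turn_kappa: float = 2.0
    p_enter_refuge: float = 0.01
    p_exit_refuge: float = 0.05
    duration_s: int = 3600
    bias_point: tuple[float, float] | None = None
    bias_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias_strength < 1.0:
            raise InvalidConfigError("bias_strength must be in [0, 1)")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        if self.step_mean_px <= 0:
            raise InvalidConfigError("step_mean_px must be positive")
        if self.turn_kappa < 0:
            raise InvalidConfigError("turn_kappa must be non-negative")
        for name in ("p_enter_refuge", "p_exit_refuge"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TraitSimConfig:
    """Ground truth for Gaussian repeated-measures trait simulation.

    ``y_ij = Xb + u_i + e_ij`` with ``u_i ~ N(0, v_ind)`` and
    ``e_ij ~ N(0, v_e)``.  ``beta`` holds (intercept, trial slope,
    reared-sample offset, length slope); trial and body length enter
    mean-centered.  ``trait_pair_corr = (r_ind, r_e)`` switches on bivariate
    generation with individual effects and residuals drawn from bivariate
    normals with those correlations.  Body lengths default to the observed
    juvenile gilthead seabream distribution (12.15 ± 1.01 cm).
    """

    n_individuals: int = 70
    n_trials: int = 4
    v_ind: float | tuple[float, float] = 0.4
    v_e: float | tuple[float, float] = 0.6
    beta: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    sample_labels: tuple[str, ...] | None = None
    length_mean_cm: float = 12.15
    length_sd_cm: float = 1.01
    trait_pair_corr: tuple[float, float] | None = None
    trait_names: tuple[str, ...] = ("trait", "trait_b")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be >= 1")
        for v, lower in (("v_ind", 0.0), ("v_e", 1e-300)):
            vals = getattr(self, v)
            for x in (vals if isinstance(vals, tuple) else (vals,)):
                if x < lower or (v == "v_e" and x <= 0):
                    raise InvalidConfigError(f"{v} must be {'>= 0' if v == 'v_ind' else '> 0'}")
        if self.trait_pair_corr is not None:
            r_ind, r_e = self.trait_pair_corr
            if abs(r_ind) > 1 or abs(r_e) > 1:
                raise InvalidConfigError("trait pair correlations must lie in [-1, 1]")
        if self.sample_labels is not None and len(self.sample_labels) != self.n_individuals:
            raise InvalidConfigError("sample_labels must have one entry per individual")

    def variances(self, which: str) -> tuple[float, float]:
        """Per-trait (trait 1, trait 2) value of ``v_ind`` or ``v_e``."""
        v = getattr(self, which)
        return v if isinstance(v, tuple) else (v, v)
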