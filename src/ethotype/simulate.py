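"""Synthetic trajectories and repeated-measures trait data with known truth.

The tracking pipeline this package analyses emits one 2-D detection per
second while a fish is outside its refuge and nothing while it hides, so
the simulator couples a correlated random walk (Von Mises turning angles,
exponential step lengths, reflective aquarium walls) to a two-state
per-second Markov chain for refuge occupancy.  Trait tables follow the
Gaussian repeated-measures model ``y_ij = Xb + u_i + e_ij`` with
between-individual variance ``v_ind`` and residual variance ``v_e``, which
is exactly the model the downstream mixed-model machinery decomposes —
so every stage can be checked against ground truth without real data.

One integer seed drives each generator; sub-streams (occupancy, turning
angles, step lengths, individual effects, residuals) are all drawn from
the single ``numpy`` Generator it initialises, in a fixed order, so runs
are bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml

from .config import ArenaConfig, InvalidConfigError, MovementConfig, TraitSimConfig
from .metrics import Track

__all__ = [
    "simulate_trajectory",
    "simulate_trait_data",
    "simulate_trait_pair",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_arena_yaml",
    "read_arena_yaml",
    "DEFAULT_DURATIONS",
]

#: Test durations in seconds (1 h for the stimulus tests, 2 h for activity).
DEFAULT_DURATIONS = {"exploration": 3600, "sociability": 3600, "activity": 7200}


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    span = hi - lo
    v = (v - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return lo + v


def _in_refuge(x: float, y: float, rect) -> bool:
    x0, y0, x1, y1 = rect
    return x0 <= x <= x1 and y0 <= y <= y1


def _exit_point(arena: ArenaConfig) -> tuple[float, float]:
    """Point just outside the refuge, on the ray toward the arena centre."""
    cx, cy = arena.refuge_center
    ax, ay = arena.width_px / 2.0, arena.height_px / 2.0
    dx, dy = ax - cx, ay - cy
    norm = float(np.hypot(dx, dy)) or 1.0
    dx, dy = dx / norm, dy / norm
    x0, y0, x1, y1 = arena.refuge_region
    candidates = []
    if dx > 0:
        candidates.append((x1 - cx) / dx)
    elif dx < 0:
        candidates.append((x0 - cx) / dx)
    if dy > 0:
        candidates.append((y1 - cy) / dy)
    elif dy < 0:
        candidates.append((y0 - cy) / dy)
    s = min(c for c in candidates if c > 0) + 1.0
    return (_reflect(cx + s * dx, 0, arena.width_px),
            _reflect(cy + s * dy, 0, arena.height_px))


def simulate_trajectory(arena: ArenaConfig, movement: MovementConfig,
                        seed: int, *, id: str = "SIM000", trial: int = 1,
                        test: str = "activity",
                        start_inside: bool = False) -> Track:
    """Simulate one track: a correlated random walk with refuge absences.

    Each second the refuge Markov chain is updated first; while outside,
    the fish turns by a Von Mises(``turn_mu_rad``, ``turn_kappa``) angle,
    moves an exponential(``step_mean_px``) distance with reflective walls,
    and emits a detection.  While inside the refuge no detection is
    emitted; on exit the fish reappears just outside the refuge with a
    fresh uniform heading.  Steps that would land inside the refuge are
    re-aimed (uniform heading resample); detections therefore never fall
    in the refuge rectangle.
    """
    if movement.duration_s <= 0:  # re-validated for plain-dict call sites
        raise InvalidConfigError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    rect = arena.refuge_region
    exit_xy = _exit_point(arena)

    inside = bool(start_inside)
    if inside:
        x, y = arena.refuge_center
    else:
        x, y = arena.width_px / 2.0, arena.height_px / 2.0
        if _in_refuge(x, y, rect):
            x, y = exit_xy
    heading = float(rng.uniform(-np.pi, np.pi))

    n = movement.duration_s
    u_trans = rng.uniform(size=n)
    turns = rng.vonmises(movement.turn_mu_rad, movement.turn_kappa, size=n)
    steps = rng.exponential(movement.step_mean_px, size=n)

    ts, xs, ys = [], [], []
    fresh_heading = False
    for t in range(n):
        if inside:
            if u_trans[t] < movement.p_exit_refuge:
                inside = False
                x, y = exit_xy
                fresh_heading = True
            else:
                continue
        elif u_trans[t] < movement.p_enter_refuge:
            inside = True
            x, y = arena.refuge_center
            continue
        if fresh_heading:
            heading = float(rng.uniform(-np.pi, np.pi))
            fresh_heading = False
        else:
            heading += turns[t]
        if movement.bias_strength > 0.0 and movement.bias_point is not None:
            # taxis: blend the heading unit vector toward the stimulus
            w = movement.bias_strength
            phi = np.arctan2(movement.bias_point[1] - y,
                             movement.bias_point[0] - x)
            heading = float(np.arctan2(
                (1 - w) * np.sin(heading) + w * np.sin(phi),
                (1 - w) * np.cos(heading) + w * np.cos(phi)))
        step = steps[t]
        for _ in range(50):
            nx = _reflect(x + step * np.cos(heading), 0.0, arena.width_px)
            ny = _reflect(y + step * np.sin(heading), 0.0, arena.height_px)
            if not _in_refuge(nx, ny, rect):
                break
            heading = float(rng.uniform(-np.pi, np.pi))  # re-aim away from refuge
        else:
            nx, ny = x, y
        if nx != x or ny != y:
            heading = float(np.arctan2(ny - y, nx - x))  # wall bounces change course
        x, y = nx, ny
        ts.append(t)
        xs.append(x)
        ys.append(y)
    return Track(id=id, trial=trial, test=test, duration_s=n,
                 t_s=np.array(ts, dtype=int),
                 x_px=np.array(xs), y_px=np.array(ys))


def _design_frame(cfg: TraitSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n, k = cfg.n_individuals, cfg.n_trials
    if k < 2:
        warnings.warn("n_trials < 2: repeatability is not identifiable",
                      UserWarning, stacklevel=3)
    ids = [f"SA{i + 1:03d}" for i in range(n)]
    if cfg.sample_labels is not None:
        samples = list(cfg.sample_labels)
    else:
        samples = ["wild"] * (n // 2) + ["reared"] * (n - n // 2)
    lengths = rng.normal(cfg.length_mean_cm, cfg.length_sd_cm, size=n)
    df = pd.DataFrame({
        "id": np.repeat(ids, k),
        "trial": np.tile(np.arange(1, k + 1), n),
        "sample": np.repeat(samples, k),
        "length_cm": np.repeat(lengths, k),
    })
    df["trial_c"] = df["trial"] - df["trial"].mean()
    df["length_c"] = df["length_cm"] - df["length_cm"].mean()
    return df


def _fixed_part(df: pd.DataFrame, beta) -> np.ndarray:
    b0, b_trial, b_sample, b_length = (float(b) for b in beta)
    return (b0 + b_trial * df["trial_c"].to_numpy()
            + b_sample * (df["sample"].to_numpy() == "reared")
            + b_length * df["length_c"].to_numpy())


def simulate_trait_data(cfg: TraitSimConfig) -> pd.DataFrame:
    """Long-format single-trait table with known variance components.

    Columns: id, trial, sample, length_cm, trait, value (plus the
    mean-centered covariates trial_c and length_c used in the linear
    predictor).  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    df = _design_frame(cfg, rng)
    n, k = cfg.n_individuals, cfg.n_trials
    v_ind, v_e = cfg.variances("v_ind")[0], cfg.variances("v_e")[0]
    u = rng.normal(0.0, np.sqrt(v_ind), size=n)
    e = rng.normal(0.0, np.sqrt(v_e), size=n * k)
    df["trait"] = cfg.trait_names[0]
    df["value"] = _fixed_part(df, cfg.beta) + np.repeat(u, k) + e
    return df


def simulate_trait_pair(cfg: TraitSimConfig) -> pd.DataFrame:
    """Paired-trait table whose two traits share individuals.

    Individual effects come from a bivariate normal with correlation
    ``r_ind``; residuals from one with correlation ``r_e``; marginal
    variances follow ``cfg.v_ind`` / ``cfg.v_e`` (scalar = shared).  The
    implied phenotypic correlation is
    ``(r_ind*sqrt(vi1*vi2) + r_e*sqrt(ve1*ve2)) / sqrt((vi1+ve1)(vi2+ve2))``.
    """
    if cfg.trait_pair_corr is None:
        raise InvalidConfigError("trait_pair_corr is required for paired simulation")
    r_ind, r_e = cfg.trait_pair_corr
    rng = np.random.default_rng(cfg.seed)
    df = _design_frame(cfg, rng)
    n, k = cfg.n_individuals, cfg.n_trials
    vi = np.asarray(cfg.variances("v_ind"))
    ve = np.asarray(cfg.variances("v_e"))

    def _mvn(var2, r, size):
        sd = np.sqrt(var2)
        cov = np.array([[var2[0], r * sd[0] * sd[1]],
                        [r * sd[0] * sd[1], var2[1]]])
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        return rng.standard_normal((size, 2)) @ L.T

    u = _mvn(vi, r_ind, n)
    e = _mvn(ve, r_e, n * k)
    # beta may be one 4-tuple shared by both traits or one per trait
    betas = cfg.beta if isinstance(cfg.beta[0], (tuple, list)) else (cfg.beta, cfg.beta)
    frames = []
    for j, name in enumerate(cfg.trait_names[:2]):
        dfj = df.copy()
        dfj["trait"] = name
        dfj["value"] = _fixed_part(df, betas[j]) + np.repeat(u[:, j], k) + e[:, j]
        frames.append(dfj)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# plain-text interchange


def write_tracks_csv(tracks, path) -> None:
    """Write tracks as CSV (id, trial, test, t_s, x_px, y_px); undetected
    seconds are simply absent rows."""
    frames = [pd.DataFrame({"id": tr.id, "trial": tr.trial, "test": tr.test,
                            "t_s": tr.t_s, "x_px": tr.x_px, "y_px": tr.y_px})
              for tr in tracks]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["id", "trial", "test", "t_s", "x_px", "y_px"]))
    out.to_csv(path, index=False)


def read_tracks_csv(path, durations: dict[str, int] | None = None) -> list[Track]:
    durations = durations or DEFAULT_DURATIONS
    df = pd.read_csv(path)
    tracks = []
    for (tid, trial, test), g in df.groupby(["id", "trial", "test"], sort=True):
        g = g.sort_values("t_s")
        dur = int(durations.get(str(test), int(g["t_s"].max()) + 1))
        tracks.append(Track(id=str(tid), trial=int(trial), test=str(test),
                            duration_s=dur,
                            t_s=g["t_s"].to_numpy(int),
                            x_px=g["x_px"].to_numpy(float),
                            y_px=g["y_px"].to_numpy(float)))
    return tracks


def write_arena_yaml(arena: ArenaConfig, path) -> None:
    d = {"width_px": arena.width_px, "height_px": arena.height_px,
         "refuge_region": list(arena.refuge_region),
         "object_point": list(arena.object_point) if arena.object_point else None,
         "conspecific_point": (list(arena.conspecific_point)
                               if arena.conspecific_point else None),
         "px_per_cm": arena.px_per_cm}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_arena_yaml(path) -> ArenaConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("refuge_region", "object_point", "conspecific_point"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return ArenaConfig(**d)
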