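"""Reproducible simulate → metrics → score → fit → syndromes pipeline.

Each stage reads and writes plain CSV/YAML in a run directory and records
a manifest (stage, seed, SHA-256 of inputs and outputs), so stage outputs
are pure functions of (inputs, config, seed) and reruns are byte-checkable.

The simulate stage couples the trait and trajectory generators: each
behavioral axis gets a latent Gaussian repeated-measures trait with
configured variance components (the ground truth the downstream models
must recover), and the latent modulates the movement simulator — a higher
exploration/sociability/activity latent raises the refuge-exit probability
(and, for activity, the step length), while annotation-style metrics
(approach counts, feeding latencies) are derived from the same latent so
the per-axis metric batteries are genuinely correlated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import metrics as tm
from . import models, scoring, simulate
from .config import ArenaConfig, MovementConfig, TraitSimConfig

log = logging.getLogger("ethotype.pipeline")

STAGES = ("simulate", "metrics", "score", "fit", "syndromes", "report")

#: Behavioral tests whose metrics come from trajectories.
TRACKED_TESTS = ("exploration", "sociability", "activity")


def demo_config() -> dict:
    """Packaged demo: 30 individuals × 4 trials, shortened test durations
    and chains so a full run finishes in well under a minute."""
    return {
        "n_individuals": 30,
        "n_trials": 4,
        "arena": {"width_px": 1000.0, "height_px": 830.0,
                  "refuge_region": [0.0, 0.0, 150.0, 150.0],
                  "object_point": [500.0, 415.0],
                  "conspecific_point": [1000.0, 415.0],
                  "px_per_cm": 16.7},
        "movement": {"step_mean_px": 10.0, "turn_mu_rad": 0.0,
                     "turn_kappa": 2.0, "p_enter_refuge": 0.01,
                     "p_exit_refuge": 0.05},
        "durations": {"exploration": 600, "sociability": 600, "activity": 1200},
        "axes": {
            "exploration": {"v_ind": 0.4, "v_e": 0.6, "beta": [0.0, 0.05, 0.3, 0.0]},
            "sociability": {"v_ind": 0.4, "v_e": 0.6, "beta": [0.0, 0.0, 0.5, 0.0]},
            "boldness": {"v_ind": 0.25, "v_e": 0.75, "beta": [0.0, 0.0, 0.0, 0.0]},
            "activity": {"v_ind": 0.5, "v_e": 0.5, "beta": [0.0, -0.05, 0.2, 0.0]},
            "aggressiveness": {"v_ind": 0.4, "v_e": 0.6, "beta": [0.0, 0.0, 0.4, 0.0]},
        },
        "syndrome_truth": {"pair": ["exploration", "activity"],
                           "r_ind": 0.6, "r_e": 0.2},
        "mcmc": {"univariate": {"n_iter": 4000, "burn_in": 1000, "thin": 3},
                 "bivariate": {"n_iter": 8000, "burn_in": 1000, "thin": 7}},
        "backward_reduction": False,
        "syndrome_pairs": [["exploration", "sociability"],
                           ["exploration", "activity"]],
        "report": {"decimals": 2},
    }


def load_config(path=None) -> dict:
    if path is None:
        return demo_config()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = demo_config()
    base.update(cfg or {})
    return base


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _manifest(outdir: Path, stage: str, seed, inputs, outputs) -> None:
    entry = {"stage": stage, "seed": seed,
             "inputs": {p.name: _sha256(p) for p in map(Path, inputs)},
             "outputs": {p.name: _sha256(p) for p in map(Path, outputs)}}
    path = outdir / "manifest.json"
    data = json.loads(path.read_text()) if path.exists() else []
    data = [e for e in data if e["stage"] != stage] + [entry]
    path.write_text(json.dumps(data, indent=1) + "\n")


def _track_seed(seed: int, i: int, trial: int, test_idx: int) -> int:
    return int(np.random.SeedSequence([seed, i, trial, test_idx])
               .generate_state(1)[0] & 0x7FFFFFFF)


def stage_simulate(config: dict, seed: int, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    arena = ArenaConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in config["arena"].items()})
    mov = config["movement"]
    durations = config["durations"]
    n, k = config["n_individuals"], config["n_trials"]
    rng = np.random.default_rng(seed)

    # latent trait per axis on a shared individual design; the configured
    # true-syndrome pair is generated jointly (correlated individual
    # effects and residuals), all other axes independently
    base = None
    cov = None
    latents: dict[str, pd.DataFrame] = {}

    def _axis_seed(j: int) -> int:
        return int(np.random.SeedSequence([seed, 1000 + j])
                   .generate_state(1)[0] & 0x7FFFFFFF)

    def _store(df: pd.DataFrame, axis: str) -> None:
        nonlocal base, cov
        if base is None:
            base = tuple(df.drop_duplicates("id")["sample"])
            cov = df.drop_duplicates("id")[["id", "sample", "length_cm"]]
        else:
            df = df.drop(columns=["sample", "length_cm"]).merge(cov, on="id")
        latents[axis] = df.reset_index(drop=True)

    truth = config.get("syndrome_truth") or {}
    pair = tuple(truth.get("pair", ()))
    if len(pair) == 2 and all(a in config["axes"] for a in pair):
        c1, c2 = (config["axes"][a] for a in pair)
        dfp = simulate.simulate_trait_pair(TraitSimConfig(
            n_individuals=n, n_trials=k,
            v_ind=(c1["v_ind"], c2["v_ind"]), v_e=(c1["v_e"], c2["v_e"]),
            beta=(tuple(c1["beta"]), tuple(c2["beta"])),
            trait_pair_corr=(truth["r_ind"], truth["r_e"]),
            trait_names=pair, seed=_axis_seed(0)))
        for axis in pair:
            _store(dfp[dfp["trait"] == axis], axis)
    for j, (axis, acfg) in enumerate(config["axes"].items()):
        if axis in pair:
            continue
        df = simulate.simulate_trait_data(TraitSimConfig(
            n_individuals=n, n_trials=k, v_ind=acfg["v_ind"],
            v_e=acfg["v_e"], beta=tuple(acfg["beta"]), sample_labels=base,
            trait_names=(axis,), seed=_axis_seed(1 + j)))
        _store(df, axis)
    cov.to_csv(outdir / "individuals.csv", index=False)

    # trajectories: the axis latent shifts the refuge-exit odds (and, for
    # activity, the step length), so tracked metrics inherit the latent
    tracks = []
    for t_idx, test in enumerate(TRACKED_TESTS):
        lat = latents[test].set_index(["id", "trial"])["value"]
        for i, iid in enumerate(cov["id"]):
            for trial in range(1, k + 1):
                z = float(lat.loc[(iid, trial)])
                if test == "exploration":
                    bias_point, bias = arena.object_point, 0.3 * float(expit(1.5 * z))
                elif test == "sociability":
                    bias_point, bias = arena.conspecific_point, 0.3 * float(expit(1.5 * z))
                else:
                    bias_point, bias = None, 0.0
                m = MovementConfig(
                    step_mean_px=mov["step_mean_px"] * (np.exp(0.4 * z)
                                                        if test == "activity" else 1.0),
                    turn_mu_rad=mov["turn_mu_rad"],
                    turn_kappa=mov["turn_kappa"],
                    p_enter_refuge=mov["p_enter_refuge"],
                    p_exit_refuge=float(expit(logit(mov["p_exit_refuge"]) + 2.0 * z)),
                    duration_s=int(durations[test]),
                    bias_point=bias_point, bias_strength=bias)
                tracks.append(simulate.simulate_trajectory(
                    arena, m, _track_seed(seed, i, trial, t_idx),
                    id=iid, trial=trial, test=test, start_inside=True))
    simulate.write_tracks_csv(tracks, outdir / "tracks.csv")
    simulate.write_arena_yaml(arena, outdir / "arena.yaml")

    # annotation-derived trait values from the same latents
    rows = []
    for axis, df in latents.items():
        z = df["value"].to_numpy()
        if axis == "exploration":
            vals = {"approaches": rng.poisson(np.exp(1.2 + 1.0 * z))}
        elif axis == "aggressiveness":
            vals = {"approaches": rng.poisson(np.exp(1.2 + 1.0 * z))}
        elif axis == "boldness":
            # latency base: bolder (higher latent) feeds sooner
            b = 1200.0 * np.exp(-1.0 * z)
            vals = {"head_latency_s": b * np.exp(rng.normal(0, 0.10, z.size)),
                    "body_latency_s": 1.2 * b * np.exp(rng.normal(0, 0.10, z.size)),
                    "first_bite_latency_s": 1.5 * b * np.exp(rng.normal(0, 0.10, z.size))}
            vals = {m: np.clip(v, 1.0, 3600.0) for m, v in vals.items()}
        else:
            continue
        for metric, v in vals.items():
            out = df[["id", "trial", "sample", "length_cm"]].copy()
            out["test"] = axis
            out["metric"] = metric
            out["value"] = v
            rows.append(out)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "annotations.csv", index=False)

    truth = pd.concat([df.assign(axis=a)[["axis", "id", "trial", "value"]]
                       for a, df in latents.items()], ignore_index=True)
    truth.to_csv(outdir / "truth_latents.csv", index=False)
    _manifest(outdir, "simulate", seed, [],
              [outdir / f for f in ("tracks.csv", "arena.yaml",
                                    "annotations.csv", "individuals.csv")])


def stage_metrics(config: dict, seed: int, outdir: Path) -> None:
    tracks_path = outdir / "tracks.csv"
    tracks = simulate.read_tracks_csv(tracks_path, config["durations"])
    if not tracks:
        raise ValueError(f"empty trajectory file: {tracks_path}")
    arena = simulate.read_arena_yaml(outdir / "arena.yaml")
    # a fish that never left the refuge writes no rows at all: reconstruct
    # the expected grid so such tests get their imputed metrics
    cov_path = outdir / "individuals.csv"
    if cov_path.exists():
        ids = pd.read_csv(cov_path)["id"]
        have = {(t.id, t.trial, t.test) for t in tracks}
        for test in TRACKED_TESTS:
            dur = int(config["durations"][test])
            for iid in ids:
                for trial in range(1, config["n_trials"] + 1):
                    if (iid, trial, test) not in have:
                        tracks.append(tm.Track(
                            id=iid, trial=trial, test=test, duration_s=dur,
                            t_s=np.empty(0, int), x_px=np.empty(0),
                            y_px=np.empty(0)))
    table = tm.metrics_table(tracks, arena)
    ann = pd.read_csv(outdir / "annotations.csv")
    table = pd.concat([table, ann[["id", "trial", "test", "metric", "value"]]],
                      ignore_index=True)
    table.to_csv(outdir / "metrics.csv", index=False)

    # cm-converted companion for the spatial metrics
    cm = table.copy()
    is_px = cm["metric"].str.endswith("_px")
    is_px2 = cm["metric"].str.endswith("_px2")
    cm.loc[is_px, "value"] = tm.px_to_cm(cm.loc[is_px, "value"], arena.px_per_cm)
    cm.loc[is_px2, "value"] = cm.loc[is_px2, "value"] / arena.px_per_cm**2
    cm["metric"] = (cm["metric"].str.replace("_px2", "_cm2", regex=False)
                    .str.replace("_px", "_cm", regex=False))
    cm["value"] = cm["value"].round(2)
    cm.to_csv(outdir / "metrics_cm.csv", index=False)
    _manifest(outdir, "metrics", seed,
              [tracks_path, outdir / "annotations.csv"],
              [outdir / "metrics.csv", outdir / "metrics_cm.csv"])


def stage_score(config: dict, seed: int, outdir: Path) -> None:
    table = pd.read_csv(outdir / "metrics.csv")
    cov = pd.read_csv(outdir / "individuals.csv")
    scores, loadings = scoring.score_axes(table, covariates=cov)
    # aggressiveness is a single count metric: passed through, not PCA-scored
    aggr = table[(table["test"] == "aggressiveness")
                 & (table["metric"] == "approaches")]
    if not aggr.empty:
        extra = aggr.rename(columns={"value": "score"})[["id", "trial", "score"]]
        extra["axis"] = "aggressiveness"
        extra["score_lmm"] = extra["score"]
        extra = extra.merge(cov, on="id", how="left")
        scores = pd.concat([scores, extra], ignore_index=True)
    scores.to_csv(outdir / "scores.csv", index=False)
    loadings.to_csv(outdir / "loadings.csv", index=False)
    _manifest(outdir, "score", seed, [outdir / "metrics.csv"],
              [outdir / "scores.csv", outdir / "loadings.csv"])


def _fmt(x, dec):
    return "" if x is None or (isinstance(x, float) and not np.isfinite(x)) \
        else f"{x:.{dec}f}"


def stage_fit(config: dict, seed: int, outdir: Path) -> None:
    scores = pd.read_csv(outdir / "scores.csv")
    mcfg = config["mcmc"]["univariate"]
    dec = config["report"]["decimals"]
    rows, lines = [], []
    for a_idx, axis in enumerate(scores["axis"].unique()):
        data = scores[scores["axis"] == axis]
        terms = models.FIXED_TERMS
        sub_seed = int(np.random.SeedSequence([seed, 2000 + a_idx])
                       .generate_state(1)[0] & 0x7FFFFFFF)
        if config.get("backward_reduction"):
            terms, _ = models.backward_reduce(data, response="score_lmm",
                                              random_state=sub_seed, **mcfg)
        full = models.BayesianLMM(response="score_lmm", fixed_terms=terms,
                                  random_state=sub_seed, **mcfg).fit(data)
        est = models.repeatability_significance(data, response="score_lmm",
                                                fixed_terms=terms,
                                                random_state=sub_seed, **mcfg)
        summ = full.summary().assign(axis=axis)
        rows.append(summ)
        rows.append(pd.DataFrame([{
            "axis": axis, "parameter": "adjusted_R",
            "post_mean": est.r_mean, "l_bci": est.bci[0], "u_bci": est.bci[1],
            "pmcmc": np.nan}]))
        lines.append(f"{axis.capitalize()}  (terms: {', '.join(terms)})")
        for _, r in summ.iterrows():
            lines.append(f"  {r['parameter']:<12} {_fmt(r['post_mean'], dec):>9}"
                         f" [{_fmt(r['l_bci'], dec)}, {_fmt(r['u_bci'], dec)}]"
                         + (f"  p={r['pmcmc']:.3f}" if np.isfinite(r["pmcmc"]) else ""))
        lines.append(f"  adjusted-R   {_fmt(est.r_mean, dec):>9}"
                     f" [{_fmt(est.bci[0], dec)}, {_fmt(est.bci[1], dec)}]"
                     f"  (plug-in {_fmt(est.r_plugin, dec)})")
        lines.append(f"  DIC = {est.dic:.2f} (DIC_C = {est.dic_constrained:.2f},"
                     f" dDIC = {est.delta_dic:.2f},"
                     f" {'significant' if est.significant else 'ns'})")
        lines.append("")
    # between-sample variance comparison on per-individual mean aggressiveness
    aggr = scores[scores["axis"] == "aggressiveness"]
    if not aggr.empty and aggr["sample"].nunique() == 2:
        means = aggr.groupby(["id", "sample"], observed=True)["score"].mean().reset_index()
        g = {s: v["score"].to_numpy() for s, v in means.groupby("sample")}
        ft = models.variance_f_test(*g.values())
        lines.append(f"Aggressiveness variance F-test ({' vs '.join(g)}): "
                     f"F = {ft.statistic:.2f}, p = {ft.pvalue:.3g}")
    pd.concat(rows, ignore_index=True).to_csv(outdir / "table2.csv", index=False)
    (outdir / "table2.txt").write_text("\n".join(lines) + "\n")
    _manifest(outdir, "fit", seed, [outdir / "scores.csv"],
              [outdir / "table2.csv", outdir / "table2.txt"])


def stage_syndromes(config: dict, seed: int, outdir: Path) -> None:
    scores = pd.read_csv(outdir / "scores.csv")
    mcfg = config["mcmc"]["bivariate"]
    dec = config["report"]["decimals"]
    rows, lines = [], []
    for p_idx, (a, b) in enumerate(config["syndrome_pairs"]):
        sub_seed = int(np.random.SeedSequence([seed, 3000 + p_idx])
                       .generate_state(1)[0] & 0x7FFFFFFF)
        est = models.syndrome_estimate(scores, responses=(a, b),
                                       random_state=sub_seed, **mcfg)
        rows.append({"trait_1": a, "trait_2": b,
                     "r_ind": est.r_ind, "r_ind_l": est.r_ind_bci[0],
                     "r_ind_u": est.r_ind_bci[1],
                     "r_e": est.r_e, "r_e_l": est.r_e_bci[0],
                     "r_e_u": est.r_e_bci[1],
                     "r_p": est.r_p, "r_p_l": est.r_p_bci[0],
                     "r_p_u": est.r_p_bci[1],
                     "delta_dic": est.delta_dic, "significant": est.significant})
        mark = "**" if est.significant else ""
        lines.append(f"{a} – {b}:")
        for nm, v, ci in (("r_ind", est.r_ind, est.r_ind_bci),
                          ("r_e", est.r_e, est.r_e_bci),
                          ("r_p", est.r_p, est.r_p_bci)):
            lines.append(f"  {nm:<6} {mark}{_fmt(v, dec)} "
                         f"[{_fmt(ci[0], dec)}, {_fmt(ci[1], dec)}]{mark}")
        lines.append(f"  dDIC = {est.delta_dic:.2f}\n")
    pd.DataFrame(rows).to_csv(outdir / "table3.csv", index=False)
    (outdir / "table3.txt").write_text("\n".join(lines) + "\n")
    _manifest(outdir, "syndromes", seed, [outdir / "scores.csv"],
              [outdir / "table3.csv", outdir / "table3.txt"])


def stage_report(config: dict, seed: int, outdir: Path) -> None:
    arena = simulate.read_arena_yaml(outdir / "arena.yaml")
    lines = [f"Calibration: 1 cm = {arena.px_per_cm} px",
             f"  novel-object impute 250 px = "
             f"{tm.px_to_cm(250, arena.px_per_cm):.2f} cm",
             f"  conspecific impute 350 px = "
             f"{tm.px_to_cm(350, arena.px_per_cm):.2f} cm",
             f"  interaction radius 100 px = "
             f"{tm.px_to_cm(100, arena.px_per_cm):.2f} cm", ""]
    for name in ("table2.txt", "table3.txt"):
        p = outdir / name
        if p.exists():
            lines += [p.read_text(), ""]
    (outdir / "report.txt").write_text("\n".join(lines))
    _manifest(outdir, "report", seed, [], [outdir / "report.txt"])


_STAGE_FNS = {"simulate": stage_simulate, "metrics": stage_metrics,
              "score": stage_score, "fit": stage_fit,
              "syndromes": stage_syndromes, "report": stage_report}


def run_pipeline(config: dict, seed: int, outdir, stages=STAGES) -> Path:
    """Run the requested stages in order into ``outdir``.

    Any stage failure is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in _STAGE_FNS:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        t0 = time.perf_counter()
        log.info("stage %s: started", stage)
        try:
            _STAGE_FNS[stage](config, seed, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
    return outdir
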