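"""End-to-end orchestration: score -> CFA -> curves -> associations -> gaze.

A run consumes the standard input CSVs (events or trial scores, battery,
gaze, musicality), executes the enabled stages in dependency order with
one root seed split per stage, and writes a JSON + Markdown report:
CFA fit indices and factor correlations, error summaries, gaze change
points, curve population parameters and elpd model comparisons,
trial-wise association curves with shape summaries, and musicality
correlations.  An adapter maps an external deposit's column names onto
the pipeline schemas.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, curves, gaze, measurement, scoring

log = logging.getLogger("skillcurve")

__all__ = ["RunConfig", "run_pipeline", "ingest_osf", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the output dir."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path = "results/run"
    events: str | Path | None = None
    trial_scores: str | Path | None = None
    battery: str | Path | None = None
    gaze: str | Path | None = None
    musicality: str | Path | None = None
    tasks: tuple[str, ...] = ("piano", "pad")
    mcmc: curves.MCMCConfig = field(default_factory=lambda: curves.REDUCED_CONFIG)
    seed: int = 1
    run_cfa: bool = True
    run_curves: bool = True
    run_comparison: bool = False
    run_associations: bool = True
    run_gaze: bool = True
    make_plots: bool = False
    predictors: tuple[str, ...] | None = None   # default: factors + musicality

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        mc = raw.pop("mcmc", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if mc:
            cfg.mcmc = curves.MCMCConfig(**mc)
        if isinstance(cfg.tasks, list):
            cfg.tasks = tuple(cfg.tasks)
        return cfg


def _load(path, reader=pd.read_csv):
    if path is None:
        return None
    if isinstance(path, pd.DataFrame):
        return path
    return reader(path)


def _stage_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(cfg: RunConfig, *, data: dict | None = None) -> dict:
    """Execute the enabled stages and write report.json / report.md.

    ``data`` may supply in-memory DataFrames (keys matching the
    RunConfig path fields) instead of files.  On stage failure a
    :class:`PipelineError` names the stage; outputs of completed stages
    remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = data or {}
    report: dict = {"config": {"seed": cfg.seed, "tasks": list(cfg.tasks),
                               "mcmc": vars(cfg.mcmc)},
                    "versions": _versions(), "stages": {}}
    t_all = time.time()

    def timed(stage):
        def deco(fn):
            def wrapper(*a, **k):
                t0 = time.time()
                try:
                    res = fn(*a, **k)
                except Exception as exc:  # halt with stage name
                    _write_report(report, out)
                    raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
                report["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
                return res
            return wrapper
        return deco

    # ---- scoring ----------------------------------------------------
    scores = data.get("trial_scores")
    if scores is None:
        scores = _load(cfg.trial_scores)
    if scores is None:
        events = data.get("events")
        events = events if events is not None else _load(cfg.events, scoring.read_events)
        if events is None:
            raise PipelineError("stage 'score' failed: no events or trial scores given")
        from .synth import default_sequences

        scores = timed("score")(scoring.score_dataset)(events, default_sequences())
    scores.to_csv(out / "trial_scores.csv", index=False)
    report["errors"] = _error_summary(scores, cfg.tasks)

    # ---- measurement ------------------------------------------------
    factor_scores_df = None
    if cfg.run_cfa:
        battery = data.get("battery")
        battery = battery if battery is not None else _load(cfg.battery)
        if battery is not None:
            if "participant" in battery.columns:
                battery = battery.set_index("participant")

            @timed("cfa")
            def _cfa():
                ind = measurement.prepare_indicators(battery)
                model = measurement.fit_cfa(ind)
                idx = measurement.fit_indices(model)
                fs = measurement.factor_scores(model, ind)
                return model, idx, fs

            model, idx, factor_scores_df = _cfa()
            factor_scores_df.to_csv(out / "factors.csv")
            (out / "cfa_report.json").write_text(json.dumps({
                "fit_indices": idx.as_dict(),
                "loadings": model.loadings.round(4).to_dict(),
                "factor_correlations": model.factor_cov.round(4).to_dict(),
                "factor_correlation_se": model.param_se,
                "residual_variances": model.residual_var.round(4).to_dict(),
                "estimator": model.estimator, "converged": model.converged,
                "heywood": model.heywood,
            }, indent=1))
            report["cfa"] = {"fit_indices": idx.as_dict(),
                             "factor_correlations": model.factor_cov.round(3).to_dict(),
                             "converged": model.converged}

    # ---- learning curves --------------------------------------------
    posts: dict[str, curves.Posterior] = {}
    indiv: dict[str, pd.DataFrame] = {}
    if cfg.run_curves:
        report["curves"] = {}
        for k, task in enumerate(cfg.tasks):
            mc = cfg.mcmc.with_seed(_stage_seed(cfg.seed, 10 + k))

            @timed(f"curves_{task}")
            def _fit(task=task, mc=mc):
                return curves.fit_hierarchical(scores, mc, task=task)

            post = _fit()
            posts[task] = post
            indiv[task] = curves.individual_estimates(post)
            report["curves"][task] = {
                "population": post.population_summary(),
                "max_rhat": round(post.max_rhat(), 4),
                "divergences": post.divergences,
            }
            if cfg.run_comparison:
                mc2 = cfg.mcmc.with_seed(_stage_seed(cfg.seed, 20 + k))

                @timed(f"compare_{task}")
                def _cmp(task=task, mc2=mc2):
                    return curves.compare_models(scores, config=mc2, task=task)

                comp = _cmp()
                report["curves"][task]["elpd"] = comp.elpd
                report["curves"][task]["elpd_diff_vs_exponential"] = {
                    fam: float(comp.diff.loc["exponential", fam])
                    for fam in comp.elpd if fam != "exponential"
                }
        if indiv:
            combined = pd.concat(indiv, names=["task"]).reset_index()
            combined.to_csv(out / "individual_params.csv", index=False)
        if len(cfg.tasks) == 2 and len(indiv) == 2:
            report["cross_task_correlations"] = _cross_task(indiv, cfg.tasks)

    # ---- associations -----------------------------------------------
    musicality = data.get("musicality")
    musicality = musicality if musicality is not None else _load(cfg.musicality)
    if musicality is not None and "participant" in musicality.columns:
        musicality = musicality.set_index("participant")
    if cfg.run_associations and posts:
        predictors = _collect_predictors(factor_scores_df, musicality, cfg.predictors)
        report["associations"] = {}
        for k, task in enumerate(cfg.tasks):
            post = posts[task]
            fitted = post.fitted_curves()
            z = association.standardize_by_trial(fitted)
            g = indiv[task]["gamma"].reindex(fitted.index)
            report["associations"][task] = {}
            for j, (name, x) in enumerate(predictors.items()):
                mc = cfg.mcmc.with_seed(_stage_seed(cfg.seed, 100 + 10 * k + j))

                @timed(f"assoc_{task}_{name}")
                def _assoc(name=name, x=x, z=z, g=g, mc=mc):
                    return association.trialwise_model(
                        z, x.reindex(z.index).to_numpy(), g.to_numpy(),
                        mc, predictor=name)

                curve = _assoc()
                curve.to_frame().to_csv(out / f"associations_{task}_{name}.csv", index=False)
                report["associations"][task][name] = association.association_profile(curve)

        # learning-rate vs ability / musicality correlations
        abil = _join_abilities(factor_scores_df, musicality)
        if abil is not None:
            rate_corr = {}
            for task in cfg.tasks:
                g = indiv[task][["gamma"]].rename(columns={"gamma": f"gamma_{task}"})
                rate_corr[task] = association.rate_ability_correlations(
                    g, abil).to_dict(orient="records")
            report["rate_ability_correlations"] = rate_corr

    # ---- gaze --------------------------------------------------------
    if cfg.run_gaze:
        gz = data.get("gaze")
        gz = gz if gz is not None else _load(cfg.gaze)
        if gz is not None:
            report["gaze"] = {}
            gaze_indiv = {}
            for k, task in enumerate(cfg.tasks):
                mc = cfg.mcmc.with_seed(_stage_seed(cfg.seed, 200 + k))

                @timed(f"gaze_{task}")
                def _gz(task=task, mc=mc):
                    return gaze.fit_changepoint(gz, mc, task=task)

                fit = _gz()
                report["gaze"][task] = {
                    "tau": fit.population_tau(),
                    "max_rhat": round(fit.max_rhat(), 4),
                    "n_participants": len(fit.participants),
                }
                gaze_indiv[task] = fit.individual_tau()
                (out / f"gaze_fit_{task}.json").write_text(json.dumps(
                    report["gaze"][task], indent=1))
            pd.concat(gaze_indiv, names=["task"]).reset_index().to_csv(
                out / "gaze_individual.csv", index=False)

    if cfg.make_plots:
        _plots(out, scores, posts, report, cfg)

    report["wall_clock_s"] = round(time.time() - t_all, 2)
    _write_report(report, out)
    return report


def _versions() -> dict:
    import arviz
    import scipy

    from . import __version__

    return {"skillcurve": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "arviz": arviz.__version__}


def _error_summary(scores: pd.DataFrame, tasks) -> dict:
    out = {}
    for task in tasks:
        df = scores[scores["task"] == task]
        if df.empty:
            continue
        first = df[df["trial"] == df["trial"].min()]
        last = df[df["trial"] == df["trial"].max()]
        errs = df["wrong_key"] + df["wrong_order"]
        out[task] = {
            "errors_trial_first": round(float((first["wrong_key"] + first["wrong_order"]).mean()), 3),
            "errors_trial_last": round(float((last["wrong_key"] + last["wrong_order"]).mean()), 3),
            "error_rate_trial_first": round(float(first["error_rate"].mean() * 100), 2),
            "error_rate_trial_last": round(float(last["error_rate"].mean() * 100), 2),
            "total_errors": int(errs.sum()),
        }
    return out


def _cross_task(indiv: dict[str, pd.DataFrame], tasks) -> dict:
    from scipy import stats

    a, b = tasks
    joined = indiv[a].join(indiv[b], lsuffix=f"_{a}", rsuffix=f"_{b}").dropna()
    out = {}
    for p in ("alpha", "beta", "gamma"):
        r, pv = stats.pearsonr(joined[f"{p}_{a}"], joined[f"{p}_{b}"])
        out[p] = {"r": round(float(r), 3), "p": float(pv)}
    return out


def _collect_predictors(factors, musicality, names) -> dict[str, pd.Series]:
    preds: dict[str, pd.Series] = {}
    if factors is not None:
        for c in factors.columns:
            preds[c] = factors[c]
    if musicality is not None:
        for c in ("gold_msi_total", "piano_hours"):
            if c in musicality.columns:
                preds[c] = musicality[c]
    if names:
        preds = {k: v for k, v in preds.items() if k in names}
    return preds


def _join_abilities(factors, musicality):
    parts = [p for p in (factors, musicality) if p is not None]
    if not parts:
        return None
    out = parts[0]
    for p in parts[1:]:
        out = out.join(p, how="outer")
    return out


def _plots(out: Path, scores, posts, report, cfg) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for task, post in posts.items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        y, t = post.y, post.t
        for i in range(min(17, y.shape[0])):
            axes[0].plot(t, y[i], alpha=0.5, lw=0.8)
        fitted = post.fitted_curves()
        for i in range(min(17, len(fitted))):
            axes[1].plot(t, fitted.iloc[i], alpha=0.6, lw=0.8)
        axes[0].set_title(f"{task}: raw")
        axes[1].set_title(f"{task}: fitted")
        for ax in axes:
            ax.set_xlabel("trial")
        axes[0].set_ylabel("correct presses")
        fig.tight_layout()
        fig.savefig(out / f"curves_{task}.png", dpi=110)
        plt.close(fig)
    if "associations" in report:
        for task, preds in report["associations"].items():
            files = sorted(out.glob(f"associations_{task}_*.csv"))
            if not files:
                continue
            fig, ax = plt.subplots(figsize=(6, 3.5))
            for f in files:
                df = pd.read_csv(f)
                name = f.stem.replace(f"associations_{task}_", "")
                ax.plot(df["trial"], df["b_mean"], label=name)
                ax.fill_between(df["trial"], df["b_low"], df["b_high"], alpha=0.15)
            ax.axhline(0, color="k", lw=0.5)
            ax.set_xlabel("trial")
            ax.set_ylabel("standardized coefficient")
            ax.set_title(f"{task}: trial-wise associations")
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(out / f"associations_{task}.png", dpi=110)
            plt.close(fig)


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    lines = ["# skillcurve run report", ""]
    if "cfa" in report:
        fi = report["cfa"]["fit_indices"]
        lines += ["## Latent factor analysis",
                  f"CFI = {fi['CFI']:.3f}, TLI = {fi['TLI']:.3f}, IFI = {fi['IFI']:.3f}, "
                  f"RMSEA = {fi['RMSEA']:.3f}, SRMR = {fi['SRMR']:.3f}", ""]
    if "errors" in report:
        lines += ["## Errors"]
        for task, e in report["errors"].items():
            lines.append(
                f"- {task}: error rate {e['error_rate_trial_first']:.1f}% (first trial) "
                f"-> {e['error_rate_trial_last']:.1f}% (last trial)")
        lines.append("")
    if "gaze" in report:
        lines += ["## Gaze change points"]
        for task, g in report["gaze"].items():
            tau = g["tau"]
            lines.append(f"- {task}: tau = {tau['mean']:.2f} "
                         f"[{tau['lower']:.2f}, {tau['upper']:.2f}]")
        lines.append("")
    if "curves" in report:
        lines += ["## Learning curves"]
        for task, c in report["curves"].items():
            mg = c["population"]["mu_gamma"]
            lines.append(f"- {task}: gamma = {mg['mean']:.2f} "
                         f"[{mg['lower']:.2f}, {mg['upper']:.2f}], "
                         f"max Rhat {c['max_rhat']}")
        lines.append("")
    if "associations" in report:
        lines += ["## Trial-wise associations"]
        for task, preds in report["associations"].items():
            for name, prof in preds.items():
                lines.append(
                    f"- {task}/{name}: b1 = {prof['initial']:.2f}, "
                    f"min at trial {prof['min_trial']}, plateau {prof['plateau']:.2f}, "
                    f"dip-rebound: {prof['dip_rebound']}")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# external-deposit adapter

SCHEMAS = {
    "events": scoring.EVENT_COLUMNS,
    "trial_scores": scoring.SCORE_COLUMNS,
    "battery": ["participant"] + measurement.BATTERY_COLUMNS,
    "gaze": gaze.GAZE_COLUMNS,
    "musicality": ["participant", "gold_msi_total", "piano_hours"],
}


def ingest_osf(path, mapping: dict, out_dir) -> dict[str, Path]:
    """Convert a deposited data directory to the pipeline input CSVs.

    ``mapping`` has one entry per logical table, e.g.::

        {"trial_scores": {"file": "perf.csv",
                          "columns": {"id": "participant", "block": "trial", ...}}}

    Every required schema column must be bound; unbound columns raise an
    error listing the candidates present in the deposit file.
    Idempotent: re-ingesting writes identical files.
    """
    src = Path(path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for table, spec in mapping.items():
        if table not in SCHEMAS:
            raise ValueError(f"unknown table {table!r}; expected one of {sorted(SCHEMAS)}")
        df = pd.read_csv(src / spec["file"])
        colmap = spec.get("columns", {})
        df = df.rename(columns=colmap)
        required = [c for c in SCHEMAS[table] if c != "error_rate"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{table}: unmapped required column(s) {missing}; "
                f"deposit file {spec['file']!r} has candidates {sorted(df.columns)}")
        keep = [c for c in SCHEMAS[table] if c in df.columns]
        dest = out / f"{table}.csv"
        df[keep].to_csv(dest, index=False)
        written[table] = dest
    return written
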