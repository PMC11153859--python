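"""One-command orchestration: simulate -> fit -> link -> report.

A single YAML config drives the whole pipeline.  Every stochastic stage
draws its seed from the config, outputs are plain CSV/JSON, and a
manifest records the config hash, seeds, library versions, per-stage
wall-times and the full output list, so a rerun with the same config
reproduces the same files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import StudyConfig, generate_study
from .design import CONDITIONS
from .inference import (
    MCMCConfig, Posterior, fit_rl_hierarchical, fit_ddm_hierarchical,
    group_contrast, posterior_predictive,
)
from .linking import correlation_table, learning_curves, RL_COLS, DDM_ROWS

__all__ = ["RunManifest", "run_pipeline", "report", "default_config"]

GROUPS = ("young", "old")
_RL_TABLE_ROWS = ["eta_r", "eta_p", "tau_r", "tau_p",
                  "eta_r_minus_eta_p", "tau_r_minus_tau_p"]
_DDM_TABLE_ROWS = [f"alpha_{c}" for c in CONDITIONS] + \
                  [f"nu_{c}" for c in CONDITIONS] + ["t0"]


def default_config() -> dict:
    """A desk-scale default configuration (small cohort, reduced MCMC)."""
    return {
        "seed": 0,
        "study": {"n_young": 10, "n_old": 10},
        "mcmc": {"iterations": 500, "burn_in": 500, "chains": 4},
        "ppc_draws": 20,
        "make_figures": False,
    }


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict[str, str]
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(config, outdir) -> RunManifest:
    """Run the full pipeline from a config dict or YAML path.

    Emits, under ``outdir``: the synthetic study CSVs (or uses user CSVs
    given as ``learning_csv``/``search_csv`` config keys), fitted
    posteriors for each group and model, group-contrast summaries,
    correlation tables, learning curves, posterior predictive tables, a
    recovery scorecard when ground truth is available, a markdown report
    and ``manifest.json``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**default_config(), **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(
        config_hash=_config_hash(cfg), seed=seed,
        versions={"valsearch": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    manifest.outputs.append("config.yaml")

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t = time.perf_counter()
            def __exit__(self_, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_.t, 3)
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
        return _Timer()

    truth = None
    with stage("data"):
        if "learning_csv" in cfg and "search_csv" in cfg:
            from .design import read_learning_trials, read_search_trials
            learning = read_learning_trials(cfg["learning_csv"])
            search = read_search_trials(cfg["search_csv"])
        else:
            study = generate_study(StudyConfig.from_dict(cfg.get("study", {})),
                                   seed, outdir=outdir)
            learning, search, truth = study["learning"], study["search"], study["truth"]
            manifest.outputs += ["learning_trials.csv", "search_trials.csv", "truth.csv"]

    mcmc = cfg["mcmc"]
    posts: dict[tuple[str, str], Posterior] = {}
    for gi, group in enumerate(GROUPS):
        ltr = learning[learning["group"] == group]
        str_ = search[search["group"] == group]
        if len(ltr) == 0:
            continue
        with stage(f"fit_rl_{group}"):
            posts[("rl", group)] = fit_rl_hierarchical(
                ltr, MCMCConfig(seed=seed + 101 + gi, model="rl", **mcmc))
            posts[("rl", group)].save(outdir / f"posterior_rl_{group}")
            manifest.outputs.append(f"posterior_rl_{group}/draws.csv")
        with stage(f"fit_ddm_{group}"):
            posts[("ddm", group)] = fit_ddm_hierarchical(
                str_, MCMCConfig(seed=seed + 201 + gi, model="ddm", **mcmc))
            posts[("ddm", group)].save(outdir / f"posterior_ddm_{group}")
            manifest.outputs.append(f"posterior_ddm_{group}/draws.csv")

    with stage("descriptives"):
        curves = learning_curves(learning, block_size=5)
        curves.to_csv(outdir / "learning_curves.csv", index=False)
        manifest.outputs.append("learning_curves.csv")

    with stage("contrasts"):
        rows = []
        for model, params in (("rl", _RL_TABLE_ROWS), ("ddm", _DDM_TABLE_ROWS)):
            if ("rl" if model == "rl" else "ddm", "young") not in posts:
                continue
            if (model, "old") not in posts:
                continue
            for p in params:
                c = group_contrast(posts[(model, "young")], posts[(model, "old")], p)
                rows.append({"model": model, "parameter": p,
                             "mean_diff": c.mean_diff,
                             "ci_lo": c.ci95[0], "ci_hi": c.ci95[1]})
        if rows:
            pd.DataFrame(rows).to_csv(outdir / "group_contrasts.csv", index=False)
            manifest.outputs.append("group_contrasts.csv")

    with stage("linking"):
        for group in GROUPS:
            if ("rl", group) not in posts or ("ddm", group) not in posts:
                continue
            rl_modes = posts[("rl", group)].individual_table(stat="mode")
            ddm_modes = posts[("ddm", group)].individual_table(stat="mode")
            tab = correlation_table(rl_modes, ddm_modes)
            tab.to_csv(outdir / f"correlations_{group}.csv", index=False)
            manifest.outputs.append(f"correlations_{group}.csv")

    with stage("ppc"):
        ppcs = {}
        for (model, group), post in posts.items():
            data = learning if model == "rl" else search
            ppc = posterior_predictive(
                model, post, data[data["group"] == group],
                seed=seed + 301, n_draws=int(cfg["ppc_draws"]))
            ppcs[(model, group)] = ppc
            ppc.table.to_csv(outdir / f"ppc_{model}_{group}.csv", index=False)
            manifest.outputs.append(f"ppc_{model}_{group}.csv")

    if cfg.get("make_figures"):
        with stage("figures"):
            manifest.outputs += _make_figures(outdir, curves, ppcs)

    if truth is not None and posts:
        with stage("recovery"):
            rows = []
            for group in GROUPS:
                sub = truth[truth["group"] == group].set_index("participant_id")
                if ("rl", group) in posts:
                    est = posts[("rl", group)].individual_table().set_index("participant_id")
                    for p in RL_COLS:
                        rows.append({"group": group, "parameter": p,
                                     "pearson_r": float(np.corrcoef(
                                         sub.loc[est.index, p], est[p])[0, 1])})
                if ("ddm", group) in posts:
                    est = posts[("ddm", group)].individual_table().set_index("participant_id")
                    for p in DDM_ROWS:
                        rows.append({"group": group, "parameter": p,
                                     "pearson_r": float(np.corrcoef(
                                         sub.loc[est.index, p], est[p])[0, 1])})
            pd.DataFrame(rows).to_csv(outdir / "recovery_scorecard.csv", index=False)
            manifest.outputs.append("recovery_scorecard.csv")

    with stage("report"):
        text = report(outdir)
        (outdir / "report.md").write_text(text)
        manifest.outputs.append("report.md")

    manifest.save(outdir / "manifest.json")
    missing = [f for f in manifest.outputs if not (outdir / f).exists()]
    if missing:
        raise StageError(f"stage 'manifest' failed: outputs missing {missing}")
    return manifest


def _make_figures(outdir: Path, curves: pd.DataFrame, ppcs: dict) -> list[str]:
    """Render learning-curve and PPC panels as PNGs under figures/."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in curves.groupby("condition"):
        ax.errorbar(sub["block"], sub["proportion"], yerr=sub["se"],
                    label=cond, capsize=2)
    ax.set(xlabel="block", ylabel="proportion target choices", ylim=(0, 1))
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "learning_curves.png", dpi=120)
    plt.close(fig)
    written.append("figures/learning_curves.png")

    for (model, group), ppc in ppcs.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        tab = ppc.table
        x = np.arange(len(tab))
        ax.fill_between(x, tab["band_lo"], tab["band_hi"], alpha=0.3,
                        label="95% predictive band")
        ax.plot(x, tab["observed"], "k.-", label="observed")
        ax.set(title=f"PPC {model} / {group}",
               ylabel="choice proportion" if model == "rl" else "RT quantile (s)")
        ax.legend()
        fig.tight_layout()
        name = f"figures/ppc_{model}_{group}.png"
        fig.savefig(outdir / name, dpi=120)
        plt.close(fig)
        written.append(name)
    return written


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    show = df.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(floatfmt.format)
    header = "| " + " | ".join(show.columns) + " |"
    sep = "|" + "|".join("---" for _ in show.columns) + "|"
    body = "\n".join("| " + " | ".join(str(v) for v in row) + " |"
                     for row in show.itertuples(index=False))
    return "\n".join([header, sep, body])


def report(run_dir) -> str:
    """Build the markdown report of a completed (or partial) run.

    Missing artefacts are listed in place rather than failing, so a
    partial run still yields a readable summary.
    """
    run_dir = Path(run_dir)
    parts = ["# Value learning and visual search — pipeline report", ""]

    def section(title: str, filename: str, render) -> None:
        parts.append(f"## {title}")
        path = run_dir / filename
        if not path.exists():
            parts.append(f"*missing: `{filename}` was not produced in this run*")
        else:
            parts.append(render(pd.read_csv(path)))
        parts.append("")

    section("Learning curves", "learning_curves.csv", lambda df: _md_table(
        df[df["block"].isin([1, 5, 10, 15, 20])]))

    def rl_tables(_):
        out = []
        for group in GROUPS:
            p = run_dir / f"posterior_rl_{group}" / "summary.csv"
            if not p.exists():
                out.append(f"*missing: RL posterior for {group} group*")
                continue
            df = pd.read_csv(p)
            df = df[df["parameter"].isin(_RL_TABLE_ROWS)]
            df = df.set_index("parameter").loc[_RL_TABLE_ROWS].reset_index()
            out.append(f"### {group.capitalize()} participants\n" + _md_table(
                df[["parameter", "mean", "ci_lo", "ci_hi", "rhat"]]))
        return "\n\n".join(out)

    parts += ["## Learning-model posteriors", rl_tables(None), ""]

    def ddm_tables(_):
        out = []
        for group in GROUPS:
            p = run_dir / f"posterior_ddm_{group}" / "summary.csv"
            if not p.exists():
                out.append(f"*missing: DDM posterior for {group} group*")
                continue
            df = pd.read_csv(p)
            df = df[df["parameter"].isin(_DDM_TABLE_ROWS)]
            out.append(f"### {group.capitalize()} participants\n" + _md_table(
                df[["parameter", "mean", "ci_lo", "ci_hi", "rhat"]]))
        return "\n\n".join(out)

    parts += ["## Diffusion-model posteriors", ddm_tables(None), ""]
    section("Group contrasts (young − old)", "group_contrasts.csv", _md_table)

    parts.append("## Cross-model correlations")
    any_corr = False
    for group in GROUPS:
        p = run_dir / f"correlations_{group}.csv"
        if p.exists():
            any_corr = True
            parts.append(f"### {group.capitalize()} participants\n"
                         + _md_table(pd.read_csv(p)))
    if not any_corr:
        parts.append("*missing: no correlation tables were produced in this run*")
    parts.append("")

    parts.append("## Model checks")
    found = []
    for model in ("rl", "ddm"):
        for group in GROUPS:
            p = run_dir / f"ppc_{model}_{group}.csv"
            if p.exists():
                df = pd.read_csv(p)
                found.append(f"- PPC {model}/{group}: "
                             f"{df['within'].mean():.0%} of cells inside the 95% band")
    rec = run_dir / "recovery_scorecard.csv"
    if rec.exists():
        df = pd.read_csv(rec)
        found.append(f"- recovery scorecard: median r = {df['pearson_r'].median():.2f} "
                     f"over {len(df)} parameters")
    parts.append("\n".join(found) if found else "*missing: no checks were produced*")
    parts.append("")
    return "\n".join(parts)
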