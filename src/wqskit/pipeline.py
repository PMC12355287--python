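"""Pipeline orchestration, reporting and run provenance.

``run_pipeline`` sequences the full analysis — exposure linkage, decile
transformation, train/validation split, bootstrap weight estimation,
stage-2 binary and/or discrete-time survival fits, effect-modification and
sensitivity fits — and writes a results bundle (weights CSV, fit JSON,
figures) together with a deterministic run manifest.  The manifest records
the config snapshot, the seed fan-out, the package version and SHA-256
digests of the input files; wall-clock timings go to a separate run log so
that identical config + seed reproduces a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .exposure import ConstituentPanel, link_cohort
from .interaction import ModifierSpec, fit_with_interaction, subgroup_table
from .simulate import SimulationConfig, simulate_cohort
from .survival import truncate_followup  # noqa: F401  (re-export for CLI use)
from .wqs import WQSRegression

logger = logging.getLogger(__name__)

DEFAULT_MODIFIERS = {
    "age_ge_55": lambda r: (r["age"] >= 55).astype(int),
    "female": lambda r: r["female"].astype(int),
    "deceased_donor": lambda r: r["deceased_donor"].astype(int),
    "cit_gt_12h": lambda r: (r["cit_hours"] > 12).astype(int),
}

BINARY_OUTCOMES = {"dgf": "dgf", "rejection": "rejection"}
SURVIVAL_OUTCOMES = {
    "death": ("months_death", "event_death"),
    "dcgf": ("months_graft_failure", "event_graft_failure"),
}


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (YAML-serialisable)."""

    seed: int = 0
    n_quantiles: int = 10
    n_bootstrap: int = 100
    train_fraction: float = 0.4
    spline_df: int = 4
    max_months: int = 60
    adjust_stage1: bool = True
    outcomes: tuple = ("dgf", "death")
    modifiers: tuple = ()
    sensitivity_horizon: int | None = None   # e.g. 12 for first-year-only refits
    extra_covariates: tuple = ()             # e.g. copollutant columns in cohort
    covariates: tuple = ("age_std", "female", "deceased_donor", "cit_std",
                         "deprivation")
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_manifest(config: PipelineConfig, input_files: dict) -> dict:
    return {
        "wqskit_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {name: _sha256(Path(p)) for name, p in input_files.items()},
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    panel: ConstituentPanel | None = None,
    cohort: pd.DataFrame | None = None,
    input_files: dict | None = None,
) -> dict:
    """Execute the full analysis and write the results bundle.

    When ``panel``/``cohort`` are omitted a synthetic cohort is generated
    from ``config.simulation`` (seeded by ``config.seed``).  Returns a dict
    of in-memory results keyed by outcome.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    timings, results = {}, {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                r = fn()
            except Exception as err:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed: {err}; "
                    "check the inputs listed in the manifest"
                ) from err
            timings[name] = time.perf_counter() - t0
            return r
        return deco

    if panel is None or cohort is None:
        sim = stage("simulate")(
            lambda: simulate_cohort(SimulationConfig(**config.simulation),
                                    seed=config.seed)
        )
        panel, cohort = sim.panel, sim.recipients
        sim.save(out / "data")
    cohort = cohort.reset_index(drop=True)

    exposures = stage("link")(lambda: link_cohort(panel, cohort))
    linked = cohort[cohort["id"].isin(exposures.index)].reset_index(drop=True)
    covariates = linked[list(config.covariates) + list(config.extra_covariates)]

    for outcome in config.outcomes:
        if outcome in BINARY_OUTCOMES:
            family, ycols = "binomial", BINARY_OUTCOMES[outcome]
            y = linked[ycols].to_numpy()
        elif outcome in SURVIVAL_OUTCOMES:
            family = "pooled-logistic"
            mcol, ecol = SURVIVAL_OUTCOMES[outcome]
            y = linked[[ecol, mcol]]
        else:
            raise RuntimeError(f"pipeline stage 'fit:{outcome}' failed: unknown "
                               f"outcome {outcome!r}")
        model = WQSRegression(
            n_quantiles=config.n_quantiles,
            n_bootstrap=config.n_bootstrap,
            train_fraction=config.train_fraction,
            family=family,
            spline_df=config.spline_df,
            max_months=config.max_months,
            adjust_stage1=config.adjust_stage1,
            random_state=config.seed,
        )
        stage(f"fit:{outcome}")(
            lambda m=model, yy=y: m.fit(exposures, yy, covariates=covariates)
        )
        results[outcome] = {"model": model}
        _write_outcome(out, outcome, model)

        if config.modifiers:
            index = model.transform(exposures).reset_index(drop=True)
            mask = (~(model.split_.assignment == "train")).to_numpy()
            sub = []
            for mname in config.modifiers:
                values = DEFAULT_MODIFIERS[mname](linked).to_numpy()
                spec = ModifierSpec(mname, values[mask])
                kwargs = dict(covariates=covariates[mask], family=family,
                              spline_df=config.spline_df,
                              max_months=config.max_months)
                if family == "binomial":
                    res = fit_with_interaction(index[mask], spec,
                                               y=y[mask], **kwargs)
                else:
                    res = fit_with_interaction(index[mask], spec,
                                               time_event=y[mask], **kwargs)
                sub.append(res)
            tab = subgroup_table(sub)
            tab.to_csv(out / f"subgroups_{outcome}.csv", index=False)
            results[outcome]["subgroups"] = tab

        if config.sensitivity_horizon and family == "pooled-logistic":
            model_h = WQSRegression(
                n_quantiles=config.n_quantiles, n_bootstrap=config.n_bootstrap,
                train_fraction=config.train_fraction, family=family,
                spline_df=config.spline_df, max_months=config.sensitivity_horizon,
                adjust_stage1=config.adjust_stage1, random_state=config.seed,
            )
            stage(f"sensitivity:{outcome}")(
                lambda m=model_h, yy=y: m.fit(exposures, yy, covariates=covariates)
            )
            _write_outcome(out, f"{outcome}_first{config.sensitivity_horizon}mo",
                           model_h)
            results[outcome]["sensitivity"] = model_h

    render_weight_report(
        {o: r["model"] for o, r in results.items()}, out / "weights_report"
    )

    manifest = build_manifest(config, input_files or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    timings["total"] = time.perf_counter() - t_start
    (out / "run_log.json").write_text(json.dumps(
        {"timings_seconds": timings,
         "n_dropped_linkage": exposures.attrs.get("n_dropped", 0)}, indent=2))
    logger.info("pipeline complete in %.1fs", timings["total"])
    return results


def _round6(x):
    return float(np.round(float(x), 6))


def _write_outcome(out: Path, outcome: str, model: WQSRegression):
    res = model.result_
    weights = model.weights_.sort_values(ascending=False)
    pd.DataFrame({
        "constituent": weights.index,
        "mean_weight": np.round(weights.to_numpy(), 6),
        "relative_importance_pct": np.round(100 * weights.to_numpy(), 1),
        "n_boot_used": model.n_boot_used_,
    }).to_csv(out / f"weights_{outcome}.csv", index=False)
    payload = {
        "outcome": outcome,
        "family": res.family,
        "beta1": _round6(res.beta1),
        "se1": _round6(res.se1),
        "ci95": [_round6(res.ci95[0]), _round6(res.ci95[1])],
        "effect_ratio": _round6(res.effect_ratio),
        "percent_increase": _round6(res.percent_increase),
        "percent_increase_ci": [_round6(res.percent_increase_ci[0]),
                                _round6(res.percent_increase_ci[1])],
        "n_boot_used": model.n_boot_used_,
        "nobs": res.nobs,
        "coefficients": {k: _round6(v) for k, v in res.params.items()},
        "notes": res.notes,
    }
    (out / f"fit_{outcome}.json").write_text(json.dumps(payload, indent=2,
                                                        sort_keys=True))


def render_weight_report(models: dict, out_prefix) -> pd.DataFrame:
    """Bar chart + CSV of relative importance (%) per outcome.

    Percentages are the simplex weights scaled to 100 and rounded to one
    decimal; constituents are ordered by descending weight.
    """
    if not models:
        raise ValueError("need at least one fitted model to report")
    out_prefix = Path(out_prefix)
    frames = []
    fig, axes = plt.subplots(1, len(models), figsize=(5 * len(models), 4),
                             squeeze=False)
    for ax, (outcome, model) in zip(axes[0], models.items()):
        w = model.weights_.sort_values(ascending=False)
        pct = np.round(100 * w.to_numpy(), 1)
        frames.append(pd.DataFrame({
            "outcome": outcome, "constituent": w.index,
            "relative_importance_pct": pct,
        }))
        ax.bar(range(len(w)), pct)
        ax.set_xticks(range(len(w)), list(w.index), rotation=90, fontsize=7)
        ax.set_ylabel("relative importance (%)")
        ax.set_title(outcome)
    fig.tight_layout()
    fig.savefig(out_prefix.with_suffix(".svg"))
    plt.close(fig)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out_prefix.with_suffix(".csv"), index=False)
    return table
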