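"""End-to-end orchestration: tune, fit, cross-validate, bootstrap, triangulate.

The pipeline applies every configured selection method to one dataset with a
common protocol: hyperparameters tuned by repeated k-fold CV (minimum MAE),
a final model per method, internal-vs-CV fit comparison, bootstrap selection
stability, cross-method aggregation, and OLS refits of the stable covariate
subsets.  Every intermediate artefact is persisted before the report is
assembled, so a crashed or deleted report can be rebuilt without refitting.

All randomness flows from three named seeds (synthesis, folds, bootstrap);
reruns with an identical configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datasets import ConfigurationError, Dataset, SyntheticSpec, generate_dataset
from .estimators import (
    LinearFit,
    PenaltySpec,
    RbvsConfig,
    selected_support,
)
from .mars import MarsModel
from .methods import METHODS, TUNABLE, cv_method, fit_method, tune_method
from .model_selection import CVResult
from .stability import (
    DEFAULT_TRIANGULATED,
    StabilityResult,
    aggregate_stability,
    bootstrap_stability,
    refit_subset_cv,
    stability_spearman,
    stable_subsets,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full triangulation run."""

    outdir: str
    input_csv: Optional[str] = None
    synthetic: Optional[SyntheticSpec] = None
    outcome: str = "y"
    methods: tuple[str, ...] = METHODS
    k: int = 10
    repeats: int = 10
    tuning_repeats: Optional[int] = None
    B: int = 500
    any_threshold: float = 90.0
    median_threshold: float = 50.0
    folds_seed: int = 0
    bootstrap_seed: int = 1
    triangulated: tuple[str, ...] = DEFAULT_TRIANGULATED
    support_tol: float = 1e-3
    rbvs: Optional[RbvsConfig] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unsupported methods: {sorted(unknown)}")
        if self.input_csv is None and self.synthetic is None:
            raise ConfigurationError("provide either input_csv or a synthetic spec")
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "triangulated", tuple(self.triangulated))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        d["rbvs"] = self.rbvs.to_dict() if self.rbvs else None
        d["methods"] = list(self.methods)
        d["triangulated"] = list(self.triangulated)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticSpec.from_dict(d["synthetic"])
        if d.get("rbvs"):
            d["rbvs"] = RbvsConfig(**d["rbvs"])
        d["methods"] = tuple(d.get("methods", METHODS))
        d["triangulated"] = tuple(d.get("triangulated", DEFAULT_TRIANGULATED))
        return cls(**d)


@dataclass
class StudyReport:
    """The assembled result tables of one pipeline run."""

    table1: pd.DataFrame  # per-method: n selected, internal & CV MAE / R^2
    table2: pd.DataFrame  # covariate x method coefficients of final models
    table3: pd.DataFrame  # stability of highly stable covariates, max/median
    table4: pd.DataFrame  # method x method Spearman correlations
    refits: dict[str, CVResult]
    provenance: dict


def _hyper_to_jsonable(method: str, hyper) -> object:
    if isinstance(hyper, PenaltySpec):
        return {"penalty": hyper.to_dict()}
    if isinstance(hyper, dict):
        out = {}
        for key, val in hyper.items():
            if isinstance(val, RbvsConfig):
                out[key] = val.to_dict()
            elif isinstance(val, tuple):
                out[key] = list(val)
            else:
                out[key] = val
        return out
    return hyper


def _hyper_from_jsonable(method: str, payload):
    if isinstance(payload, dict) and "penalty" in payload:
        d = payload["penalty"]
        return PenaltySpec(
            lam=d["lam"],
            alpha=d.get("alpha", 1.0),
            gamma=float("nan") if d.get("gamma") is None else d["gamma"],
            weights=tuple(d["weights"]) if d.get("weights") else None,
        )
    if isinstance(payload, dict) and "config" in payload:
        out = dict(payload)
        out["config"] = RbvsConfig(**payload["config"])
        if "support" in out and out["support"] is not None:
            out["support"] = tuple(out["support"])
        return out
    return payload


def _bootstrap_seed_for(config: RunConfig, method: str) -> int:
    return (config.bootstrap_seed * 1009 + METHODS.index(method) * 7919) % (2**31 - 1)


def load_input(config: RunConfig) -> Dataset:
    if config.input_csv is not None:
        return Dataset.from_csv(config.input_csv, outcome=config.outcome)
    return generate_dataset(config.synthetic)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Run all stages for every configured method and assemble the report.

    A method that fails end-to-end is dropped from the report with a logged
    reason; the pipeline continues with the remaining methods.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = load_input(config)
    data_path = outdir / "dataset.csv"
    if not data_path.exists():
        ds.to_csv(data_path)

    tuning_repeats = config.tuning_repeats or config.repeats
    fits: dict[str, object] = {}
    hypers: dict[str, object] = {}
    cvs: dict[str, CVResult] = {}
    stabilities: dict[str, StabilityResult] = {}

    for method in config.methods:
        try:
            t0 = time.perf_counter()
            hyper = _stage_tune(config, ds, method, outdir, tuning_repeats)
            fit = _stage_fit(config, ds, method, hyper, outdir)
            if method == "rbvs":
                hyper = {**(hyper or {}), "support": fit.support}
            cv = _stage_cv(config, ds, method, hyper, outdir)
            stab = _stage_stability(config, ds, method, hyper, outdir)
            logger.info("method %s done in %.1fs", method, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - method dropped, run continues
            logger.error("method %s failed and is dropped from the report: %s",
                         method, exc)
            continue
        fits[method] = fit
        hypers[method] = hyper
        cvs[method] = cv
        stabilities[method] = stab

    if not fits:
        raise ConfigurationError("every configured method failed")

    # --- triangulation -----------------------------------------------------
    include = [m for m in config.triangulated if m in stabilities]
    summary = aggregate_stability(list(stabilities.values()), include=include)
    summary = stable_subsets(summary, config.any_threshold, config.median_threshold)
    supports = {
        m: selected_support(fits[m], tol=config.support_tol) for m in fits
    }
    included_supports = [supports[m] for m in include if m in supports]
    summary.consensus_set = (
        set.intersection(*included_supports) if included_supports else set()
    )
    median90 = {
        cid
        for cid, med in zip(summary.covariate_ids, summary.median_stability)
        if med > 90.0
    }
    refits: dict[str, CVResult] = {}
    for name, subset in (
        ("median90", median90),
        ("median50", summary.median50_set),
        ("any90", summary.any90_set),
    ):
        if subset:
            refits[name] = refit_subset_cv(
                ds, subset, k=config.k, repeats=config.repeats,
                seed=config.folds_seed,
            )
        else:
            logger.warning("stable subset %s is empty; refit skipped", name)
    summary.refit_cv = refits
    stab_list = [stabilities[m] for m in config.methods if m in stabilities]
    if len(stab_list) > 1:
        spearman, spearman_methods = stability_spearman(stab_list)
    else:
        spearman, spearman_methods = np.ones((1, 1)), [stab_list[0].method]

    report = _assemble_report(
        config, ds, fits, hypers, cvs, stabilities, summary, spearman,
        spearman_methods,
    )
    write_reports(report, outdir)
    return report


# ---------------------------------------------------------------------------
# stages with persistence / resume
# ---------------------------------------------------------------------------

def _stage_tune(config, ds, method, outdir, tuning_repeats):
    path = outdir / f"{method}_hyper.json"
    if path.exists():
        return _hyper_from_jsonable(method, json.loads(path.read_text()))
    if method in TUNABLE:
        grids = {}
        if method == "aenet":
            enet_path = outdir / "enet_hyper.json"
            if enet_path.exists():
                grids["enet_hyper"] = _hyper_from_jsonable(
                    "enet", json.loads(enet_path.read_text())
                )
        tuned = tune_method(
            ds, method, k=config.k, repeats=tuning_repeats,
            seed=config.folds_seed, grids=grids,
        )
        hyper = tuned.best
        curve = pd.DataFrame(tuned.to_records())
        curve.to_csv(outdir / f"{method}_tuning.csv", index=False)
    elif method == "rbvs":
        hyper = {"config": config.rbvs or RbvsConfig()}
    else:
        hyper = None
    path.write_text(json.dumps(_hyper_to_jsonable(method, hyper), indent=2))
    return hyper


def _stage_fit(config, ds, method, hyper, outdir):
    path = outdir / f"{method}_fit.json"
    if path.exists() and method != "mars":
        return LinearFit.from_json(path.read_text())
    fit = fit_method(ds, method, hyper, seed=config.folds_seed)
    if isinstance(fit, LinearFit):
        path.write_text(fit.to_json())
    else:  # MARS serialises its hinge terms
        payload = {
            "method": "mars",
            "intercept": fit.intercept,
            "terms": [
                [[h.cov_id, h.knot, h.direction] for h in term]
                for term in fit.basis_terms
            ],
            "term_coefficients": list(map(float, fit.term_coefficients)),
            "degree": fit.degree,
            "nprune": fit.nprune,
        }
        path.write_text(json.dumps(payload, indent=2))
    return fit


def _stage_cv(config, ds, method, hyper, outdir):
    path = outdir / f"{method}_cv.json"
    if path.exists():
        d = json.loads(path.read_text())
        return CVResult(
            internal_mae=d["internal_mae"], internal_r2=d["internal_r2"],
            cv_mae=d["cv_mae"], cv_r2=d["cv_r2"],
            per_fold_mae=np.asarray(d["per_fold_mae"]),
            folds_seed=d["folds_seed"], k=d["k"], repeats=d["repeats"],
            incomplete=d.get("incomplete", False),
        )
    cv = cv_method(ds, method, hyper, k=config.k, repeats=config.repeats,
                   seed=config.folds_seed)
    payload = cv.to_dict()
    payload["per_fold_mae"] = list(map(float, cv.per_fold_mae))
    path.write_text(json.dumps(payload, indent=2))
    return cv


def _stage_stability(config, ds, method, hyper, outdir):
    path = outdir / f"{method}_stability.csv"
    seed = _bootstrap_seed_for(config, method)
    if path.exists():
        df = pd.read_csv(path)
        return StabilityResult(
            method=method,
            n_bootstraps=config.B,
            covariate_ids=list(df["covariate"]),
            selection_pct=df["selection_pct"].to_numpy(),
            coef_distributions={},
            bootstrap_seed=seed,
        )
    stab = bootstrap_stability(
        ds, (method, hyper), B=config.B, seed=seed,
        support_tol=config.support_tol,
    )
    stab.method = method  # tag with the registry name
    pd.DataFrame(
        {"covariate": stab.covariate_ids, "selection_pct": stab.selection_pct}
    ).to_csv(path, index=False)
    coef_path = outdir / f"{method}_coef_distributions.json"
    coef_path.write_text(json.dumps(stab.coef_distributions, indent=2))
    return stab


# ---------------------------------------------------------------------------
# report assembly and output
# ---------------------------------------------------------------------------

def _assemble_report(config, ds, fits, hypers, cvs, stabilities, summary,
                     spearman, spearman_methods) -> StudyReport:
    rows = []
    supports = {m: selected_support(fits[m], tol=config.support_tol) for m in fits}
    for m in config.methods:
        if m not in fits:
            continue
        cv = cvs[m]
        rows.append(
            {
                "method": m,
                "n_selected": len(supports[m]),
                "internal_mae": cv.internal_mae,
                "internal_r2": cv.internal_r2,
                "cv_mae": cv.cv_mae,
                "cv_r2": cv.cv_r2,
            }
        )
    table1 = pd.DataFrame(rows)

    included = [m for m in summary.methods_included if m in fits]
    union: list[str] = []
    for m in included:
        for cid in sorted(supports[m]):
            if cid not in union:
                union.append(cid)
    coef_cols = {}
    for m in included:
        fit = fits[m]
        if isinstance(fit, MarsModel):
            # report the per-parent net linear coefficient is not defined for
            # hinge terms; mark selection with the term coefficients summed
            col = {}
            for term, coef in zip(fit.basis_terms, fit.term_coefficients):
                for h in term:
                    col[h.cov_id] = col.get(h.cov_id, 0.0) + float(coef)
        else:
            col = {cid: b for cid, b in fit.coefficient_map().items()}
        coef_cols[m] = [col.get(cid, np.nan) for cid in union]
    table2 = pd.DataFrame(coef_cols, index=pd.Index(union, name="covariate"))

    stab_mat = pd.DataFrame(
        {m: stabilities[m].selection_pct for m in config.methods if m in stabilities},
        index=pd.Index(list(ds.covariate_ids), name="covariate"),
    )
    mask = summary.max_stability > config.any_threshold
    t3 = pd.DataFrame(
        {
            "max_stability": summary.max_stability[mask],
            "median_stability": summary.median_stability[mask],
        },
        index=pd.Index(np.array(summary.covariate_ids)[mask], name="covariate"),
    )
    t3 = t3.join(stab_mat[[m for m in included]], how="left")
    table3 = t3.sort_values("median_stability", ascending=False)

    table4 = pd.DataFrame(spearman, index=spearman_methods, columns=spearman_methods)

    provenance = {
        "config": config.to_dict(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "n": ds.n,
        "p": ds.p,
        "seeds": {
            "folds": config.folds_seed,
            "bootstrap": config.bootstrap_seed,
            "synthesis": config.synthetic.seed if config.synthetic else None,
        },
    }
    return StudyReport(
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        refits=summary.refit_cv,
        provenance=provenance,
    )


def write_reports(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the four tables plus refit metrics and provenance (6 files).

    CSV dialect: comma-separated, UTF-8, header row, covariates as rows;
    an empty cell in table2 means the covariate was not selected.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df, with_index in (
        ("table1.csv", report.table1, False),
        ("table2.csv", report.table2, True),
        ("table3.csv", report.table3, True),
        ("table4.csv", report.table4, True),
    ):
        path = outdir / name
        df.to_csv(path, index=with_index, na_rep="")
        paths.append(path)
    refit_path = outdir / "refits.json"
    refit_path.write_text(
        json.dumps({k: v.to_dict() for k, v in report.refits.items()}, indent=2)
    )
    paths.append(refit_path)
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(report.provenance, indent=2))
    paths.append(prov_path)
    return paths
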