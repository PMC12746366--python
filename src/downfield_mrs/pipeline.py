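"""End-to-end analysis pipeline: simulate -> process -> fit-peaks -> fit-T1
-> fit-exchange -> cohort summary.

Each stage is a thin orchestration over the library modules; per-subject
fitting failures degrade to missing values (as in the in-vivo analysis,
where poorly fitting peaks were omitted per subject) rather than aborting
the run.  Identical configuration and seed produce identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cohort import CohortTable, anova_tukey, paired_compare, summarize_cohort
from .container import read_container, write_container
from .hsvd import DEFAULT_WINDOWS, build_basis, extract_series
from .processing import process_scan
from .relaxation import (
    WATER_METABOLITE_M0_RATIO,
    WATER_T1_MS,
    fit_model1,
    fit_model2,
)
from .synthetic import AcquisitionProtocol, SubjectDataset, TruthSampler, make_cohort

logger = logging.getLogger("downfield_mrs")

__all__ = ["default_config", "run_pipeline", "analyze_cohort", "analyze_subject"]


def default_config() -> dict[str, Any]:
    """Baseline configuration; any subtree may be overridden."""
    return {
        "simulate": {"n_subjects": 8, "spread": 1.0},
        "process": {"lb": 5.0, "align": True, "similarity_min": 0.7,
                    "weight_mode": "peak"},
        "fit_peaks": {"n_components": 60, "windows": {k: list(v) for k, v in
                                                      DEFAULT_WINDOWS.items()}},
        "fit_exchange": {"t1_water_ms": WATER_T1_MS,
                         "m0_ratio": WATER_METABOLITE_M0_RATIO,
                         "niter": 15},
        "cohort": {"paired": True},
        "seed": 0,
    }


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def analyze_subject(
    ds: SubjectDataset, config: dict[str, Any], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Process and fit every resonance of one subject.

    Returns (amplitudes, model1, model2) tidy frames; resonances whose
    peak assignment or fits fail are reported with NaN values and a
    ``flag`` explaining the failure.
    """
    proc = config["process"]
    fp = config["fit_peaks"]
    fx = config["fit_exchange"]
    windows = {k: tuple(v) for k, v in fp["windows"].items()}

    m0c = process_scan(ds.m0, ds.water_ref, lb=proc["lb"], align=proc["align"],
                       similarity_min=proc["similarity_min"],
                       weight_mode=proc["weight_mode"])
    basis = build_basis(m0c, windows=windows, n_components=fp["n_components"])
    scans = {
        "selective": {ts: process_scan(f, ds.water_ref, lb=proc["lb"],
                                       align=proc["align"],
                                       similarity_min=proc["similarity_min"],
                                       weight_mode=proc["weight_mode"])
                      for ts, f in ds.selective.items()},
        "broadband": {ts: process_scan(f, ds.water_ref, lb=proc["lb"],
                                       align=proc["align"],
                                       similarity_min=proc["similarity_min"],
                                       weight_mode=proc["weight_mode"])
                      for ts, f in ds.broadband.items()},
    }
    series = extract_series(scans, m0c, basis,
                            ts_m0=float(ds.m0.meta.get("TS", 10000.0)))

    amp_rows, m1_rows, m2_rows = [], [], []
    for label in windows:
        if label not in basis.labels:
            m2_rows.append((ds.subject_id, label, np.nan, np.nan, np.nan,
                            "unassigned"))
            for exp_ in ("selective", "broadband"):
                m1_rows.append((ds.subject_id, label, exp_, np.nan, np.nan,
                                np.nan, np.nan, "unassigned"))
            continue
        fits = {}
        for exp_ in ("selective", "broadband"):
            s = series[(label, exp_)]
            for ts, a, r2 in zip(s.ts_ms, s.amplitudes, s.r_squared):
                amp_rows.append((ds.subject_id, label, exp_, ts, a, r2))
            fit = fit_model1(s.ts_ms, s.amplitudes, experiment=exp_)
            fits[exp_] = fit
            m1_rows.append(
                (ds.subject_id, label, exp_, fit.m0, fit.k, fit.t1_ms,
                 fit.rsquared, "" if fit.success else "model1_failed")
            )
        if not (fits["selective"].success and fits["broadband"].success):
            m2_rows.append((ds.subject_id, label, np.nan, np.nan, np.nan,
                            "model1_failed"))
            continue
        sel = series[(label, "selective")]
        br = series[(label, "broadband")]
        try:
            m2 = fit_model2(
                sel.ts_ms, sel.amplitudes, br.ts_ms, br.amplitudes,
                k_sel=fits["selective"].k, k_broad=fits["broadband"].k,
                t1_b_ms=fx["t1_water_ms"], m0_b_over_m0_a=fx["m0_ratio"],
                seed=seed, niter=fx["niter"],
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("model2 fit failed for %s/%s: %s",
                           ds.subject_id, label, exc)
            m2_rows.append((ds.subject_id, label, np.nan, np.nan, np.nan,
                            "model2_error"))
            continue
        flag = "" if m2.success else "model2_flagged"
        m2_rows.append((ds.subject_id, label, m2.t1_a_ms, m2.sigma_ab_hz,
                        m2.rsquared, flag))

    amplitudes = pd.DataFrame(
        amp_rows,
        columns=["subject", "resonance", "experiment", "TS_ms", "amplitude",
                 "r_squared"],
    )
    model1 = pd.DataFrame(
        m1_rows,
        columns=["subject", "resonance", "experiment", "M0", "k",
                 "T1_apparent_ms", "r_squared", "flag"],
    )
    model2 = pd.DataFrame(
        m2_rows,
        columns=["subject", "resonance", "T1_corrected_ms", "sigma_AB_hz",
                 "r_squared", "flag"],
    )
    return amplitudes, model1, model2


def analyze_cohort(
    datasets: list[SubjectDataset], config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Run processing + both model fits over a cohort; returns result tables."""
    cfg = _merge(default_config(), config)
    seed = cfg["seed"] if seed is None else seed
    amp_frames, m1_frames, m2_frames = [], [], []
    for i, ds in enumerate(datasets):
        try:
            a, m1, m2 = analyze_subject(ds, cfg, seed=seed + i)
        except Exception as exc:
            logger.warning("subject %s failed: %s", ds.subject_id, exc)
            m2_frames.append(pd.DataFrame(
                [(ds.subject_id, r, np.nan, np.nan, np.nan, "subject_failed")
                 for r in cfg["fit_peaks"]["windows"]],
                columns=["subject", "resonance", "T1_corrected_ms",
                         "sigma_AB_hz", "r_squared", "flag"]))
            continue
        amp_frames.append(a)
        m1_frames.append(m1)
        m2_frames.append(m2)

    amplitudes = pd.concat(amp_frames, ignore_index=True) if amp_frames else \
        pd.DataFrame()
    model1 = pd.concat(m1_frames, ignore_index=True) if m1_frames else \
        pd.DataFrame()
    model2 = pd.concat(m2_frames, ignore_index=True)

    cohort_tbl = build_cohort_table(model1, model2)
    summary = summarize_cohort(cohort_tbl)
    stats_tbl = cohort_statistics(cohort_tbl, paired=cfg["cohort"]["paired"])
    return {
        "amplitudes": amplitudes,
        "model1": model1,
        "model2": model2,
        "cohort": cohort_tbl.data,
        "summary": summary,
        "stats": stats_tbl,
    }


def build_cohort_table(model1: pd.DataFrame, model2: pd.DataFrame) -> CohortTable:
    """Assemble the subject x resonance x quantity table from fit frames.

    Flagged fits contribute NaN (missing), matching the in-vivo handling of
    peaks omitted for poor fit quality.
    """
    rows = []
    if not model1.empty:
        m1 = model1.copy()
        bad1 = m1["flag"].astype(str) != ""
        m1.loc[bad1, "T1_apparent_ms"] = np.nan
        pivot = m1.pivot_table(index=["subject", "resonance"],
                               columns="experiment", values="T1_apparent_ms",
                               aggfunc="first")
        for (subj, res), r in pivot.iterrows():
            t1s = r.get("selective", np.nan)
            t1b = r.get("broadband", np.nan)
            rows.append((subj, res, "T1_selective", t1s))
            rows.append((subj, res, "T1_broadband", t1b))
            ratio = t1b / t1s if np.isfinite(t1s) and np.isfinite(t1b) else np.nan
            rows.append((subj, res, "ratio", ratio))
    for _, r in model2.iterrows():
        bad = str(r["flag"]) != ""
        rows.append((r["subject"], r["resonance"], "T1_corrected",
                     np.nan if bad else r["T1_corrected_ms"]))
        rows.append((r["subject"], r["resonance"], "sigma",
                     np.nan if bad else r["sigma_AB_hz"]))
    return CohortTable(pd.DataFrame(
        rows, columns=["subject", "resonance", "quantity", "value"]))


def cohort_statistics(table: CohortTable, paired: bool = True) -> pd.DataFrame:
    """Group comparisons: per-resonance t-tests and cross-resonance ANOVA/Tukey."""
    rows = []
    for res in table.resonances:
        try:
            t, p, n = paired_compare(table.values("T1_selective", res),
                                     table.values("T1_broadband", res),
                                     paired=paired)
            rows.append(("t_test_T1_sel_vs_broad", res, "", t, p, n))
        except ValueError:
            rows.append(("t_test_T1_sel_vs_broad", res, "", np.nan, np.nan, 0))
    for qty in ("ratio", "T1_corrected", "sigma"):
        groups = {
            res: table.values(qty, res).dropna().to_numpy()
            for res in table.resonances
        }
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        try:
            f, p, pairwise = anova_tukey(groups)
        except ValueError:
            continue
        n_total = int(sum(v.size for v in groups.values()))
        rows.append((f"anova_{qty}", "all", "", f, p, n_total))
        for _, pr in pairwise.iterrows():
            rows.append((f"tukey_{qty}", pr["group_a"], pr["group_b"],
                         np.nan, pr["p_adj"], n_total))
    return pd.DataFrame(
        rows, columns=["test", "group_a", "group_b", "statistic", "p", "n"])


def run_pipeline(
    config: dict[str, Any] | None = None,
    out_dir: str | Path = "results",
    seed: int | None = None,
    datasets: list[SubjectDataset] | None = None,
    container: str | Path | None = None,
    write_spectra: bool = False,
) -> Path:
    """Execute the full pipeline and write tidy CSV result tables.

    Inputs come from, in order of precedence: ``datasets`` (in memory), a
    spectra ``container`` path, or the synthetic generator configured under
    ``config["simulate"]``.  Outputs under ``out_dir``: ``truth.csv`` (when
    simulated), ``amplitudes.csv``, ``model1.csv``, ``model2.csv``,
    ``cohort.csv``, ``summary.csv``, ``stats.csv`` and ``run.json`` (the
    resolved configuration and seed).
    """
    cfg = _merge(default_config(), config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if datasets is None:
        if container is not None:
            logger.info("reading container %s", container)
            datasets = read_container(container)
        else:
            sim = cfg["simulate"]
            logger.info("simulating %d subjects (seed %d)", sim["n_subjects"],
                        cfg["seed"])
            sampler = TruthSampler(spread=sim.get("spread", 1.0))
            protocol = AcquisitionProtocol(
                **sim.get("protocol", {})) if "protocol" in sim else \
                AcquisitionProtocol()
            datasets, truth = make_cohort(sim["n_subjects"], sampler, protocol,
                                          seed=cfg["seed"])
            if write_spectra:
                write_container(datasets, out / "spectra.h5")

    results = analyze_cohort(datasets, cfg, seed=cfg["seed"])
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
    for name in ("amplitudes", "model1", "model2", "cohort", "summary", "stats"):
        results[name].to_csv(out / f"{name}.csv", index=False)
    run_info = {"seed": cfg["seed"], "config": _jsonable(cfg),
                "n_subjects": len(datasets)}
    (out / "run.json").write_text(json.dumps(run_info, indent=1))
    logger.info("pipeline complete: %s", out)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
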