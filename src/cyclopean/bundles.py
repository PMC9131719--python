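"""Experiment bundles: deterministic on-disk layout and re-analysis.

A bundle directory contains::

    cohort.json          ground-truth cohort and run metadata
    phase_trials.csv     every phase-combination trial
    qiocsf_trials.csv    every adaptive 2AFC trial
    session_summary.csv  one row per subject x session (phase + AULIOCSF)
    report.json          the statistical report
    manifest.json        SHA-256 content hashes of every written file

Identical (config, seed) runs produce byte-identical bundles; the report can
be reproduced from the CSVs alone (see :func:`analyze_bundle`).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .observers import ExperimentDataset
from .stats import (RepeatedMeasuresAnova, RepeatedMeasuresTable, bf01_bic,
                    normalize_to_baseline, rm_anova_one_way)

__all__ = ["run_analysis", "write_experiment_bundle", "analyze_bundle",
           "read_manifest"]

_FLOAT_FMT = "%.12g"


def run_analysis(summary: pd.DataFrame, measure: str = "phase",
                 correction: str = "auto", baseline: str = "pre") -> dict:
    """Baseline-normalized one-way RM-ANOVA + BF01 on a session summary.

    ``summary`` needs columns subject, session and the measure column
    ("perceived_phase" for measure="phase", "aulio" for measure="aulio").
    """
    column = {"phase": "perceived_phase", "aulio": "aulio"}.get(measure)
    if column is None:
        raise ValueError("measure must be 'phase' or 'aulio'")
    wide = summary.pivot(index="subject", columns="session", values=column)
    order = [c for c in ("pre", "post0", "post10", "post20", "post30", "post40")
             if c in wide.columns]
    table = RepeatedMeasuresTable(wide[order])
    changes = normalize_to_baseline(table, baseline, drop_baseline=True)
    result = rm_anova_one_way(changes, correction=correction, effect="time")
    bf = bf01_bic(changes)
    return {
        "measure": measure,
        "baseline": baseline,
        "n_subjects": int(changes.values.shape[0]),
        "conditions": [str(c) for c in changes.conditions],
        "anova": {
            "effect": result.effect, "F": result.F, "df1": result.df1,
            "df2": result.df2, "p": result.p, "epsilon": result.epsilon,
            "mauchly_w": result.mauchly_w, "mauchly_p": result.mauchly_p,
            "GG_corrected": result.corrected, "degenerate": result.degenerate,
        },
        "bf01": {"value": bf.bf01, "band": bf.band,
                 "bic_null": bf.bic_null, "bic_alt": bf.bic_alt},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def write_experiment_bundle(
    dataset: ExperimentDataset, report: dict, out_dir: str | Path
) -> dict:
    """Write the canonical bundle layout; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_json(out / "cohort.json", dataset.meta)
    dataset.phase_trials.to_csv(out / "phase_trials.csv", index=False,
                                float_format=_FLOAT_FMT)
    dataset.iocsf_trials.to_csv(out / "qiocsf_trials.csv", index=False,
                                float_format=_FLOAT_FMT)
    summary = dataset.phase_sessions.merge(
        dataset.iocsf_sessions, on=["subject", "session", "time_min"], how="outer"
    ).sort_values(["subject", "session"], kind="stable")
    summary.to_csv(out / "session_summary.csv", index=False, float_format=_FLOAT_FMT)
    _write_json(out / "report.json", report)

    names = ["cohort.json", "phase_trials.csv", "qiocsf_trials.csv",
             "session_summary.csv", "report.json"]
    manifest = {"files": {name: _sha256(out / name) for name in names}}
    _write_json(out / "manifest.json", manifest)
    return manifest


def read_manifest(bundle_dir: str | Path) -> dict:
    return json.loads((Path(bundle_dir) / "manifest.json").read_text())


def analyze_bundle(bundle_dir: str | Path, measure: str = "phase",
                   correction: str = "auto") -> dict:
    """Recompute the statistical report from a bundle's session_summary.csv."""
    path = Path(bundle_dir) / "session_summary.csv"
    if not path.exists():
        raise FileNotFoundError(f"no session summary at {path}")
    summary = pd.read_csv(path)
    return run_analysis(summary, measure=measure, correction=correction)
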