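"""Fit-artifact tables, structured summaries and run manifests."""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult


def parameter_table(fit: FitResult, item_labels: Sequence[str] | None = None) -> pd.DataFrame:
    """One row per free difficulty slot: item, level, estimate, SE."""
    slots = fit.layout.difficulty_slots
    items = [j for j, _ in slots]
    se = (
        fit.se.difficulties
        if fit.se is not None
        else np.full(len(slots), np.nan)
    )
    return pd.DataFrame(
        {
            "slot": np.arange(len(slots)),
            "item": [item_labels[j] if item_labels else j + 1 for j in items],
            "level": [lv for _, lv in slots],
            "estimate": fit.params.difficulties,
            "se": se,
        }
    )


def class_difficulty_table(
    fit: FitResult, item_labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Item x profile expansion of the anchored difficulties.

    Cells anchored to the same slot hold literally equal values; columns are
    labelled by attribute profile.  The reported quantity is b in
    P = sigma(theta - b) (difficulty: positive is hard).
    """
    from .likelihood import class_difficulty_matrix

    B = class_difficulty_matrix(fit.params, fit.layout)
    index = (
        list(item_labels)
        if item_labels
        else [f"item{j + 1}" for j in range(B.shape[0])]
    )
    return pd.DataFrame(B, index=index, columns=[f"({','.join(l)})" for l in fit.space.labels])


def monotonicity_report(fit: FitResult) -> pd.DataFrame:
    """Post-fit check of level ordering within items.

    Level order (1 easiest) is expected but not enforced during estimation;
    this reports, per item, whether the estimated difficulties ascend with
    level index and the largest inversion if not.
    """
    rows = []
    slots = fit.layout.difficulty_slots
    b = fit.params.difficulties
    for j in sorted({s[0] for s in slots}):
        vals = [b[s] for s, (jj, _) in enumerate(slots) if jj == j]
        diffs = np.diff(vals)
        rows.append(
            {
                "item": j + 1,
                "n_levels": len(vals),
                "monotone": bool((diffs >= 0).all()) if len(vals) > 1 else True,
                "max_inversion": float(-diffs.min()) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def fit_summary(fit: FitResult) -> dict:
    mono = monotonicity_report(fit)
    summary = {
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "n_obs": fit.n_obs,
        "converged": bool(fit.converged),
        "iterations": int(fit.iterations),
        "mode": fit.mode,
        "anchored": bool(fit.anchored),
        "AIC": fit.ic["AIC"],
        "BIC": fit.ic["BIC"],
        "ABIC": fit.ic["ABIC"],
        "ability_sd": float(fit.params.ability_sd),
        "mixing": {l: float(p) for l, p in zip(fit.space.labels, fit.params.mixing)},
        "class_mass": {
            l: float(p) for l, p in zip(fit.space.labels, fit.class_mass)
        },
        "monotone_items": int(mono["monotone"].sum()),
        "items_with_inversions": mono.loc[~mono["monotone"], "item"].tolist(),
    }
    return summary


def write_fit_artifacts(
    fit: FitResult,
    outdir: str | Path,
    item_labels: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write parameter table, per-class difficulty matrix, posterior and summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "parameters": outdir / "parameters.csv",
        "class_difficulties": outdir / "class_difficulties.csv",
        "posterior": outdir / "posterior.csv",
        "summary": outdir / "summary.json",
    }
    parameter_table(fit, item_labels).to_csv(paths["parameters"], index=False)
    class_difficulty_table(fit, item_labels).to_csv(paths["class_difficulties"])
    post = pd.DataFrame(fit.posterior, columns=list(fit.space.labels))
    post.to_csv(paths["posterior"], index=False)
    paths["summary"].write_text(json.dumps(fit_summary(fit), indent=2))
    return paths


def write_manifest(
    outdir: str | Path, command: str, config: dict, seed: int | None
) -> Path:
    """Record everything needed to reproduce a run byte-for-byte."""
    from importlib.metadata import version

    try:
        ver = version("qamrm")
    except Exception:  # pragma: no cover - editable installs without metadata
        ver = "unknown"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(
        json.dumps(
            {"command": command, "package_version": ver, "seed": seed,
             "config": config},
            indent=2,
            default=str,
        )
    )
    return path
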