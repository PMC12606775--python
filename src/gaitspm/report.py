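"""Result serialisation and figures.

Figures follow the study's two-panel layout: for each comparison, the left
panel shows the two conditions' mean +- SD waveforms over the stride cycle
and the right panel the t-field with the critical threshold (dashed) and
supra-threshold clusters shaded; cluster p-values are printed with a
"< 0.001" floor.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd

from .io import FLOAT_FMT, write_stride_matrix
from .types import SPMResult, StrideMatrix

P_FLOOR = 0.001


def comparisons_table(comparisons: list[SPMResult]) -> pd.DataFrame:
    rows = []
    for r in comparisons:
        base = {"variable": r.variable, "condition_a": r.condition_a,
                "condition_b": r.condition_b, "dof": r.dof,
                "fwhm_nodes": r.fwhm, "resels": r.resels,
                "t_star": r.t_star, "alpha": r.alpha,
                "significant": r.significant}
        if r.clusters:
            for c in r.clusters:
                rows.append({**base, "cluster_start_pct": c.start_node,
                             "cluster_end_pct": c.end_node,
                             "cluster_max_abs_t": c.max_abs_t,
                             "cluster_extent_nodes": c.extent_nodes,
                             "cluster_p": c.p,
                             "cluster_p_report": c.formatted_p(P_FLOOR)})
        else:
            rows.append(base)
    return pd.DataFrame(rows)


def spm_result_json(r: SPMResult) -> dict:
    return {
        "variable": r.variable, "condition_a": r.condition_a,
        "condition_b": r.condition_b, "dof": r.dof, "fwhm_nodes": r.fwhm,
        "resels": r.resels, "t_star": r.t_star, "alpha": r.alpha,
        "significant": r.significant,
        "clusters": [{"start_node": c.start_node, "end_node": c.end_node,
                      "max_abs_t": c.max_abs_t,
                      "extent_nodes": c.extent_nodes, "p": c.p,
                      "p_report": c.formatted_p(P_FLOOR)}
                     for c in r.clusters],
        "flags": r.flags,
    }


def write_tfield_csv(r: SPMResult, path: Path) -> None:
    q = len(r.t_field)
    pd.DataFrame({"stride_pct": np.linspace(0, 100, q), "t": r.t_field,
                  "t_star": np.full(q, r.t_star)}
                 ).to_csv(path, index=False, float_format=FLOAT_FMT)


def plot_comparison(result: SPMResult, matrix_a: StrideMatrix,
                    matrix_b: StrideMatrix, path: Path,
                    unit: str = "") -> Path:
    """Two-panel figure: mean +- SD curves (left), t-field + clusters
    (right)."""
    q = matrix_a.node_count
    x = np.linspace(0, 100, q)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    for m, color in ((matrix_a, "tab:gray"), (matrix_b, "tab:blue")):
        mean, sd = m.values.mean(axis=0), m.values.std(axis=0, ddof=1)
        ax1.plot(x, mean, color=color, label=m.condition)
        ax1.fill_between(x, mean - sd, mean + sd, color=color, alpha=0.25)
    ax1.set_xlabel("stride (%)")
    ax1.set_ylabel(unit or result.variable)
    ax1.legend(frameon=False, fontsize=8)
    ax1.set_title(result.variable, fontsize=9)

    ax2.plot(x, result.t_field, "k-", lw=1)
    for s in (result.t_star, -result.t_star):
        ax2.axhline(s, color="r", ls="--", lw=0.8)
    for c in result.clusters:
        ax2.axvspan(x[c.start_node], x[c.end_node], color="0.8", zorder=0)
        ax2.text(0.5 * (x[c.start_node] + x[c.end_node]),
                 np.sign(result.t_field[c.start_node]) * result.t_star,
                 f"p {c.formatted_p(P_FLOOR)}", fontsize=6, ha="center")
    ax2.axhline(0, color="0.6", lw=0.5)
    ax2.set_xlabel("stride (%)")
    ax2.set_ylabel("SPM{t}")
    ax2.set_title(f"{result.condition_a} vs {result.condition_b} "
                  f"(t* = {result.t_star:.2f})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def write_report(report, semg: dict[str, dict[str, StrideMatrix]],
                 kin: dict[str, dict[str, StrideMatrix]], outdir: Path,
                 make_figures: bool = False) -> None:
    """Write all result artefacts of a study run into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comparisons_table(report.comparisons).to_csv(
        outdir / "comparisons.csv", index=False, float_format=FLOAT_FMT)
    summary = {
        "seed": report.seed,
        "version": report.version,
        "alpha": report.config.alpha,
        "strides_per_condition": report.config.strides_per_condition,
        "accounting": {name: {"target": acc.target, "total": acc.total,
                              "retained": acc.retained,
                              "removed": acc.removed}
                       for name, acc in report.accounting.items()},
        "rvc": report.rvc,
        "comparisons": [spm_result_json(r) for r in report.comparisons],
        "config": report.config.to_dict(),
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2))
    (outdir / "run.log").write_text("\n".join(report.log) + "\n")

    mats = outdir / "stride_matrices"
    mats.mkdir(exist_ok=True)
    for group in (semg, kin):
        for var, per_cond in group.items():
            for label, m in per_cond.items():
                write_stride_matrix(m, mats / f"{var}_{label}.csv")
    tdir = outdir / "t_fields"
    tdir.mkdir(exist_ok=True)
    lookup = {**semg, **kin}
    for r in report.comparisons:
        stem = f"{r.variable}_{r.condition_a}_vs_{r.condition_b}"
        write_tfield_csv(r, tdir / f"{stem}.csv")
        if make_figures:
            figdir = outdir / "figures"
            figdir.mkdir(exist_ok=True)
            unit = "%RVC" if r.variable in semg else "degrees"
            p = plot_comparison(r, lookup[r.variable][r.condition_a],
                                lookup[r.variable][r.condition_b],
                                figdir / f"{stem}.svg", unit=unit)
            report.figure_paths.append(str(p))
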