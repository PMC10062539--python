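"""Table and figure emission for experiment grids.

Every output file starts with a reproducibility header (comment lines with
the seeds and regressor settings that produced it), so a reported number
can always be traced back to a rerunnable configuration.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn import metrics as skmetrics

from .evaluation import EvalTag, GridResult, PredictionSet, stabilizing_labels


def _header_lines(config: dict) -> list[str]:
    return [f"# {key} = {val}" for key, val in sorted(config.items())]


def write_grid_tsv(grid: GridResult, path: str | Path) -> None:
    """Grid as TSV with a commented reproducibility header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(grid.config):
            fh.write(line + "\n")
        grid.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_grid_markdown(grid: GridResult, path: str | Path) -> None:
    """Grid as a Markdown table (R/AUC/Q2 per variant, scheme, subset)."""
    path = Path(path)
    t = grid.table
    lines = ["| variant | subset | scheme | n | R | AUC | Q2 |",
             "|---|---|---|---|---|---|---|"]
    for _, r in t.iterrows():
        lines.append(
            f"| {r['variant']} | {r['subset']} | {r['scheme']} | {r['n']} "
            f"| {r['R']:.4f} | {r['AUC']:.4f} | {r['Q2']:.4f} |"
        )
    footer = [""] + _header_lines(grid.config)
    path.write_text("\n".join(lines + footer) + "\n")


def write_predictions(ps: PredictionSet, path: str | Path) -> None:
    """Per-record prediction dump (record id, observed, predicted, fold)."""
    ps.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _iter_cells(grid: GridResult):
    for (vname, sname), ps in grid.predictions.items():
        if vname == "unbalanced":
            subsets = [("forward", ps.subset(EvalTag.HELDOUT)),
                       ("reverse", ps.subset(EvalTag.COUNTERPART))]
        elif vname == "balanced":
            held = ps.subset(EvalTag.HELDOUT)
            subsets = [("forward", held[held["direction"] == "forward"]),
                       ("reverse", held[held["direction"] == "reverse"])]
        else:
            subsets = [("all", ps.subset(EvalTag.HELDOUT))]
        for subset_name, df in subsets:
            if len(df):
                yield vname, sname, subset_name, df


def scatter_figure(grid: GridResult) -> plt.Figure:
    """Experimental vs predicted ΔΔG scatter, one panel per grid cell."""
    cells = list(_iter_cells(grid))
    ncol = 2
    nrow = (len(cells) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(8, 3.2 * nrow), squeeze=False)
    for ax in axes.flat[len(cells):]:
        ax.set_visible(False)
    for ax, (vname, sname, subset, df) in zip(axes.flat, cells):
        ax.scatter(df["observed"], df["predicted"], s=6, alpha=0.4)
        lim = [min(df["observed"].min(), df["predicted"].min()),
               max(df["observed"].max(), df["predicted"].max())]
        ax.plot(lim, lim, lw=0.8, color="grey")
        ax.set_title(f"{vname}/{subset} — {sname}", fontsize=9)
        ax.set_xlabel("experimental ΔΔG (kcal/mol)", fontsize=8)
        ax.set_ylabel("predicted ΔΔG (kcal/mol)", fontsize=8)
    fig.tight_layout()
    return fig


def roc_figure(grid: GridResult, neutral: str = "destab") -> plt.Figure:
    """ROC curves per grid cell from sweeping a threshold over predictions."""
    cells = list(_iter_cells(grid))
    fig, ax = plt.subplots(figsize=(6, 6))
    for vname, sname, subset, df in cells:
        labels = stabilizing_labels(df["observed"].to_numpy(), neutral)
        if neutral == "exclude":
            keep = labels >= 0
            df, labels = df[keep], labels[keep]
        if len(np.unique(labels)) < 2:
            continue
        fpr, tpr, _ = skmetrics.roc_curve(labels, df["predicted"])
        auc = skmetrics.auc(fpr, tpr)
        ax.plot(fpr, tpr, lw=1,
                label=f"{vname}/{subset} {sname} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], lw=0.8, color="grey", ls="--")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def write_figures(grid: GridResult, outdir: str | Path, fmt: str = "png") -> list[Path]:
    """Write the scatter and ROC figures; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, figfun in (("scatter", scatter_figure), ("roc", roc_figure)):
        fig = figfun(grid)
        p = outdir / f"{name}.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
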