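"""Result writers: TSV table (6 significant digits), full-precision JSON
sidecar, JSON run report, and optional Manhattan / QQ plots."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .gwas import GwasResult


def write_results(
    result: GwasResult,
    outdir: str | Path,
    report: dict | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise InputError(f"output directory {outdir} is not writable: {e}") from None

    paths: dict[str, Path] = {}
    table = result.table.copy()
    # flagged markers carry an empty p-value cell in the TSV
    for col in ("z", "pvalue", "neglog10p", "b_hat", "sd_b"):
        table[col] = table[col].where(table["flag"] == "ok", other=np.nan)
    paths["results"] = outdir / "results.tsv"
    table.to_csv(paths["results"], sep="\t", index=False, float_format="%.6g", na_rep="")

    paths["results_full"] = outdir / "results_full.json"
    full = {
        c: [None if (isinstance(v, float) and np.isnan(v)) else v
            for v in result.table[c].tolist()]
        for c in result.table.columns
    }
    paths["results_full"].write_text(json.dumps(full))

    if report is not None:
        paths["report"] = outdir / "report.json"
        paths["report"].write_text(json.dumps(report, indent=2, default=float))

    has_map = "chrom" in table.columns and table["chrom"].notna().any()
    if plots and has_map:
        paths["manhattan"] = manhattan_plot(
            result, outdir / "manhattan.png"
        )
        paths["qq"] = qq_plot(result, outdir / "qq.png")
    return paths


def manhattan_plot(result: GwasResult, path: str | Path) -> Path:
    """−log10 p by genome position, with the Bonferroni rejection line in red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table.dropna(subset=["neglog10p"]).copy()
    t["chrom"] = pd.to_numeric(t["chrom"], errors="coerce")
    t = t.sort_values(["chrom", "pos"]).reset_index(drop=True)
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for k, (_, grp) in enumerate(t.groupby("chrom", sort=True)):
        ax.scatter(x[grp.index], grp["neglog10p"], s=6,
                   color="#30639c" if k % 2 == 0 else "#87a8cc")
    if result.bonferroni_neglog10 is not None:
        ax.axhline(result.bonferroni_neglog10, color="red", lw=1)
    ax.set_xlabel("marker (genome order)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def qq_plot(result: GwasResult, path: str | Path) -> Path:
    """Observed vs expected −log10 p under the global null."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.qq is None:
        raise InputError("result carries no QQ coordinates")
    expected, observed = result.qq
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.plot(expected, observed, ".", ms=3, color="#30639c")
    lim = max(float(expected.max()), float(observed.max())) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    label = "" if result.lambda_gc is None else f"$\\lambda_{{GC}}$ = {result.lambda_gc:.3f}"
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    if label:
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
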