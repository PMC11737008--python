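"""Figures: interaction plots of log lambda and LTRE bar charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .params import PROCESSES  # noqa: E402


def plot_lambda_interaction(lambda_table, path):
    """Climate x management interaction plot of log lambda.

    Expects the pipeline's lambda table (columns stratum, log_lam and
    optionally boot_sd_log_lam for error bars)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    idx = {row["stratum"]: row for _, row in lambda_table.iterrows()}
    x = [0, 1]
    for management, style in (("grazing", "o-"), ("mowing", "s--")):
        ys, errs = [], []
        for climate in ("ambient", "future"):
            row = idx.get(f"{climate}_{management}")
            if row is None:
                ys.append(np.nan)
                errs.append(0.0)
            else:
                ys.append(row["log_lam"])
                sd = row.get("boot_sd_log_lam", np.nan)
                errs.append(0.0 if not np.isfinite(sd) else sd)
        ax.errorbar(x, ys, yerr=errs, fmt=style, capsize=3, label=management)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(x, ["ambient", "future"])
    ax.set_ylabel(r"log $\lambda$")
    ax.set_xlabel("climate")
    ax.legend(title="management")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ltre_bars(ltre_result, path):
    """Scaled LTRE contributions grouped into the five demographic
    processes."""
    grouped = ltre_result.scaled_process_contributions
    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(PROCESSES)
    vals = [grouped[p] for p in names]
    ax.bar(names, vals, color=["#4c72b0" if v >= 0 else "#c44e52" for v in vals])
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("scaled LTRE contribution")
    ax.set_title(" vs ".join(ltre_result.pair))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
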