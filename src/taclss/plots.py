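"""Bland-Altman and concentration-time summary figures (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .lss_validation import BlandAltman


def bland_altman_plot(ba: BlandAltman, title: str, path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.pairs["average"], ba.pairs["difference"], s=18, alpha=0.7)
    ax.axhline(ba.mean_diff, color="k", label=f"mean diff {ba.mean_diff:.1f}")
    for lim in (ba.loa_low, ba.loa_high):
        ax.axhline(lim, color="k", linestyle=":")
    ax.set_xlabel("average of predicted and observed AUC (ng·h/mL)")
    ax.set_ylabel("predicted − observed (ng·h/mL)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def concentration_time_plot(concentrations: pd.DataFrame, path: str) -> None:
    """Spaghetti + mean curve over the nominal sampling times."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for _, grp in concentrations.groupby("patient_id"):
        grp = grp.sort_values("time_h")
        ax.plot(grp["time_h"], grp["conc_ng_ml"], color="grey", alpha=0.25, lw=0.8)
    mean_curve = concentrations.groupby("time_h")["conc_ng_ml"].mean()
    ax.plot(mean_curve.index, mean_curve.values, color="purple", lw=2.5, label="mean")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("tacrolimus (ng/mL)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
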