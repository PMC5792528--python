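"""Plots hanging off the pipeline products."""

from __future__ import annotations

import pandas as pd

from lifelines import KaplanMeierFitter

CLASS_LABELS = {
    1: "1 (weak / inconsistent)",
    2: "2 (weak / consistent)",
    3: "3 (strong / inconsistent)",
    4: "4 (strong / consistent)",
}


def plot_survival_by_class(records: pd.DataFrame, class_col: str = "class_multi", ax=None):
    """Kaplan-Meier survival on the age axis, one curve per
    strength-consistency class, with delayed entry respected."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for cls, d in records.groupby(class_col):
        km = KaplanMeierFitter()
        km.fit(
            d["exit_age"], event_observed=d["event"], entry=d["entry_age"],
            label=CLASS_LABELS.get(int(cls), str(cls)),
        )
        km.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("survival probability")
    ax.set_title("Survival by strength-consistency class")
    return ax


def plot_schoenfeld(results, term: str, ax=None):
    """Scaled-time scatter of Schoenfeld residuals for one model term."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    j = results.names.index(term)
    fit = results._fit
    ax.scatter(fit.event_times, fit.schoenfeld[:, j], s=14)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("event age (years)")
    ax.set_ylabel(f"Schoenfeld residual: {term}")
    return ax
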