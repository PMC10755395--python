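"""Bland-Altman plot panels.

Four views of one paired comparison: raw scatter, classic difference
vs mean, log-scale difference vs mean, and the regression approach
with back-transformed (ratio) axis labels.
"""

from __future__ import annotations

import numpy as np

from .agreement import ClassicBlandAltman, LogRatioAgreement


def bland_altman_panels(P, I, title: str | None = None):
    """Return a matplotlib Figure with the four agreement panels."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    P = np.asarray(P, dtype=float)
    I = np.asarray(I, dtype=float)
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    ax = axes[0, 0]
    ax.scatter(I, P, s=8, alpha=0.5)
    lim = [0, max(P.max(), I.max()) * 1.05]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("intake estimate")
    ax.set_ylabel("purchase estimate")
    ax.set_title("(a) scatter")

    cba = ClassicBlandAltman().fit(P, I)
    ax = axes[0, 1]
    mean = (P + I) / 2
    ax.scatter(mean, P - I, s=8, alpha=0.5)
    ax.axhline(0, color="k", lw=1)
    ax.axhline(cba.mean_diff_, color="tab:blue", lw=1.5)
    for y in (cba.loa_lo_, cba.loa_hi_):
        ax.axhline(y, color="tab:blue", ls="--", lw=1)
    ax.set_xlabel("mean of measures")
    ax.set_ylabel("difference (purchase - intake)")
    ax.set_title("(b) Bland-Altman")

    valid = (P > 0) & (I > 0)
    lp, li = np.log(P[valid]), np.log(I[valid])
    d, m = lp - li, (lp + li) / 2

    ax = axes[1, 0]
    ax.scatter(m, d, s=8, alpha=0.5)
    ax.axhline(0, color="k", lw=1)
    ax.axhline(d.mean(), color="tab:blue", lw=1.5)
    sd = d.std(ddof=1)
    for y in (d.mean() - 1.96 * sd, d.mean() + 1.96 * sd):
        ax.axhline(y, color="tab:blue", ls="--", lw=1)
    ax.set_xlabel("mean of logs")
    ax.set_ylabel("difference of logs")
    ax.set_title("(c) log scale")

    est = LogRatioAgreement().fit(P, I)
    ax = axes[1, 1]
    ax.scatter(m, d, s=8, alpha=0.5)
    xs = np.linspace(m.min(), m.max(), 100)
    line = est.beta0_ + est.beta1_ * xs
    ax.plot(xs, line, color="tab:blue", lw=1.5)
    for sign in (-1, 1):
        ax.plot(xs, line + sign * 1.96 * est.resid_sd_, color="tab:blue", ls="--", lw=1)
    ax.axhline(0, color="k", lw=1)
    # back-transformed axis labels: x as magnitude A, y as ratio P/I
    xticks = ax.get_xticks()
    ax.set_xticks(xticks)
    ax.set_xticklabels([f"{np.exp(t):.0f}" for t in xticks])
    ax.set_xlim(m.min() - 0.1, m.max() + 0.1)
    yticks = ax.get_yticks()
    ax.set_yticks(yticks)
    ax.set_yticklabels([f"{np.exp(t):.2f}" for t in yticks])
    ax.set_xlabel("mean of measures (back-transformed)")
    ax.set_ylabel("ratio purchase/intake")
    ax.set_title("(d) regression approach")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
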