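"""Minimal plots: the SRD line plot with the randomization band.

Kept deliberately small — the figures are diagnostic, not publication
artwork.  Import is lazy so headless pipelines never touch matplotlib.
"""
from __future__ import annotations

__all__ = ["plot_srd"]


def plot_srd(results, null_percentiles=None, ax=None):
    """Normalized SRD per measure (x = SRD%, labels on the line).

    *results* is a list of :class:`binfing.srd.SRDResult`.  The 5%/50%/95%
    points of the randomization distribution are drawn as vertical dashed
    lines (taken from the first result when not given explicitly).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ordered = sorted(results, key=lambda r: r.srd_norm)
    xs = [r.srd_norm for r in ordered]
    ys = range(len(ordered))
    ax.plot(xs, list(ys), marker="o", lw=1)
    for x, y, r in zip(xs, ys, ordered):
        ax.annotate(r.measure_id, (x, y), fontsize=7, xytext=(3, 0),
                    textcoords="offset points")
    pct = null_percentiles if null_percentiles is not None else ordered[0].null_percentiles
    for q, x in zip(("5%", "50%", "95%"), pct):
        ax.axvline(x, ls="--", color="grey", lw=0.8)
        ax.annotate(q, (x, len(ordered) * 0.98), fontsize=7, color="grey")
    ax.set_xlabel("normalized SRD (%)")
    ax.set_ylabel("measure rank")
    return ax
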