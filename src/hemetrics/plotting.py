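"""Minimal plotting helper: per-mode distortion bar chart."""

from __future__ import annotations

import numpy as np

from .nsd import MODE_LABELS, NSDResult


def mode_bar_chart(results: list[NSDResult], labels: list[str] | None = None,
                   ax=None, signed: bool = False):
    """Grouped bar chart of minimal-basis amplitudes for one or more hemes.

    By default magnitudes are plotted (the conventional comparative view);
    pass ``signed=True`` to keep the convention-relative signs.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    if labels is None:
        labels = [f"{r.entry_id or 'heme'} {r.chain_id}{r.res_id}"
                  for r in results]
    n = len(results)
    width = 0.8 / max(n, 1)
    x = np.arange(len(MODE_LABELS))
    for k, (res, lab) in enumerate(zip(results, labels)):
        amps = res.amplitudes if signed else np.abs(res.amplitudes)
        ax.bar(x + (k - (n - 1) / 2) * width, amps, width, label=lab)
    ax.set_xticks(x)
    ax.set_xticklabels(MODE_LABELS)
    ax.set_ylabel("displacement (Å)" if signed else "|displacement| (Å)")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(fontsize="small")
    return ax
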