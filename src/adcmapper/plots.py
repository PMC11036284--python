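"""Matplotlib views: extracted ion chromatograms and chain site maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .sequence import ChainSequence, N_TERM  # noqa: E402

_STATUS_COLOR = {"unambiguous": "#c0392b", "ambiguous_range": "#2980b9",
                 "unsupported": "#bdc3c7"}


def plot_xic(traces: dict[str, list[tuple[float, float]]], ax=None):
    """Overlay labelled XIC traces (label -> [(rt_minutes, intensity), ...])."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    for label, trace in traces.items():
        if not trace:
            continue
        rt, inten = zip(*trace)
        ax.plot(rt, inten, label=label, linewidth=1.2)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    ax.legend(fontsize=8)
    return ax


def plot_chain_map(calls, chain: ChainSequence, ax=None):
    """Candidate conjugation sites of a chain coloured by call status."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.6))
    status = {p: "unsupported" for p in (N_TERM,) + chain.lysine_positions}
    for c in calls:
        if c.chain_id != chain.chain_id:
            continue
        for s in c.sites:
            if c.status == "unambiguous":
                status[s] = "unambiguous"
            elif c.status == "ambiguous_range" and status.get(s) != "unambiguous":
                status[s] = "ambiguous_range"
    ax.hlines(0, 0, len(chain), color="0.6", linewidth=2)
    for pos, st in status.items():
        x = 0.5 if pos == N_TERM else pos
        ax.plot([x], [0], marker="v" if pos == N_TERM else "o", markersize=6,
                color=_STATUS_COLOR[st])
    ax.set_xlim(-5, len(chain) + 5)
    ax.set_yticks([])
    ax.set_xlabel(f"{chain.chain_id} residue")
    handles = [plt.Line2D([], [], marker="o", linestyle="", color=c, label=s)
               for s, c in _STATUS_COLOR.items()]
    ax.legend(handles=handles, fontsize=7, ncol=3, loc="upper center",
              bbox_to_anchor=(0.5, 1.6))
    return ax
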