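"""Quick-look figure of normalized potential responses."""

from __future__ import annotations

from .simulate import NormalizedResponse

__all__ = ["plot_normalized_responses"]


def plot_normalized_responses(
    responses: dict[str, NormalizedResponse],
    path=None,
    threshold: float = 0.2,
    ax=None,
):
    """Plot v_norm vs time (receptor lifetimes) for each genotype.

    Draws the 20%-of-wild-type-peak return threshold as a dashed line.
    Saves a PNG when ``path`` is given; returns the axes.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, resp in responses.items():
        ax.plot(resp.times, resp.v_norm, label=name,
                lw=2 if name == "wild-type" else 1.2)
    ax.axhline(threshold, ls="--", c="grey", lw=0.8,
               label=f"{threshold:.0%} of wild-type peak")
    ax.set_xlabel("time (receptor lifetimes)")
    ax.set_ylabel("potential / wild-type peak")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
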