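"""Optional trajectory panels (requires matplotlib)."""

from __future__ import annotations

__all__ = ["plot_trajectories"]


def plot_trajectories(result, path=None):
    """Four stacked panels: MPR, VFAs, soluble COD, particulate COD."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.times
    fig, axes = plt.subplots(4, 1, figsize=(7, 9), sharex=True)
    axes[0].plot(t, result.mpr, color="tab:green")
    axes[0].set_ylabel("MPR\n(g-COD L$^{-1}$ d$^{-1}$)")
    axes[1].plot(t, result.acetate, label="acetate")
    axes[1].plot(t, result.propionate, label="propionate")
    axes[1].set_ylabel("VFA (g-COD L$^{-1}$)")
    axes[1].legend(frameon=False)
    axes[2].plot(t, result.soluble_cod, color="tab:orange")
    axes[2].set_ylabel("soluble COD\n(g L$^{-1}$)")
    axes[3].plot(t, result.particulate_cod, color="tab:brown")
    axes[3].set_ylabel("particulate COD\n(g L$^{-1}$)")
    axes[3].set_xlabel("time (d)")
    olr = [result.schedule.olr(x) for x in t]
    ax2 = axes[0].twinx()
    ax2.step(t, olr, color="0.6", lw=0.8)
    ax2.set_ylabel("OLR (g-COD L$^{-1}$ d$^{-1}$)", color="0.5")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
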