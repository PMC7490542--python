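"""Spectrum figure: cohort mean amplitudes (black, SEM bars), shuffled-null
cloud (gray) and its 2.5/97.5% CI (dashed lines)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .spectrum import SpectrumResult  # noqa: E402

__all__ = ["plot_spectrum"]


def plot_spectrum(result: SpectrumResult, path=None, null_samples=None, title=None):
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    f = result.frequencies
    if null_samples is not None:
        for k, col in enumerate(null_samples.T):
            ax.plot([f[k]] * col.size, col, ".", color="0.75", ms=2, zorder=1)
    ax.plot(f, result.null_ci_low, "--", color="0.5", lw=1)
    ax.plot(f, result.null_ci_high, "--", color="0.5", lw=1)
    ax.errorbar(f, result.mean_amplitude, yerr=result.bootstrap_sem,
                fmt="o", color="k", capsize=3, zorder=3)
    ax.set_xlabel("frequency (year$^{-1}$)")
    ax.set_ylabel("mean Fourier amplitude")
    ax.set_xticks(f)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
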