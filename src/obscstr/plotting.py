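"""Optional trajectory plots (PNG) for paired simulations."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .verification import PairedTrajectories  # noqa: E402

_STATE_NAMES = ("X (biomass)", "S (substrate)", "O (dissolved oxygen)")


def plot_paired_trajectories(traj: PairedTrajectories, path) -> Path:
    """Original vs copy states on top, error magnitudes (log scale) below."""
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for i, name in enumerate(_STATE_NAMES):
        line, = ax0.plot(traj.t, traj.nu[i], label=name)
        ax0.plot(traj.t, traj.z[i], "--", color=line.get_color(), alpha=0.6)
    ax0.set_ylabel("concentration [g/L]")
    ax0.legend(fontsize=8)
    ax0.set_title(f"case {traj.case_id} "
                  f"({'with' if traj.with_uncertainty else 'without'} "
                  "uncertainty); solid: original, dashed: copy")
    for i in range(3):
        eps = abs(traj.eps[i])
        if eps.max() > 0:
            ax1.semilogy(traj.t, eps.clip(1e-16), label=f"|eps{i + 1}|")
    if traj.with_uncertainty and abs(traj.delta_diff).max() > 0:
        ax1.semilogy(traj.t, abs(traj.delta_diff).clip(1e-16), "k:",
                     label="|dD|")
    ax1.set_xlabel("time [h]")
    ax1.set_ylabel("error [g/L]")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
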