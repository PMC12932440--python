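"""Figure helpers (cosmetic; all analyses work from the returned tables)."""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .simulation import Trajectory

__all__ = ["plot_relative_bmd", "plot_cell_populations", "plot_alpha_sweep"]


def _get_axes(ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_relative_bmd(
    trajectories: Sequence[Trajectory],
    labels: Sequence[str],
    data=None,
    ax=None,
):
    """Onset-normalized BMD vs years since onset, optionally with data."""
    ax = _get_axes(ax)
    for traj, label in zip(trajectories, labels):
        m = traj.years_since_onset() >= 0
        ax.plot(traj.years_since_onset()[m], traj.relative_bmd[m], label=label)
    if data is not None:
        ax.errorbar(
            data.times_years, data.mean_normalized_bmd, yerr=data.sd,
            fmt="o", color="k", capsize=2, label="data",
        )
    ax.set_xlabel("years since menopause onset")
    ax.set_ylabel("relative BMD")
    ax.legend()
    return ax


def plot_cell_populations(traj: Trajectory, ax=None, components=("C", "B", "S", "Sc")):
    """Cell populations / sclerostin as percent of their onset levels."""
    ax = _get_axes(ax)
    yrs = traj.years_since_onset()
    m = yrs >= 0
    i0 = np.argmin(np.abs(yrs))
    for name in components:
        y = traj.component(name)
        ax.plot(yrs[m], 100.0 * y[m] / y[i0], label=name)
    ax.set_xlabel("years since menopause onset")
    ax.set_ylabel("% of onset level")
    ax.legend()
    return ax


def plot_alpha_sweep(sweep, ax=None):
    """Steady BMD change rate vs relative sclerostin production."""
    ax = _get_axes(ax)
    ax.plot(sweep["relative_production"], sweep["bmd_rate_pct_per_year"])
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("sclerostin production relative to premenopause")
    ax.set_ylabel("steady BMD change [%/yr]")
    return ax
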