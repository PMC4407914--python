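"""Minimal figures: DTT with null envelope, LTT, MDI densities.

Matplotlib is imported lazily so the core package works without it.
"""

from __future__ import annotations

import numpy as np

from .disparity import MDIResult
from .tree import TimeTree, ltt

__all__ = ["plot_dtt", "plot_ltt", "plot_mdi_density"]


def _steps(times, values, t_end=1.0):
    t = np.append(times, t_end)
    return t, np.append(values, values[-1])


def plot_dtt(result: MDIResult, ax=None):
    """Observed DTT curve over the null median and 5-95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t, v = _steps(result.null_q05.times, result.null_q05.values)
    t2, v2 = _steps(result.null_q95.times, result.null_q95.values)
    ax.fill_between(t, v, np.interp(t, t2, v2), step="post", alpha=0.3,
                    color="0.6", label="null 5-95%")
    ax.step(*_steps(result.null_median.times, result.null_median.values),
            where="post", color="0.3", ls="--", label="null median")
    ax.step(*_steps(result.observed.times, result.observed.values),
            where="post", color="tab:orange", label="observed")
    ax.axvline(result.t_max, color="0.8", lw=0.8)
    ax.set_xlabel("relative time")
    ax.set_ylabel("average subclade disparity")
    ax.set_title(f"MDI = {result.mdi:.3f}")
    ax.legend(frameon=False)
    return ax


def plot_ltt(tree: TimeTree, ax=None, log: bool = True):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    steps = ltt(tree)
    t = np.append(steps[:, 0], tree.crown_age)
    n = np.append(steps[:, 1], steps[-1, 1])
    ax.step(t, n, where="post")
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("time since root (myr)")
    ax.set_ylabel("lineages")
    return ax


def plot_mdi_density(samples: dict, ax=None):
    """Kernel-density curves of MDI samples, one per labelled condition."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots()
    for label, vals in samples.items():
        vals = np.asarray(vals)
        kde = stats.gaussian_kde(vals)
        grid = np.linspace(vals.min() - 0.1, vals.max() + 0.1, 300)
        ax.plot(grid, kde(grid), label=str(label))
    ax.axvline(0.0, color="0.8", lw=0.8)
    ax.set_xlabel("MDI")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    return ax
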