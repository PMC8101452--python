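"""Beanplot-style rendering of pooled change distributions.

Each ecosystem service gets a panel; within a panel each scenario gets a
"bean": a mirrored kernel-density silhouette with the raw pooled values as
a faint strip, against a zero-change reference line. Scenarios are ordered
2050 before 2070 and RCP 2.6 → 8.5. The exact plotted values are exported
as CSV alongside the figure so every bean is auditable.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from climniche.services import ChangeDistribution, changes_to_frame

__all__ = ["render_change_beans", "scenario_sort_key"]


def scenario_sort_key(name: str) -> tuple[float, float]:
    """Order scenario labels by period then RCP (e.g. '2050_rcp2.6')."""
    m = re.match(r"(\d+)_rcp([\d.]+)", name)
    if not m:
        return (math.inf, math.inf)
    return (float(m.group(1)), float(m.group(2)))


def _draw_bean(ax, x: float, values: np.ndarray, width: float = 0.38,
               color: str = "#4477aa") -> None:
    vals = np.asarray(values, dtype=float)
    spread = vals.max() - vals.min() if vals.size else 0.0
    if vals.size > 1 and spread > 1e-12:
        kde = stats.gaussian_kde(vals)
        grid = np.linspace(vals.min() - 0.1 * spread, vals.max() + 0.1 * spread, 200)
        dens = kde(grid)
        dens = dens / dens.max() * width
        ax.fill_betweenx(grid, x - dens, x + dens, color=color, alpha=0.6, lw=0)
    else:
        # constant distribution collapses to a spike
        y = vals[0] if vals.size else 0.0
        ax.plot([x - width, x + width], [y, y], color=color, lw=2)
    jitter = (np.arange(vals.size) % 17 / 17.0 - 0.5) * width * 0.8
    ax.plot(x + jitter, vals, ".", color="black", ms=1.0, alpha=0.25)
    med = np.median(vals)
    ax.plot([x - width * 0.9, x + width * 0.9], [med, med], color="black", lw=1.2)


def render_change_beans(
    distributions: list[ChangeDistribution],
    out_path: str | Path,
    basename: str = "change_beans",
    ncols: int = 4,
) -> dict[str, Path]:
    """Render per-service beanplots and export the plotted data as CSV.

    Returns paths of the written artifacts (``png``, ``svg``, ``csv``).
    Refuses on an empty distribution vector, naming the service/scenario.
    """
    if not distributions:
        raise ValueError("no distributions to plot")
    for dist in distributions:
        if dist.values.size == 0:
            raise ValueError(
                f"empty change distribution for service {dist.es_name!r}, "
                f"scenario {dist.scenario!r}"
            )
    out_path = Path(out_path)
    out_path.mkdir(parents=True, exist_ok=True)

    services = sorted({d.es_name for d in distributions})
    scenarios = sorted({d.scenario for d in distributions}, key=scenario_sort_key)
    by_key = {(d.es_name, d.scenario): d for d in distributions}

    nrows = math.ceil(len(services) / ncols)
    fig, axes = plt.subplots(
        nrows, ncols,
        figsize=(3.2 * ncols, 2.6 * nrows),
        squeeze=False,
        sharex=True,
    )
    for i, service in enumerate(services):
        ax = axes[i // ncols][i % ncols]
        ax.axhline(0.0, color="0.4", lw=0.8, ls="--")
        for j, scen in enumerate(scenarios):
            dist = by_key.get((service, scen))
            if dist is not None:
                _draw_bean(ax, j, dist.values)
        n = next(
            d.n_species for d in distributions if d.es_name == service
        )
        ax.set_title(f"{service} (n={n})", fontsize=8)
        ax.set_xticks(range(len(scenarios)))
        ax.set_xticklabels(
            [s.replace("_rcp", "\nRCP") for s in scenarios], fontsize=6
        )
        ax.tick_params(labelsize=7)
        if i % ncols == 0:
            ax.set_ylabel("area change (pp)", fontsize=7)
    for i in range(len(services), nrows * ncols):
        axes[i // ncols][i % ncols].set_visible(False)
    fig.tight_layout()

    paths = {
        "png": out_path / f"{basename}.png",
        "svg": out_path / f"{basename}.svg",
        "csv": out_path / f"{basename}_data.csv",
    }
    fig.savefig(paths["png"], dpi=150)
    fig.savefig(paths["svg"])
    plt.close(fig)
    changes_to_frame(distributions).to_csv(paths["csv"], index=False)
    return paths
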