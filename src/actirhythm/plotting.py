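"""Raw-epoch vs fitted-curve rendering for one subject."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cosinor import CosinorResults
from .epochs import EpochSeries

__all__ = ["plot_subject_rhythm"]


def plot_subject_rhythm(
    series: EpochSeries, fit: CosinorResults, path: str | Path | None = None
):
    """Scatter the record's epochs on the clock day and overlay the composite
    regression curve with its maximum/minimum phase markers."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(
        series.clock_hours[series.valid],
        series.mets[series.valid],
        ".",
        ms=1.5,
        alpha=0.25,
        color="tab:gray",
        label="epoch METs",
    )
    grid = np.linspace(0.0, 24.0, 24 * 60 + 1)
    ax.plot(grid, fit.predict(grid), color="tab:blue", lw=2, label="fitted curve")
    car = fit.car_parameters()
    ax.axvline(car.max_phase_time, color="tab:red", ls="--", lw=1, label="max phase")
    ax.axvline(car.min_phase_time, color="tab:purple", ls=":", lw=1, label="min phase")
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 3))
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("METs")
    ax.set_title(
        f"{series.subject_id}: mesor {car.mesor:.2f}, range {car.range:.2f}, "
        f"R$^2$ {car.r_squared:.2f}"
    )
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
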