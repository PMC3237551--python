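"""Exchange progress-curve tables and figures.

The canonical picture of the method is a family of R(t) curves over the
first 8 hours of exchange at dissociation rates spanning three orders
of magnitude (1e-3, 1e-4, 1e-5 s^-1): a fast complex equilibrates to
R = 1 within two hours while a slow one reaches only R = 0.14 by eight
hours, which is what lets a measured series place k_off.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .kinetics import predict_R

__all__ = ["DEFAULT_K_OFFS", "exchange_curve_table", "plot_exchange_curves", "make_curve_report"]

#: The three reference dissociation rates (s^-1) spanning fast to slow
#: complexes on the 8-hour assay scale.
DEFAULT_K_OFFS = (1e-3, 1e-4, 1e-5)


def _time_grid(horizon: float, step: float) -> np.ndarray:
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    if not step > 0:
        raise ValueError("step must be > 0")
    t = np.arange(0.0, horizon, step)
    if t.size == 0 or t[-1] < horizon:
        t = np.append(t, horizon)
    return t


def exchange_curve_table(
    k_off_list: Sequence[float] = DEFAULT_K_OFFS,
    horizon: float = 28800.0,
    step: float = 1800.0,
) -> pd.DataFrame:
    """R(t) on a regular grid, one column per k_off.

    The grid runs from 0 to ``horizon`` seconds in steps of ``step``,
    always including both endpoints (a step larger than the horizon
    yields just t = 0 and t = horizon).
    """
    if len(k_off_list) == 0:
        raise ValueError("k_off_list must not be empty")
    t = _time_grid(horizon, step)
    data = {"t_seconds": t}
    for k in k_off_list:
        data[f"koff_{k:g}"] = predict_R(float(k), t)
    return pd.DataFrame(data)


def plot_exchange_curves(table: pd.DataFrame, ax=None):
    """Plot every k_off column of a curve table against time in hours."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hours = table["t_seconds"] / 3600.0
    for col in table.columns:
        if col == "t_seconds":
            continue
        k = float(col.removeprefix("koff_"))
        ax.plot(hours, table[col], label=f"$k_{{off}} = {k:g}$ s$^{{-1}}$")
    ax.set_xlabel("time after mixing (h)")
    ax.set_ylabel("R = [hybrid] / [original]")
    ax.set_ylim(-0.02, 1.05)
    ax.legend()
    return ax


def make_curve_report(
    k_off_list: Sequence[float] = DEFAULT_K_OFFS,
    horizon: float = 28800.0,
    step: float = 1800.0,
    out_prefix: Union[str, Path, None] = None,
) -> tuple[pd.DataFrame, list[Path]]:
    """Curve table plus figure; optionally written to ``<prefix>.csv/.png``."""
    import matplotlib

    table = exchange_curve_table(k_off_list, horizon, step)
    written: list[Path] = []
    if out_prefix is not None:
        import matplotlib.pyplot as plt

        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        table.to_csv(csv_path, index=False, float_format="%.17g")
        written.append(csv_path)
        fig, ax = plt.subplots(figsize=(6, 4))
        plot_exchange_curves(table, ax=ax)
        png_path = prefix.with_suffix(".png")
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(png_path)
    return table, written
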