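"""Loaders for the small reference tables bundled with the package.

Two CSVs ship with the package:

``annual_mean_projections.csv``
    Projected annual means of daily Tmax/Tmin (°C) for the six Indian
    peanut-growing study locations: one baseline row (scenario ``BL``,
    1975) per location × variable plus one row per SRES scenario
    (A2/A1B/B1) × future period (2020/2050/2080), transcribed from the
    study's published summary exactly as printed.

``reference_voltinism_cells.csv``
    The published ensemble-model voltinism summaries: mean ± SE of the
    number of generations (``n_mean``/``n_se``) and generation time in
    days (``gt_mean``/``gt_se``) per location × scenario × period.
    Used only as a consistency fixture, never as model input.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_annual_mean_projections", "load_reference_voltinism"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("voltigen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_annual_mean_projections() -> pd.DataFrame:
    """Annual-mean Tmax/Tmin projections per location × scenario × period."""
    return _read("annual_mean_projections.csv")


def load_reference_voltinism() -> pd.DataFrame:
    """Published mean ± SE voltinism cells (ensemble model)."""
    return _read("reference_voltinism_cells.csv")
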