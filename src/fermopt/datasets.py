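"""Packaged example data: the seven single-factor screens and the CCD runs.

The tables are transcriptions of a published medium-optimization study of a
biosurfactant-producing marine *Vibrio* strain: screens over temperature,
liquid volume, inoculum size, carbon source, nitrogen source, NaCl
concentration and added ion species (four measured indices per
alternative), and the 20-run three-factor central composite design over
lactose, yeast extract and NaCl with its composite-weight response.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .screen import DEFAULT_CRITERIA, ScreenTable

__all__ = ["SCREEN_NAMES", "load_screen", "load_ccd_runs", "screen_path"]

#: name -> (packaged file, label of the published optimum)
SCREEN_NAMES: dict[str, tuple[str, str]] = {
    "temperature": ("screen_temperature.csv", "28"),
    "liquid_volume": ("screen_liquid_volume.csv", "100"),
    "inoculum": ("screen_inoculum.csv", "4"),
    "carbon": ("screen_carbon.csv", "lactose"),
    "nitrogen": ("screen_nitrogen.csv", "yeast_extract"),
    "salinity": ("screen_salinity.csv", "20"),
    "ions": ("screen_ions.csv", "Na2HPO4"),
}


def screen_path(name: str):
    """Filesystem path of a packaged screen CSV."""
    try:
        fname = SCREEN_NAMES[name][0]
    except KeyError:
        raise ValueError(f"unknown screen {name!r}; options: {sorted(SCREEN_NAMES)}")
    return resources.files("fermopt.data") / fname


def load_screen(name: str) -> ScreenTable:
    """Load one of the packaged single-factor screens by name."""
    with resources.as_file(screen_path(name)) as p:
        df = pd.read_csv(p)
    return ScreenTable(df, name=name, criteria=DEFAULT_CRITERIA)


def load_ccd_runs(exact_alpha: bool = True) -> pd.DataFrame:
    """The 20-run CCD: coded levels, the four indices, and the composite
    response (columns ``run, x1, x2, x3, ..., response``).

    The source table prints the axial levels as +-1.682, a rounding of the
    rotatable axial distance 2^(3/4) = 1.68179... actually used by the
    design.  With ``exact_alpha`` (default) the axial entries are restored
    to full precision -- this is what reproduces the published ANOVA to the
    printed digit; pass ``False`` for the verbatim printed levels.
    """
    with resources.as_file(resources.files("fermopt.data") / "ccd_runs.csv") as p:
        df = pd.read_csv(p)
    if exact_alpha:
        a = 2.0 ** 0.75
        for c in ("x1", "x2", "x3"):
            col = df[c].to_numpy(float)
            df[c] = np.where(np.abs(col) > 1.5, np.sign(col) * a, col)
    return df
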