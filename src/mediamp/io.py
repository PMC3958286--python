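"""CSV serialization of simulation results.

Fixed column layouts:

* profiles (long format): ``x, layer, species, concentration``;
* transients: ``t, current``;
* calibration tables: ``s0, i_st, t_r``;
* sweep tables: ``param, value, s0, i_st_anaerobic, i_st_aerobic, B_O2``.

Currents are written in scientific notation with 12 significant digits
(the oxygen-sensitivity statistic differences currents that agree to
~6 digits).  Output is deterministic: identical inputs give
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .analysis import SweepTable
from .model import ENZYME_SPECIES, MOBILE_SPECIES
from .solver import Grid, State, Transient

__all__ = [
    "profile_frame",
    "transient_frame",
    "sweep_frame",
    "write_csv",
]

_FLOAT_FMT = "%.12e"


def profile_frame(state: State, g: Grid) -> pd.DataFrame:
    """Long-format concentration profile ``(x, layer, species, concentration)``.

    Interface nodes are labelled with the inner (electrode-side) layer.
    Enzyme species appear only on the enzyme-layer nodes.
    """
    layer = g.node_layer()
    rows = []
    for sp in MOBILE_SPECIES:
        u = state.field_for(sp)
        rows.append(
            pd.DataFrame(
                {"x": g.x, "layer": layer, "species": sp.value, "concentration": u}
            )
        )
    ne = g.i_enzyme_edge + 1
    for sp in ENZYME_SPECIES:
        rows.append(
            pd.DataFrame(
                {
                    "x": g.x[:ne],
                    "layer": layer[:ne],
                    "species": sp.value,
                    "concentration": state.field_for(sp),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def transient_frame(tr: Transient) -> pd.DataFrame:
    """Current transient as a ``(t, current)`` frame."""
    return pd.DataFrame({"t": tr.t, "current": tr.current})


def sweep_frame(sw: SweepTable) -> pd.DataFrame:
    """Sweep table in the documented export layout."""
    df = sw.table.rename(columns={sw.param: "value"}).copy()
    df.insert(0, "param", sw.param)
    return df[["param", "value", "s0", "i_st_anaerobic", "i_st_aerobic", "B_O2"]]


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV dump (12 significant digits, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
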