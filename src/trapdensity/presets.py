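"""Bundled trap-system parameter presets.

Ten published trap–insect systems spanning five insect orders and two
trapping methods (chemical attractants and light), shipped as a small CSV
so density estimates can be produced without refitting anything.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .model import TrapSystemParams

__all__ = ["preset_table", "load_presets", "get_preset", "preset_keys"]

_DATA_FILE = "trap_system_presets.csv"


@lru_cache(maxsize=1)
def preset_table() -> pd.DataFrame:
    """The preset table as a DataFrame, one row per trap–insect system."""
    ref = resources.files("trapdensity") / "data" / _DATA_FILE
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    df["rmax_estimated"] = df["rmax_estimated"].astype(bool)
    return df.set_index("key", drop=False)


def preset_keys() -> list[str]:
    return list(preset_table()["key"])


@lru_cache(maxsize=1)
def load_presets() -> dict[str, TrapSystemParams]:
    """All presets as ``{key: TrapSystemParams}``."""
    out: dict[str, TrapSystemParams] = {}
    for row in preset_table().itertuples(index=False):
        out[row.key] = TrapSystemParams(
            sptfer0=float(row.sptfer0),
            d50=float(row.d50_m),
            rmax=float(row.rmax_m),
            d50_sem=float(row.d50_sem_m),
            label=f"{row.label} / {row.trap_type} trap",
        )
    return out


def get_preset(key: str) -> TrapSystemParams:
    """Look up a preset by key (e.g. ``"codling_moth"``)."""
    presets = load_presets()
    try:
        return presets[key]
    except KeyError:
        known = ", ".join(sorted(presets))
        raise KeyError(f"unknown preset {key!r}; available: {known}") from None
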