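"""Colourimetric indices for tuber-flesh phenotyping and phenotype QC.

Tuber colour is summarised from CIELAB coordinates (L: lightness 0–100,
a: green–red, b: blue–yellow).  The indices implemented are the standard
published forms:

* whiteness index  WI   = 100 − √((100−L)² + a² + b²)
* yellow index     YI   = 142.86·b / L
* colour index of red grapes  CIRG = (180 − h) / (L + C)
* hue index        HI   = hue angle h = atan2(b, a)
* brown index      BI   = 100·(x − 0.31)/0.172,
  with x = (a + 1.75·L) / (5.645·L + a − 3.012·b)

Hue is reported either signed in (−180, 180] (the default) or unsigned
in [0, 360); CIRG always uses the unsigned angle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LabColor", "rgb_to_lab", "colour_indices", "phenotype_qc",
           "signed_hue", "unsigned_hue"]


def unsigned_hue(a: float, b: float) -> float:
    """Hue angle atan2(b, a) mapped to [0, 360) degrees."""
    return math.degrees(math.atan2(b, a)) % 360.0


def signed_hue(a: float, b: float) -> float:
    """Hue angle in (−180, 180] degrees."""
    h = unsigned_hue(a, b)
    return h - 360.0 if h > 180.0 else h


@dataclass(frozen=True)
class LabColor:
    """A CIELAB colour with derived chroma and hue angle."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L must be in [0, 100], got {self.L}")

    @property
    def chroma(self) -> float:
        return math.hypot(self.a, self.b)

    @property
    def hue(self) -> float:
        """Unsigned hue angle in [0, 360)."""
        return unsigned_hue(self.a, self.b)


def rgb_to_lab(rgb: tuple[float, float, float]) -> LabColor:
    """sRGB (channels in [0, 1]) → CIELAB under the D65 white point."""
    from skimage.color import rgb2lab

    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"rgb channels must lie in [0, 1], got {rgb}")
    L, a, b = rgb2lab(arr.reshape(1, 1, 3))[0, 0]
    return LabColor(float(np.clip(L, 0.0, 100.0)), float(a), float(b))


def colour_indices(lab: LabColor, signed: bool = True) -> dict[str, float]:
    """Compute {WI, YI, CIRG, HI, BI} from one Lab colour.

    With ``signed=True`` (default) HI is reported in (−180, 180];
    otherwise in [0, 360).  At L = 0 the YI and BI denominators vanish:
    both are returned as NaN with a warning.
    """
    L, a, b = lab.L, lab.a, lab.b
    h = lab.hue
    wi = 100.0 - math.sqrt((100.0 - L) ** 2 + a * a + b * b)
    cirg = (180.0 - h) / (L + lab.chroma) if (L + lab.chroma) > 0 else math.nan
    if L == 0:
        warnings.warn("L = 0: yellow and brown indices undefined")
        yi = math.nan
        bi = math.nan
    else:
        yi = 142.86 * b / L
        x = (a + 1.75 * L) / (5.645 * L + a - 3.012 * b)
        bi = 100.0 * (x - 0.31) / 0.172
    hi = signed_hue(a, b) if signed else h
    return {"WI": wi, "YI": yi, "CIRG": cirg, "HI": hi, "BI": bi}


def phenotype_qc(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per trait with a per-location breakdown.

    Requires columns sample/trait/location/replicate/value, rejects
    duplicated (sample, trait, location, replicate) keys and non-numeric
    values (naming the offending row), and reports n, mean, SD (n−1
    denominator; NaN for a single observation), min and max per trait
    (location "all") and per (trait, location).
    """
    required = {"sample", "trait", "location", "replicate", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    keys = table[["sample", "trait", "location", "replicate"]]
    dup = keys.duplicated()
    if dup.any():
        first = keys[dup].iloc[0].to_dict()
        raise ValueError(f"duplicate phenotype key: {first}")
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = values.isna() & table["value"].notna()
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-numeric value in row {i}: {table.iloc[i].to_dict()}")

    def _stats(sub: pd.Series) -> dict:
        return {
            "n": int(sub.count()),
            "mean": float(sub.mean()),
            "sd": float(sub.std(ddof=1)) if sub.count() > 1 else math.nan,
            "min": float(sub.min()),
            "max": float(sub.max()),
        }

    work = table.assign(value=values)
    rows = []
    for trait, sub in work.groupby("trait"):
        rows.append({"trait": trait, "location": "all", **_stats(sub["value"])})
        for loc, loc_sub in sub.groupby("location"):
            rows.append({"trait": trait, "location": loc, **_stats(loc_sub["value"])})
    return pd.DataFrame(rows, columns=["trait", "location", "n", "mean", "sd", "min", "max"])
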