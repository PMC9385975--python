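"""Depression rating-scale linking: HAMD onto the BDI range (H2B).

The Hamilton Rating Scale for Depression (HAMD, clinician-administered,
0-48) and the Beck Depression Inventory (BDI, self-reported, 0-63) grade
severity in four conventional categories.  The H2B conversion fits the
endpoints of each HAMD category to the endpoints of the corresponding BDI
category and interpolates linearly within the category:

    HAMD  minimum 0-7   mild 8-13   moderate 14-18   severe 19-48
    BDI   minimum 0-13  mild 14-19  moderate 20-28   severe 29-63

A subject's working severity score ("H2B") is the converted HAMD when a
HAMD assessment exists, otherwise the raw BDI.  The conversion is exact at
category endpoints (0->0, 8->14, 14->20, 48->63), monotone non-decreasing,
and category-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CategoryMap",
    "DEFAULT_CATEGORY_MAP",
    "hamd_to_h2b",
    "h2b_to_hamd",
    "assign_h2b",
    "depression_label",
    "DEPRESSION_BOUNDARY",
]

#: BDI-scale severity boundary: scores >= 14 count as depressed.
DEPRESSION_BOUNDARY = 14.0


@dataclass(frozen=True)
class CategoryMap:
    """Paired category endpoints of the source and target scales.

    ``hamd_categories[i] = (lo, hi)`` maps linearly onto
    ``bdi_categories[i] = (lo', hi')``.  Categories are closed intervals on
    the integer-valued instruments; the conversion output is real-valued.
    """

    hamd_categories: tuple[tuple[int, int], ...] = (
        (0, 7), (8, 13), (14, 18), (19, 48))
    bdi_categories: tuple[tuple[int, int], ...] = (
        (0, 13), (14, 19), (20, 28), (29, 63))
    names: tuple[str, ...] = ("minimum", "mild", "moderate", "severe")

    def __post_init__(self) -> None:
        if len(self.hamd_categories) != len(self.bdi_categories):
            raise ValueError("category lists must pair one-to-one")
        for cats in (self.hamd_categories, self.bdi_categories):
            flat = [x for lo_hi in cats for x in lo_hi]
            if any(b < a for a, b in zip(flat, flat[1:])):
                raise ValueError("category endpoints must be non-decreasing")
            if any(hi <= lo for lo, hi in cats):
                raise ValueError("each category needs lo < hi")

    @property
    def hamd_max(self) -> int:
        return self.hamd_categories[-1][1]

    def category_of_hamd(self, hamd: float) -> int:
        for i, (lo, hi) in enumerate(self.hamd_categories):
            if lo <= hamd <= hi:
                return i
        raise ValueError(f"HAMD {hamd} outside [0, {self.hamd_max}]")

    def category_of_bdi(self, bdi: float) -> int:
        """Category index of a BDI-scale value; gaps between integer
        category endpoints (e.g. 13 < x < 14) attach to the lower category."""
        for i, (lo, hi) in enumerate(self.bdi_categories):
            if bdi <= hi or i == len(self.bdi_categories) - 1:
                if bdi < lo and i > 0:
                    return i - 1
                return i
        raise ValueError(f"BDI {bdi} out of range")


DEFAULT_CATEGORY_MAP = CategoryMap()


def _check_integer_score(value, name: str, lo: int, hi: int) -> int:
    v = np.asarray(value).item()
    if v != int(v):
        raise ValueError(f"{name} is an integer-valued instrument, got {value}")
    v = int(v)
    if not lo <= v <= hi:
        raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
    return v


def hamd_to_h2b(hamd, category_map: CategoryMap = DEFAULT_CATEGORY_MAP) -> float:
    """Convert a HAMD score to the BDI scale by per-category linear scaling.

    Within the category [lo, hi] -> [lo', hi']:
    ``h2b = lo' + (hamd - lo) * (hi' - lo') / (hi - lo)``.
    Scalars only; see :func:`assign_h2b` for tables.  Non-integer input is
    rejected (the instrument is integer-valued); the output is real-valued.
    """
    h = _check_integer_score(hamd, "HAMD", 0, category_map.hamd_max)
    i = category_map.category_of_hamd(h)
    lo, hi = category_map.hamd_categories[i]
    blo, bhi = category_map.bdi_categories[i]
    return blo + (h - lo) * (bhi - blo) / (hi - lo)


def h2b_to_hamd(h2b: float,
                category_map: CategoryMap = DEFAULT_CATEGORY_MAP) -> float:
    """Inverse of the conversion on the real line (category interiors)."""
    i = category_map.category_of_bdi(h2b)
    lo, hi = category_map.hamd_categories[i]
    blo, bhi = category_map.bdi_categories[i]
    return lo + (h2b - blo) * (hi - lo) / (bhi - blo)


def depression_label(score, boundary: float = DEPRESSION_BOUNDARY):
    """True where a BDI-scale score meets the depression boundary (>= 14)."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0):
        raise ValueError("scores must be non-negative")
    out = arr >= boundary
    return bool(out) if np.isscalar(score) else out


def assign_h2b(subjects: pd.DataFrame,
               category_map: CategoryMap = DEFAULT_CATEGORY_MAP) -> pd.DataFrame:
    """Attach ``h2b`` and ``set`` columns to a subject table.

    Expects columns ``bdi`` (required) and ``hamd`` (optional values may be
    NaN).  H2B is the converted HAMD where present, otherwise the BDI; the
    set label is "II" where HAMD is present, otherwise "I".
    """
    if "bdi" not in subjects.columns:
        raise ValueError("subject table must have a 'bdi' column")
    if subjects["bdi"].isna().any():
        raise ValueError("every subject needs a BDI score")
    out = subjects.copy()
    hamd = out["hamd"] if "hamd" in out.columns else pd.Series(
        np.nan, index=out.index)
    has_hamd = hamd.notna()
    h2b = out["bdi"].astype(float).copy()
    h2b[has_hamd] = [hamd_to_h2b(v, category_map) for v in hamd[has_hamd]]
    out["h2b"] = h2b
    out["set"] = np.where(has_hamd, "II", "I")
    return out
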