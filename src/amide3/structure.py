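"""Aggregation of fitted components into secondary-structure class totals."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .deconv import DeconvolutionResult, relative_content

#: Canonical class order used in reports.
CLASS_ORDER = ("β-sheet", "random coil", "β-turn", "α-helix")


@dataclass(frozen=True)
class ClassTotals:
    """Per-class summed area and summed relative percentage."""

    area: dict[str, float]
    pct: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area_total": pd.Series(self.area), "pct_total": pd.Series(self.pct)}
        ).loc[[c for c in CLASS_ORDER if c in self.area]]


def class_totals(result: DeconvolutionResult) -> ClassTotals:
    """Sum component areas and relative % within each structure class.

    Class membership is carried by each component's `assignment` field (data
    from the component library, not code), so alternative assignment tables
    aggregate without changes here.
    """
    rel = relative_content(result)
    area: dict[str, float] = {}
    pct: dict[str, float] = {}
    for comp, r in zip(result.components, rel):
        if comp.assignment not in CLASS_ORDER:
            raise ValueError(f"unknown secondary-structure class {comp.assignment!r}")
        area[comp.assignment] = area.get(comp.assignment, 0.0) + comp.area
        pct[comp.assignment] = pct.get(comp.assignment, 0.0) + float(r)
    return ClassTotals(area=area, pct=pct)
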