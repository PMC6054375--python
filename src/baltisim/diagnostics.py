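"""Calibration-quality checks, reusable on any archived run result.

The checks mirror how a long calibration run is judged: every group
should reach a quasi-equilibrium (low drift of annual-mean biomass),
terminal biomass should stay within a band around the initial stocks,
realized diets must be emergent and normalized, cohort numbers should
decay with age, and no resident group should vanish from a box it is
known to occupy (seasonal zeros from forced migration are not
failures).  All checks are pure functions of a RunResult plus
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .ecosystem import RunResult
from .groups import ADULT, FunctionalGroup, JUVENILE
from .model_domain import ModelGeometry, ValidationError


@dataclass
class EquilibriumResult:
    flag: Optional[bool]
    drift_pct_per_decade: float


def detect_equilibrium(
    annual_series: np.ndarray,
    window_years: int = 10,
    threshold_pct_per_decade: float = 2.0,
) -> EquilibriumResult:
    """Linear-trend drift of an annual-mean series over the last window.

    drift = |slope x 10 yr| / window mean, in percent per decade; the
    flag is None (undefined) for a zero-mean window.
    """
    series = np.asarray(annual_series, dtype=float)
    if len(series) < window_years:
        raise ValidationError("series shorter than the equilibrium window")
    tail = series[-window_years:]
    mean = tail.mean()
    if mean == 0:
        return EquilibriumResult(flag=None, drift_pct_per_decade=float("nan"))
    slope = np.polyfit(np.arange(window_years), tail, 1)[0]
    drift = abs(slope * 10.0) / abs(mean) * 100.0
    return EquilibriumResult(flag=bool(drift < threshold_pct_per_decade), drift_pct_per_decade=float(drift))


def biomass_factor(
    terminal: float, initial: float, band: tuple[float, float] = (0.5, 2.0)
) -> tuple[float, bool]:
    """Terminal/initial biomass factor and whether it leaves the band.

    The band is inclusive: a factor exactly at either edge is not
    flagged.
    """
    if initial <= 0:
        raise ValidationError("initial biomass must be > 0")
    factor = terminal / initial
    flagged = not (band[0] <= factor <= band[1])
    return float(factor), flagged


def diet_composition(
    diet: pd.DataFrame,
    predator: str,
    stage: str | None = None,
    last_n_years: int = 5,
) -> dict[str, float]:
    """Fractional diet of a predator (stage) from the feeding ledger.

    Fractions are consumed mass of each prey over total consumed mass
    in the window; an empty ledger returns an empty dict (undefined)
    rather than NaNs.
    """
    if diet.empty:
        return {}
    ymax = diet["year"].max()
    sel = diet[(diet["predator"] == predator) & (diet["year"] > ymax - last_n_years)]
    if stage is not None:
        sel = sel[sel["stage"] == stage]
    total = sel["tons"].sum()
    if total <= 0:
        return {}
    out = sel.groupby("prey")["tons"].sum() / total
    return {str(k): float(v) for k, v in out.items()}


def demography_report(numbers: np.ndarray) -> tuple[np.ndarray, bool]:
    """Cohort numbers plus a strictly-decreasing-with-age flag.

    The terminal plus-group is exempt from the monotonicity
    requirement; single-cohort groups pass vacuously.
    """
    n = np.asarray(numbers, dtype=float)
    if len(n) <= 2:
        return n, True
    core = n[:-1]  # plus-group exempt
    flag = bool(np.all(np.diff(core) < 0))
    return n, flag


def persistence_check(
    result: RunResult,
    groups: Mapping[str, FunctionalGroup],
    geometry: ModelGeometry,
    floor_frac: float = 1e-6,
    window: int = 5,
) -> pd.DataFrame:
    """Extinction flags per (group, box).

    A (group, box) is flagged when the terminal-average biomass falls
    below floor_frac of the group's initial biomass in that box while
    the group is expected there: for age-structured groups, any quarter
    of the distribution map assigns the box a nonzero share; for pools,
    the group started there.  Seasonal zeros from migration are not
    flagged.
    """
    term = result.annual_box_biomass[-window:].mean(axis=0)  # (G, B)
    init = result.annual_box_biomass[0]  # first-year mean as the reference field
    rows = []
    for i, code in enumerate(result.group_codes):
        grp = groups[code]
        if grp.is_vertebrate:
            dist = result.final_groups.verts[code].dist
            mapped = np.zeros(geometry.n_boxes, dtype=bool)
            for stage in (JUVENILE, ADULT):
                mapped |= (dist[stage] > 0).any(axis=0)
            # a box the group occupied in year one; purely-anoxic boxes the
            # group never used (like seasonal migration zeros) do not count
            expected = mapped & (init[i] > 0)
        else:
            expected = init[i] > 0
        tot0 = max(init[i].sum(), 1e-300)
        for b in range(geometry.n_boxes):
            if expected[b] and term[i, b] < floor_frac * init[i, b]:
                rows.append({"group": code, "box": b, "terminal": term[i, b]})
    return pd.DataFrame(rows, columns=["group", "box", "terminal"])


@dataclass
class CalibrationReport:
    equilibrium: dict[str, EquilibriumResult]
    factors: dict[str, tuple[float, bool]]
    diets: dict[tuple[str, str], dict[str, float]]
    demography: dict[str, tuple[np.ndarray, bool]]
    extinctions: pd.DataFrame
    bottom_o2: pd.DataFrame

    @property
    def all_equilibrated(self) -> bool:
        return all(r.flag for r in self.equilibrium.values())

    @property
    def band_fraction(self) -> float:
        flags = [flagged for _, flagged in self.factors.values()]
        return 1.0 - sum(flags) / len(flags)

    @property
    def all_demography_ok(self) -> bool:
        return all(ok for _, ok in self.demography.values())

    @property
    def diets_normalized(self) -> bool:
        return all(
            abs(sum(d.values()) - 1.0) < 1e-9 for d in self.diets.values() if d
        )

    def passed(self, band_quota: float = 0.9) -> bool:
        return (
            self.all_equilibrated
            and self.band_fraction >= band_quota
            and self.all_demography_ok
            and self.diets_normalized
            and self.extinctions.empty
        )

    def summary(self) -> str:
        lines = ["calibration report", "==================="]
        for code, eq in self.equilibrium.items():
            fac, flagged = self.factors[code]
            lines.append(
                f"{code:5s} drift {eq.drift_pct_per_decade:6.2f} %/decade"
                f" [{'ok' if eq.flag else 'DRIFT'}]  factor {fac:6.2f}"
                f" [{'outside band' if flagged else 'in band'}]"
            )
        lines.append(f"demography monotone: {self.all_demography_ok}")
        lines.append(f"extinction flags: {len(self.extinctions)}")
        lines.append(f"groups in band: {self.band_fraction:.0%}")
        return "\n".join(lines)


def build_calibration_report(
    result: RunResult,
    groups: Mapping[str, FunctionalGroup],
    geometry: ModelGeometry,
    window: int = 5,
    equilibrium_window: int = 10,
    band: tuple[float, float] = (0.5, 2.0),
    drift_threshold: float = 2.0,
) -> CalibrationReport:
    """Full calibration-quality report for a finished run."""
    eq = {}
    factors = {}
    for i, code in enumerate(result.group_codes):
        series = result.annual_biomass[:, i]
        eq[code] = detect_equilibrium(series, equilibrium_window, drift_threshold)
        init = groups[code].init_biomass
        terminal = series[-window:].mean()
        factors[code] = biomass_factor(terminal, init, band)
    diets = {}
    for code, grp in groups.items():
        for stage in grp.stages():
            d = diet_composition(result.diet, code, stage, window)
            if d:
                diets[(code, stage)] = d
    demo = {
        code: demography_report(result.demography[code][-window:].mean(axis=0))
        for code in result.demography
    }
    ext = persistence_check(result, groups, geometry, window=window)
    o2 = pd.DataFrame(
        {
            "box": np.arange(geometry.n_boxes),
            "bottom_o2_mean": result.bottom_o2_annual[-window:].mean(axis=0),
            "bottom_o2_min": result.bottom_o2_min[-window:].min(axis=0),
        }
    )
    return CalibrationReport(
        equilibrium=eq,
        factors=factors,
        diets=diets,
        demography=demo,
        extinctions=ext,
        bottom_o2=o2,
    )
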