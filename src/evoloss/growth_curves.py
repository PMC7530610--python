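"""Growth-rate estimation from OD600 time series.

Rates are estimated as the maximal slope of ln(OD) over a sliding window of
consecutive readings, the standard "maximal specific growth rate" estimator
for plate-reader curves sampled every 15 min.  Endpoint ODs, normalization of
rate matrices against a control condition, and generation counting per serial
transfer are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthPhenotype",
    "FinalOD",
    "estimate_growth_rate",
    "final_od",
    "normalize_to_control",
    "estimate_generations",
    "mean_rate",
    "read_curves_tsv",
    "write_phenotypes_tsv",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one lineage in one condition.

    ``time`` is in hours and must be strictly increasing; ``od`` holds the
    raw OD600 readings (>= 0).
    """

    time: np.ndarray
    od: np.ndarray
    lineage_id: str = ""
    condition_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("time and od must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("OD readings must be nonnegative")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class GrowthPhenotype:
    """Summary of a growth curve: maximal rate (h^-1) and the fitted window."""

    rate: float
    fit_window: tuple[float, float] | None = None
    fit_r2: float = float("nan")
    no_growth: bool = False
    clamped: bool = False
    lineage_id: str = ""
    condition_id: str = ""


@dataclass(frozen=True)
class FinalOD:
    value: float
    truncated: bool = False  # True when the curve ended before the horizon


def _window_slopes(t: np.ndarray, y: np.ndarray, w: int):
    """Least-squares slope and R^2 of y vs t for every window of w points."""
    from numpy.lib.stride_tricks import sliding_window_view

    tw = sliding_window_view(t, w)
    yw = sliding_window_view(y, w)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = ((tw - tm) ** 2).sum(axis=1)
    sxy = ((tw - tm) * (yw - ym)).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 1.0)
    return slope, r2


def estimate_growth_rate(
    curve: GrowthCurve, window_points: int = 8, min_od: float = 0.02
) -> GrowthPhenotype:
    """Maximal sliding-window log-linear slope of a growth curve.

    Readings below ``min_od`` (reader noise floor) are excluded; windows run
    over consecutive retained readings.  The reported rate is the maximum
    least-squares slope of ln(OD) versus time; negative maxima are clamped to
    zero and flagged.

    Raises ``ValueError`` when fewer than ``window_points`` readings are above
    the floor but the curve does show some signal; a curve entirely below the
    floor yields rate 0 with the ``no_growth`` flag set.
    """
    if window_points < 2:
        raise ValueError("window_points must be >= 2")
    mask = curve.od >= min_od
    if not mask.any():
        return GrowthPhenotype(
            rate=0.0,
            no_growth=True,
            lineage_id=curve.lineage_id,
            condition_id=curve.condition_id,
        )
    t = curve.time[mask]
    y = np.log(curve.od[mask])
    if t.size < window_points:
        raise ValueError(
            f"only {t.size} readings >= min_od={min_od}; "
            f"need at least window_points={window_points}"
        )
    slopes, r2 = _window_slopes(t, y, window_points)
    i = int(np.argmax(slopes))
    rate = float(slopes[i])
    clamped = rate < 0
    window = (float(t[i]), float(t[i + window_points - 1]))
    return GrowthPhenotype(
        rate=max(rate, 0.0),
        fit_window=window,
        fit_r2=float(r2[i]),
        clamped=clamped,
        lineage_id=curve.lineage_id,
        condition_id=curve.condition_id,
    )


def final_od(curve: GrowthCurve, horizon: float = 120.0) -> FinalOD:
    """OD at the last reading taken at or before ``horizon`` hours.

    When the curve ends before the horizon the last available reading is
    returned with ``truncated=True``.
    """
    if len(curve) == 0:
        raise ValueError("empty growth curve")
    idx = np.nonzero(curve.time <= horizon)[0]
    if idx.size == 0:
        raise ValueError(f"no readings at or before horizon {horizon} h")
    truncated = curve.time[-1] < horizon
    return FinalOD(value=float(curve.od[idx[-1]]), truncated=truncated)


def normalize_to_control(
    rates: pd.DataFrame,
    control_condition: str,
    exempt_conditions: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Divide each lineage's rates by its rate on the control condition.

    ``rates`` is a lineage x condition matrix.  Conditions listed in
    ``exempt_conditions`` (alternate carbon sources) are returned unchanged.
    Lineages whose control rate is zero or missing get NaN in the normalized
    columns, with a warning, rather than a division by zero.
    """
    if control_condition not in rates.columns:
        raise ValueError(f"control condition {control_condition!r} not in matrix")
    control = rates[control_condition].astype(float)
    bad = ~(control > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} lineage(s) with zero/missing control rate; "
            "normalized values set to NaN",
            stacklevel=2,
        )
    denom = control.where(~bad)
    out = rates.astype(float).copy()
    for col in rates.columns:
        if col in exempt_conditions:
            continue
        out[col] = rates[col] / denom
    return out


def estimate_generations(od_at_transfer: float, od_after_dilution: float) -> float:
    """Generations per transfer cycle: log2 of the regrowth ratio.

    With a 1:100 dilution and full regrowth this gives log2(100) ~ 6.64
    generations per cycle.
    """
    if od_at_transfer <= 0 or od_after_dilution <= 0:
        raise ValueError("ODs must be positive")
    return float(np.log2(od_at_transfer / od_after_dilution))


def mean_rate(replicate_rates) -> float:
    """Replicate summary: plain mean of the replicate measurements."""
    arr = np.asarray(list(replicate_rates), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate rates")
    return float(arr.mean())


# ---------------------------------------------------------------------------
# TSV interfaces


def read_curves_tsv(path) -> list[GrowthCurve]:
    """Read long-format curves: columns lineage, condition, time_h, od600."""
    df = pd.read_csv(path, sep="\t")
    required = {"lineage", "condition", "time_h", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curves TSV missing columns: {sorted(missing)}")
    curves = []
    for (lineage, condition), grp in df.groupby(["lineage", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                time=grp["time_h"].to_numpy(float),
                od=grp["od600"].to_numpy(float),
                lineage_id=str(lineage),
                condition_id=str(condition),
            )
        )
    return curves


def write_phenotypes_tsv(phenotypes, path) -> None:
    rows = [
        {
            "lineage": p.lineage_id,
            "condition": p.condition_id,
            "rate_per_h": p.rate,
            "fit_t_start": p.fit_window[0] if p.fit_window else np.nan,
            "fit_t_end": p.fit_window[1] if p.fit_window else np.nan,
            "fit_r2": p.fit_r2,
            "no_growth": p.no_growth,
        }
        for p in phenotypes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
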