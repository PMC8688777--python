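"""Kinetic apoptosis/necrosis plate assays and estimation statistics.

Models a 96-well real-time kinetic assay: cells seeded at 5,000 per well,
three replicate wells per (species, dose) condition, one empty no-cell
column for background, and drug dilution series whose nominal concentrations
are halved by reagent addition.  Readings arrive every 30 minutes for 48 h
(97 timepoints including t = 0) on a luminescence (apoptosis) channel, with
a fluorescence (necrosis) channel carried alongside.

Group comparisons use estimation statistics in the Gardner–Altman style: the
unpaired mean difference with a 95% bias-corrected and accelerated (BCa)
bootstrap confidence interval (5,000 resamples, stratified within groups)
and a two-sided permutation p-value (5,000 label reshuffles; exact
enumeration when the partition count is small), reported with no add-one
correction so an empty tail prints 0.0.
"""

from __future__ import annotations

import dataclasses
import math
import re
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import _perm_pvalue

__all__ = [
    "PlateSpec",
    "build_plate",
    "KineticSeries",
    "read_plate_csv",
    "write_plate_csv",
    "background_correct",
    "slice_timepoint",
    "mean_difference",
    "MeanDifferenceResult",
    "parse_effect",
    "viability_summary",
    "TIME_GRID",
    "DILUTION_SERIES",
]

ROWS = "ABCDEFGH"
N_COLS = 12
TIME_GRID = np.round(np.arange(0.0, 48.0 + 1e-9, 0.5), 2)  # 97 readings
N_TIMEPOINTS = TIME_GRID.size
CHANNELS = ("luminescence", "fluorescence")

# printed nominal dilution series per drug (μM); reagent addition halves them
DILUTION_SERIES = {
    "tunicamycin": (0.0, 10.0, 50.0, 100.0),
    "etoposide": (0.0, 100.0, 500.0, 1000.0),
    "paraquat": (0.0, 100.0, 1000.0, 5000.0),
}


@dataclasses.dataclass
class PlateSpec:
    """96-well layout with dilution bookkeeping.

    ``wells`` columns: well, species, drug, nominal_uM, final_uM,
    replicate, role (treatment | vehicle | nocell).
    """

    wells: pd.DataFrame
    seeding_density: int = 5000
    channels: tuple = CHANNELS

    def of_role(self, role: str) -> pd.DataFrame:
        return self.wells[self.wells["role"] == role]


def build_plate(species: list[str], drug: str, nominal_series=None,
                replicates: int = 3, seeding_density: int = 5000) -> PlateSpec:
    """Deterministic plate layout for one drug.

    Conditions (species × dose × replicate) fill the plate row-major over
    columns 1–11; column 12 is the no-cell background column (drug plus
    reagent, no cells, at the top dose).  Final concentration is always
    nominal/2; dose 0 wells are the vehicle controls.
    """
    if nominal_series is None:
        nominal_series = DILUTION_SERIES[drug.lower()]
    series = [float(c) for c in nominal_series]
    if any(c < 0 for c in series):
        raise ValueError("dilution series must be non-negative")
    if 0.0 not in series:
        raise ValueError("dilution series must include 0 (vehicle)")
    n_cond = len(species) * len(series) * replicates
    capacity = len(ROWS) * (N_COLS - 1)
    if n_cond > capacity:
        raise ValueError(
            f"{n_cond} condition wells exceed plate capacity {capacity}"
        )
    slots = [f"{r}{c}" for r in ROWS for c in range(1, N_COLS)]
    rows = []
    i = 0
    for sp in species:
        for conc in series:
            for rep in range(replicates):
                rows.append(
                    {
                        "well": slots[i],
                        "species": sp,
                        "drug": drug,
                        "nominal_uM": conc,
                        "final_uM": conc / 2.0,
                        "replicate": rep,
                        "role": "vehicle" if conc == 0.0 else "treatment",
                    }
                )
                i += 1
    top = max(series)
    for r in ROWS:
        rows.append(
            {
                "well": f"{r}{N_COLS}",
                "species": "",
                "drug": drug,
                "nominal_uM": top,
                "final_uM": top / 2.0,
                "replicate": 0,
                "role": "nocell",
            }
        )
    return PlateSpec(pd.DataFrame(rows), seeding_density=seeding_density)


class KineticSeries:
    """Per-well kinetic traces on the fixed 0.5-h grid, one channel."""

    def __init__(self, data: pd.DataFrame, channel: str):
        times = data.index.to_numpy(dtype=float)
        if times.size != N_TIMEPOINTS or not np.allclose(times, TIME_GRID):
            raise ValueError(
                f"expected {N_TIMEPOINTS} readings on the 0–48 h half-hour grid"
            )
        if not np.all(np.isfinite(data.to_numpy())):
            raise ValueError("signals must be finite")
        self.data = data
        self.channel = channel

    @property
    def wells(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other):
        return (
            isinstance(other, KineticSeries)
            and self.channel == other.channel
            and self.data.equals(other.data)
        )


def write_plate_csv(series: dict[str, KineticSeries], path) -> None:
    """Long-format CSV: well, channel, time_h, signal."""
    frames = []
    for ch, ks in series.items():
        long = ks.data.reset_index(names="time_h").melt(
            id_vars="time_h", var_name="well", value_name="signal"
        )
        long["channel"] = ch
        frames.append(long[["well", "channel", "time_h", "signal"]])
    pd.concat(frames).to_csv(path, index=False)


def read_plate_csv(path) -> dict[str, KineticSeries]:
    df = pd.read_csv(path)
    out = {}
    for ch, sub in df.groupby("channel"):
        wide = sub.pivot(index="time_h", columns="well", values="signal")
        wide = wide.sort_index()
        wide.columns.name = None
        out[ch] = KineticSeries(wide, ch)
    return out


def background_correct(series: dict[str, KineticSeries],
                       plate: PlateSpec) -> dict[str, KineticSeries]:
    """Subtract the per-timepoint mean of the no-cell wells (per drug/channel).

    Negative corrected signals are retained, not clamped.
    """
    out = {}
    for ch, ks in series.items():
        corrected = ks.data.copy()
        for drug, wp in plate.wells.groupby("drug"):
            nocell = [w for w in wp.loc[wp["role"] == "nocell", "well"]
                      if w in ks.data.columns]
            if not nocell:
                raise ValueError(
                    f"no no-cell wells for drug {drug!r}, channel {ch!r}"
                )
            bg = ks.data[nocell].mean(axis=1)
            cols = [w for w in wp["well"] if w in ks.data.columns]
            corrected[cols] = ks.data[cols].sub(bg, axis=0)
        out[ch] = KineticSeries(corrected, ch)
    return out


def slice_timepoint(series: dict[str, KineticSeries], t: float,
                    plate: PlateSpec, channel: str = "luminescence",
                    grid_tol: float = 0.25) -> pd.DataFrame:
    """Dose–response table at the grid point nearest ``t`` hours.

    Returns one row per (species, final_uM, replicate) for cell-bearing
    wells; 24 h maps to reading index 48.
    """
    if not 0.0 <= t <= 48.0:
        raise ValueError(f"t = {t} h outside the 0–48 h assay window")
    idx = int(np.argmin(np.abs(TIME_GRID - t)))
    if abs(TIME_GRID[idx] - t) > grid_tol:
        raise ValueError(f"t = {t} h is more than {grid_tol} h from the grid")
    ks = series[channel]
    row = ks.data.iloc[idx]
    cells = plate.wells[plate.wells["role"] != "nocell"]
    out = cells[["species", "drug", "final_uM", "replicate", "well"]].copy()
    out["value"] = out["well"].map(row)
    out["time_h"] = TIME_GRID[idx]
    return out.reset_index(drop=True)


@dataclasses.dataclass
class MeanDifferenceResult:
    """Unpaired mean difference with BCa CI and permutation p."""

    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    n_perm: int
    n_test: int
    n_control: int
    seed: int
    exact_permutation: bool = False

    def format(self, digits: int | None = None) -> str:
        def fmt(x):
            return repr(float(x)) if digits is None else f"{x:.{digits}g}"

        return (
            f"{fmt(self.difference)} (95% CI {fmt(self.ci_low)}, "
            f"{fmt(self.ci_high)}), two-sided permutation P = {fmt(self.p_value)}"
        )

    def summary(self) -> str:
        return self.format(digits=3)


_EFFECT_RE = re.compile(
    r"^\s*(?P<d>[-+0-9.eE]+)\s*\(95% CI\s*(?P<lo>[-+0-9.eE]+),\s*"
    r"(?P<hi>[-+0-9.eE]+)\),\s*two-sided permutation P = (?P<p>[-+0-9.eE]+)\s*$"
)


def parse_effect(text: str) -> dict:
    """Parse the textual effect format back into its numbers."""
    m = _EFFECT_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse effect string: {text!r}")
    return {
        "difference": float(m["d"]),
        "ci_low": float(m["lo"]),
        "ci_high": float(m["hi"]),
        "p_value": float(m["p"]),
    }


def mean_difference(test, control, n_boot: int = 5000, n_perm: int = 5000,
                    seed: int = 0, conf: float = 0.95,
                    force_percentile: bool = False,
                    conservative_p: bool = False) -> MeanDifferenceResult:
    """Unpaired mean difference with BCa bootstrap CI and permutation p.

    Bootstrap resampling is stratified within groups.  The bias term z0
    comes from the fraction of bootstrap statistics below the observed
    difference; the acceleration from the jackknife skewness of the
    statistic.  ``force_percentile`` sets z0 = 0, a = 0, collapsing BCa to
    the plain percentile interval (used for verification).
    """
    t = np.asarray(list(test), dtype=float)
    c = np.asarray(list(control), dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
        raise ValueError("group values must be finite")
    observed = float(t.mean() - c.mean())
    rng = np.random.Generator(np.random.PCG64(seed))

    boot = (
        t[rng.integers(0, t.size, size=(n_boot, t.size))].mean(axis=1)
        - c[rng.integers(0, c.size, size=(n_boot, c.size))].mean(axis=1)
    )

    degenerate = np.ptp(boot) == 0.0
    if degenerate:
        warnings.warn("zero-variance groups: CI collapses to a point",
                      stacklevel=2)
        lo = hi = observed
    else:
        if force_percentile:
            z0 = 0.0
            a = 0.0
        else:
            prop = np.mean(boot < observed)
            prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1))
            z0 = float(norm.ppf(prop))
            # jackknife acceleration over the pooled leave-one-out statistics
            jack = np.empty(t.size + c.size)
            for i in range(t.size):
                jack[i] = np.delete(t, i).mean() - c.mean()
            for j in range(c.size):
                jack[t.size + j] = t.mean() - np.delete(c, j).mean()
            d = jack.mean() - jack
            denom = (d**2).sum() ** 1.5
            a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
        alpha = (1.0 - conf) / 2.0
        z_lo, z_hi = norm.ppf(alpha), norm.ppf(1.0 - alpha)
        q_lo = norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
        q_hi = norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
        lo, hi = np.quantile(boot, [q_lo, q_hi])

    pooled = np.concatenate([t, c])
    p, exact, used = _perm_pvalue(pooled, t.size, observed, n_perm, seed + 1)
    if conservative_p:
        p = (p * used + 1.0) / (used + 1.0)
    return MeanDifferenceResult(
        difference=observed, ci_low=float(lo), ci_high=float(hi),
        p_value=float(p), n_boot=n_boot, n_perm=used,
        n_test=t.size, n_control=c.size, seed=seed,
        exact_permutation=exact,
    )


def viability_summary(live, total) -> dict:
    """Per-passage viability percentages with mean ± sample SD.

    Mirrors the cell-line QC convention: viability = 100 × live / total at
    each passage; SD uses n − 1.
    """
    lv = np.asarray(list(live), dtype=float)
    tt = np.asarray(list(total), dtype=float)
    if lv.size != tt.size or lv.size == 0:
        raise ValueError("live and total must be equal-length non-empty")
    if np.any(lv < 0) or np.any(tt <= 0):
        raise ValueError("counts must be positive")
    if np.any(lv > tt):
        raise ValueError("live counts exceed totals")
    pct = 100.0 * lv / tt
    single = pct.size == 1
    return {
        "per_passage_percent": pct.tolist(),
        "mean_percent": float(pct.mean()),
        "sd_percent": 0.0 if single else float(pct.std(ddof=1)),
        "n_passages": int(pct.size),
        "note": "single passage" if single else "",
    }
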