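"""Measurement procedures: COM thickness, ten-segment surface tracking,
population counts, regional turnover, stability and recovery detection.

All metrics are pure functions of sampled per-cell snapshots (or of a
lattice state), so every number is recomputable from a run's dumps.
Undefined values (e.g. thickness while the superficial layer is ablated)
are represented as NaN markers, never exceptions, so injury transients
remain representable.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .potts import LatticeState
from .types import BASAL, PIXEL_UM, STEM, SUPER, TYPE_NAMES, WING

__all__ = [
    "counts_frame",
    "fragmentation_fraction",
    "recovery_time",
    "region_population",
    "segment_surface_positions",
    "segment_thickness_sd",
    "stability_time",
    "stratification_day",
    "survival_curve",
    "thickness_com",
    "thickness_series",
    "turnover_time",
]

EPI_TYPES = (STEM, BASAL, WING, SUPER)


# --------------------------------------------------------------------------
# thickness
# --------------------------------------------------------------------------

def _sample_thickness(ctype, com_y, pixel_um: float) -> float:
    sup = com_y[ctype == SUPER]
    base = com_y[(ctype == BASAL) | (ctype == STEM)]
    if len(sup) == 0 or len(base) == 0:
        return np.nan
    return float((sup.mean() - base.mean()) * pixel_um)


def thickness_com(state: LatticeState) -> float:
    """Epithelial thickness in μm by the center-of-mass difference method:
    (mean y-COM of superficial cells − mean y-COM of basal∪stem cells) ×
    pixel size.  NaN marker when either layer is absent."""
    t = state.table
    ids = state.epithelial_ids()
    v = t.volume[ids].astype(float)
    com_y = t.sum_y[ids] / np.maximum(v, 1)
    return _sample_thickness(t.ctype[ids], com_y, state.pixel_um)


def thickness_series(result) -> pd.Series:
    days = result.sample_days()
    vals = [_sample_thickness(s.ctype, s.com_y, result.pixel_um)
            for s in result.samples]
    return pd.Series(vals, index=days, name="thickness_um")


# --------------------------------------------------------------------------
# counts
# --------------------------------------------------------------------------

def counts_frame(result) -> pd.DataFrame:
    """Counts of the four epithelial types at each sampled MCS."""
    rows = []
    for s in result.samples:
        row = {"mcs": s.mcs}
        for code in EPI_TYPES:
            row[TYPE_NAMES[code]] = int(np.count_nonzero(s.ctype == code))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("mcs")
    df["total"] = df[[TYPE_NAMES[c] for c in EPI_TYPES]].sum(axis=1)
    return df


# --------------------------------------------------------------------------
# segmentation (ten X-axis segments)
# --------------------------------------------------------------------------

def segment_surface_positions(state_or_sample, n_segments: int = 10,
                              pixel_um: float = PIXEL_UM,
                              width: int = 200) -> np.ndarray:
    """Mean y-COM of superficial cells per equal-width X segment, in μm.

    Segments are [0,w), [w,2w), ... in voxels (w = width/n_segments, i.e.
    0-19, 20-39, …, 180-199 for the default lattice).  Empty segments get
    NaN markers."""
    if isinstance(state_or_sample, LatticeState):
        st = state_or_sample
        t = st.table
        ids = st.ids_of_type(SUPER)
        v = np.maximum(t.volume[ids].astype(float), 1)
        xs = t.sum_x[ids] / v
        ys = t.sum_y[ids] / v
        pixel_um = st.pixel_um
        width = st.width
    else:
        s = state_or_sample
        sel = s.ctype == SUPER
        xs = s.com_x[sel].astype(float)
        ys = s.com_y[sel].astype(float)
    w = width // n_segments
    out = np.full(n_segments, np.nan)
    seg = np.clip((xs // w).astype(int), 0, n_segments - 1)
    for i in range(n_segments):
        m = seg == i
        if m.any():
            out[i] = ys[m].mean() * pixel_um
    return out


def _segment_layer_means(sample, codes, n_segments, width):
    sel = np.isin(sample.ctype, codes)
    xs = sample.com_x[sel].astype(float)
    ys = sample.com_y[sel].astype(float)
    w = width // n_segments
    out = np.full(n_segments, np.nan)
    seg = np.clip((xs // w).astype(int), 0, n_segments - 1)
    for i in range(n_segments):
        m = seg == i
        if m.any():
            out[i] = ys[m].mean()
    return out


def segment_thickness_sd(result, window_days: tuple[float, float],
                         n_segments: int = 10) -> float:
    """SD (μm) across segments of the temporal-mean per-segment thickness
    over a stable window (thickness = super minus basal∪stem mean y per
    segment, × pixel size)."""
    width = result.config.geometry.width
    days = result.sample_days()
    lo, hi = window_days
    per_seg = []
    for s, d in zip(result.samples, days):
        if not (lo <= d <= hi):
            continue
        top = _segment_layer_means(s, [SUPER], n_segments, width)
        bot = _segment_layer_means(s, [BASAL, STEM], n_segments, width)
        per_seg.append((top - bot) * result.pixel_um)
    if not per_seg:
        return np.nan
    temporal_mean = np.nanmean(np.array(per_seg), axis=0)
    return float(np.nanstd(temporal_mean))


# --------------------------------------------------------------------------
# developmental timeline
# --------------------------------------------------------------------------

def stratification_day(result) -> Optional[float]:
    """First sampled day at which all four epithelial types exist with the
    correct vertical ordering (basal/stem below wing below superficial)."""
    days = result.sample_days()
    for s, d in zip(result.samples, days):
        means = {}
        ok = True
        for key, codes in (("base", (STEM, BASAL)), ("wing", (WING,)),
                           ("super", (SUPER,))):
            sel = np.isin(s.ctype, codes)
            if not sel.any():
                ok = False
                break
            means[key] = s.com_y[sel].mean()
        if not ok or not (s.ctype == STEM).any() or not (s.ctype == BASAL).any():
            continue
        if means["base"] < means["wing"] < means["super"]:
            return float(d)
    return None


def stability_time(result, band: float = 0.10, window_days: float = 5.0,
                   atol: float = 1.0):
    """First day τ after which all four cell-type counts stay within ±band of
    their trailing ``window_days`` mean for ``window_days`` consecutive days.

    The condition is evaluated on daily-mean counts: with tens of cells per
    type, per-sample integer jitter would dominate a ±10% band, so the day is
    the natural granularity of the detector.  ``atol`` widens the band to at
    least one cell — counts are integers, so a band narrower than the count
    resolution would never admit the handful-sized stem population.  Returns
    None when the detector never fires within the run."""
    df = counts_frame(result)
    days = df.index.to_numpy() / result.day_to_mcs
    cols = [TYPE_NAMES[c] for c in EPI_TYPES]
    counts = df[cols].to_numpy(dtype=float)
    n_days = int(np.floor(days[-1]))
    if n_days < 2 * window_days:
        return None
    daily = np.full((n_days, len(cols)), np.nan)
    for d in range(n_days):
        sel = (days > d) & (days <= d + 1)
        if sel.any():
            daily[d] = counts[sel].mean(axis=0)
    w = int(window_days)
    ok = np.zeros(n_days, dtype=bool)
    for d in range(w, n_days):
        mean = daily[d - w:d + 1].mean(axis=0)
        if np.any(~np.isfinite(mean)) or np.any(mean <= 0):
            continue
        tol = np.maximum(band * mean, atol)
        ok[d] = bool(np.all(np.abs(daily[d] - mean) <= tol))
    for d in range(2 * w, n_days):
        if ok[d - w + 1:d + 1].all():
            return float(d - w + 1)
    return None


# --------------------------------------------------------------------------
# turnover
# --------------------------------------------------------------------------

def _region_mask(com_x, region, limbal_width: int):
    if region == "limbal":
        return com_x < limbal_width
    if region == "peripheral":
        return com_x >= limbal_width
    raise ValueError(f"unknown region {region!r}")


def survival_curve(result, region: str, baseline_day: float,
                   limbal_width: Optional[int] = None):
    """(days-since-baseline, surviving fraction) of the epithelial cell IDs
    present in the region at baseline.  Daughters are new IDs, so the curve
    is monotone non-increasing."""
    if limbal_width is None:
        limbal_width = result.config.geometry.limbal_width
    days = result.sample_days()
    i0 = int(np.argmin(np.abs(days - baseline_day)))
    s0 = result.samples[i0]
    base = s0.ids[_region_mask(s0.com_x, region, limbal_width)]
    base = np.sort(base)
    if len(base) == 0:
        return np.array([0.0]), np.array([np.nan])
    ts, fr = [], []
    for s, d in zip(result.samples[i0:], days[i0:]):
        alive = np.isin(base, s.ids, assume_unique=False)
        ts.append(d - days[i0])
        fr.append(alive.mean())
    return np.array(ts), np.array(fr)


def turnover_time(result, region: str, baseline_day: float,
                  threshold: float = 0.05):
    """Days (from baseline) until the surviving fraction of baseline IDs
    drops to ≤ threshold — "nearly complete cellular substitution".  Returns
    (days, last_fraction); days is None when censored by run end."""
    ts, fr = survival_curve(result, region, baseline_day)
    below = np.nonzero(fr <= threshold)[0]
    if len(below) == 0:
        return None, float(fr[-1])
    return float(ts[below[0]]), float(fr[below[0]])


# --------------------------------------------------------------------------
# injury recovery
# --------------------------------------------------------------------------

def region_population(result, x_range: tuple[float, float],
                      types: Iterable[int] = (WING, SUPER)) -> pd.Series:
    """Population of the given types whose COM lies in [x0, x1) voxels."""
    days = result.sample_days()
    lo, hi = x_range
    vals = []
    for s in result.samples:
        sel = np.isin(s.ctype, list(types)) & (s.com_x >= lo) & (s.com_x < hi)
        vals.append(int(sel.sum()))
    return pd.Series(vals, index=days, name="region_population")


def recovery_time(result, injury_day: float, baseline_window: float = 5.0,
                  tol: float = 0.10, sustain_days: float = 1.0,
                  baseline_count: Optional[float] = None,
                  baseline_thickness: Optional[float] = None):
    """Post-injury recovery detector on total epithelial count and thickness.

    Baseline = pre-injury means over ``baseline_window`` days before the
    injury (pass ``baseline_count``/``baseline_thickness`` explicitly for a
    branch run whose samples start at the injury itself).  Recovery day
    (relative to injury) = first time both series are within ±tol of
    baseline and stay there for ``sustain_days``; 0 when they never left
    the band.  Also returns the recurrence count: the number of distinct
    later excursions of the count below the band after first recovery.
    Returns (recovery_day | None, recurrence_count).
    """
    df = counts_frame(result)
    days = df.index.to_numpy() / result.day_to_mcs
    total = df["total"].to_numpy(dtype=float)
    thick = thickness_series(result).to_numpy(dtype=float)
    # the sample taken exactly at the injury MCS predates the deposit, so a
    # branch run starting at the injury still has a one-sample baseline
    pre = (days >= injury_day - baseline_window) & (days <= injury_day)
    if not pre.any() and (baseline_count is None
                          or baseline_thickness is None):
        raise ValueError("no pre-injury samples to form a baseline")
    b_count = baseline_count if baseline_count is not None \
        else total[pre].mean()
    b_thick = baseline_thickness if baseline_thickness is not None \
        else np.nanmean(thick[pre])
    in_band = (np.abs(total - b_count) <= tol * b_count) \
        & np.isfinite(thick) & (np.abs(thick - b_thick) <= tol * b_thick)
    post = days >= injury_day
    rec_day = None
    if in_band[post].all():
        rec_day = 0.0
    else:
        for i in np.nonzero(post)[0]:
            sel = (days >= days[i]) & (days <= days[i] + sustain_days)
            if days[sel][-1] < days[i] + sustain_days - 1e-9:
                break  # not enough run left to confirm sustain
            if in_band[sel].all():
                rec_day = float(days[i] - injury_day)
                break
    recurrences = 0
    if rec_day is not None:
        after = days >= injury_day + rec_day + sustain_days
        below = total < (1 - tol) * b_count
        state = False
        for i in np.nonzero(after)[0]:
            if below[i] and not state:
                recurrences += 1
                state = True
            elif not below[i]:
                state = False
    return rec_day, recurrences


def recurrent_collapses(series: pd.Series, baseline: float,
                        start_day: float, reclosure: float = 0.75,
                        collapse: float = 0.5):
    """Count erosion cycles in a wound-region population series.

    Re-closure = series ≥ ``reclosure``·baseline; a collapse is a subsequent
    excursion below ``collapse``·baseline.  Returns (first_closure_day |
    None, n_collapses) with collapses counted after the first re-closure.
    """
    days = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    post = days >= start_day
    # anchor at the post-injury trough so the pre-injury level is not
    # mistaken for a closure
    wounded = np.nonzero(post & (vals < collapse * baseline))[0]
    if len(wounded) == 0:
        return None, 0
    closed = np.nonzero((np.arange(len(vals)) > wounded[0])
                        & (vals >= reclosure * baseline))[0]
    if len(closed) == 0:
        return None, 0
    i0 = closed[0]
    n = 0
    state = False
    for i in range(i0, len(vals)):
        if vals[i] < collapse * baseline and not state:
            n += 1
            state = True
        elif vals[i] >= reclosure * baseline:
            state = False
    return float(days[i0] - start_day), n


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def fragmentation_fraction(state: LatticeState) -> float:
    """Fraction of live epithelial cells whose pixel set is disconnected
    under 8-connectivity (cell connectivity is not enforced by the engine;
    this monitors it)."""
    ids = state.epithelial_ids()
    if len(ids) == 0:
        return 0.0
    grid = state.owner_grid
    frag = 0
    for cid in ids:
        ys, xs = state.pixels_of(int(cid))
        n = len(ys)
        if n == 0:
            continue
        key = {(int(y), int(x)): i for i, (y, x) in enumerate(zip(ys, xs))}
        seen = {next(iter(key))}
        stack = [next(iter(key))]
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    p = (y + dy, x + dx)
                    if p in key and p not in seen:
                        seen.add(p)
                        stack.append(p)
        if len(seen) != n:
            frag += 1
    return frag / len(ids)
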