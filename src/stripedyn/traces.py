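"""Per-nucleus trace processing: DV windowing, time normalization, activity
calls, cumulative mRNA output, amplitude and spatial binning.

Conventions (documented because the experimental procedure leaves them open):

* NC14 is normalized to a fixed 100-point grid on [0, 1]; fluorescence is
  linearly interpolated from acquisition frames onto that grid, and grid
  points outside a nucleus's observed frames are NaN ("nucleus not present").
* A nucleus is *active* at a grid point when its signal strictly exceeds the
  threshold (ties are inactive).
* Cumulative mRNA output is the trapezoidal integral of fluorescence over
  normalized time, over the observed support only; units are a.u. × NC14.
* Active duration is the count of active grid points, i.e. ``count/100`` in
  normalized-time units; transcriptional amplitude = output / (count/100),
  which keeps amplitude in fluorescence units and equal to the burst loading
  amplitude for an idealized on/off trace.
* The AP axis is divided into 50 bins of 2 %EL, half-open ``[2k, 2k+2)``
  with the last bin closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedTraces",
    "SpatialProfile",
    "select_dv_window",
    "normalize_time",
    "call_active",
    "estimate_threshold",
    "mrna_output",
    "nucleus_metrics",
    "bin_profile",
]

N_TIME_POINTS = 100
N_AP_BINS = 50


@dataclass
class NormalizedTraces:
    """A cohort of traces on the common normalized NC14 time grid.

    ``fluor`` (and optional ``pp7``) are (n_nuclei, 100) arrays, NaN where
    the nucleus was not observed. ``meta`` has one row per nucleus
    (nucleus_id, el_pct, dv_um). ``active`` is set by :meth:`set_threshold`.
    """

    meta: pd.DataFrame
    t_norm: np.ndarray
    fluor: np.ndarray
    pp7: np.ndarray | None = None
    threshold: float | None = None
    active: np.ndarray | None = None
    nc14_duration_s: float | None = None

    @property
    def n_nuclei(self) -> int:
        return len(self.meta)

    def set_threshold(self, threshold: float | str = "auto") -> float:
        if threshold == "auto":
            threshold = estimate_threshold(self.fluor)
        self.threshold = float(threshold)
        self.active = call_active(self.fluor, self.threshold)
        return self.threshold


@dataclass
class SpatialProfile:
    """Mean signal per %EL bin at one time (or cumulated over time)."""

    bin_edges: np.ndarray   # length n_bins + 1
    bin_mean: np.ndarray    # NaN where bin_count == 0
    bin_count: np.ndarray
    label: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.bin_mean)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def select_dv_window(traces: pd.DataFrame, window_um: float = 282.0,
                     center_um: float | None = None) -> pd.DataFrame:
    """Keep nuclei whose mean DV position lies within a centered window.

    The window defaults to 282 µm about the embryo's DV midline (midpoint of
    the occupied DV range when ``center_um`` is not given).
    """
    if window_um <= 0:
        raise ValueError("window_um must be positive")
    mean_dv = traces.groupby("nucleus_id")["dv_um"].mean()
    if center_um is None:
        center_um = 0.5 * (mean_dv.min() + mean_dv.max())
    keep = mean_dv[(mean_dv - center_um).abs() <= window_um / 2].index
    return traces[traces["nucleus_id"].isin(keep)].copy()


def normalize_time(traces: pd.DataFrame, t_start: float, t_end: float,
                   n_points: int = N_TIME_POINTS) -> NormalizedTraces:
    """Interpolate each nucleus's trace onto the fixed normalized grid.

    ``t_start``/``t_end`` are the seconds of the end of the 13th mitosis and
    the beginning of gastrulation. Linear interpolation; grid points outside
    a nucleus's observed frames are NaN. Idempotent on its own output.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    grid = np.linspace(0.0, 1.0, n_points)
    t_grid_s = t_start + grid * (t_end - t_start)

    has_pp7 = "fluor_pp7" in traces.columns
    piv = traces.pivot_table(index="nucleus_id", columns="t_seconds",
                             values="fluor_ms2")
    ids = piv.index.to_numpy()
    tt = piv.columns.to_numpy(dtype=float)
    F = piv.to_numpy(dtype=float)
    meta = (traces.groupby("nucleus_id")
            .agg(el_pct=("el_pct", "mean"), dv_um=("dv_um", "mean"))
            .loc[ids].reset_index())

    def _interp(mat: np.ndarray) -> np.ndarray:
        out = np.full((len(ids), n_points), np.nan)
        complete = ~np.isnan(mat).any(axis=1)
        if complete.any():
            # shared frame grid: one vectorized interpolation per column block
            idx = np.clip(np.searchsorted(tt, t_grid_s, side="right") - 1,
                          0, tt.size - 2)
            t0, t1 = tt[idx], tt[idx + 1]
            w = np.where(t1 > t0, (t_grid_s - t0) / np.where(t1 > t0, t1 - t0, 1.0),
                         0.0)
            vals = (mat[np.ix_(complete, idx)] * (1 - w)
                    + mat[np.ix_(complete, idx + 1)] * w)
            vals[:, t_grid_s < tt[0]] = np.nan
            vals[:, t_grid_s > tt[-1]] = np.nan
            out[complete] = vals
        for i in np.flatnonzero(~complete):
            ok = ~np.isnan(mat[i])
            if ok.sum() < 2:
                continue
            ti, fi = tt[ok], mat[i, ok]
            out[i] = np.interp(t_grid_s, ti, fi)
            out[i, (t_grid_s < ti[0]) | (t_grid_s > ti[-1])] = np.nan
        return out

    fluor = _interp(F)
    pp7 = None
    if has_pp7:
        piv7 = traces.pivot_table(index="nucleus_id", columns="t_seconds",
                                  values="fluor_pp7").reindex(ids)
        pp7 = _interp(piv7.to_numpy(dtype=float))
    return NormalizedTraces(meta=meta, t_norm=grid, fluor=fluor, pp7=pp7,
                            nc14_duration_s=t_end - t_start)


def call_active(fluor: np.ndarray, threshold: float) -> np.ndarray:
    """Strictly-above-threshold activity calls; NaN (absent) is inactive."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    fluor = np.asarray(fluor, dtype=float)
    with np.errstate(invalid="ignore"):
        return fluor > threshold


def estimate_threshold(fluor: np.ndarray, n_sd: float = 5.0,
                       dim_fraction: float = 0.10) -> float:
    """Background-based activity threshold for one embryo.

    The 10% dimmest nuclei (by time-mean signal) are taken as never-active
    background; the threshold is the mean + ``n_sd`` standard deviations of
    all their frame values. The default of 5 SD keeps the expected number
    of false activity calls below one per embryo (an embryo contributes on
    the order of 10^5 background nucleus-frames, so a 3 SD rule would plant
    hundreds of spurious active nuclei and bridge inter-stripe gaps) while
    remaining far below burst-level signal.
    """
    fluor = np.asarray(fluor, dtype=float)
    if fluor.ndim == 1:
        fluor = fluor[None, :]
    means = np.nanmean(fluor, axis=1)
    k = max(1, int(np.floor(dim_fraction * means.size)))
    dim_rows = np.argsort(means)[:k]
    vals = fluor[dim_rows]
    vals = vals[~np.isnan(vals)]
    return float(np.mean(vals) + n_sd * np.std(vals))


def mrna_output(fluor: np.ndarray, t_norm: np.ndarray) -> np.ndarray:
    """Cumulative mRNA output: trapezoidal integral over normalized time.

    Accepts one trace (1D) or a stack (2D, one row per nucleus). Integration
    runs over the observed (non-NaN) support only; rows with fewer than two
    defined points yield NaN.
    """
    fluor = np.asarray(fluor, dtype=float)
    single = fluor.ndim == 1
    F = fluor[None, :] if single else fluor
    out = np.full(F.shape[0], np.nan)
    all_ok = ~np.isnan(F).any(axis=1)
    if all_ok.any():
        out[all_ok] = np.trapezoid(F[all_ok], t_norm, axis=1)
    for i in np.flatnonzero(~all_ok):
        ok = ~np.isnan(F[i])
        if ok.sum() >= 2:
            out[i] = np.trapezoid(F[i, ok], t_norm[ok])
    return float(out[0]) if single else out


def nucleus_metrics(nt: NormalizedTraces) -> pd.DataFrame:
    """Per-nucleus output, active duration and transcriptional amplitude.

    active_duration_points counts active grid points; duration_min converts
    to minutes of NC14 when the trace knows its wall-clock span; amplitude =
    output / (active_duration_points / 100) — NaN for never-active nuclei
    (their output can still be positive if sub-threshold signal integrates).
    """
    if nt.active is None:
        raise ValueError("call set_threshold() before nucleus_metrics()")
    output = mrna_output(nt.fluor, nt.t_norm)
    n_active = nt.active.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        amplitude = np.where(n_active > 0,
                             output / (n_active / nt.t_norm.size), np.nan)
    df = pd.DataFrame({
        "nucleus_id": nt.meta["nucleus_id"].to_numpy(),
        "el_pct": nt.meta["el_pct"].to_numpy(),
        "dv_um": nt.meta["dv_um"].to_numpy(),
        "mrna_output": output,
        "active_duration_points": n_active,
        "amplitude": amplitude,
    })
    if nt.nc14_duration_s is not None:
        df["active_duration_min"] = (n_active / nt.t_norm.size
                                     * nt.nc14_duration_s / 60.0)
    return df


def bin_profile(values: np.ndarray, el_pct: np.ndarray,
                n_bins: int = N_AP_BINS, el_range: tuple[float, float] = (0.0, 100.0),
                label: str = "") -> SpatialProfile:
    """Mean of ``values`` per %EL bin (default: 50 bins of 2 %EL).

    Bins are half-open [left, right) with the last bin closed; empty bins
    have NaN mean and zero count. NaN values do not contribute.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(values, dtype=float)
    el_pct = np.asarray(el_pct, dtype=float)
    lo, hi = el_range
    if np.any((el_pct < lo) | (el_pct > hi)):
        raise ValueError(f"el_pct values must lie in [{lo}, {hi}]")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(((el_pct - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    ok = ~np.isnan(values)
    count = np.bincount(idx[ok], minlength=n_bins)
    total = np.bincount(idx[ok], weights=values[ok], minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return SpatialProfile(bin_edges=edges, bin_mean=mean, bin_count=count,
                          label=label)
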