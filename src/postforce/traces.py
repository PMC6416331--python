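"""Per-field-of-view trace averaging and endpoint summaries.

Multiple sensors are measured in one camera field of view; their force
curves are averaged into a mean +/- SEM trace (the dashed-bound traces of
the assay's readout).  Endpoints are evaluated at a fixed assay time
(120 s by default) by linear interpolation, never extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import AggregateMask, PostTrack

__all__ = ["ForceTrace", "EndpointSummary", "fov_average", "endpoint_summary",
           "percent_inhibition", "area_trace"]


@dataclass
class ForceTrace:
    """Mean +/- SEM force trace over the usable sensors of one field of view."""

    times: np.ndarray          # s, uniform grid
    site_matrix: np.ndarray    # (n_sites, n_times) nN, NaN = missing
    mean: np.ndarray           # nN
    sem: np.ndarray            # nN, NaN where n < 2
    n_sites: np.ndarray        # valid sites per timepoint

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "mean_force_nN": self.mean,
            "sem_nN": self.sem,
            "n_sites": self.n_sites,
        })

    def plot(self, ax=None, label=None, ylabel="force (nN)"):
        """Mean trace as a solid line with dashed SEM bounds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.mean, "-", label=label)
        ok = np.isfinite(self.sem)
        if ok.any():
            ax.plot(self.times[ok], (self.mean + self.sem)[ok], "--",
                    color=ax.lines[-1].get_color(), linewidth=0.8)
            ax.plot(self.times[ok], (self.mean - self.sem)[ok], "--",
                    color=ax.lines[-1].get_color(), linewidth=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(ylabel)
        return ax


@dataclass
class EndpointSummary:
    """Force (and optionally area) at the evaluation time, per sample."""

    sample_id: str
    force_nN: float
    area_um2: float | None
    eval_time_s: float


def _resample(track_times, values, grid):
    """Linear interpolation onto ``grid``; NaN outside the valid span and
    across gaps adjacent to invalid frames."""
    v = np.asarray(values, float)
    t = np.asarray(track_times, float)
    ok = np.isfinite(v)
    if ok.sum() == 0:
        return np.full(len(grid), np.nan)
    out = np.interp(grid, t[ok], v[ok], left=np.nan, right=np.nan)
    # do not bridge interior gaps: mark grid points whose bracketing source
    # samples are not both valid
    if (~ok).any():
        bad_t = t[~ok]
        for bt in bad_t:
            lo = t[ok][t[ok] < bt].max(initial=-np.inf)
            hi = t[ok][t[ok] > bt].min(initial=np.inf)
            out[(grid > lo) & (grid < hi)] = np.nan
    return out


def fov_average(tracks: list[PostTrack], grid: np.ndarray | None = None,
                values: str = "forces") -> ForceTrace:
    """Average usable tracks of one field of view into a mean +/- SEM trace.

    Tracks are resampled onto ``grid`` (default: the union span at the
    median frame interval) by linear interpolation; missing frames stay
    missing and are dropped per timepoint, not imputed.  SEM = sd/sqrt(n),
    undefined (NaN) where fewer than two sites contribute.
    """
    usable = [t for t in tracks if t.usable]
    if not usable:
        raise ValueError("no usable tracks to average")
    if grid is None:
        t0 = min(t.times[0] for t in usable)
        t1 = max(t.times[-1] for t in usable)
        dt = float(np.median(np.concatenate([np.diff(t.times) for t in usable])))
        grid = np.arange(t0, t1 + 0.5 * dt, dt)
    grid = np.asarray(grid, float)
    mat = np.vstack([_resample(t.times, getattr(t, values), grid) for t in usable])
    mean, sem, n = _column_stats(mat)
    return ForceTrace(times=grid, site_matrix=mat, mean=mean, sem=sem, n_sites=n)


def _column_stats(mat: np.ndarray):
    n = np.isfinite(mat).sum(axis=0)
    mean = np.where(n > 0, np.nansum(np.nan_to_num(mat), axis=0) / np.maximum(n, 1),
                    np.nan)
    sd = np.full(mat.shape[1], np.nan)
    multi = n >= 2
    if multi.any():
        sd[multi] = np.nanstd(mat[:, multi], axis=0, ddof=1)
    sem = sd / np.sqrt(np.maximum(n, 1))
    sem[n < 2] = np.nan
    return mean, sem, n


def area_trace(masks: list[AggregateMask], times: np.ndarray) -> ForceTrace:
    """Mean +/- SEM projected-area trace (um^2) across sites; same contract
    as :func:`fov_average`."""
    if not masks:
        raise ValueError("no masks to average")
    grid = np.asarray(times, float)
    mat = np.vstack([np.where(m.flagged_empty, np.nan, m.areas_um2) for m in masks])
    mean, sem, n = _column_stats(mat)
    return ForceTrace(times=grid, site_matrix=mat, mean=mean, sem=sem, n_sites=n)


def _interp_at(times, values, t):
    ok = np.isfinite(values)
    tt, vv = times[ok], values[ok]
    if len(tt) == 0 or t < tt[0] or t > tt[-1]:
        raise ValueError(f"evaluation time {t} s outside the trace span")
    return float(np.interp(t, tt, vv))


def endpoint_summary(trace: ForceTrace, t: float = 120.0,
                     area: ForceTrace | None = None,
                     sample_id: str = "sample") -> EndpointSummary:
    """Evaluate the mean force (and optionally area) trace at assay time ``t``
    by linear interpolation.  ``t`` outside the trace span is an error."""
    force = _interp_at(trace.times, trace.mean, t)
    area_v = _interp_at(area.times, area.mean, t) if area is not None else None
    return EndpointSummary(sample_id=sample_id, force_nN=force,
                           area_um2=area_v, eval_time_s=t)


def percent_inhibition(control: EndpointSummary, treated: EndpointSummary) -> dict:
    """Percent reduction of force and area in the treated vs control sample:
    ``100 * (control - treated) / control`` for each quantity."""
    if control.force_nN <= 0:
        raise ValueError("control force must be positive")
    out = {"force_pct": 100.0 * (control.force_nN - treated.force_nN)
           / control.force_nN}
    if control.area_um2 is not None and treated.area_um2 is not None:
        if control.area_um2 <= 0:
            raise ValueError("control area must be positive")
        out["area_pct"] = 100.0 * (control.area_um2 - treated.area_um2) \
            / control.area_um2
    return out
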