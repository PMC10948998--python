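"""Stripe domains, boundary tracking, activation kinetics and aligned
mRNA-output profiles.

Mature stripes are anchored at the last frame before gastrulation: the
nuclei active there are clustered along the AP axis, and each stripe's
*domain* runs from its anterior border to the next stripe's anterior border
(the last stripe's domain extends to the posterior end). Boundaries are
tracked over time by splitting the DV window into five equal sections,
marking the most anterior/posterior active nucleus of the stripe per
section, and averaging the five sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import NormalizedTraces, SpatialProfile

__all__ = [
    "StripeDomain",
    "BoundaryTrack",
    "KineticsCurve",
    "define_mature_stripes",
    "assign_nuclei_to_stripes",
    "boundary_track",
    "summarize_window",
    "stripe2_expansion",
    "activation_kinetics",
    "onset_delay",
    "interstripe_distance",
    "aligned_output_profile",
    "profile_boundaries_by_threshold",
]

N_DV_SECTIONS = 5


@dataclass
class StripeDomain:
    stripe_id: int
    mature_anterior: float   # %EL of the stripe's anteriormost active nucleus
    mature_posterior: float
    domain_start: float      # [domain_start, domain_end) is the stripe domain
    domain_end: float
    member_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class BoundaryTrack:
    """Per-time stripe boundaries (%EL), averaged over five DV sections."""

    stripe_id: int
    t_norm: np.ndarray
    anterior_by_section: np.ndarray   # (n_sections, n_t), NaN where empty
    posterior_by_section: np.ndarray
    anterior: np.ndarray              # mean over non-empty sections
    posterior: np.ndarray

    @property
    def width_el(self) -> np.ndarray:
        return self.posterior - self.anterior

    @property
    def position(self) -> np.ndarray:
        """Stripe position = midpoint of averaged anterior/posterior."""
        return 0.5 * (self.anterior + self.posterior)


@dataclass
class KineticsCurve:
    stripe_id: int
    t_norm: np.ndarray
    n_active: np.ndarray
    frac_active: np.ndarray
    onset_time: float  # NaN if onset_frac never reached
    onset_frac: float = 0.10


def define_mature_stripes(nt: NormalizedTraces, gap_min_el: float = 2.0,
                          min_cluster: int = 3) -> list[StripeDomain]:
    """Cluster the nuclei active at the last grid point into mature stripes.

    1-D gap clustering: active nuclei are sorted by %EL and split wherever
    the gap between consecutive nuclei exceeds ``gap_min_el`` (default two
    internuclear spacings on the reference lattice). Clusters smaller than
    ``min_cluster`` nuclei are discarded. Stripes are numbered anterior to
    posterior; domains tile [first anterior border, 100 %EL).
    """
    if nt.active is None:
        raise ValueError("call set_threshold() before define_mature_stripes()")
    last = nt.active[:, -1]
    if not last.any():
        raise ValueError("no mature stripes: no active nuclei at the last frame")
    el = nt.meta["el_pct"].to_numpy()
    ids = nt.meta["nucleus_id"].to_numpy()
    order = np.argsort(el[last], kind="stable")
    el_a = el[last][order]
    ids_a = ids[last][order]
    splits = np.flatnonzero(np.diff(el_a) > gap_min_el) + 1
    clusters = np.split(np.arange(el_a.size), splits)
    clusters = [c for c in clusters if c.size >= min_cluster]
    if not clusters:
        raise ValueError("no mature stripes: all clusters below min_cluster")
    domains: list[StripeDomain] = []
    for k, c in enumerate(clusters):
        domains.append(StripeDomain(
            stripe_id=k + 1,
            mature_anterior=float(el_a[c[0]]),
            mature_posterior=float(el_a[c[-1]]),
            domain_start=float(el_a[c[0]]),
            domain_end=np.nan,
            member_ids=ids_a[c],
        ))
    for k in range(len(domains) - 1):
        domains[k].domain_end = domains[k + 1].domain_start
    domains[-1].domain_end = 100.0
    return domains


def assign_nuclei_to_stripes(domains: list[StripeDomain],
                             nt: NormalizedTraces) -> np.ndarray:
    """Stripe id per nucleus (0 = anterior to stripe 1 / unassigned).

    Domain intervals are half-open [start, end); a nucleus exactly on a
    domain's left edge belongs to that domain. The last domain is closed on
    the right (100 %EL). Also refreshes each domain's ``member_ids``.
    """
    starts = np.array([d.domain_start for d in domains])
    ends = np.array([d.domain_end for d in domains])
    if np.any(starts[1:] < ends[:-1] - 1e-9) and np.any(starts[1:] != ends[:-1]):
        raise ValueError("overlapping stripe domains")
    el = nt.meta["el_pct"].to_numpy()
    ids = nt.meta["nucleus_id"].to_numpy()
    assign = np.zeros(el.size, dtype=int)
    for d in domains:
        right_closed = d is domains[-1]
        inside = (el >= d.domain_start) & (
            (el <= d.domain_end) if right_closed else (el < d.domain_end))
        assign[inside] = d.stripe_id
        d.member_ids = ids[inside]
    return assign


def boundary_track(nt: NormalizedTraces, domain: StripeDomain,
                   n_sections: int = N_DV_SECTIONS,
                   dv_range: tuple[float, float] | None = None) -> BoundaryTrack:
    """Track one stripe's anterior/posterior boundaries over time.

    The DV window is split into ``n_sections`` equal-height sections. At each
    time, the anterior (posterior) boundary in a section is the min (max)
    %EL of that stripe's active member nuclei in the section; sections with
    no active member are excluded from that time's mean. Times with no
    active member anywhere give NaN.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if nt.active is None:
        raise ValueError("call set_threshold() first")
    member = nt.meta["nucleus_id"].isin(domain.member_ids).to_numpy()
    el = nt.meta["el_pct"].to_numpy()[member]
    dv = nt.meta["dv_um"].to_numpy()[member]
    act = nt.active[member]
    n_t = nt.t_norm.size
    if dv_range is None:
        all_dv = nt.meta["dv_um"].to_numpy()
        dv_range = (float(all_dv.min()), float(all_dv.max()))
    edges = np.linspace(dv_range[0], dv_range[1], n_sections + 1)
    sec = np.clip(np.searchsorted(edges, dv, side="right") - 1, 0, n_sections - 1)

    ant = np.full((n_sections, n_t), np.nan)
    post = np.full((n_sections, n_t), np.nan)
    for s in range(n_sections):
        rows = sec == s
        if not rows.any():
            continue
        sub = act[rows]
        el_s = el[rows][:, None]
        lo = np.where(sub, el_s, np.inf).min(axis=0)
        hi = np.where(sub, el_s, -np.inf).max(axis=0)
        any_active = sub.any(axis=0)
        ant[s] = np.where(any_active, lo, np.nan)
        post[s] = np.where(any_active, hi, np.nan)
    n_def = (~np.isnan(ant)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_ant = np.where(n_def > 0, np.nansum(ant, axis=0)
                            / np.maximum(n_def, 1), np.nan)
        mean_post = np.where(n_def > 0, np.nansum(post, axis=0)
                             / np.maximum(n_def, 1), np.nan)
    return BoundaryTrack(domain.stripe_id, nt.t_norm, ant, post,
                         mean_ant, mean_post)


def summarize_window(bt: BoundaryTrack,
                     window: tuple[float, float] = (0.80, 0.90)
                     ) -> tuple[float, float]:
    """Time-averaged (position, width) over a normalized-time window.

    Default window covers grid points 80-90 of the normalized 100, the
    late-NC14 interval used to summarize stripe position and width.
    Returns (NaN, NaN) when the stripe is undefined throughout the window.
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    sel = (bt.t_norm >= lo) & (bt.t_norm <= hi)
    pos = bt.position[sel]
    wid = bt.width_el[sel]
    if np.all(np.isnan(pos)):
        return float("nan"), float("nan")
    return float(np.nanmean(pos)), float(np.nanmean(wid))


def stripe2_expansion(wt_tracks: list[BoundaryTrack],
                      het_tracks: list[BoundaryTrack],
                      window: tuple[float, float] = (0.40, 0.70),
                      nuclei_per_el: float = 1.0) -> float:
    """Transient stripe expansion: max over mid-NC14 of the mean width
    difference (heterozygote - wild type), in nuclei."""
    if not wt_tracks or not het_tracks:
        raise ValueError("both cohorts must be nonempty")
    t = wt_tracks[0].t_norm
    sel = (t >= window[0]) & (t <= window[1])

    def _colmean(mats):
        m = np.vstack(mats)
        n = (~np.isnan(m)).sum(axis=0)
        return np.where(n > 0, np.nansum(m, axis=0) / np.maximum(n, 1), np.nan)

    wt_w = _colmean([bt.width_el for bt in wt_tracks])
    het_w = _colmean([bt.width_el for bt in het_tracks])
    diff = (het_w - wt_w)[sel]
    if np.all(np.isnan(diff)):
        return float("nan")
    return float(np.nanmax(diff) * nuclei_per_el)


def activation_kinetics(nt: NormalizedTraces, domain: StripeDomain,
                        onset_frac: float = 0.10) -> KineticsCurve:
    """Fraction of the stripe domain's nuclei active at each time point.

    Onset is the first grid point where the fraction reaches ``onset_frac``.
    """
    member = nt.meta["nucleus_id"].isin(domain.member_ids).to_numpy()
    if not member.any():
        raise ValueError(f"stripe {domain.stripe_id} has no member nuclei")
    act = nt.active[member]
    n_active = act.sum(axis=0)
    frac = n_active / member.sum()
    crossed = np.flatnonzero(frac >= onset_frac)
    onset = float(nt.t_norm[crossed[0]]) if crossed.size else float("nan")
    return KineticsCurve(domain.stripe_id, nt.t_norm, n_active, frac,
                         onset, onset_frac)


def onset_delay(curve_ref: KineticsCurve, curve_test: KineticsCurve,
                nc14_duration_s: float) -> float:
    """Onset difference (test - reference) in minutes of NC14."""
    return (curve_test.onset_time - curve_ref.onset_time) * nc14_duration_s / 60.0


def interstripe_distance(track_a: BoundaryTrack,
                         track_b: BoundaryTrack) -> np.ndarray:
    """Midpoint-to-midpoint distance (%EL) per time; NaN where undefined."""
    return track_b.position - track_a.position


def aligned_output_profile(per_embryo: list[tuple[np.ndarray, np.ndarray]],
                           bin_el: float = 1.0, min_n: int = 10,
                           max_extent_el: float = 30.0
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled stripe mRNA-output profile aligned to each embryo's
    anteriormost stripe nucleus.

    ``per_embryo`` holds (el_pct, output) arrays for one stripe's nuclei in
    each embryo. Within each embryo the EL coordinate is re-origined at the
    stripe's anteriormost nucleus; pooled nuclei are binned at ``bin_el``
    resolution and bins with fewer than ``min_n`` pooled nuclei are dropped.
    Returns (bin_centers, mean_output, count) for the kept bins.
    """
    if not per_embryo or all(len(e[0]) == 0 for e in per_embryo):
        raise ValueError("empty stripe: no nuclei to align")
    rel, out = [], []
    for el, vals in per_embryo:
        el = np.asarray(el, dtype=float)
        vals = np.asarray(vals, dtype=float)
        if el.size == 0:
            continue
        rel.append(el - el.min())
        out.append(vals)
    rel = np.concatenate(rel)
    out = np.concatenate(out)
    n_bins = int(np.ceil(max_extent_el / bin_el))
    idx = np.clip((rel / bin_el).astype(int), 0, n_bins - 1)
    ok = ~np.isnan(out)
    count = np.bincount(idx[ok], minlength=n_bins)
    total = np.bincount(idx[ok], weights=out[ok], minlength=n_bins)
    keep = count >= min_n
    centers = (np.arange(n_bins) + 0.5) * bin_el
    with np.errstate(invalid="ignore"):
        mean = total[keep] / count[keep]
    return centers[keep], mean, count[keep]


def profile_boundaries_by_threshold(profile: SpatialProfile,
                                    threshold: float) -> tuple[float, float]:
    """Domain boundaries from a binned profile by threshold crossing.

    Anterior boundary = left edge of the first bin whose mean exceeds the
    threshold; posterior = right edge of the last such bin (contiguity is
    not required). Returns (NaN, NaN) when no bin exceeds the threshold.
    """
    with np.errstate(invalid="ignore"):
        above = np.flatnonzero(np.nan_to_num(profile.bin_mean, nan=-np.inf)
                               > threshold)
    if above.size == 0:
        return float("nan"), float("nan")
    return (float(profile.bin_edges[above[0]]),
            float(profile.bin_edges[above[-1] + 1]))
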