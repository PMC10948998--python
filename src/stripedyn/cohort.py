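"""Cross-embryo analyses: genotype calls from the PP7 reporter channel,
coefficient-of-variation profiles along the AP axis, and wild-type versus
heterozygote comparisons with Student's t-tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traces import NormalizedTraces, SpatialProfile

__all__ = [
    "CVProfile",
    "classify_genotype",
    "modal_stripe_filter",
    "cv_profile",
    "student_t",
    "compare_genotypes",
]


@dataclass
class CVProfile:
    bin_centers: np.ndarray
    cv: np.ndarray          # NaN where mean <= 0 or fewer than 2 embryos
    n_embryos: np.ndarray


def modal_stripe_filter(analyses: list) -> list:
    """Keep embryos whose detected stripe count equals the cohort mode.

    A quality-control guard for pooling: an embryo in which two stripes
    merged (or a spurious cluster appeared) would misalign stripe ids
    across the cohort.
    """
    if not analyses:
        return analyses
    counts = [len(a.domains) for a in analyses]
    mode = max(set(counts), key=counts.count)
    return [a for a in analyses if len(a.domains) == mode]


def classify_genotype(nt: NormalizedTraces,
                      posterior_window: tuple[float, float] = (72.0, 92.0),
                      threshold: float = 100.0,
                      min_frac: float = 0.2) -> str:
    """Call wt/kr_het from the posterior PP7 reporter signal.

    An embryo is wild type when at least ``min_frac`` of the nuclei in the
    posterior reporter window ever exceed ``threshold`` in the PP7 channel
    (reporter present); otherwise it is a heterozygote. Returns ``unknown``
    when no nuclei fall in the window.
    """
    if nt.pp7 is None:
        raise ValueError("traces carry no PP7 channel")
    el = nt.meta["el_pct"].to_numpy()
    lo, hi = posterior_window
    inside = (el >= lo) & (el <= hi)
    if not inside.any():
        return "unknown"
    with np.errstate(invalid="ignore"):
        ever = np.nanmax(nt.pp7[inside], axis=1) > threshold
    return "wt" if ever.mean() >= min_frac else "kr_het"


def cv_profile(embryo_profiles: list[SpatialProfile]) -> CVProfile:
    """Across-embryo coefficient of variation per AP bin.

    Each embryo contributes one value per bin (its per-bin mean, e.g. of
    cumulative mRNA output); the CV is the sample standard deviation (ddof=1)
    divided by the mean across embryos. Scale-invariant by construction.
    """
    if len(embryo_profiles) < 2:
        raise ValueError("cv_profile needs at least 2 embryos")
    edges = embryo_profiles[0].bin_edges
    for p in embryo_profiles[1:]:
        if not np.array_equal(p.bin_edges, edges):
            raise ValueError("embryo profiles must share bin edges")
    mat = np.vstack([p.bin_mean for p in embryo_profiles])
    n = (~np.isnan(mat)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
        sd = np.full(mean.shape, np.nan)
        ok = n >= 2
        sd[ok] = np.nanstd(mat[:, ok], axis=0, ddof=1)
        cv = np.where(ok & (mean > 0), sd / mean, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CVProfile(bin_centers=centers, cv=cv, n_embryos=n)


def student_t(a: np.ndarray, b: np.ndarray,
              welch: bool = False) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance; Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample in t-test")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_genotypes(wt, het, nuclei_per_el: float, nc14_duration_s: float,
                      late_window: tuple[float, float] = (0.80, 0.90),
                      mid_window: tuple[float, float] = (0.40, 0.70),
                      welch: bool = False) -> dict:
    """Wild-type vs heterozygote comparison report.

    ``wt``/``het`` are lists of :class:`~stripedyn.pipeline.EmbryoAnalysis`.
    Per stripe the report carries mean ± s.e.m. (across embryos) of the
    late-NC14 width and position, the onset delay in minutes, and Student's
    t statistic / p-value on the pooled per-nucleus cumulative mRNA output
    of ever-active stripe nuclei. A scalar transient stripe-2 expansion
    (max mid-NC14 width difference, in nuclei) accompanies the table.
    """
    from .stripes import stripe2_expansion, summarize_window

    if not wt or not het:
        raise ValueError("both cohorts must be nonempty")

    def sem(x):
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan

    stripe_ids = sorted(
        set.intersection(*[set(a.boundaries) for a in wt + het]))
    rows = []
    for sid in stripe_ids:
        rec: dict = {"stripe_id": sid}
        for name, cohort in (("wt", wt), ("het", het)):
            pos, wid, onset, pool = [], [], [], []
            for a in cohort:
                p, w = summarize_window(a.boundaries[sid], late_window)
                pos.append(p)
                wid.append(w)
                onset.append(a.kinetics[sid].onset_time)
                m = a.metrics
                members = m["nucleus_id"].isin(a.domains_by_id[sid].member_ids)
                ever = m["active_duration_points"] > 0
                pool.append(m.loc[members & ever, "mrna_output"].to_numpy())
            rec[f"width_{name}_nuclei"] = np.nanmean(wid) * nuclei_per_el
            rec[f"width_{name}_sem"] = sem(wid) * nuclei_per_el
            rec[f"position_{name}_el"] = np.nanmean(pos)
            rec[f"position_{name}_sem"] = sem(pos)
            rec[f"onset_{name}"] = np.nanmean(onset)
            rec[f"n_nuclei_{name}"] = int(sum(len(p) for p in pool))
            rec[f"_pool_{name}"] = np.concatenate(pool) if pool else np.array([])
        rec["width_delta_nuclei"] = (rec["width_het_nuclei"]
                                     - rec["width_wt_nuclei"])
        rec["position_shift_el"] = (rec["position_het_el"]
                                    - rec["position_wt_el"])
        rec["onset_delay_min"] = ((rec["onset_het"] - rec["onset_wt"])
                                  * nc14_duration_s / 60.0)
        t, p = student_t(rec.pop("_pool_wt"), rec.pop("_pool_het"), welch)
        rec["t_stat"] = t
        rec["p_value"] = p
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("stripe_id")

    expansion = {}
    for sid in stripe_ids:
        expansion[sid] = stripe2_expansion(
            [a.boundaries[sid] for a in wt], [a.boundaries[sid] for a in het],
            window=mid_window, nuclei_per_el=nuclei_per_el)
    report = {
        "per_stripe": table,
        "stripe2_expansion_nuclei": expansion.get(2, float("nan")),
        "expansion_by_stripe": expansion,
        "n_wt": len(wt),
        "n_het": len(het),
    }
    return report
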