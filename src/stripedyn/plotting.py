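"""Figure-style views of the pipeline outputs.

Every plot draws only from objects regenerable from the saved CSVs:
boundary tracks, kinetics curves, spatial/CV profiles.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_boundary_tracks", "plot_kinetics", "plot_cv_profiles"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_boundary_tracks(tracks, ax=None, label_prefix=""):
    """Anterior/posterior boundaries of one or more stripes over time."""
    ax = _ax(ax)
    if not isinstance(tracks, (list, tuple)):
        tracks = [tracks]
    for bt in tracks:
        line, = ax.plot(bt.t_norm, bt.anterior,
                        label=f"{label_prefix}stripe {bt.stripe_id}")
        ax.plot(bt.t_norm, bt.posterior, color=line.get_color(), ls="--")
    ax.set_xlabel("normalized NC14 time")
    ax.set_ylabel("boundary position (%EL)")
    ax.legend(fontsize="small")
    return ax


def plot_kinetics(curves, ax=None, label_prefix=""):
    """Fraction of domain nuclei active over time."""
    ax = _ax(ax)
    if not isinstance(curves, (list, tuple)):
        curves = [curves]
    for kc in curves:
        ax.plot(kc.t_norm, kc.frac_active,
                label=f"{label_prefix}stripe {kc.stripe_id}")
        if np.isfinite(kc.onset_time):
            ax.axvline(kc.onset_time, color="gray", lw=0.5)
    ax.set_xlabel("normalized NC14 time")
    ax.set_ylabel("fraction of nuclei active")
    ax.legend(fontsize="small")
    return ax


def plot_cv_profiles(cv_by_genotype: dict, ax=None):
    """Coefficient-of-variation profiles along the AP axis per genotype."""
    ax = _ax(ax)
    for name, prof in cv_by_genotype.items():
        ax.plot(prof.bin_centers, prof.cv, label=name)
    ax.set_xlabel("AP position (%EL)")
    ax.set_ylabel("CV of cumulative mRNA output")
    ax.legend()
    return ax
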