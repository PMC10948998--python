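"""Synthetic blastoderm embryos with bursty pair-rule stripe transcription.

This module generates the inputs the rest of the package analyzes: a nucleus
monolayer covering the trunk of a *Drosophila*-like embryo, gap-gene-like
regulator fields along the anterior-posterior (AP) axis, two-state
(telegraph) transcription traces for seven pair-rule stripes, and optionally
rendered two-channel time-lapse image stacks.

Coordinates: AP position is expressed in %EL (egg length), measured from the
anterior tip (anterior = 0%). The dorsal-ventral (DV) coordinate is in µm,
centered on the embryo midline.

Two genotypes are supported. ``wt`` is the reference; ``kr_het`` emulates an
embryo carrying a single functional copy of the gap gene *Krüppel*. The
heterozygote's effects on the seven stripes are *planted parameters* (edge
shifts, onset delays, amplitude factors) so that downstream recovery can be
checked against an exact ground truth; they are not derived from the
regulator network. A parallel regulator-based pathway (:func:`gap_profile`,
:func:`stripe_rate`) expresses the same regulatory logic — halved Kr,
anteriorly shifted posterior *gt* and *kni* domains, reduced anterior *hb* —
for experiments that want the repression logic itself to move the stripes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "EmbryoGeometry",
    "RegulatorProfile",
    "StripeRule",
    "EmbryoSim",
    "RenderParams",
    "GENES",
    "GENOTYPES",
    "gap_profile",
    "stripe_rate",
    "default_regulators",
    "default_stripe_rules",
    "make_embryo",
    "simulate_traces",
    "simulate_telegraph",
    "simulate_cohort",
    "render_frames",
]

GENES = ("Kr", "gt_ant", "gt_post", "kni", "hb_ant", "hb_post")
GENOTYPES = ("wt", "kr_het")

TRACE_COLUMNS = [
    "nucleus_id",
    "frame",
    "t_seconds",
    "ap_um",
    "dv_um",
    "el_pct",
    "fluor_ms2",
    "fluor_pp7",
    "true_state",
]


def _check_genotype(genotype: str) -> None:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbryoGeometry:
    """Nucleus lattice and acquisition timing for one synthetic embryo.

    The AP lattice pitch is ``ap_length_um / n_ap_nuclei``; with the defaults
    (500 µm, 100 nuclei) one nucleus corresponds to exactly 1 %EL, which makes
    planted effect sizes stated in nuclei easy to bookkeep. The DV window is
    282 µm spanning 17 nuclei, and frames are 61 s apart; NC14 lasts 3000 s
    (~50 min) from the end of the 13th mitosis to gastrulation.
    """

    ap_length_um: float = 500.0
    dv_window_um: float = 282.0
    n_ap_nuclei: int = 100
    n_dv_nuclei: int = 17
    frame_interval_s: float = 61.0
    nc14_duration_s: float = 3000.0

    def __post_init__(self) -> None:
        if self.ap_length_um <= 0:
            raise ValueError("ap_length_um must be positive")
        if self.dv_window_um <= 0:
            raise ValueError("dv_window_um must be positive")
        if self.n_ap_nuclei < 1 or self.n_dv_nuclei < 1:
            raise ValueError("need at least one nucleus along each axis")
        if self.frame_interval_s <= 0 or self.nc14_duration_s <= 0:
            raise ValueError("frame_interval_s and nc14_duration_s must be positive")

    @property
    def internuclear_spacing_um(self) -> float:
        return self.ap_length_um / self.n_ap_nuclei

    @property
    def spacing_el(self) -> float:
        """AP lattice pitch in %EL."""
        return 100.0 / self.n_ap_nuclei

    @property
    def nuclei_per_el(self) -> float:
        """Conversion factor from %EL to nuclei: width_nuclei = width_el * this."""
        return self.n_ap_nuclei / 100.0

    def el(self, ap_um: np.ndarray | float) -> np.ndarray | float:
        return 100.0 * np.asarray(ap_um) / self.ap_length_um

    def frame_times(self) -> np.ndarray:
        """Acquisition times in seconds, frame 0 at the start of NC14."""
        n = int(np.floor(self.nc14_duration_s / self.frame_interval_s)) + 1
        return np.arange(n) * self.frame_interval_s


# ---------------------------------------------------------------------------
# regulator fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulatorProfile:
    """A gap-gene-like expression domain: a product-of-logistics bump in %EL.

    ``het_scaling`` multiplies the amplitude in the *Kr* heterozygote (0.5 for
    Kr itself: halved dosage), ``het_shift_el`` displaces the domain center
    (negative = anterior shift). ``ramp_time`` is the normalized time over
    which the field ramps linearly from 0 to its plateau.
    """

    gene: str
    amplitude: float = 1.0
    center_el: float = 50.0
    half_width_el: float = 10.0
    edge_steepness: float = 1.0  # 1/%EL
    ramp_time: float = 0.2
    het_scaling: float = 1.0
    het_shift_el: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.half_width_el <= 0:
            raise ValueError("half_width_el must be positive")
        if not 0.0 <= self.center_el <= 100.0:
            raise ValueError("center_el must lie in [0, 100]")

    def concentration(self, x, t, genotype: str = "wt"):
        _check_genotype(genotype)
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        center = self.center_el
        scale = self.amplitude
        if genotype == "kr_het":
            center = center + self.het_shift_el
            scale = scale * self.het_scaling
        if self.ramp_time > 0:
            ramp = np.clip(t / self.ramp_time, 0.0, 1.0)
        else:
            ramp = np.ones_like(t)
        k = self.edge_steepness
        lo = expit(k * (x - (center - self.half_width_el)))
        hi = expit(k * ((center + self.half_width_el) - x))
        return scale * ramp * lo * hi


def default_regulators() -> dict[str, RegulatorProfile]:
    """Trunk gap-gene fields: Kr central, gt/kni flanking, hb at both poles.

    Heterozygote modifications encode the regulatory picture of a halved Kr
    dosage: Kr itself at 50%, the posterior gt and kni domains shifted
    anteriorly (weaker Kr repression), anterior hb reduced (Kr activates
    low-level hb).
    """
    profs = [
        RegulatorProfile("Kr", amplitude=1.0, center_el=47.0, half_width_el=9.0,
                         het_scaling=0.5),
        RegulatorProfile("hb_ant", amplitude=1.0, center_el=15.0, half_width_el=15.0,
                         het_scaling=0.8),
        RegulatorProfile("hb_post", amplitude=0.8, center_el=92.0, half_width_el=5.0),
        RegulatorProfile("kni", amplitude=1.0, center_el=66.0, half_width_el=7.0,
                         het_shift_el=-1.5),
        RegulatorProfile("gt_ant", amplitude=1.0, center_el=26.0, half_width_el=6.0),
        RegulatorProfile("gt_post", amplitude=1.0, center_el=82.0, half_width_el=5.0,
                         het_shift_el=-2.0),
    ]
    return {p.gene: p for p in profs}


def gap_profile(gene: str, x, t, genotype: str = "wt",
                regulators: Mapping[str, RegulatorProfile] | None = None):
    """Evaluate a regulator field at AP position ``x`` (%EL), time ``t`` (normalized).

    For ``gene='Kr'`` the heterozygote value is exactly half the wild-type
    value at every (x, t) — halved gene dosage with assumed linear
    mRNA/protein correspondence.
    """
    if regulators is None:
        regulators = default_regulators()
    if gene not in regulators:
        raise ValueError(
            f"unknown gene {gene!r}; valid genes: {sorted(regulators)}")
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("x must lie in [0, 100] %EL")
    if np.any((t < 0) | (t > 1)):
        raise ValueError("t must lie in [0, 1] normalized time")
    return regulators[gene].concentration(x, t, genotype)


# ---------------------------------------------------------------------------
# stripe rules
# ---------------------------------------------------------------------------


def _trapezoid_bump(t, a: float, b: float, c: float, d: float):
    """Piecewise-linear membership: 0 before a, ramps to 1 on [a,b], 1 on
    [b,c], ramps to 0 on [c,d], 0 after d."""
    t = np.asarray(t, dtype=float)
    up = np.clip((t - a) / max(b - a, 1e-12), 0.0, 1.0)
    down = np.clip((d - t) / max(d - c, 1e-12), 0.0, 1.0)
    return np.minimum(up, down)


@dataclass(frozen=True)
class StripeRule:
    """Transcription rule for one stripe: where, when and how it bursts.

    The stripe occupies [anterior_el, posterior_el] at maturity. Burst
    initiation follows a two-state telegraph process with rate ``k_on``
    graded by logistic edges of scale ``edge_softness_el`` (0 = hard step
    edges), zero before ``onset_time`` (normalized NC14 time). While ON, the
    transcription site emits fluorescence ``loading_amplitude``.

    ``het_*`` fields are the planted heterozygote modifications; all default
    to neutral. ``het_transient_posterior_el`` adds a *transient* posterior
    edge excursion, following the trapezoidal time window
    ``het_transient_window`` — this models a mid-NC14 expansion that vanishes
    again before gastrulation.

    ``repressor_weights``/``activator_floor`` parameterize the alternative
    regulator-driven rate (:func:`stripe_rate`).
    """

    stripe_id: int
    anterior_el: float
    posterior_el: float
    k_on_max: float = 0.02      # 1/s
    k_off: float = 0.005        # 1/s
    loading_amplitude: float = 300.0
    onset_time: float = 0.15
    edge_softness_el: float = 0.5
    deterministic: bool = False
    activator_floor: float = 1.0
    repressor_weights: Mapping[str, float] = field(default_factory=dict)
    het_anterior_shift_el: float = 0.0
    het_posterior_shift_el: float = 0.0
    het_transient_posterior_el: float = 0.0
    # transient ends by ~0.7 so the OFF-decay tail (1/k_off ~ 0.07 of NC14)
    # clears before the late-NC14 summary window
    het_transient_window: tuple[float, float, float, float] = (0.35, 0.45, 0.60, 0.72)
    het_onset_delay_s: float = 0.0
    het_amplitude_factor: float = 1.0
    het_k_on_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k_on_max < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.onset_time <= 1.0:
            raise ValueError("onset_time must lie in [0, 1]")
        if self.posterior_el <= self.anterior_el:
            raise ValueError("posterior_el must exceed anterior_el")

    # -- planted ground truth accessors -------------------------------------

    def edges(self, t_norm, genotype: str = "wt"):
        """Planted (anterior, posterior) stripe edges in %EL at time(s) t_norm."""
        _check_genotype(genotype)
        t_norm = np.asarray(t_norm, dtype=float)
        ant = np.broadcast_to(np.float64(self.anterior_el), t_norm.shape).copy()
        post = np.broadcast_to(np.float64(self.posterior_el), t_norm.shape).copy()
        if genotype == "kr_het":
            ant += self.het_anterior_shift_el
            post += self.het_posterior_shift_el
            if self.het_transient_posterior_el != 0.0:
                post += self.het_transient_posterior_el * _trapezoid_bump(
                    t_norm, *self.het_transient_window)
        return ant, post

    def onset(self, genotype: str, nc14_duration_s: float) -> float:
        """Planted onset in normalized time for the given genotype."""
        _check_genotype(genotype)
        t0 = self.onset_time
        if genotype == "kr_het":
            t0 = t0 + self.het_onset_delay_s / nc14_duration_s
        return t0

    def amplitude(self, genotype: str) -> float:
        _check_genotype(genotype)
        if genotype == "kr_het":
            return self.loading_amplitude * self.het_amplitude_factor
        return self.loading_amplitude

    def planted_width_delta_el(self) -> float:
        """Steady-state het-minus-wt width change (%EL), excluding transients."""
        return self.het_posterior_shift_el - self.het_anterior_shift_el

    def planted_position_shift_el(self) -> float:
        """Steady-state het-minus-wt midpoint shift (%EL)."""
        return 0.5 * (self.het_anterior_shift_el + self.het_posterior_shift_el)

    # -- burst propensity ----------------------------------------------------

    def k_on_profile(self, el, t_norm, genotype: str, nc14_duration_s: float):
        """Burst initiation rate (1/s) at AP positions ``el`` and time ``t_norm``."""
        el = np.asarray(el, dtype=float)
        ant, post = self.edges(t_norm, genotype)
        if self.edge_softness_el > 0:
            gate = (expit((el - ant) / self.edge_softness_el)
                    * expit((post - el) / self.edge_softness_el))
        else:
            gate = ((el >= ant) & (el <= post)).astype(float)
        if np.asarray(t_norm).ndim == 0 and float(t_norm) < self.onset(
                genotype, nc14_duration_s):
            gate = np.zeros_like(gate)
        k = self.k_on_max
        if genotype == "kr_het":
            k = k * self.het_k_on_factor
        return k * gate


def stripe_rate(rule: StripeRule, concentrations: Mapping[str, float],
                t: float) -> tuple[float, float]:
    """Regulator-driven burst propensity for one stripe.

    k_on = k_on_max * max(0, 1 - sum_i w_i c_i / activator_floor), clipped to
    [0, k_on_max]; zero before the rule's onset time. Returns
    (k_on, loading_amplitude). Monotone non-increasing in every repressor
    concentration.
    """
    for gene, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {gene!r}")
    if t < rule.onset_time:
        return 0.0, rule.loading_amplitude
    load = sum(w * concentrations.get(g, 0.0)
               for g, w in rule.repressor_weights.items())
    k_on = rule.k_on_max * max(0.0, 1.0 - load / rule.activator_floor)
    return min(k_on, rule.k_on_max), rule.loading_amplitude


def default_stripe_rules(preset: str = "default") -> list[StripeRule]:
    """Seven stripes, anterior borders every 8 %EL from 30 %EL, 4 %EL wide.

    Presets:

    ``default``
        Bursty stripes with soft edges and the planted heterozygote effects:
        stripe 2 transiently 1.6 nuclei wider (posterior excursion around
        mid-NC14), stripes 3 and 4 each 0.9 nuclei narrower with reduced
        loading amplitude, stripe 4 additionally shifted anteriorly, delayed
        by 360 s and bursting more sporadically, stripe 5 shifted 3 nuclei
        toward the anterior.
    ``neutral``
        Same stripes with every heterozygote effect switched off (null
        cohorts for calibration).
    ``ideal``
        Deterministic, step-edged, always-on stripes from t = 0 — the
        noise-free ground-truth surface for exact boundary recovery.
    """
    if preset not in ("default", "neutral", "ideal"):
        raise ValueError(f"unknown preset {preset!r}")
    het = {
        2: dict(het_transient_posterior_el=1.6),
        3: dict(het_posterior_shift_el=-0.9, het_amplitude_factor=0.75),
        4: dict(het_anterior_shift_el=-0.4, het_posterior_shift_el=-1.3,
                het_onset_delay_s=360.0, het_amplitude_factor=0.75,
                het_k_on_factor=0.6),
        5: dict(het_anterior_shift_el=-3.0, het_posterior_shift_el=-3.0),
    }
    rules = []
    for i in range(1, 8):
        ant = 30.0 + 8.0 * (i - 1)
        kwargs: dict = dict(stripe_id=i, anterior_el=ant, posterior_el=ant + 4.0,
                            repressor_weights={"Kr": 1.0})
        if preset == "default":
            kwargs.update(het.get(i, {}))
        if preset == "ideal":
            kwargs.update(onset_time=0.0, edge_softness_el=0.0,
                          deterministic=True, k_off=0.0)
        rules.append(StripeRule(**kwargs))
    return rules


# ---------------------------------------------------------------------------
# embryo assembly and trace simulation
# ---------------------------------------------------------------------------


@dataclass
class EmbryoSim:
    """A fully specified synthetic embryo ready for simulation.

    ``has_pp7_reporter`` is True iff the genotype is wild type, emulating the
    posterior PP7 reporter whose presence/absence separates wild types from
    heterozygotes in the two-channel movies.
    """

    geometry: EmbryoGeometry
    genotype: str
    nuclei: pd.DataFrame  # nucleus_id, ap_um, dv_um, el_pct
    stripe_rules: Sequence[StripeRule]
    regulators: Mapping[str, RegulatorProfile]
    seed: int = 0
    background: float = 40.0
    noise_sd: float = 15.0
    has_pp7_reporter: bool = True
    pp7_domain_el: tuple[float, float] = (72.0, 92.0)
    pp7_amplitude: float = 250.0
    pp7_onset: float = 0.10

    def __post_init__(self) -> None:
        _check_genotype(self.genotype)
        ids = self.nuclei["nucleus_id"].to_numpy()
        if len(ids) != len(np.unique(ids)):
            raise ValueError("nucleus ids must be unique")
        ap = self.nuclei["ap_um"].to_numpy()
        if np.any((ap < 0) | (ap > self.geometry.ap_length_um)):
            raise ValueError("nuclei must lie within [0, ap_length_um]")
        half = self.geometry.dv_window_um / 2
        dv = self.nuclei["dv_um"].to_numpy()
        if np.any(np.abs(dv) > half + 1e-9):
            raise ValueError("nuclei must lie within the DV window")


def make_embryo(genotype: str = "wt", preset: str = "default",
                geometry: EmbryoGeometry | None = None, seed: int = 0,
                jitter_um: float = 0.0, **overrides) -> EmbryoSim:
    """Build a synthetic embryo on a regular nucleus lattice.

    ``overrides`` are forwarded to :class:`EmbryoSim` (e.g. ``noise_sd=0``).
    The ``ideal`` preset switches noise and background off unless explicitly
    overridden.
    """
    _check_genotype(genotype)
    geometry = geometry or EmbryoGeometry()
    g = geometry
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11CE]))
    ap_pitch = g.internuclear_spacing_um
    dv_pitch = g.dv_window_um / g.n_dv_nuclei
    ai = (np.arange(g.n_ap_nuclei) + 0.5) * ap_pitch
    dj = (np.arange(g.n_dv_nuclei) + 0.5) * dv_pitch - g.dv_window_um / 2
    ap, dv = np.meshgrid(ai, dj, indexing="ij")
    ap = ap.ravel()
    dv = dv.ravel()
    if jitter_um > 0:
        ap = np.clip(ap + rng.normal(0, jitter_um, ap.size), 0, g.ap_length_um)
        dv = np.clip(dv + rng.normal(0, jitter_um, dv.size),
                     -g.dv_window_um / 2, g.dv_window_um / 2)
    nuclei = pd.DataFrame({
        "nucleus_id": np.arange(ap.size, dtype=np.int64),
        "ap_um": ap,
        "dv_um": dv,
        "el_pct": 100.0 * ap / g.ap_length_um,
    })
    if preset == "ideal":
        overrides.setdefault("background", 0.0)
        overrides.setdefault("noise_sd", 0.0)
    return EmbryoSim(
        geometry=g,
        genotype=genotype,
        nuclei=nuclei,
        stripe_rules=default_stripe_rules(preset),
        regulators=default_regulators(),
        seed=int(seed),
        has_pp7_reporter=(genotype == "wt"),
        **overrides,
    )


def simulate_telegraph(k_on: np.ndarray, k_off: np.ndarray, dt: float,
                       rng: np.random.Generator,
                       init: np.ndarray | None = None) -> np.ndarray:
    """Sample a two-state telegraph process on a frame grid.

    ``k_on`` and ``k_off`` are (n_units, n_frames) rate arrays (1/s), piecewise
    constant over each frame interval. Uses the exact two-state propagator
    P(on at t+dt | state s) = pi + (s - pi) exp(-(k_on + k_off) dt) with
    pi = k_on / (k_on + k_off), so samples at frame times follow the law of
    the continuous-time chain. If ``init`` is None, frame-0 states are drawn
    from the stationary law of the frame-0 rates.

    Returns a boolean (n_units, n_frames) ON/OFF matrix.
    """
    k_on = np.atleast_2d(np.asarray(k_on, dtype=float))
    k_off = np.atleast_2d(np.asarray(k_off, dtype=float))
    k_off = np.broadcast_to(k_off, k_on.shape)
    n, nf = k_on.shape
    states = np.zeros((n, nf), dtype=bool)
    ktot0 = k_on[:, 0] + k_off[:, 0]
    pi0 = np.divide(k_on[:, 0], ktot0, out=np.zeros(n), where=ktot0 > 0)
    if init is None:
        s = rng.random(n) < pi0
    else:
        s = np.asarray(init, dtype=bool).copy()
    states[:, 0] = s
    for j in range(1, nf):
        kon = k_on[:, j - 1]
        koff = k_off[:, j - 1]
        ktot = kon + koff
        pi = np.divide(kon, ktot, out=np.zeros(n), where=ktot > 0)
        decay = np.exp(-ktot * dt)
        p_on = pi + (s.astype(float) - pi) * decay
        s = rng.random(n) < p_on
        states[:, j] = s
    return states


def _rates_and_amplitudes(embryo: EmbryoSim, t_norm: np.ndarray):
    """Per-nucleus-per-frame k_on/k_off, loading amplitude and forced states.

    Stripes are spatially disjoint, so each nucleus is governed by at most
    one rule: the one contributing the largest k_on (deterministic rules
    gate directly). Loading is time-resolved: a nucleus emits only while it
    sits inside the rule's *current* permissive window (spatial gate > 1/2,
    past onset) — a locus that drifts outside a refining stripe edge stops
    loading polymerases even if its promoter state has not yet decayed.
    Nuclei outside every stripe decay OFF at the default k_off.
    """
    g = embryo.geometry
    el = embryo.nuclei["el_pct"].to_numpy()
    n, nf = el.size, t_norm.size
    k_on = np.zeros((n, nf))
    k_off = np.full((n, nf), 0.005)
    amp = np.zeros((n, nf))
    det_state = np.zeros((n, nf), dtype=bool)
    for rule in embryo.stripe_rules:
        onset = rule.onset(embryo.genotype, g.nc14_duration_s)
        ant, post = rule.edges(t_norm, embryo.genotype)
        if rule.deterministic:
            inside = (el[:, None] >= ant[None, :]) & (el[:, None] <= post[None, :])
            inside &= (t_norm[None, :] >= onset)
            det_state |= inside
            emitting = inside
        else:
            if rule.edge_softness_el > 0:
                gate = (expit((el[:, None] - ant[None, :]) / rule.edge_softness_el)
                        * expit((post[None, :] - el[:, None]) / rule.edge_softness_el))
            else:
                gate = ((el[:, None] >= ant[None, :])
                        & (el[:, None] <= post[None, :])).astype(float)
            gate = gate * (t_norm[None, :] >= onset)
            k = rule.k_on_max
            if embryo.genotype == "kr_het":
                k = k * rule.het_k_on_factor
            contrib = k * gate
            better = contrib > k_on
            k_on = np.where(better, contrib, k_on)
            k_off = np.where(better, rule.k_off, k_off)
            emitting = gate > 0.5
        amp = np.where(emitting & (amp == 0), rule.amplitude(embryo.genotype), amp)
    return k_on, k_off, amp, det_state


def simulate_traces(embryo: EmbryoSim) -> pd.DataFrame:
    """Simulate per-nucleus fluorescence traces over NC14.

    Returns a long-form table with one row per (nucleus, frame) and columns
    ``nucleus_id, frame, t_seconds, ap_um, dv_um, el_pct, fluor_ms2,
    fluor_pp7, true_state``. Fluorescence is background + loading amplitude
    while ON + additive Gaussian noise, clipped at zero. Bit-identical for a
    fixed embryo seed.
    """
    if len(embryo.nuclei) == 0:
        raise ValueError("embryo has no nuclei")
    g = embryo.geometry
    times = g.frame_times()
    t_norm = times / g.nc14_duration_s
    n, nf = len(embryo.nuclei), times.size
    rng = np.random.default_rng(np.random.SeedSequence([int(embryo.seed), 0x57A7E]))

    k_on, k_off, amp, det_state = _rates_and_amplitudes(embryo, t_norm)
    states = simulate_telegraph(k_on, k_off, g.frame_interval_s, rng)
    states |= det_state

    fluor = embryo.background + amp * states
    if embryo.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, embryo.noise_sd, size=(n, nf))
    fluor = np.clip(fluor, 0.0, None)

    el = embryo.nuclei["el_pct"].to_numpy()
    pp7 = np.full((n, nf), embryo.background)
    if embryo.has_pp7_reporter:
        lo, hi = embryo.pp7_domain_el
        in_dom = (el >= lo) & (el <= hi)
        on = (t_norm[None, :] >= embryo.pp7_onset) & in_dom[:, None]
        pp7 = pp7 + embryo.pp7_amplitude * on
    if embryo.noise_sd > 0:
        pp7 = pp7 + rng.normal(0.0, embryo.noise_sd, size=(n, nf))
    pp7 = np.clip(pp7, 0.0, None)

    idx = pd.MultiIndex.from_product(
        [embryo.nuclei["nucleus_id"], np.arange(nf)], names=["nucleus_id", "frame"])
    out = pd.DataFrame(index=idx).reset_index()
    out["t_seconds"] = np.tile(times, n)
    out["ap_um"] = np.repeat(embryo.nuclei["ap_um"].to_numpy(), nf)
    out["dv_um"] = np.repeat(embryo.nuclei["dv_um"].to_numpy(), nf)
    out["el_pct"] = np.repeat(el, nf)
    out["fluor_ms2"] = fluor.ravel()
    out["fluor_pp7"] = pp7.ravel()
    out["true_state"] = states.ravel().astype(np.int8)
    return out[TRACE_COLUMNS]


def simulate_cohort(n_wt: int, n_het: int, preset: str = "default",
                    geometry: EmbryoGeometry | None = None, seed: int = 0,
                    **overrides) -> list[tuple[EmbryoSim, pd.DataFrame]]:
    """Simulate a mixed cohort; per-embryo seeds derive from ``seed``."""
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_wt + n_het)]
    out = []
    for i in range(n_wt + n_het):
        genotype = "wt" if i < n_wt else "kr_het"
        emb = make_embryo(genotype, preset=preset, geometry=geometry,
                          seed=child_seeds[i], **overrides)
        out.append((emb, simulate_traces(emb)))
    return out


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for synthetic 2-channel frames.

    The MS2 punctum peak is pre-compensated so that the mean of the two
    brightest pixels in the nucleus equals the planted trace value exactly
    (the punctum is snapped to the nearest pixel center; its four nearest
    neighbours then share the second-brightest value).
    """

    px_per_um: float = 1.0
    nucleus_radius_px: float = 5.0
    psf_sigma_px: float = 2.0
    background: float = 0.0
    noise_sd: float = 0.0
    nucleus_peak: float = 200.0
    pad_px: int = 8

    def __post_init__(self) -> None:
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")


def _add_gaussian(img: np.ndarray, cy: float, cx: float, sigma: float,
                  peak: float, extent: float = 4.0) -> None:
    h, w = img.shape
    r = int(np.ceil(extent * sigma))
    y0, y1 = max(0, int(np.floor(cy)) - r), min(h, int(np.floor(cy)) + r + 1)
    x0, x1 = max(0, int(np.floor(cx)) - r), min(w, int(np.floor(cx)) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += peak * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))


def render_frames(embryo: EmbryoSim, traces: pd.DataFrame,
                  params: RenderParams | None = None) -> tuple[np.ndarray, dict]:
    """Render 2-channel frames (channel 0: nuclei, channel 1: MS2 puncta).

    Returns ``(stack, meta)`` with stack shape (n_frames, 2, H, W) float32 and
    a sidecar dict describing the channel order and pixel geometry.
    Deterministic for a fixed embryo seed.
    """
    params = params or RenderParams()
    g = embryo.geometry
    ap_pitch_px = g.internuclear_spacing_um * params.px_per_um
    dv_pitch_px = (g.dv_window_um / g.n_dv_nuclei) * params.px_per_um
    if params.nucleus_radius_px >= min(ap_pitch_px, dv_pitch_px) / 2:
        raise ValueError(
            "nucleus_radius_px must be smaller than half the internuclear "
            "spacing in pixels (non-overlapping nuclei contract)")
    pad = params.pad_px
    W = int(np.ceil(g.ap_length_um * params.px_per_um)) + 2 * pad
    H = int(np.ceil(g.dv_window_um * params.px_per_um)) + 2 * pad

    frames = np.sort(traces["frame"].unique())
    stack = np.full((frames.size, 2, H, W), params.background, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([int(embryo.seed), 0xF1A6]))

    nuc = embryo.nuclei.set_index("nucleus_id")
    x_px = nuc["ap_um"].to_numpy() * params.px_per_um + pad
    y_px = (nuc["dv_um"].to_numpy() + g.dv_window_um / 2) * params.px_per_um + pad
    pos = dict(zip(nuc.index.to_numpy(), zip(y_px, x_px)))

    sig = params.psf_sigma_px
    # top-2 compensation: neighbour pixels sit one pixel from the snapped center
    comp = 2.0 / (1.0 + np.exp(-1.0 / (2.0 * sig ** 2)))
    nuc_sigma = params.nucleus_radius_px / 2.0

    by_frame = traces.groupby("frame")
    for fi, frame in enumerate(frames):
        sub = by_frame.get_group(frame)
        for _, row in sub.iterrows():
            cy, cx = pos[row["nucleus_id"]]
            _add_gaussian(stack[fi, 0], cy, cx, nuc_sigma, params.nucleus_peak)
            f = float(row["fluor_ms2"])
            if f > 0:
                _add_gaussian(stack[fi, 1], round(cy), round(cx), sig, comp * f)
        if params.noise_sd > 0:
            stack[fi] += rng.normal(0, params.noise_sd, size=(2, H, W))
    np.clip(stack, 0.0, None, out=stack)
    meta = {
        "channels": ["nuclei", "ms2"],
        "px_per_um": params.px_per_um,
        "pad_px": pad,
        "frame_interval_s": g.frame_interval_s,
        "ap_length_um": g.ap_length_um,
        "dv_window_um": g.dv_window_um,
    }
    return stack, meta
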