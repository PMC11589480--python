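"""Minimal model of the Marchantia nuclear auxin pathway (NAP).

The model couples three layers:

1. **Aux/IAA turnover.**  Free MpIAA (``I``) is produced at a constant rate
   and degraded both basally and via the TIR1-auxin co-receptor::

       dI/dt = pi_I - (delta_I0 + delta_Imax * a / (K_aux + a)) * I

   TIR1 abundance is folded into ``delta_Imax`` (its level changes slowly
   relative to IAA turnover).

2. **ARF competition for shared DNA sites.**  MpARF1 (auxin-switchable
   activator) and MpARF2 (auxin-independent repressor) compete for the same
   auxin-response elements.  MpIAA binds MpARF1 pairwise (dissociation
   constant ``K_AI``, solved exactly at quasi-equilibrium); the ARF1-IAA
   complex still binds DNA with ARF1's affinity but activates nothing.
   Per-site occupancy follows the equilibrium partition function::

       phi_act = (A1f/K_1) / (1 + A1f/K_1 + A1I/K_1 + A2/K_2)

   Total ARF levels enter as measured fold-change profiles scaled by
   ``s1``/``s2`` into concentration units, interpolated in time by a
   shape-preserving piecewise cubic (PCHIP: C1, monotone, no overshoot).

3. **Transcription of a hypothetical auxin-regulated gene.** ::

       dm/dt = lambda_m * phi_act**h + basal_m - delta_m * m

Scenarios switch individual ARF degradation off by freezing that ARF's
profile at its t = 0 value — the in-silico analogue of blocking its
proteasomal turnover.  Units: minutes inside the integrator, hours at the
I/O boundary; concentrations are arbitrary units anchored by ``s1``/``s2``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .params import load_nap_defaults

__all__ = [
    "ARFProfile", "NAPParameters", "SimulationResult",
    "fit_arf_profile", "fit_arf_profiles",
    "arf1_iaa_equilibrium", "occupancy", "occupancy_bruteforce",
    "simulate", "iaa_effective_halflife", "scenario_report",
]

SCENARIOS = ("degradation_on", "arf2_degradation_off", "arf1_degradation_off", "custom")


# --------------------------------------------------------------------------
# ARF input profiles

@dataclass(frozen=True)
class ARFProfile:
    """Piecewise-cubic fold-change profile of one ARF in one replicate.

    Evaluation clamps to the fitted domain (constant extrapolation beyond
    the last knot) and floors at 0.  PCHIP interpolation guarantees the
    curve is C1, passes exactly through the knots, and never overshoots the
    data range, so non-negative data give a non-negative profile.
    """

    species: str
    replicate: str
    knots: np.ndarray          # hours
    values: np.ndarray         # fold change at the knots
    _interp: PchipInterpolator = field(repr=False, compare=False, default=None)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def __call__(self, t_h) -> np.ndarray:
        t = np.clip(np.asarray(t_h, dtype=float), *self.domain)
        return np.maximum(self._interp(t), 0.0)

    def at_t0(self) -> float:
        return float(self.values[0])


def fit_arf_profile(times_h, fc, species: str = "", replicate: str = "") -> ARFProfile:
    """Fit a shape-preserving piecewise cubic through one fold-change series."""
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(fc, dtype=float)
    order = np.argsort(t)
    t, v = t[order], v[order]
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate knots in the time course")
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    if t[0] != 0.0:
        raise ValueError("profile must include t = 0 (the dormant reference)")
    if np.any(v < 0):
        raise ValueError("fold-change values must be >= 0")
    interp = PchipInterpolator(t, v, extrapolate=False)
    return ARFProfile(species=species, replicate=replicate, knots=t, values=v,
                      _interp=interp)


def fit_arf_profiles(fc_table: pd.DataFrame) -> dict[tuple[str, str], ARFProfile]:
    """Fit one profile per (arf, replicate) from a long fold-change table."""
    out = {}
    for (arf, rep), grp in fc_table.groupby(["arf", "replicate"]):
        grp = grp.sort_values("time_h")
        out[(str(arf), str(rep))] = fit_arf_profile(
            grp["time_h"], grp["fc"], species=str(arf), replicate=str(rep))
    return out


# --------------------------------------------------------------------------
# Parameters

_DEFAULTS = None


@dataclass(frozen=True)
class NAPParameters:
    """Rate constants, affinities and scales of the NAP model (see module docs).

    Rates are per minute, concentrations in arbitrary units.  Defaults load
    from the packaged parameter file; only the IAA turnover rate there is
    anchored to a measurement.
    """

    pi_I: float          # MpIAA production, conc/min
    delta_I0: float      # basal MpIAA decay, 1/min
    delta_Imax: float    # maximal TIR1-auxin-mediated MpIAA decay, 1/min
    K_aux: float         # auxin half-saturation, conc
    K_AI: float          # ARF1-IAA dissociation constant, conc
    K_1: float           # ARF1-DNA dissociation constant, conc
    K_2: float           # ARF2-DNA dissociation constant, conc
    lambda_m: float      # maximal transcription rate, a.u./min
    delta_m: float       # mRNA decay, 1/min
    basal_m: float       # basal transcription, a.u./min
    s1: float            # ARF1 fold-change -> concentration scale
    s2: float            # ARF2 fold-change -> concentration scale
    n_sites: int = 1     # promoter site count
    h: float = 1.0       # activation cooperativity exponent

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("n_sites",):
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.delta_I0 + self.delta_Imax <= 0:
            raise ValueError("total IAA decay capacity must be positive")

    @classmethod
    def defaults(cls, **overrides) -> "NAPParameters":
        global _DEFAULTS
        if _DEFAULTS is None:
            raw = load_nap_defaults()
            _DEFAULTS = {f.name: raw[f.name] for f in fields(cls)}
        return cls(**{**_DEFAULTS, **overrides})

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Equilibria and promoter occupancy

def arf1_iaa_equilibrium(A1_tot, I_tot, K_AI):
    """Exact pairwise ARF1-IAA binding equilibrium.

    Solves ``A1f * If = K_AI * C`` with conservation ``A1f + C = A1_tot``
    and ``If + C = I_tot`` via the stable root of the quadratic; returns
    ``(A1_free, A1I, I_free)``.  Vectorized over numpy inputs.
    """
    A = np.asarray(A1_tot, dtype=float)
    I = np.asarray(I_tot, dtype=float)
    K = np.asarray(K_AI, dtype=float)
    if np.any(A < 0) or np.any(I < 0) or np.any(K < 0):
        raise ValueError("concentrations and K_AI must be >= 0")
    b = A + I + K
    disc = np.sqrt(np.maximum(b * b - 4.0 * A * I, 0.0))
    C = np.where(b > 0, 0.5 * (b - disc), 0.0)
    C = np.minimum(C, np.minimum(A, I))  # guard rounding at K -> 0
    return A - C, C, I - C


@dataclass(frozen=True)
class OccupancyState:
    """Per-site equilibrium occupancy of the shared ARF binding site."""

    p_empty: float | np.ndarray
    p_A1: float | np.ndarray     # free-ARF1-bound (activating)
    p_A1I: float | np.ndarray    # ARF1-IAA-complex-bound (silent)
    p_A2: float | np.ndarray     # ARF2-bound (repressed)
    phi_act: float | np.ndarray  # = p_A1
    activation_weight: float | np.ndarray  # phi_act ** h


def occupancy(A1_free, A1I, A2, params: NAPParameters) -> OccupancyState:
    """Closed-form competitive single-site occupancy.

    Statistical weights: empty 1, free ARF1 ``A1f/K_1``, ARF1-IAA complex
    ``A1I/K_1`` (binds like ARF1, activates nothing), ARF2 ``A2/K_2``.  The
    activating occupancy is the free-ARF1 weight over the partition
    function; with ``n_sites`` independent identical sites the per-site
    marginals are unchanged, and the promoter activation weight is
    ``phi_act ** h``.
    """
    A1f = np.asarray(A1_free, dtype=float)
    w1 = A1f / params.K_1
    wi = np.asarray(A1I, dtype=float) / params.K_1
    w2 = np.asarray(A2, dtype=float) / params.K_2
    Z = 1.0 + w1 + wi + w2
    return OccupancyState(p_empty=1.0 / Z, p_A1=w1 / Z, p_A1I=wi / Z,
                          p_A2=w2 / Z, phi_act=w1 / Z,
                          activation_weight=(w1 / Z) ** params.h)


def occupancy_bruteforce(A1_free: float, A1I: float, A2: float,
                         params: NAPParameters, n_sites: int | None = None):
    """Exhaustive promoter-microstate enumeration (verification oracle).

    Enumerates all ``4**n_sites`` microstates (each site empty, ARF1-bound,
    ARF1-IAA-bound or ARF2-bound) with Boltzmann weights equal to products
    of per-site statistical weights.  Returns ``(per_site, microstates)``:
    the per-site marginal occupancy as an :class:`OccupancyState` and the
    full normalized microstate distribution as a dict mapping state tuples
    to probabilities.  Deliberately independent of :func:`occupancy`.
    """
    n = params.n_sites if n_sites is None else int(n_sites)
    if n > 8:
        raise ValueError("brute-force enumeration is capped at 8 sites")
    w = {"empty": 1.0, "A1": A1_free / params.K_1,
         "A1I": A1I / params.K_1, "A2": A2 / params.K_2}
    states = list(itertools.product(w, repeat=n))
    weights = np.array([math.prod(w[s] for s in st) for st in states])
    Z = weights.sum()
    probs = weights / Z
    micro = dict(zip(states, probs))
    per_site = {k: 0.0 for k in w}
    for st, p in micro.items():
        for s in st:
            per_site[s] += p / n
    phi = per_site["A1"]
    state = OccupancyState(p_empty=per_site["empty"], p_A1=per_site["A1"],
                           p_A1I=per_site["A1I"], p_A2=per_site["A2"],
                           phi_act=phi, activation_weight=phi ** params.h)
    return state, micro


# --------------------------------------------------------------------------
# Simulation

@dataclass(frozen=True)
class SimulationResult:
    """Trajectory of one scenario on a uniform reporting grid."""

    times_h: np.ndarray
    I: np.ndarray                   # free + complexed MpIAA, conc
    m: np.ndarray                   # mRNA, a.u.
    A1_free: np.ndarray
    A1I: np.ndarray
    A2: np.ndarray
    phi_act: np.ndarray
    transcription_rate: np.ndarray  # lambda_m * phi_act**h + basal_m, a.u./min
    scenario: str
    replicate: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times_h, "scenario": self.scenario,
            "replicate": self.replicate, "I": self.I, "m": self.m,
            "phi_act": self.phi_act,
            "transcription_rate": self.transcription_rate,
        })


def iaa_effective_halflife(params: NAPParameters, auxin: float) -> float:
    """Effective MpIAA half-life (minutes) at a fixed auxin level.

    ln(2) / (delta_I0 + delta_Imax * a / (K_aux + a)); infinite when the
    total decay rate is zero.  With the packaged defaults the saturating-
    auxin limit reproduces the measured 6.5-minute half-life.
    """
    if auxin < 0:
        raise ValueError("auxin must be >= 0")
    rate = params.delta_I0 + params.delta_Imax * auxin / (params.K_aux + auxin) \
        if auxin > 0 else params.delta_I0
    if rate == 0:
        return float("inf")
    return float(np.log(2) / rate)


def _as_auxin_fn(auxin):
    if callable(auxin):
        return auxin
    level = float(auxin)
    return lambda t_h: level


def simulate(params: NAPParameters, profile_arf1: ARFProfile,
             profile_arf2: ARFProfile, auxin=10.0,
             t_span: tuple[float, float] | None = None,
             scenario: str = "degradation_on", n_report: int = 201,
             replicate: str = "") -> SimulationResult:
    """Integrate the NAP model driven by measured ARF profiles.

    ``auxin`` is a constant level or a callable of time in hours.  ``t_span``
    (hours) defaults to the intersection of the two profile domains.
    Scenarios ``arf2_degradation_off`` / ``arf1_degradation_off`` freeze the
    corresponding ARF at its t = 0 level.  The state starts at the t = 0
    steady state (dormant gemmae are assumed equilibrated), and the stiff-
    capable LSODA integrator reports on a uniform grid of ``n_report``
    points.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if t_span is None:
        t_span = (max(profile_arf1.domain[0], profile_arf2.domain[0]),
                  min(profile_arf1.domain[1], profile_arf2.domain[1]))
    t0_h, t1_h = map(float, t_span)
    for prof in (profile_arf1, profile_arf2):
        if prof.domain[0] > t0_h or prof.domain[1] < t1_h:
            raise ValueError(f"profile {prof.species}/{prof.replicate} does not cover t_span")
    aux_fn = _as_auxin_fn(auxin)

    def arf_inputs(t_h: float) -> tuple[float, float]:
        a1 = params.s1 * (profile_arf1.at_t0() if scenario == "arf1_degradation_off"
                          else float(profile_arf1(t_h)))
        a2 = params.s2 * (profile_arf2.at_t0() if scenario == "arf2_degradation_off"
                          else float(profile_arf2(t_h)))
        return a1, a2

    def iaa_decay_rate(t_h: float) -> float:
        a = float(aux_fn(t_h))
        return params.delta_I0 + params.delta_Imax * a / (params.K_aux + a)

    def observables(t_h: float, I: float):
        A1_tot, A2 = arf_inputs(t_h)
        A1f, A1I, _ = arf1_iaa_equilibrium(A1_tot, max(I, 0.0), params.K_AI)
        occ = occupancy(A1f, A1I, A2, params)
        rate = params.lambda_m * occ.activation_weight + params.basal_m
        return A1f, A1I, A2, occ.phi_act, rate

    def rhs(t_min: float, y: np.ndarray) -> list[float]:
        t_h = t_min / 60.0
        I, m = y
        *_, rate = observables(t_h, I)
        dI = params.pi_I - iaa_decay_rate(t_h) * I
        dm = rate - params.delta_m * m
        return [dI, dm]

    # t = 0 steady state as initial condition
    I0 = params.pi_I / iaa_decay_rate(t0_h)
    *_, rate0 = observables(t0_h, I0)
    m0 = rate0 / params.delta_m if params.delta_m > 0 else 0.0

    t_eval_min = np.linspace(t0_h * 60.0, t1_h * 60.0, n_report)
    sol = solve_ivp(rhs, (t_eval_min[0], t_eval_min[-1]), [I0, m0],
                    method="LSODA", t_eval=t_eval_min, rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"NAP integration failed: {sol.message}")

    times_h = sol.t / 60.0
    I_tr, m_tr = sol.y
    obs = np.array([observables(t, I) for t, I in zip(times_h, I_tr)])
    A1f_tr, A1I_tr, A2_tr, phi_tr, rate_tr = obs.T
    return SimulationResult(times_h=times_h, I=I_tr, m=m_tr, A1_free=A1f_tr,
                            A1I=A1I_tr, A2=A2_tr, phi_act=phi_tr,
                            transcription_rate=rate_tr, scenario=scenario,
                            replicate=replicate)


def scenario_report(results: list[SimulationResult]) -> pd.DataFrame:
    """Tabulate degradation-on vs degradation-off trajectories per replicate.

    Input results are grouped by replicate; each replicate must carry the
    same reporting grid across its scenarios (mismatched grids are an
    error).  Output columns: replicate, time_h, one transcription-rate
    column per scenario, and ``ratio_on_off`` where both canonical scenarios
    are present.
    """
    if not results:
        return pd.DataFrame(columns=["replicate", "time_h"])
    frames = []
    for rep in sorted({r.replicate for r in results}):
        group = [r for r in results if r.replicate == rep]
        grid = group[0].times_h
        for r in group[1:]:
            if r.times_h.shape != grid.shape or not np.allclose(r.times_h, grid):
                raise ValueError(f"replicate {rep!r}: scenario time grids do not match")
        wide = pd.DataFrame({"replicate": rep, "time_h": grid})
        for r in group:
            wide[r.scenario] = r.transcription_rate
        if "degradation_on" in wide and "arf2_degradation_off" in wide:
            wide["ratio_on_off"] = wide["degradation_on"] / wide["arf2_degradation_off"]
        frames.append(wide)
    return pd.concat(frames, ignore_index=True)
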