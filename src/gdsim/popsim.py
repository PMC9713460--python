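"""Stage-structured stochastic mosquito population model driven by an
inheritance cube.

Daily-time-step model of a single closed *Aedes aegypti* population with
egg, larva, and pupa stages of fixed duration, density-dependent larval
survival, once-mated adult females, and offspring genotypes sampled from a
mother x father x offspring inheritance cube.  Designed for single-release
population-replacement experiments: release drive-homozygous males into a
wild-type population at demographic equilibrium and track genotype
trajectories and the "window of protection" (the period during which most
adult females carry at least one drive allele and hence a linked antiviral
effector).

Model structure (one day, in order):

1. adult mortality — every adult survives with probability ``1 - muAD``;
2. oviposition — each mated female lays ``Poisson(betaK * fertility)`` eggs
   with genotypes drawn from the cube row of her own and her mate's
   genotype (females mated the previous day or earlier lay; a female never
   lays on her emergence day);
3. aquatic aging — each stage applies its daily survival and advances one
   day of age; larvae additionally face the density factor
   ``gamma / (gamma + L_total)``; larvae graduating to pupae are split
   50:50 into females and males and thinned by the sex-specific
   pupation-success multiplier ``xi`` of their genotype;
4. emergence and mating — pupae completing ``tPupa`` days join the adults;
   each new female mates exactly once, with mate genotype drawn in
   proportion to current adult male counts (if no males are present she
   retries the next day);
5. scheduled releases are added to the adult pool.

Calibration closed form
-----------------------
The density-independent daily aquatic survival ``s0`` (identical for eggs,
larvae and pupae) is fixed by requiring the *intrinsic* (low-density)
per-generation growth rate to equal ``popGrowth``:

    0.5 * betaK * (1 - muAD) / muAD * s0**(tEgg+tLarva+tPupa) = popGrowth

At equilibrium the density factor must cancel exactly that surplus growth,
which under this update order gives the closed forms

    f* = popGrowth**(-1/tLarva)          (equilibrium density factor)
    gamma = f* * L* / (1 - f*)           (L* = equilibrium larval total)

so no numerical root solve is required; the contract (a wild-type-only
deterministic run stays within 2% of ``N_eq`` for a year) is verified by
running the model.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cube import GENOTYPES, GENOTYPE_INDEX, H_CARRIER, H_COPIES, R_COPIES, W_COPIES, DriveParams, InheritanceCube

logger = logging.getLogger(__name__)

__all__ = [
    "LifecycleParams",
    "ReleaseEvent",
    "ReleaseSchedule",
    "PopulationState",
    "Calibration",
    "Trajectory",
    "CalibrationError",
    "SimulationError",
    "calibrate_equilibrium",
    "simulate",
    "effector_coverage",
    "summary_metrics",
    "scenario_substitute",
]

NG = len(GENOTYPES)
WW = GENOTYPE_INDEX["WW"]
HH = GENOTYPE_INDEX["HH"]


class CalibrationError(ValueError):
    """Population not sustainable (or otherwise uncalibratable) under the
    given lifecycle parameters."""


class SimulationError(RuntimeError):
    """Internal invariant violation during simulation (bug guard)."""


@dataclass(frozen=True)
class LifecycleParams:
    """Stage-structured demography of the modelled population.

    Defaults are the single-patch study conditions: 5-day egg and 2-day pupa
    stages, a 6-day larval stage, per-female daily egg output
    ``betaK = 75 * 4 / 11`` (average fecundity per gonotrophic cycle times
    four blood meals over an 11-day urban adult lifespan), adult daily
    mortality 0.123, intrinsic per-generation growth 1.175, and a stable
    population of 10,000 adults at a 1:1 sex ratio.
    """

    tEgg: int = 5
    tLarva: int = 6
    tPupa: int = 2
    betaK: float = 75.0 * 4.0 / 11.0
    muAD: float = 0.123
    popGrowth: float = 1.175
    N_eq: float = 10_000.0
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if min(self.tEgg, self.tLarva, self.tPupa) < 1:
            raise CalibrationError("stage durations must be at least 1 day")
        if not 0.0 < self.muAD <= 1.0:
            raise CalibrationError("muAD must lie in (0, 1]")
        if self.betaK <= 0:
            raise CalibrationError("betaK must be positive")
        if self.N_eq <= 0:
            raise CalibrationError("N_eq must be positive")
        if not 0.0 < self.sex_ratio < 1.0:
            raise CalibrationError("sex_ratio must lie in (0, 1)")


@dataclass(frozen=True)
class ReleaseEvent:
    day: int
    sex: str  # "M" or "F"
    genotype: str
    count: int

    def __post_init__(self) -> None:
        if self.day < 1 or self.count < 0:
            raise ValueError("release day must be >= 1 and count >= 0")
        if self.sex not in ("M", "F"):
            raise ValueError("release sex must be 'M' or 'F'")
        if self.genotype not in GENOTYPE_INDEX:
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass(frozen=True)
class ReleaseSchedule:
    """Release events; the study scenario is 2,000 HH males on day 25."""

    events: tuple[ReleaseEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))

    @classmethod
    def single_male_release(cls, day: int = 25, count: int = 2000,
                            genotype: str = "HH") -> "ReleaseSchedule":
        return cls((ReleaseEvent(day=day, sex="M", genotype=genotype, count=count),))

    @property
    def first_day(self) -> int | None:
        return min((e.day for e in self.events), default=None)


@dataclass
class PopulationState:
    """Daily simulation state (counts by age and genotype).

    ``pupae`` carries a sex axis (0 = female, 1 = male): sex is assigned at
    the larva-to-pupa transition so the sex-specific pupation modifier can
    act there.  ``mated`` is indexed [female genotype, mate genotype].
    """

    eggs: np.ndarray      # (tEgg, NG)
    larvae: np.ndarray    # (tLarva, NG)
    pupae: np.ndarray     # (tPupa, 2, NG)
    males: np.ndarray     # (NG,)
    mated: np.ndarray     # (NG, NG)
    unmated: np.ndarray   # (NG,)

    def copy(self) -> "PopulationState":
        return PopulationState(*(a.copy() for a in
                                 (self.eggs, self.larvae, self.pupae,
                                  self.males, self.mated, self.unmated)))

    def rounded(self) -> "PopulationState":
        """Integer-valued copy (seed state for stochastic runs)."""
        return PopulationState(*(np.rint(a).astype(np.int64) for a in
                                 (self.eggs, self.larvae, self.pupae,
                                  self.males, self.mated, self.unmated)))

    @property
    def females(self) -> np.ndarray:
        return self.mated.sum(axis=1) + self.unmated

    @property
    def adults_total(self) -> float:
        return float(self.males.sum() + self.mated.sum() + self.unmated.sum())

    def h_allele_total(self) -> float:
        """Drive-allele copies across every life stage.

        Counts adults, all aquatic stages, and the stored sperm of mated
        females (a female mated to a drive-carrying male can still produce
        drive offspring after the last living carrier dies, so elimination
        requires the mate axis to be drive-free too).
        """
        aquatic = self.eggs.sum(axis=0) + self.larvae.sum(axis=0) + self.pupae.sum(axis=(0, 1))
        adults = self.males + self.females
        sperm = self.mated.sum(axis=0)  # mate-genotype marginal
        return float(((aquatic + adults + sperm) * H_COPIES).sum())


@dataclass(frozen=True)
class Calibration:
    """Density constant and baseline survivals for a lifecycle at equilibrium."""

    lifecycle: LifecycleParams
    s0: float          # density-independent daily aquatic survival
    f_star: float      # equilibrium larval density factor
    gamma: float       # density constant: factor = gamma / (gamma + L_total)
    larvae_eq: float   # equilibrium larval total L*
    eggs_per_day: float
    state0: PopulationState  # wild-type-only seeded equilibrium (real-valued)


def calibrate_equilibrium(lc: LifecycleParams) -> Calibration:
    """Solve for the density constant and seed a wild-type equilibrium state.

    Raises :class:`CalibrationError` when the parameters cannot sustain a
    population (e.g. ``muAD`` -> 1, or intrinsic growth at or below 1).
    """
    if lc.muAD >= 1.0:
        raise CalibrationError(
            "muAD = 1: no adult survives to oviposit, population not sustainable"
        )
    if lc.popGrowth <= 1.0:
        raise CalibrationError(
            f"popGrowth = {lc.popGrowth} <= 1: no density-independent surplus growth; "
            "equilibrium would require a density *boost*"
        )
    t_aqua = lc.tEgg + lc.tLarva + lc.tPupa
    target = lc.popGrowth * lc.muAD / (0.5 * lc.betaK * (1.0 - lc.muAD))
    if target >= 1.0:
        raise CalibrationError(
            "required daily aquatic survival >= 1: fecundity too low (or adult "
            "mortality too high) to sustain the population"
        )
    s0 = target ** (1.0 / t_aqua)
    f_star = lc.popGrowth ** (-1.0 / lc.tLarva)

    n_f = lc.N_eq * lc.sex_ratio
    eggs_per_day = lc.betaK * n_f * (1.0 - lc.muAD)

    eggs = np.zeros((lc.tEgg, NG))
    larvae = np.zeros((lc.tLarva, NG))
    pupae = np.zeros((lc.tPupa, 2, NG))
    eggs[:, WW] = eggs_per_day * s0 ** np.arange(lc.tEgg)
    larva_in = eggs_per_day * s0**lc.tEgg
    larvae[:, WW] = larva_in * (s0 * f_star) ** np.arange(lc.tLarva)
    pupa_in = larva_in * (s0 * f_star) ** lc.tLarva
    pupae[:, 0, WW] = lc.sex_ratio * pupa_in * s0 ** np.arange(lc.tPupa)
    pupae[:, 1, WW] = (1.0 - lc.sex_ratio) * pupa_in * s0 ** np.arange(lc.tPupa)
    emerge = pupa_in * s0**lc.tPupa

    males = np.zeros(NG)
    mated = np.zeros((NG, NG))
    males[WW] = (1.0 - lc.sex_ratio) * emerge / lc.muAD
    mated[WW, WW] = lc.sex_ratio * emerge / lc.muAD

    larvae_eq = float(larvae.sum())
    gamma = f_star * larvae_eq / (1.0 - f_star)
    state0 = PopulationState(eggs, larvae, pupae, males, mated, np.zeros(NG))
    return Calibration(
        lifecycle=lc,
        s0=s0,
        f_star=f_star,
        gamma=gamma,
        larvae_eq=larvae_eq,
        eggs_per_day=eggs_per_day,
        state0=state0,
    )


@dataclass
class Trajectory:
    """Daily adult counts by sex and genotype for one realization."""

    rep_id: int
    seed: int | None
    release_day: int | None
    days: np.ndarray              # (D,), contiguous from 1
    females: np.ndarray           # (D, NG)
    males: np.ndarray             # (D, NG)
    h_total: np.ndarray           # (D,) drive-allele copies across all stages
    aquatic_total: np.ndarray     # (D,)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format daily adult counts (rep, day, sex, genotype, count)."""
        frames = []
        for sex, counts in (("F", self.females), ("M", self.males)):
            df = pd.DataFrame(counts, columns=list(GENOTYPES))
            df.insert(0, "day", self.days)
            df = df.melt(id_vars="day", var_name="genotype", value_name="count")
            df.insert(0, "sex", sex)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "rep", self.rep_id)
        return out.sort_values(["rep", "day", "sex", "genotype"], ignore_index=True)


def _xi_arrays(params: DriveParams) -> tuple[np.ndarray, np.ndarray]:
    xi_f = np.array([params.pupation_multiplier(g, "F") for g in GENOTYPES])
    xi_m = np.array([params.pupation_multiplier(g, "M") for g in GENOTYPES])
    return xi_f, xi_m


def _fertility_array(params: DriveParams) -> np.ndarray:
    return np.array([params.fertility_multiplier(g) for g in GENOTYPES])


def _check_nonneg(*arrays: np.ndarray) -> None:
    for a in arrays:
        if (a < 0).any():
            raise SimulationError("negative count encountered; internal invariant violated")


def _run_one(
    cube_probs: np.ndarray,
    lc: LifecycleParams,
    cal: Calibration,
    releases: dict[int, list[ReleaseEvent]],
    params: DriveParams,
    days: int,
    rng: np.random.Generator | None,
    rep_id: int,
    seed_label: int | None,
    release_day: int | None,
    initial: PopulationState,
) -> Trajectory:
    stochastic = rng is not None
    state = initial.copy()
    xi_f, xi_m = _xi_arrays(params)
    fert = _fertility_array(params)
    s0, gamma = cal.s0, cal.gamma
    p_ad = 1.0 - lc.muAD

    out_f = np.zeros((days, NG))
    out_m = np.zeros((days, NG))
    out_h = np.zeros(days)
    out_aq = np.zeros(days)

    for day in range(1, days + 1):
        # 1. adult mortality
        if stochastic:
            state.males = rng.binomial(state.males, p_ad)
            state.mated = rng.binomial(state.mated, p_ad)
            state.unmated = rng.binomial(state.unmated, p_ad)
        else:
            state.males = state.males * p_ad
            state.mated = state.mated * p_ad
            state.unmated = state.unmated * p_ad

        # 2. oviposition by mated females (mated before today)
        lam = state.mated * (lc.betaK * fert)[:, None]
        if stochastic:
            n_eggs = rng.poisson(lam)
            flat = n_eggs.reshape(-1)
            new_eggs = rng.multinomial(flat, cube_probs.reshape(-1, NG)).sum(axis=0)
        else:
            new_eggs = np.einsum("fm,fmk->k", lam, cube_probs)

        # 3. aquatic aging (all transitions computed from the start-of-step state)
        l_total = state.larvae.sum()
        f_dens = gamma / (gamma + l_total)
        p_larva = s0 * f_dens
        if stochastic:
            emerging = rng.binomial(state.pupae[-1], s0)                 # (2, NG)
            pupae_new = rng.binomial(state.pupae[:-1], s0)
            grad = rng.binomial(state.larvae[-1], p_larva)
            grad_f = rng.binomial(grad, lc.sex_ratio)
            grad_m = grad - grad_f
            grad_f = rng.binomial(grad_f, np.minimum(xi_f, 1.0))
            grad_m = rng.binomial(grad_m, np.minimum(xi_m, 1.0))
            larvae_new = rng.binomial(state.larvae[:-1], p_larva)
            hatch = rng.binomial(state.eggs[-1], s0)
            eggs_new = rng.binomial(state.eggs[:-1], s0)
        else:
            emerging = state.pupae[-1] * s0
            pupae_new = state.pupae[:-1] * s0
            grad = state.larvae[-1] * p_larva
            grad_f = grad * lc.sex_ratio * xi_f
            grad_m = grad * (1.0 - lc.sex_ratio) * xi_m
            larvae_new = state.larvae[:-1] * p_larva
            hatch = state.eggs[-1] * s0
            eggs_new = state.eggs[:-1] * s0
        state.pupae = np.concatenate(
            [np.stack([grad_f, grad_m])[None], pupae_new], axis=0
        )
        state.larvae = np.concatenate([hatch[None], larvae_new], axis=0)
        state.eggs = np.concatenate([new_eggs[None], eggs_new], axis=0)

        # 4. emergence and mating
        state.males = state.males + emerging[1]
        new_females = emerging[0] + state.unmated
        m_total = state.males.sum()
        if m_total > 0:
            probs = state.males / m_total
            if stochastic:
                new_females = np.asarray(new_females, dtype=np.int64)
                matings = rng.multinomial(new_females, probs)
            else:
                matings = np.outer(new_females, probs)
            state.mated = state.mated + matings
            state.unmated = np.zeros_like(state.unmated)
        else:
            state.unmated = new_females

        # 5. releases
        for ev in releases.get(day, ()):  # released adults join the pool today
            gi = GENOTYPE_INDEX[ev.genotype]
            if ev.sex == "M":
                state.males = state.males.copy()
                state.males[gi] += ev.count
            else:
                state.unmated = state.unmated.copy()
                state.unmated[gi] += ev.count

        _check_nonneg(state.eggs, state.larvae, state.pupae,
                      state.males, state.mated, state.unmated)

        # 6. record
        out_f[day - 1] = state.females
        out_m[day - 1] = state.males
        out_h[day - 1] = state.h_allele_total()
        out_aq[day - 1] = state.eggs.sum() + state.larvae.sum() + state.pupae.sum()

    return Trajectory(
        rep_id=rep_id,
        seed=seed_label,
        release_day=release_day,
        days=np.arange(1, days + 1),
        females=out_f,
        males=out_m,
        h_total=out_h,
        aquatic_total=out_aq,
    )


def simulate(
    cube: InheritanceCube,
    lc: LifecycleParams,
    rel: ReleaseSchedule,
    params: DriveParams,
    days: int,
    reps: int = 1,
    seed: int = 0,
    mode: str = "stochastic",
    calibration: Calibration | None = None,
    initial_state: PopulationState | None = None,
) -> list[Trajectory]:
    """Run the daily population model.

    ``mode="stochastic"`` draws integer counts (binomial survival, Poisson
    egg clutches, multinomial genotypes and matings); ``"deterministic"``
    propagates expectations with real-valued state.  Replicate ``i`` uses an
    independent stream derived from ``(seed, i)``, so runs are reproducible
    and replicates independent.  The lifecycle is calibrated internally
    unless a :class:`Calibration` is supplied.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ValueError(f"mode must be 'stochastic' or 'deterministic', got {mode!r}")
    if days < 1:
        raise ValueError("days must be >= 1")
    cal = calibration if calibration is not None else calibrate_equilibrium(lc)
    releases: dict[int, list[ReleaseEvent]] = {}
    for ev in rel.events:
        releases.setdefault(ev.day, []).append(ev)
    release_day = rel.first_day

    base = cal.state0 if initial_state is None else initial_state
    trajs = []
    n_reps = reps if mode == "stochastic" else 1
    for rep in range(n_reps):
        if mode == "stochastic":
            rng = np.random.default_rng([seed, rep])
            init = base.rounded()
        else:
            rng = None
            init = base.copy()
        trajs.append(
            _run_one(cube.probs, lc, cal, releases, params, days, rng,
                     rep_id=rep, seed_label=seed, release_day=release_day,
                     initial=init)
        )
    return trajs


def effector_coverage(traj: Trajectory) -> np.ndarray:
    """Daily fraction of adult females carrying >= 1 drive allele.

    The proxy for a drive-linked antiviral effector: a female carrying any
    drive-bearing genotype (WH, HH, HR) would carry the linked effector.
    Defined as 0 on days with no females.
    """
    carriers = traj.females[:, H_CARRIER].sum(axis=1)
    total = traj.females.sum(axis=1)
    return np.divide(carriers, total, out=np.zeros_like(total), where=total > 0)


def _first_day(mask: np.ndarray, days: np.ndarray) -> int | None:
    idx = np.flatnonzero(mask)
    return int(days[idx[0]]) if idx.size else None


def _pr(day: int | None, release_day: int | None) -> int | None:
    if day is None:
        return None
    return day - release_day if release_day is not None else day


def summary_metrics(trajs: Sequence[Trajectory]) -> dict:
    """Window-of-protection and elimination summaries per replicate.

    First-passage days are reported post-release (simulation day minus
    release day); events that never occur are reported as ``None`` (absent),
    not 0.  ``day_WW_eliminated`` uses adult counts; ``day_H_eliminated``
    requires the drive allele to be absent from every life stage.
    Across-replicate medians and quartiles ignore absent values
    (``n_absent`` reports how many replicates lacked the event).
    """
    if not trajs:
        raise ValueError("no trajectories given")
    per_rep = []
    for t in trajs:
        cov = effector_coverage(t)
        ww_adults = t.females[:, WW] + t.males[:, WW]
        peak_idx = int(np.argmax(cov))
        after_peak = np.zeros_like(cov, dtype=bool)
        after_peak[peak_idx:] = cov[peak_idx:] < 0.5
        # elimination means loss *after* introduction, not pre-release absence
        h_present = np.flatnonzero(t.h_total > 0)
        h_gone = np.zeros_like(cov, dtype=bool)
        if h_present.size:
            h_gone[h_present[0]:] = t.h_total[h_present[0]:] == 0
        adults = t.females.sum(axis=1) + t.males.sum(axis=1)
        alleles = 2.0 * adults[-1]
        final = {
            a: float((t.females[-1] + t.males[-1]) @ copies / alleles) if alleles else 0.0
            for a, copies in (("W", W_COPIES), ("H", H_COPIES), ("R", R_COPIES))
        }
        per_rep.append(
            {
                "rep_id": t.rep_id,
                "day_WW_eliminated": _pr(_first_day(ww_adults == 0, t.days), t.release_day),
                "peak_coverage": float(cov[peak_idx]),
                "day_of_peak": _pr(int(t.days[peak_idx]), t.release_day),
                "day_coverage_below_half": (
                    _pr(_first_day(after_peak, t.days), t.release_day)
                    if cov[peak_idx] > 0 else None
                ),
                "day_H_eliminated": _pr(_first_day(h_gone, t.days), t.release_day),
                "final_allele_freq": final,
            }
        )
    aggregate = {}
    for key in ("day_WW_eliminated", "peak_coverage", "day_of_peak",
                "day_coverage_below_half", "day_H_eliminated"):
        vals = [r[key] for r in per_rep if r[key] is not None]
        aggregate[key] = {
            "median": float(np.median(vals)) if vals else None,
            "q1": float(np.percentile(vals, 25)) if vals else None,
            "q3": float(np.percentile(vals, 75)) if vals else None,
            "n_absent": len(per_rep) - len(vals),
        }
    return {"per_rep": per_rep, "aggregate": aggregate}


_DRIVE_FIELDS = frozenset(DriveParams.__dataclass_fields__)
_LIFECYCLE_FIELDS = frozenset(LifecycleParams.__dataclass_fields__)


def scenario_substitute(base: dict, overrides: dict) -> dict:
    """Deep-copied scenario config with selected parameters replaced.

    ``base`` maps ``"drive"`` to a :class:`DriveParams` and ``"lifecycle"``
    to a :class:`LifecycleParams` (extra keys, e.g. a release schedule, are
    deep-copied through).  Override keys are routed to the dataclass that
    owns the field; unknown keys raise.  Each substitution is logged.
    """
    out = copy.deepcopy(base)
    drive_over: dict[str, float] = {}
    lc_over: dict[str, float] = {}
    for key, value in overrides.items():
        if key in _DRIVE_FIELDS:
            drive_over[key] = value
        elif key in _LIFECYCLE_FIELDS:
            lc_over[key] = value
        else:
            raise KeyError(f"unknown scenario parameter {key!r}")
        logger.info("scenario override: %s = %r", key, value)
    if drive_over:
        out["drive"] = replace(out["drive"], **drive_over)
    if lc_over:
        out["lifecycle"] = replace(out["lifecycle"], **lc_over)
    return out
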