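"""Overlapping-generation, stage-structured release model.

Daily time steps track egg, larval, pupal, and adult cohorts per genotype.
Adults die geometrically (daily survival 1 - 1/lifespan), females lay
Poisson egg clutches sired by males drawn at the current adult-male
genotype frequencies, larvae suffer Beverton-Holt density-dependent daily
mortality calibrated so that an unperturbed wildtype population sits at the
configured adult equilibrium, and pupae eclose with a fair binomial sex
split.  Scheduled male releases (a fraction of the current adult census)
are added on release days.

The protection metrics follow the release-program design questions: the
first day the female drive-carrier frequency exceeds 95%, and the
window of protection (WOP) — the number of days that frequency stays above
95% between the first release and the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import (
    FitnessModel,
    InheritanceCube,
    carries_allele,
    cas9_homozygote,
    drive_homozygote,
    genotype_to_string,
    wildtype_genotype,
)

__all__ = [
    "LifecycleParams",
    "ReleaseSchedule",
    "ProtectionMetrics",
    "weekly_releases",
    "simulate_field",
    "time_to_threshold",
    "window_of_protection",
    "protection_metrics",
]

FOUR_YEARS = 4 * 365


@dataclass(frozen=True)
class LifecycleParams:
    """Insect lifecycle and density-dependence settings.

    Stage durations are in days; ``adult_lifespan`` is the expected adult
    lifespan in days (geometric daily mortality 1/lifespan);
    ``eggs_per_female_per_day`` is the wildtype daily oviposition rate;
    ``equilibrium_adults`` is the adult census the density dependence is
    calibrated to hold.
    """

    egg_days: int = 2
    larva_days: int = 5
    pupa_days: int = 1
    adult_lifespan: float = 11.0
    eggs_per_female_per_day: float = 20.0
    equilibrium_adults: int = 10_000

    def __post_init__(self):
        for name in ("egg_days", "larva_days", "pupa_days"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer (got {v!r})")
        if self.adult_lifespan <= 1:
            raise ValueError("adult_lifespan must exceed 1 day")
        if self.eggs_per_female_per_day <= 0 or self.equilibrium_adults <= 0:
            raise ValueError("rates and equilibrium size must be positive")

    @property
    def daily_adult_survival(self) -> float:
        return 1.0 - 1.0 / self.adult_lifespan

    def calibrate(self) -> tuple[float, float]:
        """(alpha, equilibrium larval total) of the Beverton-Holt daily
        larval survival s(L) = 1 / (1 + alpha * L).

        At equilibrium the daily adult recruitment must replace adult
        deaths N/lifespan, which fixes the stage-survival product and hence
        alpha in closed form.
        """
        N = float(self.equilibrium_adults)
        eggs_per_day = self.eggs_per_female_per_day * N / 2.0
        needed = (N / self.adult_lifespan) / eggs_per_day  # total larval survival
        s_daily = needed ** (1.0 / self.larva_days)
        if s_daily >= 1.0:
            raise ValueError(
                "egg production too low to sustain the requested equilibrium"
            )
        L_star = eggs_per_day * sum(s_daily**k for k in range(self.larva_days))
        alpha = (1.0 / s_daily - 1.0) / L_star
        return alpha, L_star


@dataclass(frozen=True)
class ReleaseSchedule:
    """Male release program.

    ``days`` are simulation days on which releases occur; each release adds
    ``release_fraction`` of the current total adult census as males of the
    scheduled genotype.  Split designs follow the two-stage program: the
    first release is drive+Cas9 double homozygous, later releases are
    Cas9-only homozygous.
    """

    days: tuple = ()
    release_fraction: float = 0.20
    first_genotype: tuple | None = None
    subsequent_genotype: tuple | None = None

    def __post_init__(self):
        if self.days and not (0.0 < self.release_fraction <= 1.0):
            raise ValueError("release_fraction must be in (0, 1]")
        if any(d < 0 for d in self.days):
            raise ValueError("release days must be non-negative")

    def genotype_for(self, k: int):
        if k == 0 or self.subsequent_genotype is None:
            return self.first_genotype
        return self.subsequent_genotype


def weekly_releases(
    architecture: str,
    loci_config: str,
    n_releases: int = 13,
    release_fraction: float = 0.20,
    start_day: int = 1,
) -> ReleaseSchedule:
    """Weekly male releases; split designs release Cas9-only males after
    the first drive+Cas9 release."""
    days = tuple(start_day + 7 * k for k in range(n_releases))
    first = drive_homozygote(architecture, loci_config)
    subsequent = (
        cas9_homozygote(architecture, loci_config) if loci_config == "two_locus" else first
    )
    return ReleaseSchedule(days, release_fraction, first, subsequent)


@dataclass
class ProtectionMetrics:
    reached_95: bool
    first_day: int | None
    wop_days: int

    def __post_init__(self):
        if self.wop_days < 0:
            raise ValueError("window of protection cannot be negative")
        if self.wop_days > 0 and not self.reached_95:
            raise ValueError("positive WOP requires the threshold to be reached")


def _female_carrier_freq(adults_f: np.ndarray, mask: np.ndarray) -> float:
    tot = adults_f.sum()
    return float(adults_f[mask].sum() / tot) if tot > 0 else 0.0


def simulate_field(
    cube: InheritanceCube,
    fitness: FitnessModel,
    lifecycle: LifecycleParams,
    schedule: ReleaseSchedule,
    horizon_days: int,
    seed: int | None = None,
    full_table: bool = False,
):
    """Daily stochastic simulation of a release program.

    Returns a DataFrame with one row per day: adult counts by sex, female
    drive-carrier and Cas9-carrier frequencies, and the larval census.  With
    ``full_table=True`` a long-format (day, stage, genotype, sex, count)
    table is returned alongside.
    """
    if schedule.days and horizon_days < max(schedule.days):
        raise ValueError("horizon shorter than the release schedule")
    rng = np.random.default_rng(seed)
    genotypes = cube.genotypes
    n = len(genotypes)
    idx = {g: i for i, g in enumerate(genotypes)}
    T = cube.as_tensor()
    # (mother, father x offspring) laying kernel, viability applied at the egg
    viable = np.array([fitness.viable(g) for g in genotypes], dtype=float)
    fec = np.array([fitness.fecundity(g) for g in genotypes])
    drive_mask = np.array(
        [carries_allele(g, "H") for g in genotypes], dtype=bool
    )
    cas9_sym = "C" if cube.loci_config == "two_locus" else "H"
    cas9_mask = np.array([carries_allele(g, cas9_sym) for g in genotypes], dtype=bool)

    alpha, _ = lifecycle.calibrate()
    p_adult = lifecycle.daily_adult_survival
    beta = lifecycle.eggs_per_female_per_day

    wt = idx[wildtype_genotype(cube.architecture, cube.loci_config)]
    # wildtype equilibrium initial condition
    N0 = lifecycle.equilibrium_adults
    eggs_day = beta * N0 / 2.0
    s_daily = ((N0 / lifecycle.adult_lifespan) / eggs_day) ** (1.0 / lifecycle.larva_days)
    eggs = np.zeros((lifecycle.egg_days, n))
    eggs[:, wt] = eggs_day
    larvae = np.zeros((lifecycle.larva_days, n))
    for a in range(lifecycle.larva_days):
        larvae[a, wt] = eggs_day * s_daily**a
    pupae = np.zeros((lifecycle.pupa_days, n))
    pupae[:, wt] = eggs_day * s_daily**lifecycle.larva_days
    adults_f = np.zeros(n)
    adults_m = np.zeros(n)
    adults_f[wt] = adults_m[wt] = N0 / 2.0
    # integerize
    eggs = np.floor(eggs)
    larvae = np.floor(larvae)
    pupae = np.floor(pupae)
    adults_f = np.floor(adults_f)
    adults_m = np.floor(adults_m)

    release_days = {d: k for k, d in enumerate(sorted(schedule.days))}
    records = []
    long_records = []

    for day in range(horizon_days + 1):
        # scheduled male releases (fraction of current total adult census)
        if day in release_days:
            k = release_days[day]
            g_rel = schedule.genotype_for(k)
            size = int(round(schedule.release_fraction * (adults_f.sum() + adults_m.sum())))
            adults_m[idx[g_rel]] += size

        records.append(
            (
                day,
                float(adults_f.sum()),
                float(adults_m.sum()),
                _female_carrier_freq(adults_f, drive_mask),
                _female_carrier_freq(adults_f, cas9_mask),
                float(larvae.sum()),
            )
        )
        if full_table:
            for stage, arr in (("egg", eggs), ("larva", larvae), ("pupa", pupae)):
                tot = arr.sum(axis=0)
                for g in np.nonzero(tot)[0]:
                    long_records.append((day, stage, genotype_to_string(genotypes[g]), "U", int(tot[g])))
            for sex, arr in (("F", adults_f), ("M", adults_m)):
                for g in np.nonzero(arr)[0]:
                    long_records.append((day, "adult", genotype_to_string(genotypes[g]), sex, int(arr[g])))
        if day == horizon_days:
            break

        # egg laying by today's adults
        new_eggs = np.zeros(n)
        tot_m = adults_m.sum()
        if tot_m > 0 and adults_f.sum() > 0:
            male_freq = adults_m / tot_m
            kernel = np.einsum("j,ijg->ig", male_freq, T) * viable[None, :]
            for i in np.nonzero(adults_f)[0]:
                lam = adults_f[i] * beta * fec[i]
                if lam <= 0:
                    continue
                clutch = rng.poisson(lam)
                if clutch:
                    pk = kernel[i]
                    psum = pk.sum()
                    if psum > 0:
                        # unviable embryos die before the egg stage
                        viable_clutch = rng.binomial(clutch, min(psum, 1.0))
                        if viable_clutch:
                            new_eggs += rng.multinomial(viable_clutch, pk / psum)

        # stage transitions (oldest first)
        eclosing = pupae[-1].astype(np.int64)
        pupae[1:] = pupae[:-1]
        s_L = 1.0 / (1.0 + alpha * larvae.sum())
        surv = rng.binomial(larvae.astype(np.int64), s_L)
        pupae[0] = surv[-1]
        larvae[1:] = surv[:-1]
        larvae[0] = eggs[-1]
        eggs[1:] = eggs[:-1]
        eggs[0] = new_eggs

        sons = rng.binomial(eclosing, 0.5)
        adults_f = rng.binomial(adults_f.astype(np.int64), p_adult) + (eclosing - sons)
        adults_m = rng.binomial(adults_m.astype(np.int64), p_adult) + sons

    daily = pd.DataFrame(
        records,
        columns=[
            "day",
            "adult_females",
            "adult_males",
            "female_drive_carrier_freq",
            "female_cas9_carrier_freq",
            "larvae",
        ],
    )
    if full_table:
        long_df = pd.DataFrame(
            long_records, columns=["day", "stage", "genotype", "sex", "count"]
        )
        return daily, long_df
    return daily


def time_to_threshold(daily: pd.DataFrame, threshold: float = 0.95,
                      column: str = "female_drive_carrier_freq"):
    """First day the frequency exceeds the threshold, or None."""
    above = daily.loc[daily[column] > threshold, "day"]
    return int(above.iloc[0]) if len(above) else None


def window_of_protection(
    daily: pd.DataFrame,
    threshold: float = 0.95,
    horizon_days: int = FOUR_YEARS,
    start_day: int = 0,
    column: str = "female_drive_carrier_freq",
) -> int:
    """Days the female drive-carrier frequency stays above the threshold,
    counted from ``start_day`` (first release) up to the horizon."""
    window = daily[(daily["day"] >= start_day) & (daily["day"] <= start_day + horizon_days)]
    return int((window[column] > threshold).sum())


def protection_metrics(
    daily: pd.DataFrame,
    schedule: ReleaseSchedule,
    threshold: float = 0.95,
    horizon_days: int = FOUR_YEARS,
) -> ProtectionMetrics:
    start = min(schedule.days) if schedule.days else 0
    first = time_to_threshold(daily, threshold)
    wop = window_of_protection(daily, threshold, horizon_days, start)
    return ProtectionMetrics(reached_95=first is not None, first_day=first, wop_days=wop)
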