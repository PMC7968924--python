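"""Discrete-generation stochastic cage simulator.

Each generation follows the laboratory cage protocol: adult females obtain
a mate by multinomial choice over adult-male genotype frequencies, mated
females lay Poisson-distributed egg clutches scaled by their genotype's
fecundity multiplier, offspring genotypes are multinomial draws from the
inheritance-cube row of the parental pair, unviable zygotes are removed,
sexes are assigned by a fair binomial, and the next adult generation is a
multivariate-hypergeometric sample of census/2 individuals per sex from the
surviving offspring (all survivors carry over if a sex undershoots).

Generation labels follow the cage convention: seeded adults are P
(index -1) and the first scored offspring cohort is G0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import (
    FitnessModel,
    InheritanceCube,
    canonicalize,
    carries_allele,
    genotype_to_string,
)

__all__ = [
    "CageState",
    "SeedingSpec",
    "CageTrajectory",
    "paper_cage_seeding",
    "comparative_seeding",
    "step_generation",
    "simulate",
    "simulate_replicates",
    "carrier_frequency",
    "allele_frequency",
    "drive_efficacy",
    "efficacy_sweep",
    "expected_generation",
]

DEFAULT_CENSUS = 400
DEFAULT_MEAN_EGGS = 50.0


@dataclass
class CageState:
    """Adult counts per genotype and sex at one discrete generation."""

    genotypes: tuple
    females: np.ndarray  # integer counts aligned with genotypes
    males: np.ndarray
    generation: int  # -1 = parental (P), 0 = G0, ...

    @property
    def total(self) -> int:
        return int(self.females.sum() + self.males.sum())

    def counts(self) -> dict:
        out = {}
        for g, nf, nm in zip(self.genotypes, self.females, self.males):
            if nf:
                out[(g, "F")] = int(nf)
            if nm:
                out[(g, "M")] = int(nm)
        return out


@dataclass(frozen=True)
class SeedingSpec:
    """Parental-generation composition: (genotype, sex, count) entries."""

    entries: tuple

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty seeding")
        sexes = {s for _, s, _ in self.entries}
        if not {"F", "M"} <= sexes:
            raise ValueError("seeding must include both sexes")
        if any(n <= 0 for _, _, n in self.entries):
            raise ValueError("seeding counts must be positive")

    def to_state(self, genotypes: tuple) -> CageState:
        idx = {g: i for i, g in enumerate(genotypes)}
        f = np.zeros(len(genotypes), dtype=np.int64)
        m = np.zeros(len(genotypes), dtype=np.int64)
        for g, sex, n in self.entries:
            g = canonicalize(g)
            if g not in idx:
                raise ValueError(f"seeding genotype {genotype_to_string(g)} not in cube")
            (f if sex == "F" else m)[idx[g]] += n
        return CageState(genotypes, f, m, generation=-1)


def paper_cage_seeding(architecture: str = "homer", loci_config: str = "one_locus"):
    """Cage-trial seeding: 50 drive-homozygous males + 50 wildtype males
    + 100 wildtype virgin females (25% drive allele frequency)."""
    from .genetics import drive_homozygote, wildtype_genotype

    dd = drive_homozygote(architecture, loci_config)
    wt = wildtype_genotype(architecture, loci_config)
    return SeedingSpec(((dd, "M", 50), (wt, "M", 50), (wt, "F", 100)))


def comparative_seeding(architecture: str, loci_config: str, census: int = DEFAULT_CENSUS):
    """Comparative-model seeding: 25% drive-homozygous males, 25% wildtype
    males, 50% wildtype females of a ``census``-adult cage."""
    from .genetics import drive_homozygote, wildtype_genotype

    q = census // 4
    dd = drive_homozygote(architecture, loci_config)
    wt = wildtype_genotype(architecture, loci_config)
    return SeedingSpec(((dd, "M", q), (wt, "M", q), (wt, "F", 2 * q)))


@dataclass
class CageTrajectory:
    """Ordered cage states plus an extinction flag."""

    states: list
    extinct: bool = False
    architecture: str = ""
    loci_config: str = ""

    def state_at(self, generation: int) -> CageState:
        """State at a generation index, or the terminal state if the
        trajectory ended earlier (extinction)."""
        for s in self.states:
            if s.generation == generation:
                return s
        return self.states[-1]

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        recs = []
        for s in self.states:
            for (g, sex), n in s.counts().items():
                recs.append((replicate, s.generation, genotype_to_string(g), sex, n))
        return pd.DataFrame(recs, columns=["replicate", "generation", "genotype", "sex", "count"])

    def summary_frame(self, replicate: int = 0) -> pd.DataFrame:
        recs = []
        for s in self.states:
            recs.append(
                (
                    replicate,
                    s.generation,
                    carrier_frequency(s, "H"),
                    carrier_frequency(s, "C"),
                    allele_frequency(s, "H"),
                )
            )
        return pd.DataFrame(
            recs,
            columns=[
                "replicate",
                "generation",
                "carrier_freq_drive",
                "carrier_freq_cas9",
                "allele_freq_drive",
            ],
        )


def _viability_mask(genotypes, fitness: FitnessModel) -> np.ndarray:
    return np.array([fitness.viable(g) for g in genotypes], dtype=bool)


def _fecundity_vector(genotypes, fitness: FitnessModel) -> np.ndarray:
    return np.array([fitness.fecundity(g) for g in genotypes])


def step_generation(
    state: CageState,
    cube: InheritanceCube,
    fitness: FitnessModel,
    census: int = DEFAULT_CENSUS,
    rng: np.random.Generator | None = None,
    mean_eggs: float = DEFAULT_MEAN_EGGS,
    cube_tensor: np.ndarray | None = None,
) -> CageState | None:
    """Advance one discrete generation; returns None on extinction."""
    rng = np.random.default_rng() if rng is None else rng
    genotypes = state.genotypes
    n = len(genotypes)
    if state.females.sum() == 0 or state.males.sum() == 0:
        return None
    T = cube.as_tensor() if cube_tensor is None else cube_tensor

    male_freq = state.males / state.males.sum()
    fec = _fecundity_vector(genotypes, fitness)
    offspring = np.zeros(n, dtype=np.int64)
    for i in np.nonzero(state.females)[0]:
        mates = rng.multinomial(state.females[i], male_freq)
        for j in np.nonzero(mates)[0]:
            eggs = rng.poisson(mates[j] * mean_eggs * fec[i])
            if eggs:
                offspring += rng.multinomial(eggs, T[i, j])

    offspring[~_viability_mask(genotypes, fitness)] = 0
    if offspring.sum() == 0:
        return None

    sons = rng.binomial(offspring, 0.5)
    daughters = offspring - sons
    half = census // 2
    next_f = (
        rng.multivariate_hypergeometric(daughters, half)
        if daughters.sum() > half
        else daughters
    )
    next_m = (
        rng.multivariate_hypergeometric(sons, half) if sons.sum() > half else sons
    )
    return CageState(genotypes, next_f.astype(np.int64), next_m.astype(np.int64),
                     state.generation + 1)


def simulate(
    seeding: SeedingSpec,
    cube: InheritanceCube,
    fitness: FitnessModel,
    generations: int,
    census: int = DEFAULT_CENSUS,
    seed: int | None = None,
    mean_eggs: float = DEFAULT_MEAN_EGGS,
) -> CageTrajectory:
    """Run one stochastic cage replicate for ``generations`` offspring cohorts."""
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    T = cube.as_tensor()
    state = seeding.to_state(cube.genotypes)
    states = [state]
    for _ in range(generations):
        state = step_generation(state, cube, fitness, census, rng, mean_eggs, cube_tensor=T)
        if state is None:
            return CageTrajectory(states, extinct=True,
                                  architecture=cube.architecture, loci_config=cube.loci_config)
        states.append(state)
    return CageTrajectory(states, extinct=False,
                          architecture=cube.architecture, loci_config=cube.loci_config)


def simulate_replicates(
    seeding: SeedingSpec,
    cube: InheritanceCube,
    fitness: FitnessModel,
    generations: int,
    reps: int,
    census: int = DEFAULT_CENSUS,
    seed: int = 0,
    mean_eggs: float = DEFAULT_MEAN_EGGS,
) -> list:
    """Independent replicates; replicate index offsets the seed."""
    return [
        simulate(seeding, cube, fitness, generations, census, seed + k, mean_eggs)
        for k in range(reps)
    ]


def carrier_frequency(state: CageState, allele_symbol: str = "H") -> float:
    """Fraction of adults carrying >= 1 copy of the allele at any locus."""
    total = state.total
    if total == 0:
        raise ValueError("empty cage state")
    carriers = 0
    for g, nf, nm in zip(state.genotypes, state.females, state.males):
        if carries_allele(g, allele_symbol):
            carriers += int(nf) + int(nm)
    return carriers / total


def allele_frequency(state: CageState, allele_symbol: str = "H") -> float:
    """Frequency of the allele among all copies at its locus."""
    total = state.total
    if total == 0:
        raise ValueError("empty cage state")
    copies = 0
    for g, nf, nm in zip(state.genotypes, state.females, state.males):
        k = sum(pair.count(allele_symbol) for pair in g)
        copies += k * (int(nf) + int(nm))
    return copies / (2 * total)


def drive_efficacy(trajectories, generation: int = 20, allele_symbol: str = "H") -> float:
    """Mean drive-carrier frequency at a generation across replicates.

    Replicates that ended earlier (extinction) contribute their terminal
    state.
    """
    if not trajectories:
        raise ValueError("no replicates")
    return float(
        np.mean([carrier_frequency(t.state_at(generation), allele_symbol) for t in trajectories])
    )


def efficacy_sweep(
    architecture: str,
    fitness_grid,
    cleavage_grid,
    reps: int,
    seed: int,
    loci_config: str = "one_locus",
    base_params=None,
    generations: int = 20,
    census: int = DEFAULT_CENSUS,
    mean_eggs: float = DEFAULT_MEAN_EGGS,
) -> np.ndarray:
    """Drive-efficacy matrix over (fitness cost, cleavage) grids.

    Fitness costs are applied as the architecture's dominant female-specific
    fecundity reduction; cleavage is set equally in both sexes, and the
    maternal-carryover fraction follows the cleavage rate (deposition is
    produced by the same Cas9/gRNA activity).  Entry ``[i, j]`` is the mean
    carrier frequency at ``generations`` over ``reps`` replicates for
    ``fitness_grid[i]`` and ``cleavage_grid[j]``.
    """
    from .genetics import build_cube
    from .presets import preset_parameters

    if base_params is None:
        base_params = preset_parameters(f"ideal_{architecture}")
    out = np.zeros((len(fitness_grid), len(cleavage_grid)))
    for i, s in enumerate(fitness_grid):
        for j, c in enumerate(cleavage_grid):
            params = base_params.with_(
                s_F=float(s), c_F=float(c), c_M=float(c),
                d_F=min(float(c), base_params.d_F),
            )
            cube = build_cube(architecture, loci_config, params)
            fit = FitnessModel(architecture, loci_config, params)
            seeding = comparative_seeding(architecture, loci_config, census)
            trajs = simulate_replicates(
                seeding, cube, fit, generations, reps, census,
                seed=seed + 1000 * (i * len(cleavage_grid) + j), mean_eggs=mean_eggs,
            )
            out[i, j] = drive_efficacy(trajs, generations)
    return out


def expected_generation(
    freq_f: np.ndarray,
    freq_m: np.ndarray,
    cube_tensor: np.ndarray,
    viable: np.ndarray,
    fecundity: np.ndarray,
):
    """One step of the infinite-population (deterministic) recursion.

    Mothers are weighted by fecundity, fathers enter at their adult
    frequencies, offspring follow the cube, unviable genotypes are removed,
    and both sexes of the next generation share the renormalized
    distribution.  This is the expectation limit of :func:`step_generation`.
    """
    w = freq_f * fecundity
    tot = w.sum()
    if tot <= 0:
        raise ValueError("zero total fecundity")
    w = w / tot
    m = freq_m / freq_m.sum()
    off = np.einsum("i,j,ijo->o", w, m, cube_tensor)
    off = off * viable
    off = off / off.sum()
    return off, off
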