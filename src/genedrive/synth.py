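"""Synthetic cage observations and field scenarios.

Emulates the cage-trial study end to end so that every fitting stage is
testable without laboratory data:

* cage trajectories — the parental generation is seeded with 50
  drive-homozygous males, 50 wildtype males, and 100 wildtype virgin
  females; each discrete generation the cage is propagated stochastically
  at a 400-adult census and a subsample of emerged flies (250-350 by
  default, the number anesthetized and scored in the protocol) is
  phenotyped for the dominant drive marker;
* pair crosses — replicate vials of trans-heterozygous females (and
  males) outcrossed to wildtype, each scoring F1 flies for the marker;
* genotype surveys — every marker-negative scored fly in early
  generations is genotyped (the protocol isolates and genotypes
  marker-negative escapees), and a sequencing survey genotypes a sample
  of marker-positive flies at the final generation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cage import (
    DEFAULT_CENSUS,
    SeedingSpec,
    paper_cage_seeding,
    simulate,
)
from .genetics import FitnessModel, build_cube
from .inference import (
    _ALLELES,
    _PAIRS,
    CageObservations,
    FitParameters,
    cross_transmission,
)

__all__ = [
    "generate_cage_observations",
    "mendelian_null_dataset",
    "generate_field_scenario",
]

_N_GENO = len(_PAIRS)


def _cube_to_fit_index(cube):
    """Map cube genotype order onto the drive-locus genotype index."""
    out = []
    for g in cube.genotypes:
        pair = tuple(sorted(_ALLELES.index(a) for a in g[0]))
        out.append(_PAIRS.index(pair))
    return np.array(out)


def _label(idx: int) -> str:
    i, j = _PAIRS[idx]
    return f"{_ALLELES[i]}/{_ALLELES[j]}"


def generate_cage_observations(
    true_params: FitParameters,
    n_cages: int = 5,
    generations: int = 10,
    flies_scored_per_gen: int | None = None,
    seeding: SeedingSpec | None = None,
    seed: int | None = None,
    census: int = DEFAULT_CENSUS,
    cross_vials: int = 10,
    f1_per_vial: int = 200,
    survey_neg_generations: tuple = (2, 3),
    final_survey_flies: int = 60,
) -> CageObservations:
    """Simulate cage trials and the accompanying assays.

    ``flies_scored_per_gen=None`` draws a uniform integer in [250, 350]
    per generation; an integer fixes the count (capped at the adults
    present).  Scored flies are a multinomial genotype draw at the cage's
    adult genotype frequencies; marker counts and survey genotype counts
    derive from the same draw, so the channels are mutually consistent.
    A cage that goes extinct early simply stops contributing rows.

    ``cross_vials`` trans-heterozygote outcross vials per parent sex score
    ``f1_per_vial`` F1 flies each; set ``cross_vials=0`` for cage data
    only.  All marker-negative scored flies at ``survey_neg_generations``
    are genotyped, and ``final_survey_flies`` marker-positive flies are
    genotyped at the last generation (0 disables either survey).
    """
    rng = np.random.default_rng(seed)
    seeding = paper_cage_seeding("homer", "one_locus") if seeding is None else seeding
    params = true_params.to_drive_params()
    cube = build_cube("homer", "one_locus", params)
    fitness = FitnessModel("homer", "one_locus", params)
    fit_idx = _cube_to_fit_index(cube)
    carrier_by_fit = np.array([1 in p for p in _PAIRS])  # allele H = index 1

    rows = []
    survey_rows = []
    final_gen = generations - 1
    for cage in range(n_cages):
        traj = simulate(
            seeding, cube, fitness, generations, census,
            seed=int(rng.integers(2**31 - 1)),
        )
        for state in traj.states:
            if state.generation < 0:  # parental generation is known, not scored
                continue
            if flies_scored_per_gen is None:
                n_scored = int(rng.integers(250, 351))
            else:
                n_scored = int(flies_scored_per_gen)
            n_scored = min(n_scored, state.total)
            adults = (state.females + state.males).astype(float)
            freqs = adults / adults.sum()
            draw = rng.multinomial(n_scored, freqs)
            counts = np.zeros(_N_GENO)
            np.add.at(counts, fit_idx, draw)
            n_pos = int(counts[carrier_by_fit].sum())
            rows.append((cage, state.generation, n_pos, n_scored - n_pos))

            g = state.generation
            if g in survey_neg_generations:
                neg = counts * (~carrier_by_fit)
                for i in np.nonzero(neg)[0]:
                    survey_rows.append((cage, g, "neg", _label(i), int(neg[i])))
            if g == final_gen and final_survey_flies > 0:
                pos = (counts * carrier_by_fit).astype(int)
                if pos.sum() > 0:
                    sub = rng.multivariate_hypergeometric(
                        pos, int(min(final_survey_flies, pos.sum()))
                    )
                    for i in np.nonzero(sub)[0]:
                        survey_rows.append((cage, g, "pos", _label(i), int(sub[i])))
    df = pd.DataFrame(rows, columns=["cage_id", "generation", "n_marker_pos", "n_marker_neg"])

    crosses = None
    if cross_vials > 0:
        xrows = []
        for sex in ("F", "M"):
            t = cross_transmission(true_params, sex)
            for _ in range(cross_vials):
                k = int(rng.binomial(f1_per_vial, t))
                xrows.append((sex, k, f1_per_vial - k))
        crosses = pd.DataFrame(xrows, columns=["parent_sex", "n_marker_pos", "n_marker_neg"])

    surveys = (
        pd.DataFrame(
            survey_rows,
            columns=["cage_id", "generation", "marker_class", "genotype", "count"],
        )
        if survey_rows
        else None
    )
    return CageObservations(df, seeding, crosses, surveys)


def mendelian_null_dataset(
    seed: int | None = None,
    n_cages: int = 3,
    generations: int = 10,
    flies_scored_per_gen: int | None = None,
) -> CageObservations:
    """No-drive control cages: all cleavage zero, marker drifts neutrally.

    Control pair crosses (Mendelian ~50% transmission) are generated
    alongside, mirroring the no-Cas9 cross assays of a cage study; no
    genotype surveys are produced (without cleavage there is nothing to
    sequence).
    """
    null = FitParameters(c_F=0.0, c_M=0.0, ch_F=0.0, ch_M=0.0, cr=0.0, s_F=0.0)
    return generate_cage_observations(
        null, n_cages=n_cages, generations=generations,
        flies_scored_per_gen=flies_scored_per_gen, seed=seed,
        survey_neg_generations=(), final_survey_flies=0,
    )


def generate_field_scenario(
    architecture: str,
    params,
    schedule=None,
    seed: int | None = None,
    loci_config: str = "one_locus",
    horizon_days: int = 120,
    equilibrium_adults: int = 1_000,
) -> pd.DataFrame:
    """Small-horizon field run for fast testing of the release metrics."""
    from .field import LifecycleParams, ReleaseSchedule, simulate_field

    cube = build_cube(architecture, loci_config, params)
    fitness = FitnessModel(architecture, loci_config, params)
    lifecycle = LifecycleParams(equilibrium_adults=equilibrium_adults)
    schedule = ReleaseSchedule() if schedule is None else schedule
    return simulate_field(cube, fitness, lifecycle, schedule, horizon_days, seed)
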