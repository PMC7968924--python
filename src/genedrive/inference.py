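"""Model fitting to cage phenotype trajectories.

The fitted model is the discrete-generation, random-mixing homing model at
a single drive locus: adults heterozygous for the drive (H) and wildtype
(W) alleles transmit a cleaved W allele as H (accurate HDR), or as an
in-frame functional resistant allele R, or as an out-of-frame
loss-of-function allele B; cleavage (c) and HDR-given-cleavage (p_HDR)
probabilities are sex-specific, the in-frame fraction among resistant
alleles (p_RES) is shared, B/B homozygotes are unviable, and drive-carrier
females pay a dominant fecundity cost s_F.  Maternal deposition is not part
of the fitted model.

The likelihood combines the assay channels of a cage study:

* cage trajectories — flies scored each generation are a binomial draw of
  drive-marker-positive counts at the model-expected carrier fraction; by
  default the expectation for each generation is computed one step ahead
  from the previously *observed* marker fraction (the within-class genotype
  composition coming from the model), which keeps cage-to-cage genetic
  drift from accumulating into the fit;
* pair crosses — F1 marker counts from trans-heterozygote outcrosses,
  binomial at the sex-specific transmission rate 0.5(1 + c*ch);
* genotype surveys — genotyped subsamples of marker-negative (early
  generations) or marker-positive (late generations) flies, multinomial
  over the model's within-class genotype composition.

The carrier trajectory alone does not identify the six parameters: distant
parameter combinations produce numerically indistinguishable carrier
curves, and with the fecundity cost free the female and male transmission
roles are exchangeable.  The cross and survey channels break those ridges.
The posterior is explored with covariance-adaptive random-walk Metropolis
on logit-transformed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, logit

from .genetics import DriveParams

__all__ = [
    "PARAM_NAMES",
    "GENOTYPE_LABELS",
    "FitParameters",
    "CageObservations",
    "PosteriorSummary",
    "McmcResult",
    "cross_transmission",
    "expected_phenotype_trajectory",
    "log_likelihood",
    "run_mcmc",
    "summarize_posterior",
]

PARAM_NAMES = ("c_F", "c_M", "ch_F", "ch_M", "cr", "s_F")

# one-locus drive genotypes over alleles W, H, R, B (allele indices 0..3)
_ALLELES = ("W", "H", "R", "B")
_PAIRS = tuple((i, j) for i in range(4) for j in range(i, 4))
_PAIR_INDEX = {p: k for k, p in enumerate(_PAIRS)}
_N_GENO = len(_PAIRS)  # 10
_WW = _PAIR_INDEX[(0, 0)]
_BB = _PAIR_INDEX[(3, 3)]
_HH = _PAIR_INDEX[(1, 1)]

# P[a, b, g]: zygote genotype index from maternal allele a and paternal b
_PAIRING = np.zeros((4, 4, _N_GENO))
for _a in range(4):
    for _b in range(4):
        _PAIRING[_a, _b, _PAIR_INDEX[tuple(sorted((_a, _b)))]] = 1.0

_CARRIER = np.array([1 in p for p in _PAIRS], dtype=float)  # has >=1 H
_NONCARRIER = 1.0 - _CARRIER
_VIABLE = np.ones(_N_GENO)
_VIABLE[_BB] = 0.0

GENOTYPE_LABELS = tuple(f"{_ALLELES[i]}/{_ALLELES[j]}" for i, j in _PAIRS)
_LABEL_INDEX = {lab: k for k, lab in enumerate(GENOTYPE_LABELS)}
_LABEL_INDEX.update(
    {f"{_ALLELES[j]}/{_ALLELES[i]}": k for k, (i, j) in enumerate(_PAIRS)}
)


@dataclass(frozen=True)
class FitParameters:
    """The six fitted drive parameters, all probabilities in [0, 1]."""

    c_F: float
    c_M: float
    ch_F: float
    ch_M: float
    cr: float
    s_F: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"FitParameters.{name} = {v!r} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, x) -> "FitParameters":
        return cls(*(float(v) for v in x))

    def to_drive_params(self) -> DriveParams:
        """Map onto the full parameter set (no maternal deposition)."""
        return DriveParams(
            c_F=self.c_F, c_M=self.c_M, ch_F=self.ch_F, ch_M=self.ch_M,
            cr_F=self.cr, cr_M=self.cr, d_F=0.0, dr_F=0.0, s_F=self.s_F,
        )


def _gamete_matrix(c: float, ch: float, cr: float) -> np.ndarray:
    """(genotype, transmitted allele) matrix for one sex.

    Only H/W heterozygotes deviate from Mendelian transmission: their W
    allele is cleaved with probability c, converted by HDR to H with
    probability ch given cleavage, and otherwise end-joined to R (fraction
    cr) or B.
    """
    G = np.zeros((_N_GENO, 4))
    for g, (i, j) in enumerate(_PAIRS):
        G[g, i] += 0.5
        G[g, j] += 0.5
    hw = _PAIR_INDEX[(0, 1)]
    G[hw] = 0.0
    G[hw, 1] = 0.5 + 0.5 * c * ch  # H: own copy + homing
    G[hw, 0] = 0.5 * (1.0 - c)  # W escapes cleavage
    G[hw, 2] = 0.5 * c * (1.0 - ch) * cr  # in-frame R
    G[hw, 3] = 0.5 * c * (1.0 - ch) * (1.0 - cr)  # LOF B
    return G


def _cube_tensor(p: FitParameters) -> np.ndarray:
    Gf = _gamete_matrix(p.c_F, p.ch_F, p.cr)
    Gm = _gamete_matrix(p.c_M, p.ch_M, p.cr)
    return np.einsum("ma,fb,abg->mfg", Gf, Gm, _PAIRING)


_DEFAULT_SEED_F = np.zeros(_N_GENO)
_DEFAULT_SEED_F[_WW] = 1.0  # 100 wildtype females
_DEFAULT_SEED_M = np.zeros(_N_GENO)
_DEFAULT_SEED_M[_WW] = 0.5  # 50 wildtype males
_DEFAULT_SEED_M[_HH] = 0.5  # 50 drive-homozygous males


def seeding_frequencies(seeding=None) -> tuple[np.ndarray, np.ndarray]:
    """Parental genotype frequencies by sex from a cage seeding.

    ``seeding`` may be None (cage-trial default: 50 drive-homozygous males,
    50 wildtype males, 100 wildtype females) or an object with ``entries``
    of (genotype, sex, count) over one-locus drive genotypes.
    """
    if seeding is None:
        return _DEFAULT_SEED_F.copy(), _DEFAULT_SEED_M.copy()
    f = np.zeros(_N_GENO)
    m = np.zeros(_N_GENO)
    for genotype, sex, count in seeding.entries:
        (pair,) = genotype  # one drive locus
        idx = _PAIR_INDEX[tuple(sorted(_ALLELES.index(a) for a in pair))]
        (f if sex == "F" else m)[idx] += count
    if f.sum() == 0 or m.sum() == 0:
        raise ValueError("seeding must include both sexes")
    return f / f.sum(), m / m.sum()


def expected_phenotype_trajectory(
    params: FitParameters, generations: int, seeding=None
) -> np.ndarray:
    """Expected drive-carrier fraction at G0..G(generations-1).

    Deterministic infinite-population recursion: mothers weighted by
    fecundity (drive carriers x (1 - s_F)), fathers at adult frequencies,
    offspring from the inheritance rules, B/B zygotes removed, both sexes
    sharing the renormalized genotype distribution.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    T = _cube_tensor(params)
    fec = np.where(_CARRIER > 0, 1.0 - params.s_F, 1.0)
    freq_f, freq_m = seeding_frequencies(seeding)
    out = np.empty(generations)
    for g in range(generations):
        w = freq_f * fec
        w = w / w.sum()
        off = np.einsum("i,j,ijg->g", w, freq_m, T)
        off *= _VIABLE
        off = off / off.sum()
        freq_f = freq_m = off
        out[g] = float(off @ _CARRIER)
    return out


@dataclass
class CageObservations:
    """Drive-marker counts from cage trials and optional pair crosses.

    ``data`` has columns cage_id, generation, n_marker_pos, n_marker_neg;
    generations are the scored offspring cohorts G0, G1, ... produced by the
    shared ``seeding``.

    ``crosses``, when present, holds F1 marker counts from individual
    trans-heterozygote (H/W) outcrosses to wildtype with columns
    parent_sex ('F' or 'M'), n_marker_pos, n_marker_neg.  The cage carrier
    trajectory alone does not separate cleavage from HDR (distant parameter
    combinations produce identical trajectories), so the transmission
    assays that anchor c*ch per sex are fitted jointly when supplied.

    ``surveys``, when present, holds genotyped fly counts with columns
    cage_id, generation, marker_class ('pos' or 'neg'), genotype (e.g.
    'H/B', 'W/R'), count — the genotyping of marker-negative flies in
    early generations and the sequencing survey of marker-positive flies
    at the end of a trial.
    """

    data: pd.DataFrame
    seeding: object = None
    crosses: pd.DataFrame | None = None
    surveys: pd.DataFrame | None = None

    REQUIRED = ("cage_id", "generation", "n_marker_pos", "n_marker_neg")
    CROSS_REQUIRED = ("parent_sex", "n_marker_pos", "n_marker_neg")
    SURVEY_REQUIRED = ("cage_id", "generation", "marker_class", "genotype", "count")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"observations missing columns: {missing}")
        d = self.data
        if (d[["n_marker_pos", "n_marker_neg"]] < 0).any().any():
            raise ValueError("negative counts")
        for cid, grp in d.groupby("cage_id"):
            gens = np.sort(grp["generation"].to_numpy())
            if not np.array_equal(gens, np.arange(gens[0], gens[0] + len(gens))):
                raise ValueError(f"cage {cid}: generations not consecutive")
        if self.crosses is not None:
            missing = [c for c in self.CROSS_REQUIRED if c not in self.crosses.columns]
            if missing:
                raise ValueError(f"cross observations missing columns: {missing}")
            if not set(self.crosses["parent_sex"]) <= {"F", "M"}:
                raise ValueError("cross parent_sex must be 'F' or 'M'")
            if (self.crosses[["n_marker_pos", "n_marker_neg"]] < 0).any().any():
                raise ValueError("negative cross counts")
        if self.surveys is not None:
            missing = [c for c in self.SURVEY_REQUIRED if c not in self.surveys.columns]
            if missing:
                raise ValueError(f"survey observations missing columns: {missing}")
            if not set(self.surveys["marker_class"]) <= {"pos", "neg"}:
                raise ValueError("survey marker_class must be 'pos' or 'neg'")
            bad = [g for g in self.surveys["genotype"] if g not in _LABEL_INDEX]
            if bad:
                raise ValueError(f"unknown survey genotype(s): {sorted(set(bad))}")
            if (self.surveys["count"] < 0).any():
                raise ValueError("negative survey counts")
            have = set(zip(self.data["cage_id"], self.data["generation"]))
            orphan = [
                key
                for key in zip(self.surveys["cage_id"], self.surveys["generation"])
                if key not in have
            ]
            if orphan:
                raise ValueError(
                    f"survey rows without matching cage generations: {sorted(set(orphan))}"
                )

    def _fit_arrays(self):
        """Cached numeric views used by the likelihood."""
        cache = getattr(self, "_cache", None)
        if cache is None:
            cages = []
            for cid, grp in self.data.groupby("cage_id"):
                grp = grp.sort_values("generation")
                k = grp["n_marker_pos"].to_numpy()
                n = k + grp["n_marker_neg"].to_numpy()
                cages.append((cid, k, n, grp["generation"].to_numpy()))
            surveys: dict[tuple, np.ndarray] = {}
            if self.surveys is not None:
                for _, row in self.surveys.iterrows():
                    key = (row["cage_id"], int(row["generation"]), row["marker_class"])
                    vec = surveys.setdefault(key, np.zeros(_N_GENO))
                    vec[_LABEL_INDEX[row["genotype"]]] += row["count"]
            if self.crosses is not None and len(self.crosses):
                kx = self.crosses["n_marker_pos"].to_numpy()
                nx = kx + self.crosses["n_marker_neg"].to_numpy()
                sexes = tuple(self.crosses["parent_sex"])
            else:
                kx = nx = sexes = None
            cache = (cages, surveys, kx, nx, sexes)
            object.__setattr__(self, "_cache", cache)
        return cache

    @property
    def n_generations(self) -> int:
        if len(self.data) == 0:
            return 0
        return int(self.data["generation"].max()) + 1

    @classmethod
    def read_csv(cls, path_or_buf, seeding=None, crosses_path=None,
                 surveys_path=None) -> "CageObservations":
        crosses = pd.read_csv(crosses_path) if crosses_path is not None else None
        surveys = pd.read_csv(surveys_path) if surveys_path is not None else None
        return cls(pd.read_csv(path_or_buf), seeding, crosses, surveys)

    def to_csv(self, path_or_buf=None):
        return self.data.to_csv(path_or_buf, index=False)


def cross_transmission(params: FitParameters, parent_sex: str) -> float:
    """Expected drive-marker fraction among surviving F1 of a
    trans-heterozygous (H/W) parent crossed to wildtype.

    The wildtype parent contributes a W allele, so every F1 is viable and
    the marker fraction equals the H-gamete probability
    0.5 * (1 + c * ch) of the drive parent's sex.
    """
    c = params.c_F if parent_sex == "F" else params.c_M
    ch = params.ch_F if parent_sex == "F" else params.ch_M
    return 0.5 * (1.0 + c * ch)


def _binom_logpmf(k, n, p):
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    comb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = comb + np.where(k > 0, k * np.log(p), 0.0) + np.where(
            n - k > 0, (n - k) * np.log1p(-p), 0.0
        )
    return np.where(np.isnan(lp), -np.inf, lp)


def _class_loglik(counts: np.ndarray, state: np.ndarray, mask: np.ndarray) -> float:
    """Multinomial log likelihood (up to a constant) of genotyped flies
    within a marker class, given the model genotype state."""
    q = state * mask
    tot = q.sum()
    if tot <= 0:
        return 0.0 if counts.sum() == 0 else -np.inf
    q = q / tot
    with np.errstate(divide="ignore"):
        lq = np.where(counts > 0, np.log(np.maximum(q, 1e-300)), 0.0)
    return float(np.sum(counts * lq))


def log_likelihood(obs: CageObservations, params: FitParameters,
                   conditional: bool = True) -> float:
    """Joint log likelihood of cage, cross, and survey observations.

    Cage terms: marker-positive counts each generation are binomial at the
    model-expected carrier fraction.  With ``conditional=True`` (default)
    each generation's expectation is predicted from the previous
    generation's observed marker fraction, with within-class genotype
    composition taken from the model — a one-step-ahead fit that keeps
    accumulated genetic drift of a finite cage out of the parameter
    estimates.  With ``conditional=False`` the open-loop deterministic
    trajectory from the seeding is used.  Cross and survey terms are
    binomial/multinomial as described in the module docstring.  Independent
    across cages; -inf only when an expected fraction of exactly 0 or 1 is
    contradicted by the data.
    """
    fec = np.where(_CARRIER > 0, 1.0 - params.s_F, 1.0)
    T = _cube_tensor(params)
    cages, surveys, kx, nx, sexes = obs._fit_arrays()
    ll = 0.0
    f0, m0 = seeding_frequencies(obs.seeding)
    for cid, k, n, gens in cages:
        f, m = f0, m0
        for kk, nn, g in zip(k, n, gens):
            w = f * fec
            w = w / w.sum()
            off = np.einsum("i,j,ijg->g", w, m, T) * _VIABLE
            off = off / off.sum()
            ll += float(_binom_logpmf(kk, nn, float(off @ _CARRIER)))
            if surveys:
                for cls, mask in (("pos", _CARRIER), ("neg", _NONCARRIER)):
                    counts = surveys.get((cid, int(g), cls))
                    if counts is not None:
                        ll += _class_loglik(counts, off, mask)
            if not np.isfinite(ll):
                return -np.inf
            if conditional and nn > 0:
                qhat = kk / nn
                oc = off * _CARRIER
                on = off * _NONCARRIER
                if oc.sum() > 0 and on.sum() > 0:
                    off = qhat * oc / oc.sum() + (1.0 - qhat) * on / on.sum()
            f = m = off
    if kx is not None:
        px = np.array([cross_transmission(params, s) for s in sexes])
        ll += float(np.sum(_binom_logpmf(kx, nx, px)))
    return ll


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Equal-tailed posterior medians and 95% credible intervals."""

    table: pd.DataFrame  # index: parameter; columns: median, cri_lower, cri_upper
    acceptance_rate: float = float("nan")
    n_samples: int = 0

    def __post_init__(self):
        t = self.table
        bad = (t["cri_lower"] > t["median"]) | (t["median"] > t["cri_upper"])
        if bad.any():
            raise ValueError("credible interval does not bracket the median")

    def median(self, name: str) -> float:
        return float(self.table.loc[name, "median"])

    def cri(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["cri_lower"]), float(row["cri_upper"])


@dataclass
class McmcResult:
    samples: pd.DataFrame  # post burn-in, unit scale, one column per parameter
    summary: PosteriorSummary
    acceptance_rate: float
    log_post: np.ndarray


def summarize_posterior(samples, acceptance_rate: float = float("nan")) -> PosteriorSummary:
    """Equal-tailed 2.5/50/97.5 percentiles per parameter."""
    if isinstance(samples, pd.DataFrame):
        df = samples[[c for c in samples.columns if c in PARAM_NAMES]] if any(
            c in PARAM_NAMES for c in samples.columns
        ) else samples
    else:
        arr = np.atleast_2d(np.asarray(samples, float))
        df = pd.DataFrame(arr, columns=PARAM_NAMES[: arr.shape[1]])
    if len(df) == 0:
        raise ValueError("empty sample set")
    q = df.quantile([0.025, 0.5, 0.975])
    table = pd.DataFrame(
        {
            "median": q.loc[0.5],
            "cri_lower": q.loc[0.025],
            "cri_upper": q.loc[0.975],
        }
    )
    return PosteriorSummary(table, acceptance_rate, len(df))


def _logit_log_post(z, obs, log_prior, conditional=True):
    theta = np.clip(expit(z), 1e-12, 1.0 - 1e-12)
    # uniform-prior density transforms with the logit Jacobian
    jac = float(np.sum(np.log(theta) + np.log1p(-theta)))
    lp = 0.0 if log_prior is None else float(log_prior(theta))
    if not np.isfinite(lp):
        return -np.inf
    ll = log_likelihood(obs, FitParameters.from_array(theta), conditional)
    return ll + lp + jac


def _find_start(obs, log_prior, rng, conditional=True) -> np.ndarray:
    """Posterior-mode search: Nelder-Mead polish of the best of a spread
    of prior draws (plus the prior midpoint)."""
    starts = [np.zeros(len(PARAM_NAMES))]
    starts += [logit(rng.uniform(0.02, 0.98, len(PARAM_NAMES))) for _ in range(15)]
    f = lambda z: -_logit_log_post(z, obs, log_prior, conditional)
    best = min(starts, key=f)
    res = optimize.minimize(f, best, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-4, "fatol": 1e-3})
    return res.x


def run_mcmc(
    obs: CageObservations,
    log_prior=None,
    iterations: int = 50_000,
    burn_in: int = 10_000,
    proposal_scale: float = 0.05,
    seed: int | None = None,
    init: FitParameters | None = None,
    thin: int = 1,
    conditional: bool = True,
) -> McmcResult:
    """Covariance-adaptive random-walk Metropolis on logit-transformed
    parameters.

    The prior is uniform on [0,1]^6 unless ``log_prior(theta)`` is given.
    The chain starts at the posterior mode (or ``init``); during burn-in
    the proposal covariance is re-estimated from the recent chain history
    (scaled by 2.38^2/d) to follow the posterior's correlation ridges, and
    it is frozen afterwards.  Summaries are computed from post-burn-in
    draws.  ``proposal_scale`` sets the initial isotropic proposal
    variance on the logit scale.
    """
    if iterations > 0 and burn_in > iterations:
        raise ValueError("burn_in exceeds iterations")
    rng = np.random.default_rng(seed)
    z = (
        logit(np.clip(init.to_array(), 1e-9, 1 - 1e-9))
        if init is not None
        else _find_start(obs, log_prior, rng, conditional)
    )
    lp = _logit_log_post(z, obs, log_prior, conditional)
    if not np.isfinite(lp):
        raise RuntimeError("initial point has zero posterior density")

    if iterations == 0:
        theta = expit(z)
        df = pd.DataFrame([theta], columns=PARAM_NAMES)
        return McmcResult(df, summarize_posterior(df), float("nan"), np.array([lp]))

    d = len(PARAM_NAMES)
    sf = 2.38**2 / d
    cov = np.eye(d) * float(proposal_scale)
    jitter = 1e-6 * np.eye(d)
    chol = np.linalg.cholesky(sf * cov + jitter)
    history = [z.copy()]
    kept = []
    log_posts = []
    accepted = 0
    accepted_burn = 0
    window_acc = 0
    for it in range(iterations):
        prop = z + chol @ rng.standard_normal(d)
        lp_prop = _logit_log_post(prop, obs, log_prior, conditional)
        if np.log(rng.uniform()) < lp_prop - lp:
            z, lp = prop, lp_prop
            accepted += 1
            if it < burn_in:
                accepted_burn += 1
                window_acc += 1
        if it < burn_in:
            history.append(z.copy())
            if it > 200 and it % 200 == 0:
                # follow the posterior's ridges and keep acceptance near 25%
                sf *= float(np.exp((window_acc / 200 - 0.25) * 0.5))
                window_acc = 0
                emp = np.cov(np.array(history[-2000:]).T)
                cov = (emp + emp.T) / 2.0
                chol = np.linalg.cholesky(sf * cov + jitter)
            if it + 1 == burn_in and accepted_burn == 0:
                raise RuntimeError(
                    "zero acceptance over burn-in; check data/model or proposal scale"
                )
        elif (it - burn_in) % thin == 0:
            kept.append(expit(z))
            log_posts.append(lp)

    samples = pd.DataFrame(np.array(kept), columns=PARAM_NAMES)
    rate = accepted / iterations
    summary = summarize_posterior(samples, rate)
    return McmcResult(samples, summary, rate, np.array(log_posts))
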