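"""Drive genetics: alleles, genotypes, fitness rules, and inheritance cubes.

Four drive architectures are modeled over up to three unlinked autosomal loci:

* ``homer`` — home-and-rescue drive: a Cas9/gRNA cassette inserted into an
  essential gene together with a re-coded, cleavage-immune rescue of that
  gene.  Homing (HDR copying of the cassette onto the wildtype homolog)
  biases transmission; loss-of-function resistant alleles are recessive
  lethal and therefore purged.
* ``hgd`` — classical homing gene drive: same homing rules but no rescue;
  the target gene is assumed non-essential so no genotype is unviable.
* ``clvr`` — cleave-and-rescue toxin–antidote drive: the cassette (gRNAs +
  rescue, plus Cas9 in the one-locus design) sits at a locus distinct from
  the target gene; there is no homing, spread comes from killing progeny
  that carry no functional target copy and no rescue.
* ``tare`` — toxin–antidote recessive embryo drive: like ClvR but with the
  cassette inserted at the target locus itself.

"One-locus" means the complete drive (Cas9 + gRNAs [+ rescue]) travels as a
single cassette; "two-locus" (split drive) places Cas9 at its own unlinked
locus so that drive conversion requires both components in one individual.

Allele symbols at the target/cassette locus: ``W`` wildtype, ``H`` drive
cassette, ``R`` in-frame functional (cost-free) resistant, ``B``
out-of-frame / loss-of-function resistant.  A standalone ClvR cassette locus
uses ``H``/``h0`` (cassette present/absent) and a split Cas9 locus uses
``C``/``c0``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DriveParams",
    "FitnessModel",
    "InheritanceCube",
    "ARCHITECTURES",
    "HOMING_ARCHITECTURES",
    "locus_roles",
    "locus_alleles",
    "enumerate_genotypes",
    "wildtype_genotype",
    "drive_homozygote",
    "cas9_homozygote",
    "genotype_to_string",
    "genotype_from_string",
    "carries_allele",
    "carries_cas9",
    "carries_drive",
    "gamete_distribution",
    "apply_maternal_carryover",
    "viability_and_fitness",
    "build_cube",
    "mendelian_cube",
    "validate_cube",
]

ARCHITECTURES = ("homer", "hgd", "clvr", "tare")
HOMING_ARCHITECTURES = ("homer", "hgd")
LOCI_CONFIGS = ("one_locus", "two_locus")

# canonical within-pair ordering: drive allele first, wildtype next
_ALLELE_RANK = {"H": 0, "W": 1, "R": 2, "B": 3, "h0": 1, "C": 0, "c0": 1}


@dataclass(frozen=True)
class DriveParams:
    """Probabilities governing drive conversion, resistance, and cost.

    Parameters
    ----------
    c_F, c_M
        Germline cleavage probability per W allele in females / males.
    ch_F, ch_M
        Probability of accurate HDR (homing) given cleavage; meaningful for
        homing architectures only and must be 0 for ClvR/TARE cubes.
    cr_F, cr_M
        In-frame (functional R) fraction among end-joined alleles.
    d_F
        Fraction of zygotes of Cas9+gRNA mothers affected by maternal
        carryover of Cas9/gRNA complexes.
    dr_F
        In-frame fraction among carryover-cleaved alleles.
    s_F
        Dominant female-fecundity cost of the architecture-specific
        cost-bearing genotype class (drive carriers for HomeR/TARE/HGD,
        Cas9 carriers for ClvR).
    """

    c_F: float = 0.0
    c_M: float = 0.0
    ch_F: float = 0.0
    ch_M: float = 0.0
    cr_F: float = 0.0
    cr_M: float = 0.0
    d_F: float = 0.0
    dr_F: float = 0.0
    s_F: float = 0.0

    def __post_init__(self):
        for name in ("c_F", "c_M", "ch_F", "ch_M", "cr_F", "cr_M", "d_F", "dr_F", "s_F"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"DriveParams.{name} = {v!r} outside [0, 1]")

    def with_(self, **kw) -> "DriveParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# genotype machinery
# ---------------------------------------------------------------------------

def locus_roles(architecture: str, loci_config: str) -> tuple[str, ...]:
    """Ordered locus roles for an architecture/loci configuration."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if loci_config not in LOCI_CONFIGS:
        raise ValueError(f"unknown loci_config {loci_config!r}")
    if architecture == "clvr":
        roles = ("cassette", "target")
    else:
        roles = ("target",)
    if loci_config == "two_locus":
        roles = roles + ("cas9",)
    return roles


def locus_alleles(architecture: str, role: str) -> tuple[str, ...]:
    if role == "cas9":
        return ("C", "c0")
    if role == "cassette":
        return ("H", "h0")
    if role == "target":
        return ("W", "R", "B") if architecture == "clvr" else ("W", "H", "R", "B")
    raise ValueError(f"unknown locus role {role!r}")


def _canon_pair(pair) -> tuple[str, str]:
    a, b = pair
    return tuple(sorted((a, b), key=lambda x: (_ALLELE_RANK[x], x)))


def canonicalize(genotype) -> tuple[tuple[str, str], ...]:
    return tuple(_canon_pair(p) for p in genotype)


def enumerate_genotypes(architecture: str, loci_config: str) -> tuple:
    """All canonical diploid genotypes for the architecture, ordered."""
    roles = locus_roles(architecture, loci_config)
    per_locus = []
    for role in roles:
        alleles = locus_alleles(architecture, role)
        pairs = [
            _canon_pair((alleles[i], alleles[j]))
            for i in range(len(alleles))
            for j in range(i, len(alleles))
        ]
        per_locus.append(pairs)
    return tuple(itertools.product(*per_locus))


def genotype_to_string(genotype) -> str:
    return ";".join("/".join(pair) for pair in genotype)


def genotype_from_string(s: str):
    return canonicalize(tuple(tuple(part.split("/")) for part in s.split(";")))


def wildtype_genotype(architecture: str, loci_config: str):
    roles = locus_roles(architecture, loci_config)
    wt = {"cas9": ("c0", "c0"), "cassette": ("h0", "h0"), "target": ("W", "W")}
    return tuple(wt[r] for r in roles)


def drive_homozygote(architecture: str, loci_config: str, with_cas9: bool = True):
    """Genotype homozygous for the drive cassette (and Cas9 if requested)."""
    roles = locus_roles(architecture, loci_config)
    out = []
    for r in roles:
        if r == "cas9":
            out.append(("C", "C") if with_cas9 else ("c0", "c0"))
        elif r == "cassette":
            out.append(("H", "H"))
        else:  # target
            out.append(("H", "H") if architecture != "clvr" else ("W", "W"))
    return tuple(out)


def cas9_homozygote(architecture: str, loci_config: str):
    """Cas9-only homozygote (split designs); otherwise wildtype."""
    roles = locus_roles(architecture, loci_config)
    g = list(wildtype_genotype(architecture, loci_config))
    for i, r in enumerate(roles):
        if r == "cas9":
            g[i] = ("C", "C")
    return tuple(g)


def carries_allele(genotype, symbol: str) -> bool:
    return any(symbol in pair for pair in genotype)


def _role_index(roles, role):
    return roles.index(role) if role in roles else None


def carries_cas9(genotype, architecture: str, loci_config: str) -> bool:
    roles = locus_roles(architecture, loci_config)
    i = _role_index(roles, "cas9")
    if i is not None:
        return "C" in genotype[i]
    # one-locus designs: the cassette itself carries Cas9
    return carries_drive(genotype, architecture, loci_config)


def carries_drive(genotype, architecture: str, loci_config: str) -> bool:
    """True if the genotype has >=1 copy of the drive/effector cassette."""
    roles = locus_roles(architecture, loci_config)
    i = roles.index("cassette") if architecture == "clvr" else roles.index("target")
    return "H" in genotype[i]


def _germline_active(genotype, architecture, loci_config) -> bool:
    # cleavage requires Cas9 and gRNAs in the same individual
    return carries_drive(genotype, architecture, loci_config) and carries_cas9(
        genotype, architecture, loci_config
    )


# ---------------------------------------------------------------------------
# gametes
# ---------------------------------------------------------------------------

def _check_arch_params(architecture: str, params: DriveParams) -> None:
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if architecture not in HOMING_ARCHITECTURES and (params.ch_F > 0 or params.ch_M > 0):
        raise ValueError(
            f"{architecture} is a non-homing architecture: ch_F/ch_M must be 0 "
            f"(got ch_F={params.ch_F}, ch_M={params.ch_M})"
        )


def _w_branch(c: float, ch: float, cr: float) -> dict[str, float]:
    """Fate of one W allele in an active germline: remain W, home to H, or EJ."""
    return {
        "H": c * ch,
        "W": 1.0 - c,
        "R": c * (1.0 - ch) * cr,
        "B": c * (1.0 - ch) * (1.0 - cr),
    }


def gamete_distribution(
    parent, sex: str, params: DriveParams, architecture: str, loci_config: str = "one_locus"
) -> dict:
    """Distribution over haploid gametes of a parent genotype.

    Cleavage acts on germline W alleles only when the parent carries both
    Cas9 and gRNAs; homing (W -> H) additionally requires the drive cassette
    on the homologous chromosome as repair template, which for the merged
    cassette/target architectures means the active parent is H/W at the
    target locus.  H, R, and B alleles transmit unchanged; any standalone
    Cas9 or cassette locus segregates Mendelianly.
    """
    _check_arch_params(architecture, params)
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    parent = canonicalize(parent)
    roles = locus_roles(architecture, loci_config)
    if len(parent) != len(roles):
        raise ValueError(f"genotype {parent} does not match loci {roles}")

    active = _germline_active(parent, architecture, loci_config)
    c = params.c_F if sex == "F" else params.c_M
    ch = params.ch_F if sex == "F" else params.ch_M
    cr = params.cr_F if sex == "F" else params.cr_M

    per_locus: list[dict[str, float]] = []
    for role, pair in zip(roles, parent):
        dist: dict[str, float] = {}
        homing_ok = architecture in HOMING_ARCHITECTURES and "H" in pair
        for allele in pair:
            if role == "target" and allele == "W" and active and c > 0:
                branch = _w_branch(c, ch if homing_ok else 0.0, cr)
                for sym, p in branch.items():
                    if p > 0:
                        dist[sym] = dist.get(sym, 0.0) + 0.5 * p
            else:
                dist[allele] = dist.get(allele, 0.0) + 0.5
        per_locus.append(dist)

    out: dict[tuple, float] = {}
    for combo in itertools.product(*(d.items() for d in per_locus)):
        gamete = tuple(sym for sym, _ in combo)
        p = 1.0
        for _, pi in combo:
            p *= pi
        out[gamete] = out.get(gamete, 0.0) + p
    return out


def apply_maternal_carryover(zygote, mother, params: DriveParams, architecture: str,
                             loci_config: str = "one_locus") -> dict:
    """Maternal Cas9/gRNA carryover acting on zygotic W alleles.

    When the mother carries both Cas9 and gRNAs, a fraction ``d_F`` of her
    zygotes have every W allele converted to R (probability ``dr_F``) or B
    (``1 - dr_F``); the remaining zygotes are untouched.  Returns a
    distribution over genotypes.
    """
    zygote = canonicalize(zygote)
    if not _germline_active(mother, architecture, loci_config) or params.d_F == 0.0:
        return {zygote: 1.0}
    roles = locus_roles(architecture, loci_config)
    t = roles.index("target")
    n_w = zygote[t].count("W")
    if n_w == 0:
        return {zygote: 1.0}

    d, dr = params.d_F, params.dr_F
    out: dict[tuple, float] = {}
    if d < 1.0:
        out[zygote] = 1.0 - d
    non_w = [a for a in zygote[t] if a != "W"]
    # each W independently -> R (dr) or B (1 - dr) in an impacted zygote
    for fates in itertools.product(("R", "B"), repeat=n_w):
        p = d
        for f in fates:
            p *= dr if f == "R" else (1.0 - dr)
        if p == 0.0:
            continue
        new = list(zygote)
        new[t] = _canon_pair(tuple(non_w) + fates)
        new = tuple(new)
        out[new] = out.get(new, 0.0) + p
    return out


# ---------------------------------------------------------------------------
# viability and fitness
# ---------------------------------------------------------------------------

def viability_and_fitness(genotype, architecture: str, params: DriveParams,
                          loci_config: str = "one_locus") -> tuple[bool, float]:
    """(viable, female-fecundity multiplier) for a zygote genotype.

    Viability encodes the rescue logic: HomeR and TARE cassettes rescue the
    essential target gene in cis, so only B/B target genotypes die; ClvR
    rescues in trans from the cassette locus, so a genotype dies only with
    zero functional target copies *and* no cassette; HGD targets a
    non-essential gene and every genotype is viable.  Fecundity costs are
    dominant and female-specific.
    """
    genotype = canonicalize(genotype)
    roles = locus_roles(architecture, loci_config)
    if len(genotype) != len(roles):
        raise ValueError(f"genotype {genotype} missing loci for {architecture} {loci_config}")
    t = roles.index("target")
    target = genotype[t]

    if architecture in ("homer", "tare"):
        viable = target != ("B", "B")
        mult = 1.0 - params.s_F if carries_drive(genotype, architecture, loci_config) else 1.0
    elif architecture == "hgd":
        viable = True
        costly = carries_drive(genotype, architecture, loci_config) or target == ("B", "B")
        mult = 1.0 - params.s_F if costly else 1.0
    elif architecture == "clvr":
        functional = ("W" in target) or ("R" in target)
        viable = functional or carries_drive(genotype, architecture, loci_config)
        mult = 1.0 - params.s_F if carries_cas9(genotype, architecture, loci_config) else 1.0
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    return viable, (mult if viable else 0.0)


@dataclass(frozen=True)
class FitnessModel:
    """Viability indicator and female fecundity multiplier per genotype."""

    architecture: str
    loci_config: str
    params: DriveParams

    def viable(self, genotype) -> bool:
        return viability_and_fitness(genotype, self.architecture, self.params, self.loci_config)[0]

    def fecundity(self, genotype) -> float:
        return viability_and_fitness(genotype, self.architecture, self.params, self.loci_config)[1]


# ---------------------------------------------------------------------------
# inheritance cube
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InheritanceCube:
    """Parent-pair -> offspring-genotype distribution table (pre-viability).

    ``rows[(mother, father)]`` maps each offspring genotype to its
    probability, after germline conversion and maternal carryover but before
    the viability filter.  Every row sums to 1.
    """

    architecture: str
    loci_config: str
    params: DriveParams
    genotypes: tuple
    rows: dict = field(repr=False)

    def row(self, mother, father) -> dict:
        return self.rows[(canonicalize(mother), canonicalize(father))]

    @property
    def index(self) -> dict:
        return {g: i for i, g in enumerate(self.genotypes)}

    def as_tensor(self) -> np.ndarray:
        """Dense (mother, father, offspring) probability tensor."""
        idx = self.index
        n = len(self.genotypes)
        T = np.zeros((n, n, n))
        for (m, f), dist in self.rows.items():
            i, j = idx[m], idx[f]
            for off, p in dist.items():
                T[i, j, idx[off]] = p
        return T

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (genotype_to_string(m), genotype_to_string(f), genotype_to_string(o), p)
            for (m, f), dist in self.rows.items()
            for o, p in dist.items()
        ]
        return pd.DataFrame(
            recs, columns=["mother_genotype", "father_genotype", "offspring_genotype", "probability"]
        )


def _cross(mother_gametes: dict, father_gametes: dict, n_loci: int) -> dict:
    out: dict[tuple, float] = {}
    for gm, pm in mother_gametes.items():
        for gf, pf in father_gametes.items():
            z = tuple(_canon_pair((gm[k], gf[k])) for k in range(n_loci))
            out[z] = out.get(z, 0.0) + pm * pf
    return out


def build_cube(architecture: str, loci_config: str, params: DriveParams) -> InheritanceCube:
    """Construct the full inheritance cube for an architecture.

    For every (mother, father) genotype pair the offspring distribution is
    the outer product of parental gamete distributions followed by maternal
    carryover; rows sum to 1 and are deterministic given the parameters.
    """
    _check_arch_params(architecture, params)
    genotypes = enumerate_genotypes(architecture, loci_config)
    n_loci = len(locus_roles(architecture, loci_config))

    gam_f = {g: gamete_distribution(g, "F", params, architecture, loci_config) for g in genotypes}
    gam_m = {g: gamete_distribution(g, "M", params, architecture, loci_config) for g in genotypes}
    carryover_active = {g: _germline_active(g, architecture, loci_config) for g in genotypes}

    rows = {}
    for mother in genotypes:
        for father in genotypes:
            zygotes = _cross(gam_f[mother], gam_m[father], n_loci)
            if carryover_active[mother] and params.d_F > 0:
                adjusted: dict[tuple, float] = {}
                for z, pz in zygotes.items():
                    for z2, p2 in apply_maternal_carryover(
                        z, mother, params, architecture, loci_config
                    ).items():
                        adjusted[z2] = adjusted.get(z2, 0.0) + pz * p2
                zygotes = adjusted
            rows[(mother, father)] = zygotes
    return InheritanceCube(architecture, loci_config, params, genotypes, rows)


def mendelian_cube(architecture: str, loci_config: str) -> InheritanceCube:
    """Pure Mendelian cube (all cleavage and carryover zero)."""
    return build_cube(architecture, loci_config, DriveParams())


def validate_cube(cube: InheritanceCube, atol: float = 1e-12) -> list[str]:
    """Check structural invariants; returns a list of violations (empty on pass).

    Checks row sums (1 within ``atol``), entry non-negativity, and — when the
    cube's parameters have zero cleavage and carryover — exact agreement with
    the independently built Mendelian cube.
    """
    violations = []
    for (m, f), dist in cube.rows.items():
        s = sum(dist.values())
        if abs(s - 1.0) > atol:
            violations.append(
                f"row {genotype_to_string(m)} x {genotype_to_string(f)} sums to {s:.12f}"
            )
        for off, p in dist.items():
            if p < 0:
                violations.append(
                    f"negative probability {p} for offspring {genotype_to_string(off)} "
                    f"of {genotype_to_string(m)} x {genotype_to_string(f)}"
                )
    p = cube.params
    if p.c_F == p.c_M == p.d_F == 0.0:
        ref = mendelian_cube(cube.architecture, cube.loci_config)
        for key, dist in cube.rows.items():
            rdist = ref.rows[key]
            keys = set(dist) | set(rdist)
            if any(abs(dist.get(k, 0.0) - rdist.get(k, 0.0)) > atol for k in keys):
                m, f = key
                violations.append(
                    f"zero-cleavage row {genotype_to_string(m)} x {genotype_to_string(f)} "
                    "deviates from Mendelian inheritance"
                )
    return violations
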