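"""Inheritance-cube construction: gametes, carryover, viability, cubes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genedrive.genetics import (
    DriveParams,
    FitnessModel,
    apply_maternal_carryover,
    build_cube,
    carries_allele,
    enumerate_genotypes,
    gamete_distribution,
    genotype_from_string,
    genotype_to_string,
    mendelian_cube,
    validate_cube,
    viability_and_fitness,
    wildtype_genotype,
)

HW = genotype_from_string("H/W")
WW = genotype_from_string("W/W")

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestGametes:
    @pytest.mark.parametrize(
        "params, expected",
        [
            # perfect drive limit
            (dict(c_F=1.0, ch_F=1.0), {("H",): 1.0}),
            # Mendelian limit
            (dict(c_F=0.0), {("H",): 0.5, ("W",): 0.5}),
            # four-branch enumeration
            (
                dict(c_F=0.99, ch_F=0.90, cr_F=0.005),
                {("H",): 0.9455, ("W",): 0.005, ("R",): 0.0002475, ("B",): 0.0492525},
            ),
        ],
    )
    def test_trans_heterozygous_female_branching(self, params, expected):
        d = gamete_distribution(HW, "F", DriveParams(**params), "homer")
        assert d == pytest.approx(expected, abs=1e-12)
        assert sum(d.values()) == pytest.approx(1.0)

    def test_resistant_alleles_transmit_unchanged(self):
        p = DriveParams(c_F=0.9, ch_F=0.5, cr_F=0.5)
        d = gamete_distribution(genotype_from_string("H/R"), "F", p, "homer")
        assert d == pytest.approx({("H",): 0.5, ("R",): 0.5})

    def test_cas9_locus_segregates_mendelianly(self):
        p = DriveParams(c_F=1.0, ch_F=1.0)
        d = gamete_distribution(genotype_from_string("H/W;C/c0"), "F", p, "homer", "two_locus")
        assert d == pytest.approx({("H", "C"): 0.5, ("H", "c0"): 0.5})

    def test_split_drive_without_cas9_is_mendelian(self):
        p = DriveParams(c_F=1.0, ch_F=1.0)
        d = gamete_distribution(genotype_from_string("H/W;c0/c0"), "F", p, "homer", "two_locus")
        assert d == pytest.approx({("H", "c0"): 0.5, ("W", "c0"): 0.5})

    def test_clvr_target_cleaved_without_homing(self):
        p = DriveParams(c_F=1.0, cr_F=0.25)
        d = gamete_distribution(genotype_from_string("H/h0;W/W"), "F", p, "clvr")
        # both cassette alleles segregate; every W is cleaved to R or B
        assert d == pytest.approx(
            {("H", "R"): 0.125, ("H", "B"): 0.375, ("h0", "R"): 0.125, ("h0", "B"): 0.375}
        )

    def test_monte_carlo_sampler_matches_analytic(self, rng):
        """Independent gamete sampler agrees within 3 binomial SE."""
        p = DriveParams(c_F=0.95, ch_F=0.8, cr_F=0.1)
        n = 100_000
        counts = {"H": 0, "W": 0, "R": 0, "B": 0}
        for allele in rng.choice(["H", "W"], size=n):
            if allele == "W":
                if rng.random() < p.c_F:
                    if rng.random() < p.ch_F:
                        allele = "H"
                    else:
                        allele = "R" if rng.random() < p.cr_F else "B"
            counts[allele] += 1
        d = gamete_distribution(HW, "F", p, "homer")
        for sym, prob in d.items():
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(counts[sym[0]] / n - prob) < 3 * se + 1e-9

    @given(c=probs, ch=probs, cr=probs)
    @settings(max_examples=50, deadline=None)
    def test_homing_transmission_closed_form(self, c, ch, cr):
        """Drive transmission from an active heterozygote is 0.5(1 + c*ch)."""
        d = gamete_distribution(HW, "F", DriveParams(c_F=c, ch_F=ch, cr_F=cr), "homer")
        assert d.get(("H",), 0.0) == pytest.approx(0.5 * (1 + c * ch))
        assert sum(d.values()) == pytest.approx(1.0)


class TestMaternalCarryover:
    def test_inactive_mother_leaves_zygote_unchanged(self):
        p = DriveParams(d_F=1.0)
        assert apply_maternal_carryover(WW, WW, p, "homer") == {WW: 1.0}

    def test_full_deposition_destroys_all_w(self):
        p = DriveParams(d_F=1.0, dr_F=0.0)
        out = apply_maternal_carryover(WW, HW, p, "homer")
        assert out == pytest.approx({genotype_from_string("B/B"): 1.0})

    def test_single_w_branching(self):
        p = DriveParams(d_F=0.95, dr_F=0.0)
        out = apply_maternal_carryover(HW, HW, p, "homer")
        assert out == pytest.approx(
            {HW: 0.05, genotype_from_string("H/B"): 0.95}
        )

    def test_non_w_alleles_never_modified(self):
        p = DriveParams(d_F=1.0, dr_F=0.3)
        z = genotype_from_string("R/B")
        assert apply_maternal_carryover(z, HW, p, "homer") == {z: 1.0}


class TestViabilityFitness:
    def test_homer_lof_homozygote_unviable(self):
        viable, _ = viability_and_fitness(genotype_from_string("B/B"), "homer", DriveParams())
        assert not viable

    def test_homer_rescue_with_cost(self):
        viable, mult = viability_and_fitness(
            genotype_from_string("H/B"), "homer", DriveParams(s_F=0.05)
        )
        assert viable and mult == pytest.approx(0.95)

    def test_clvr_rescue_rule(self):
        p = DriveParams(s_F=0.05)
        no_rescue = genotype_from_string("h0/h0;B/B")
        rescued = genotype_from_string("H/h0;B/B")
        assert viability_and_fitness(no_rescue, "clvr", p)[0] is False
        v, mult = viability_and_fitness(rescued, "clvr", p)
        assert v and mult == pytest.approx(0.95)  # Cas9-carrying female cost

    def test_hgd_always_viable_with_carrier_cost(self):
        p = DriveParams(s_F=0.20)
        v, mult = viability_and_fitness(genotype_from_string("B/B"), "hgd", p)
        assert v and mult == pytest.approx(0.80)
        v, mult = viability_and_fitness(HW, "hgd", p)
        assert v and mult == pytest.approx(0.80)
        v, mult = viability_and_fitness(WW, "hgd", p)
        assert v and mult == pytest.approx(1.0)


class TestBuildCube:
    def test_zero_cleavage_reduces_to_mendelian(self):
        for arch in ("homer", "hgd", "tare"):
            cube = build_cube(arch, "one_locus", DriveParams())
            ref = mendelian_cube(arch, "one_locus")
            assert cube.rows == ref.rows

    def test_ideal_clvr_heterozygous_mother_kills_half(self):
        p = DriveParams(c_F=1.0, c_M=1.0, d_F=1.0)
        cube = build_cube("clvr", "one_locus", p)
        fit = FitnessModel("clvr", "one_locus", p)
        row = cube.row(genotype_from_string("H/h0;W/W"), genotype_from_string("h0/h0;W/W"))
        dead = sum(pr for g, pr in row.items() if not fit.viable(g))
        assert dead == pytest.approx(0.5)

    def test_fitted_carrier_marginal(self, fitted_cube_1l):
        row = fitted_cube_1l.row(HW, WW)
        carrier = sum(p for g, p in row.items() if carries_allele(g, "H"))
        assert carrier == pytest.approx(0.5 + 0.5 * 0.992 * 0.995)

    def test_nonhoming_rejects_hdr(self):
        with pytest.raises(ValueError, match="non-homing"):
            build_cube("clvr", "one_locus", DriveParams(ch_F=0.5))
        with pytest.raises(ValueError, match="non-homing"):
            build_cube("tare", "one_locus", DriveParams(ch_M=0.1))

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="architecture"):
            build_cube("zpg", "one_locus", DriveParams())
        with pytest.raises(ValueError, match="loci_config"):
            build_cube("homer", "three_locus", DriveParams())

    def test_export_schema(self, mendelian_cube_1l):
        df = mendelian_cube_1l.to_frame()
        assert list(df.columns) == [
            "mother_genotype", "father_genotype", "offspring_genotype", "probability",
        ]
        sums = df.groupby(["mother_genotype", "father_genotype"])["probability"].sum()
        assert np.allclose(sums, 1.0)


class TestValidateCube:
    def test_mendelian_cube_passes(self, mendelian_cube_1l):
        assert validate_cube(mendelian_cube_1l) == []

    def test_corrupted_row_reported(self, mendelian_cube_1l):
        import copy

        bad = copy.deepcopy(mendelian_cube_1l)
        key = next(iter(bad.rows))
        first = next(iter(bad.rows[key]))
        bad.rows[key][first] -= 0.1
        report = validate_cube(bad)
        assert report and any("sums to" in v for v in report)

    @given(
        c_F=probs, c_M=probs, ch_F=probs, ch_M=probs,
        cr=probs, d=probs, dr=probs, s=probs,
    )
    @settings(max_examples=25, deadline=None)
    def test_random_parameters_always_valid(self, c_F, c_M, ch_F, ch_M, cr, d, dr, s):
        """Rows sum to 1 and stay non-negative over the whole unit cube."""
        p = DriveParams(c_F=c_F, c_M=c_M, ch_F=ch_F, ch_M=ch_M,
                        cr_F=cr, cr_M=cr, d_F=d, dr_F=dr, s_F=s)
        assert validate_cube(build_cube("homer", "one_locus", p)) == []

    @pytest.mark.parametrize("arch,loci", [
        ("homer", "two_locus"), ("hgd", "one_locus"),
        ("clvr", "one_locus"), ("tare", "one_locus"),
    ])
    def test_all_architectures_valid_at_presets(self, arch, loci):
        from genedrive.presets import preset_parameters

        name = {"homer": "ideal_homer", "hgd": "ideal_hgd",
                "clvr": "ideal_clvr", "tare": "ideal_tare"}[arch]
        assert validate_cube(build_cube(arch, loci, preset_parameters(name))) == []


def test_genotype_string_round_trip():
    for arch, loci in [("homer", "two_locus"), ("clvr", "two_locus")]:
        for g in enumerate_genotypes(arch, loci):
            assert genotype_from_string(genotype_to_string(g)) == g


def test_canonicalization_is_order_insensitive():
    assert genotype_from_string("W/H") == genotype_from_string("H/W")
    assert genotype_to_string(genotype_from_string("W/H;c0/C")) == "H/W;C/c0"


def test_drive_params_rejects_out_of_range():
    with pytest.raises(ValueError, match="c_F"):
        DriveParams(c_F=1.5)
    with pytest.raises(ValueError, match="s_F"):
        DriveParams(s_F=-0.1)


def test_wildtype_genotype_carries_nothing():
    for arch in ("homer", "clvr"):
        for loci in ("one_locus", "two_locus"):
            g = wildtype_genotype(arch, loci)
            assert not carries_allele(g, "H") and not carries_allele(g, "C")
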