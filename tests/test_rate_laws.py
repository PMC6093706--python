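"""Rate laws against literal transcriptions of the published equations.

The oracles below re-code each rate law exactly as printed — per-j
competition sums s_Bj, s'_Bj, explicit Km_Ax [B_j] and [Ax][B_j]
denominator terms — independently of the aggregate (AE, AE', s_I)
representation the package evaluates.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoswitch import (
    DonorParams,
    KineticParams,
    ReactionParams,
    SiteConstants,
    apparent_km,
    competition_sums,
    inhibition_sum_factorized,
    ki_pairs_from_sites,
    rate_compulsory_order,
    rate_inhibited,
    rate_random_order,
    rate_single_inhibited,
)

from conftest import random_concs, random_kinetics


# ---------------------------------------------------------------------------
# literal oracles

def oracle_random_order(j, donor, concs, params):
    """Per-competitor form with explicit own-substrate terms."""
    e = params.edges[j]
    own = params.site(e.substrate, e.site)
    s_bj = sum(concs[s.species] / s.Km for s in params.sites
               if s.Km is not None and (s.species, s.site) != (e.substrate, e.site))
    s_bj_p = sum(concs[s.species] / s.Ks for s in params.sites
                 if s.Ks is not None and (s.species, s.site) != (e.substrate, e.site))
    km_ax = donor.Ks * e.Km / own.Ks
    a, b = donor.conc, concs[e.substrate]
    den = (donor.Ks * e.Km * (1 + s_bj_p) + e.Km * a * (1 + s_bj)
           + km_ax * b + a * b)
    return e.Vmax * a * b / den


def oracle_compulsory_order(j, donor, concs, params):
    """Quasi-steady-state compulsory-order law, as printed."""
    e = params.edges[j]
    own = params.site(e.substrate, e.site)
    s_bj = sum(concs[s.species] / s.Km for s in params.sites
               if s.Km is not None and (s.species, s.site) != (e.substrate, e.site))
    km_ax = donor.Ks * e.Km / own.Ks
    a, b = donor.conc, concs[e.substrate]
    den = donor.Ks * e.Km * (1 + s_bj) + e.Km * a + km_ax * b + a * b
    return e.Vmax * a * b / den


def oracle_inhibited(j, donor, concs, params):
    """Per-competitor inhibited form with the double-sum s_I."""
    e = params.edges[j]
    own = params.site(e.substrate, e.site)
    s_bj = sum(concs[s.species] / s.Km for s in params.sites
               if s.Km is not None and (s.species, s.site) != (e.substrate, e.site))
    s_bj_p = sum(concs[s.species] / s.Ks for s in params.sites
                 if s.Ks is not None and (s.species, s.site) != (e.substrate, e.site))
    s_i = sum(
        (concs[k.species] / k.KI) * (concs[i.species] / i.Ks)
        for k in params.sites if k.KI is not None
        for i in params.sites if i.Ks is not None
    )
    km_ax = donor.Ks * e.Km / own.Ks
    a, b = donor.conc, concs[e.substrate]
    den = (donor.Ks * e.Km * (1 + s_bj_p + s_i) + e.Km * a * (1 + s_bj)
           + km_ax * b + a * b)
    return e.Vmax * a * b / den


def eq9_sixteen_terms(concs):
    """The diantennary inhibition sum written out term by term."""
    b1, b2, b3, b4 = concs["B1"], concs["B2"], concs["B3"], concs["B4"]
    ks11, ks21 = 0.05, 0.05    # B1, sites 1 and 2
    ks12, ks13 = 0.002, 0.1    # B2, B3
    ki12, ki13 = 0.02, 20.0    # B2, B3
    ki14, ki24 = 20.0, 20.0    # B4, sites 1 and 2
    return (
        b4 / ki14 * b1 / ks11 + b4 / ki24 * b1 / ks11
        + b3 / ki13 * b1 / ks11 + b2 / ki12 * b1 / ks11
        + b4 / ki14 * b1 / ks21 + b4 / ki24 * b1 / ks21
        + b3 / ki13 * b1 / ks21 + b2 / ki12 * b1 / ks21
        + b4 / ki14 * b2 / ks12 + b4 / ki24 * b2 / ks12
        + b3 / ki13 * b2 / ks12 + b2 / ki12 * b2 / ks12
        + b4 / ki14 * b3 / ks13 + b4 / ki24 * b3 / ks13
        + b3 / ki13 * b3 / ks13 + b2 / ki12 * b3 / ks13
    )


# ---------------------------------------------------------------------------
# competition sums

class TestCompetitionSums:
    def test_zero_concentrations_give_zero_sums(self, table1_sites):
        concs = {s: 0.0 for s in ("B1", "B2", "B3", "B4")}
        cs = competition_sums(concs, table1_sites)
        assert cs.AE == cs.AEprime == cs.sI == 0.0

    def test_galt_sI_matches_sixteen_term_transcription(self, table1_sites):
        rng = np.random.default_rng(11)
        for _ in range(25):
            concs = {s: float(10 ** rng.uniform(-2, 0.5))
                     for s in ("B1", "B2", "B3", "B4")}
            cs = competition_sums(concs, table1_sites)
            assert cs.sI == pytest.approx(eq9_sixteen_terms(concs), rel=1e-12)

    def test_double_sum_equals_factorised_product(self, table1_sites):
        rng = np.random.default_rng(7)
        for _ in range(100):
            concs = {s: float(10 ** rng.uniform(-3, 1))
                     for s in ("B1", "B2", "B3", "B4")}
            cs = competition_sums(concs, table1_sites)
            assert cs.sI == pytest.approx(
                inhibition_sum_factorized(concs, table1_sites), rel=1e-12)

    def test_single_species_symmetric_constants(self):
        sites = (SiteConstants("B", 0, Ks=0.05, KI=0.05),)
        cs = competition_sums({"B": 0.1}, sites)
        assert cs.sI == pytest.approx(4.0, rel=1e-14)

    def test_missing_concentration_raises(self, table1_sites):
        with pytest.raises(ValueError, match="B4"):
            competition_sums({"B1": 0.1, "B2": 0.1, "B3": 0.1}, table1_sites)


# ---------------------------------------------------------------------------
# rate laws vs literal transcriptions

class TestRepresentationEquivalence:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_random_order_matches_literal_form(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(40):
            donor, params, species = random_kinetics(rng, n)
            concs = random_concs(rng, species)
            for j in params.edges:
                v = rate_random_order(j, donor, concs, params)
                assert v == pytest.approx(
                    oracle_random_order(j, donor, concs, params), rel=1e-12)

    def test_compulsory_order_matches_literal_form(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            donor, params, species = random_kinetics(rng, 3)
            concs = random_concs(rng, species)
            for j in params.edges:
                v = rate_compulsory_order(j, donor, concs, params)
                assert v == pytest.approx(
                    oracle_compulsory_order(j, donor, concs, params), rel=1e-12)

    def test_inhibited_matches_literal_form(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            donor, params, species = random_kinetics(rng, 3, with_ki=True)
            concs = random_concs(rng, species)
            for j in params.edges:
                v = rate_inhibited(j, donor, concs, params)
                assert v == pytest.approx(
                    oracle_inhibited(j, donor, concs, params), rel=1e-12)

    def test_inhibited_without_pairs_reduces_to_random_order(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            donor, params, species = random_kinetics(rng, 2)
            concs = random_concs(rng, species)
            for j in params.edges:
                assert rate_inhibited(j, donor, concs, params, ki_pairs=()) \
                    == pytest.approx(rate_random_order(j, donor, concs, params),
                                     rel=1e-14)

    def test_huge_ki_recovers_uninhibited_rate(self):
        rng = np.random.default_rng(51)
        donor, params, species = random_kinetics(rng, 2)
        sites = tuple(
            SiteConstants(s.species, s.site, Km=s.Km, Ks=s.Ks, KI=1e12)
            for s in params.sites)
        params_inh = KineticParams(edges=params.edges, sites=sites)
        for _ in range(20):
            concs = random_concs(rng, species)
            for j in params.edges:
                v_inh = rate_inhibited(j, donor, concs, params_inh)
                v_ref = rate_random_order(j, donor, concs, params)
                assert v_inh == pytest.approx(v_ref, rel=1e-6)


class TestRateLawProperties:
    def test_saturating_donor_reduces_to_acceptor_only_law(self):
        """As [Ax] -> infinity the random-order law loses its donor terms."""
        rng = np.random.default_rng(61)
        for _ in range(20):
            donor, params, species = random_kinetics(rng, 2)
            concs = random_concs(rng, species)
            sat = DonorParams(Ks=donor.Ks, conc=1e9 * donor.Ks)
            for j in params.edges:
                e = params.edges[j]
                s_bj = sum(concs[s.species] / s.Km for s in params.sites
                           if s.Km is not None
                           and (s.species, s.site) != (e.substrate, e.site))
                b = concs[e.substrate]
                limit = e.Vmax * b / (e.Km * (1 + s_bj) + b)
                assert rate_random_order(j, sat, concs, params) \
                    == pytest.approx(limit, rel=1e-6)

    def test_label_symmetry_of_identical_acceptors(self):
        site = dict(Km=0.3, Ks=0.07)
        params = KineticParams(
            edges={
                "e1": ReactionParams("e1", "B1", 0, Vmax=2.0, Km=0.3),
                "e2": ReactionParams("e2", "B2", 0, Vmax=2.0, Km=0.3),
            },
            sites=(SiteConstants("B1", 0, **site), SiteConstants("B2", 0, **site)),
        )
        donor = DonorParams(Ks=0.5, conc=1.0)
        concs = {"B1": 0.2, "B2": 0.2}
        assert rate_random_order("e1", donor, concs, params) \
            == pytest.approx(rate_random_order("e2", donor, concs, params),
                             rel=1e-14)

    @pytest.mark.parametrize("law", [rate_random_order, rate_compulsory_order,
                                     rate_inhibited])
    def test_rates_bounded_by_vmax(self, law):
        rng = np.random.default_rng(71)
        for _ in range(30):
            donor, params, species = random_kinetics(rng, 3, with_ki=True)
            concs = random_concs(rng, species)
            for j in params.edges:
                v = law(j, donor, concs, params)
                assert 0.0 <= v < params.edges[j].Vmax

    @pytest.mark.parametrize("law", [rate_random_order, rate_compulsory_order])
    def test_adding_competitor_never_increases_rate(self, law):
        rng = np.random.default_rng(81)
        for _ in range(30):
            donor, params, species = random_kinetics(rng, 3)
            concs = random_concs(rng, species)
            lowered = dict(concs)
            lowered[species[-1]] = 0.0
            v_with = law("e1", donor, concs, params)
            v_without = law("e1", donor, lowered, params)
            assert v_with <= v_without + 1e-15

    def test_competitive_suppression_lessens_with_donor(self):
        """For compulsory order the competition penalty shrinks as [Ax] grows."""
        rng = np.random.default_rng(91)
        donor, params, species = random_kinetics(rng, 3)
        concs = random_concs(rng, species)
        alone = dict(concs)
        for sp in species[1:]:
            alone[sp] = 0.0
        ratios = []
        for mult in (0.5, 5.0, 50.0):
            d = DonorParams(Ks=donor.Ks, conc=mult * donor.Ks)
            ratios.append(rate_compulsory_order("e1", d, concs, params)
                          / rate_compulsory_order("e1", d, alone, params))
        assert ratios[0] < ratios[1] < ratios[2] <= 1.0 + 1e-12


class TestSingleSubstrateInhibited:
    # the published 1-D constants (donor Michaelis constant as Ks_Ax)
    P = dict(Vmax=1.0, Ka=0.6, Kb=0.1, Ks_Ax=0.6, KI=0.05)

    def test_zero_acceptor_gives_zero_rate(self):
        assert rate_single_inhibited(a=0.6, b=0.0, **self.P) == 0.0

    def test_published_tangency_point_value(self):
        """v(0.10755) with the published constants, denominator
        0.12 + 1.2 b + 12 b^2; the mapped external level b* + v/K
        reproduces the printed upper fold parameter."""
        b = 0.10755
        v = rate_single_inhibited(a=0.6, b=b, **self.P)
        den = 0.12 + 1.2 * b + 12 * b * b
        assert v == pytest.approx(0.6 * b / den, rel=1e-14)
        assert v == pytest.approx(0.16637, abs=5e-6)
        assert b + v / 0.075 == pytest.approx(2.32585, abs=5e-5)

    def test_single_interior_maximum(self):
        bs = np.linspace(1e-6, 5.0, 20000)
        vs = np.array([rate_single_inhibited(a=0.6, b=float(b), **self.P)
                       for b in bs])
        signs = np.sign(np.diff(vs))
        # exactly one sign change of the derivative on (0, inf)
        changes = np.flatnonzero(signs[:-1] * signs[1:] < 0)
        assert len(changes) == 1

    def test_agrees_with_general_law_at_n_equal_one(self):
        rng = np.random.default_rng(101)
        for _ in range(20):
            km, ks, ki = (float(10 ** rng.uniform(-2, 1)) for _ in range(3))
            vmax = float(10 ** rng.uniform(-1, 1))
            ks_ax = float(10 ** rng.uniform(-1, 1))
            a = float(10 ** rng.uniform(-1, 1))
            b = float(10 ** rng.uniform(-2, 0.5))
            params = KineticParams(
                edges={"e1": ReactionParams("e1", "B", 0, Vmax=vmax, Km=km)},
                sites=(SiteConstants("B", 0, Km=km, Ks=ks, KI=ki),),
            )
            donor = DonorParams(Ks=ks_ax, conc=a)
            v_general = rate_inhibited("e1", donor, {"B": b}, params)
            # the n=1 reduction has Km_Ax = Ks_Ax Km / Ks and a b^2
            # coefficient Km_Ax / KI
            km_ax = ks_ax * km / ks
            den = (ks_ax * km + km * a + km_ax * b
                   + (km_ax / ki) * b * b + a * b)
            assert v_general == pytest.approx(vmax * a * b / den, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rate_single_inhibited(a=-0.1, b=0.1, **self.P)
        with pytest.raises(ValueError):
            rate_single_inhibited(a=0.1, b=-0.1, **self.P)


class TestApparentKm:
    def test_two_sites_is_geometric_mean(self):
        assert apparent_km([0.25, 0.45]) == pytest.approx(
            math.sqrt(0.25 * 0.45), rel=1e-10)
        assert apparent_km([0.25, 0.45]) == pytest.approx(0.335410, abs=5e-7)

    def test_identical_sites_for_two(self):
        assert apparent_km([0.3, 0.3]) == pytest.approx(0.3, rel=1e-12)

    def test_three_sites_against_dense_scan(self):
        kms = [0.1, 0.2, 0.4]
        root = apparent_km(kms)

        def g(k):
            return sum(k / (km + k) for km in kms) - 1.0

        grid = np.arange(1e-6, 0.5, 1e-6)
        vals = np.array([g(k) for k in grid])
        idx = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        assert len(idx) == 1
        assert abs(root - grid[idx[0]]) < 2e-6
        assert abs(g(root)) < 1e-12

    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scaling_and_bounds_for_two_sites(self, k1, k2, c):
        km = apparent_km([k1, k2])
        assert min(k1, k2) - 1e-12 <= km <= max(k1, k2) + 1e-12
        assert apparent_km([c * k1, c * k2]) == pytest.approx(c * km, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            apparent_km([])
        with pytest.raises(ValueError):
            apparent_km([0.1, -0.2])
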