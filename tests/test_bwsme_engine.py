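"""Block-WSME enumeration, energetics, ensemble, and calibration."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sodscape import bwsme_engine as bw
from sodscape import structure_contacts as sc

from conftest import random_contact_system, toy_variant


# ---------------------------------------------------------------------------
# independent oracles


def bitstring_states(n):
    """Exhaustive enumeration over all 2^n folded/unfolded strings, keeping
    configurations with at most two islands and doubling two-island ones."""
    out = []
    for bits in itertools.product([0, 1], repeat=n):
        islands = []
        i = 0
        while i < n:
            if bits[i]:
                j = i
                while j + 1 < n and bits[j + 1]:
                    j += 1
                islands.append((i, j))
                i = j + 1
            else:
                i += 1
        if len(islands) <= 1:
            out.append((tuple(islands), False))
        elif len(islands) == 2:
            out.append((tuple(islands), False))
            out.append((tuple(islands), True))
    return out


def direct_free_energy(islands, interacting, cm, q, bs, vs, p):
    """Term-by-term free energy, summed straight over contacts and residues
    (no block matrices, no prefix sums)."""
    r2b = bs.residue_to_block()
    folded_blocks = set()
    block_island = {}
    for isl_idx, (s, e) in enumerate(islands):
        for b in range(s, e + 1):
            folded_blocks.add(b)
            block_island[b] = isl_idx

    def active(i, j):
        bi, bj = r2b[i], r2b[j]
        if bi not in folded_blocks or bj not in folded_blocks:
            return False
        return block_island[bi] == block_island[bj] or interacting

    solv = p.dCp * ((p.T - p.T_ref) - p.T * math.log(p.T / p.T_ref))
    total = 0.0
    for i, j, n_ij in cm.contacts:
        if active(i, j):
            total += n_ij * p.xi + n_ij * solv
    kappa = bw.debye_kappa(p.ionic_strength, p.effective_dielectric, p.T)
    charged = sorted(q.charges)
    for a, i in enumerate(charged):
        for j in charged[a + 1:]:
            if j - i < cm.min_separation or not active(i, j):
                continue
            r = float(np.linalg.norm(q.centroids[i] - q.centroids[j]))
            total += (
                bw.COULOMB_KCAL * q.charges[i] * q.charges[j]
                / (p.effective_dielectric * r) * math.exp(-kappa * r)
                * bw.KCAL_TO_J
            )
    positions = list(range(1, bs.n_residues + 1))
    dS = vs.entropy_map(positions, p)
    for r in range(bs.n_residues):
        if r2b[r] in folded_blocks:
            total -= p.T * dS[r]
    return total


def direct_ensemble(cm, q, bs, vs, p):
    """Exhaustive direct summation of Z, P_fold, and F(n)."""
    nb = bs.n_blocks
    RT = p.R * p.T
    r2b = bs.residue_to_block()
    Z = 0.0
    pf = np.zeros(bs.n_residues)
    by_n = {}
    for islands, inter in bitstring_states(nb):
        w = math.exp(-direct_free_energy(islands, inter, cm, q, bs, vs, p) / RT)
        Z += w
        folded = {b for s, e in islands for b in range(s, e + 1)}
        by_n[sum(e - s + 1 for s, e in islands)] = (
            by_n.get(sum(e - s + 1 for s, e in islands), 0.0) + w
        )
        for r in range(bs.n_residues):
            if r2b[r] in folded:
                pf[r] += w
    profile = np.full(nb + 1, np.inf)
    for n, w in by_n.items():
        profile[n] = -RT * math.log(w)
    return Z, pf / Z, profile


# ---------------------------------------------------------------------------
# enumeration and counting


class TestEnumeration:
    def test_single_block_has_two_states(self):
        states = list(bw.enumerate_microstates(1))
        assert len(states) == 2
        assert states[0].islands == ()
        assert states[1].islands == ((0, 0),)

    def test_three_blocks_has_nine_states(self):
        assert len(list(bw.enumerate_microstates(3))) == 9
        assert len(bitstring_states(3)) == 9

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6, 7, 8])
    def test_stream_matches_exhaustive_bitstring_oracle(self, n):
        got = sorted(
            (s.islands, s.interacting) for s in bw.enumerate_microstates(n)
        )
        assert got == sorted(bitstring_states(n))

    @given(st.integers(min_value=1, max_value=60))
    @settings(max_examples=25, deadline=None)
    def test_closed_form_count_equals_stream_length(self, n):
        assert bw.count_microstates(n) == sum(
            1 for _ in bw.enumerate_microstates(n)
        )

    def test_no_duplicate_states(self):
        states = [(s.islands, s.interacting) for s in bw.enumerate_microstates(7)]
        assert len(states) == len(set(states))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            bw.count_microstates(0)
        with pytest.raises(ValueError):
            next(bw.enumerate_microstates(0))


# ---------------------------------------------------------------------------
# microstate free energy


class TestMicrostateFreeEnergy:
    def test_fully_unfolded_state_is_reference_zero(self):
        cm, q, bs, vs, p = random_contact_system(1)
        m = bw.Microstate(islands=())
        assert bw.microstate_free_energy(m, cm, q, bs, vs, p) == 0.0

    def test_energy_entropy_cancellation_by_construction(self):
        # one block of 3 residues, a single n_ij=1 contact, T = T_ref:
        # xi chosen equal to T * sum(dS) makes dF vanish exactly
        bs = bw.BlockScheme.from_block_length(3, 3)
        cm = sc.ContactMap(3, [(0, 2, 1)], cutoff=6.0, min_separation=2)
        q = sc.ChargeSet(charges={})
        vs = bw.VariantScheme("holo", loop_zn=(1, 1), loop_cu=(2, 2))
        T = 298.0
        xi = T * (-13.6) * 3
        p = bw.EnergyParams(xi=xi, T=T, T_ref=T)
        m = bw.Microstate(islands=((0, 0),))
        assert bw.microstate_free_energy(m, cm, q, bs, vs, p) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_matches_spreadsheet_style_direct_summation(self):
        # 4-block toy, hand-built 5-contact map, charges included
        bs = bw.BlockScheme.from_block_length(12, 3)
        contacts = [(0, 3, 2), (0, 5, 1), (2, 7, 4), (4, 9, 3), (8, 11, 5)]
        cm = sc.ContactMap(12, contacts, cutoff=6.0, min_separation=2)
        rng = np.random.default_rng(11)
        centroids = {k: rng.normal(scale=8.0, size=3) for k in (1, 6, 10)}
        q = sc.ChargeSet(charges={1: -1.0, 6: 1.0, 10: 1.0}, centroids=centroids)
        vs = bw.VariantScheme("apo", loop_zn=(4, 6), loop_cu=(10, 12))
        p = bw.EnergyParams(xi=-250.0)
        for m in bw.enumerate_microstates(4):
            expected = direct_free_energy(m.islands, m.interacting, cm, q, bs, vs, p)
            got = bw.microstate_free_energy(m, cm, q, bs, vs, p)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-9)

    def test_cross_island_contacts_need_interacting_flag(self):
        bs = bw.BlockScheme.from_block_length(9, 3)
        cm = sc.ContactMap(9, [(0, 8, 2)], cutoff=6.0, min_separation=2)
        q = sc.ChargeSet(charges={})
        vs = bw.VariantScheme("holo", loop_zn=(1, 1), loop_cu=(2, 2))
        p = bw.EnergyParams(xi=-500.0, T_ref=298.0)
        off = bw.Microstate(islands=((0, 0), (2, 2)), interacting=False)
        on = bw.Microstate(islands=((0, 0), (2, 2)), interacting=True)
        dF_off = bw.microstate_free_energy(off, cm, q, bs, vs, p)
        dF_on = bw.microstate_free_energy(on, cm, q, bs, vs, p)
        assert dF_off - dF_on == pytest.approx(2 * 500.0)

    def test_solvation_vanishes_at_reference_temperature(self):
        cm, q, bs, vs, p = random_contact_system(5)
        p_ref = replace(p, T_ref=p.T)
        p_ref2 = replace(p_ref, dCp=-5.0)
        m = bw.Microstate(islands=((0, bs.n_blocks - 1),))
        assert bw.microstate_free_energy(
            m, cm, q, bs, vs, p_ref
        ) == pytest.approx(
            bw.microstate_free_energy(m, cm, q, bs, vs, p_ref2), rel=1e-12
        )

    def test_size_mismatch_rejected(self):
        cm = sc.ContactMap(6, [(0, 3, 1)], cutoff=6.0, min_separation=2)
        bs = bw.BlockScheme.from_block_length(9, 3)
        q = sc.ChargeSet(charges={})
        vs = bw.VariantScheme("holo", loop_zn=(1, 1), loop_cu=(2, 2))
        with pytest.raises(ValueError):
            bw.microstate_free_energy(
                bw.Microstate(islands=()), cm, q, bs, vs, bw.EnergyParams()
            )


# ---------------------------------------------------------------------------
# ensemble


class TestEnsemble:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_direct_summation(self, seed):
        cm, q, bs, vs, p = random_contact_system(seed)
        res = bw.ensemble(cm, q, bs, vs, p)
        Z, pf, profile = direct_ensemble(cm, q, bs, vs, p)
        assert res.Z == pytest.approx(Z, rel=1e-12)
        np.testing.assert_allclose(res.P_fold, pf, rtol=1e-11, atol=1e-14)
        fin = np.isfinite(profile)
        np.testing.assert_allclose(
            res.profile[fin], profile[fin], rtol=1e-10
        )

    def test_entropy_only_landscape_stays_unfolded(self, two_loop):
        p = bw.EnergyParams(xi=0.0)
        res = bw.ensemble(
            two_loop["cm"], two_loop["q"], two_loop["bs"], toy_variant("holo"), p
        )
        assert np.all(res.P_fold < 0.5)

    def test_probabilities_bounded_and_profile_consistent(self, two_loop):
        from scipy.special import logsumexp

        p = bw.EnergyParams(xi=-2000.0)
        res = bw.ensemble(
            two_loop["cm"], two_loop["q"], two_loop["bs"], toy_variant("apo"), p
        )
        assert np.all((res.P_fold >= 0.0) & (res.P_fold <= 1.0))
        assert np.all((res.P_matrix >= 0.0) & (res.P_matrix <= 1.0))
        fin = np.isfinite(res.profile)
        lse = logsumexp(-res.profile[fin] / (p.R * p.T))
        assert lse == pytest.approx(res.log_Z, rel=1e-10)

    def test_apo_partition_function_never_exceeds_holo(self, two_loop):
        p = bw.EnergyParams(xi=-1500.0)
        z = {
            v: bw.ensemble(
                two_loop["cm"], two_loop["q"], two_loop["bs"], toy_variant(v), p
            ).log_Z
            for v in ("holo", "apo")
        }
        assert z["apo"] <= z["holo"]

    def test_pfold_monotone_in_stabilizing_xi(self, two_loop):
        prev = None
        for xi in (-1200.0, -1800.0, -2400.0):
            res = bw.ensemble(
                two_loop["cm"], two_loop["q"], two_loop["bs"],
                toy_variant("holo"), bw.EnergyParams(xi=xi),
            )
            if prev is not None:
                assert np.all(res.P_fold >= prev - 1e-12)
            prev = res.P_fold

    def test_variant_ordering_at_fixed_xi(self, two_loop):
        p = bw.EnergyParams(xi=-2100.0)
        mean_pf = {
            v: float(
                np.mean(
                    bw.ensemble(
                        two_loop["cm"], two_loop["q"], two_loop["bs"],
                        toy_variant(v), p,
                    ).P_fold
                )
            )
            for v in bw.VARIANT_NAMES
        }
        assert mean_pf["apo"] <= mean_pf["cu_bound"] <= mean_pf["holo"]
        assert mean_pf["apo"] <= mean_pf["zn_bound"] <= mean_pf["holo"]


# ---------------------------------------------------------------------------
# stability and calibration


class TestStability:
    def _result_with_profile(self, profile):
        n = len(profile) - 1
        return bw.LandscapeResult(
            log_Z=0.0, P_fold=np.zeros(1), profile=np.asarray(profile, float),
            P_matrix=np.zeros((1, n + 1)), n_blocks=n,
        )

    def test_constructed_two_state_profile(self):
        # minima at n=0 and n=2 differing by 10 kJ/mol, high barrier between
        res = self._result_with_profile([0.0, 60_000.0, -10_000.0])
        p = bw.EnergyParams()
        assert bw.stability(res, p) == pytest.approx(10_000.0, rel=1e-6)

    def test_monotone_profile_uses_end_state_fallback(self):
        res = self._result_with_profile([0.0, -5_000.0, -20_000.0])
        assert bw.stability(res, bw.EnergyParams()) == pytest.approx(20_000.0)

    def test_zero_xi_gives_negative_stability(self, two_loop):
        p = bw.EnergyParams(xi=0.0)
        res = bw.ensemble(
            two_loop["cm"], two_loop["q"], two_loop["bs"], toy_variant("holo"), p
        )
        assert bw.stability(res, p) < 0

    def test_matches_basin_sums_from_direct_oracle(self):
        cm, q, bs, vs, p = random_contact_system(7)
        res = bw.ensemble(cm, q, bs, vs, p)
        _, _, profile = direct_ensemble(cm, q, bs, vs, p)
        oracle = self._result_with_profile(profile)
        assert bw.stability(res, p) == pytest.approx(
            bw.stability(oracle, p), rel=1e-9
        )


class TestCalibration:
    def test_calibrated_xi_reproduces_target_stability(self, two_loop):
        vs = toy_variant("holo")
        p = bw.EnergyParams()
        xi = bw.calibrate_xi(
            two_loop["cm"], two_loop["q"], two_loop["bs"], vs, p,
            target_stability=25_000.0,
        )
        res = bw.ensemble(
            two_loop["cm"], two_loop["q"], two_loop["bs"], vs,
            replace(p, xi=xi),
        )
        assert bw.stability(res, replace(p, xi=xi)) == pytest.approx(
            25_000.0, abs=1.0
        )

    def test_bad_bracket_raises_with_guidance(self, two_loop):
        with pytest.raises(ValueError, match="bracket"):
            bw.calibrate_xi(
                two_loop["cm"], two_loop["q"], two_loop["bs"],
                toy_variant("holo"), bw.EnergyParams(),
                bracket=(-10.0, 0.0),
            )
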