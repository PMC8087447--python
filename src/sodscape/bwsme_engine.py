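"""Block Wako-Saito-Munoz-Eaton (bWSME) folding-landscape engine.

Each block of consecutive residues is folded (1) or unfolded (0).  The
ensemble is restricted to microstates with at most two folded islands:

* the fully unfolded state,
* single-sequence states (one contiguous folded island),
* double-sequence states (two islands separated by >= 1 unfolded block),
  each counted twice -- once with the islands non-interacting and once with
  cross-island native interactions switched on.

This gives exactly ``2*C(n+1, 4) + C(n+1, 2) + 1`` microstates for ``n``
blocks: 461,826 for the 49-block SOD1 chain versus >42.7 million at the
residue level.

The free energy of a microstate relative to the fully unfolded reference is

    dF = sum_active n_ij * [xi + dCp*((T - T_ref) - T*ln(T/T_ref))]
       + sum_active screened-Coulomb(q_i, q_j, r_ij)
       - T * sum_folded dS(residue)

where a contact or charge pair is *active* iff both residues sit in folded
blocks that belong to the same island, or to two islands of an interacting
double-sequence state.  Statistical weights exp(-dF/RT) are accumulated in
log space into the partition function, per-residue folding probabilities,
the free-energy profile F(n structured blocks), and the folding-probability
matrix P(residue folded | n blocks).

Metal occupancy enters purely through conformational entropy: the Zn-binding
loop (residues 49-82 in SOD1) and the Cu-binding loop (121-142) pay an excess
entropic penalty when their metal is absent.  Iso-stability calibration then
finds, per variant, the mean van der Waals energy per atomic contact xi that
makes the folded basin 25 kJ/mol more stable than the unfolded basin at 298 K,
so that variants differ only in their folding mechanism, not their stability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy.special import logsumexp

from sodscape.structure_contacts import ChargeSet, ContactMap

logger = logging.getLogger(__name__)

R_GAS = 8.314  # J mol^-1 K^-1
KCAL_TO_J = 4184.0
COULOMB_KCAL = 332.0637  # kcal mol^-1 A e^-2

# Debye screening constant: kappa^2 = 2*NA*e^2*(1000*I) / (eps0*eps_r*kB*T)
_E_CHARGE = 1.602176634e-19
_N_AVOGADRO = 6.02214076e23
_K_BOLTZMANN = 1.380649e-23
_EPS0 = 8.8541878128e-12


def debye_kappa(ionic_strength: float, eps_r: float, T: float) -> float:
    """Inverse Debye length in A^-1 for ionic strength in mol/L."""
    if ionic_strength <= 0:
        return 0.0
    kappa_sq = (
        2.0
        * _N_AVOGADRO
        * _E_CHARGE**2
        * (1000.0 * ionic_strength)
        / (_EPS0 * eps_r * _K_BOLTZMANN * T)
    )
    return math.sqrt(kappa_sq) * 1e-10  # m^-1 -> A^-1


@dataclass(frozen=True)
class BlockScheme:
    """Contiguous partition of the chain into folding blocks.

    ``boundaries[k]:boundaries[k+1]`` are the 0-based residue positions of
    block k.  Default construction uses floor division with the remainder
    merged into the terminal block; an explicit boundary list reproduces any
    reference blocking.
    """

    n_residues: int
    boundaries: tuple[int, ...]  # length n_blocks + 1, starts 0, ends n_residues

    @classmethod
    def from_block_length(cls, n_residues: int, block_length: int = 3) -> "BlockScheme":
        if n_residues < 1 or block_length < 1:
            raise ValueError("n_residues and block_length must be >= 1")
        n_blocks = max(1, n_residues // block_length)
        bounds = [k * block_length for k in range(n_blocks)] + [n_residues]
        return cls(n_residues=n_residues, boundaries=tuple(bounds))

    @classmethod
    def from_boundaries(cls, boundaries: list[int]) -> "BlockScheme":
        return cls(n_residues=boundaries[-1], boundaries=tuple(boundaries))

    def __post_init__(self) -> None:
        b = self.boundaries
        if b[0] != 0 or b[-1] != self.n_residues or any(
            b[k] >= b[k + 1] for k in range(len(b) - 1)
        ):
            raise ValueError("block boundaries must be increasing and cover the chain")

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries) - 1

    def residue_to_block(self) -> np.ndarray:
        out = np.empty(self.n_residues, dtype=int)
        for k in range(self.n_blocks):
            out[self.boundaries[k] : self.boundaries[k + 1]] = k
        return out

    def block_sizes(self) -> np.ndarray:
        b = np.asarray(self.boundaries)
        return b[1:] - b[:-1]


@dataclass(frozen=True)
class Microstate:
    """0, 1, or 2 inclusive block ranges; ``interacting`` is meaningful only
    for 2-island states."""

    islands: tuple[tuple[int, int], ...]
    interacting: bool = False

    def __post_init__(self) -> None:
        if len(self.islands) < 2 and self.interacting:
            raise ValueError("interacting flag requires two islands")
        if len(self.islands) == 2:
            (s1, e1), (s2, e2) = self.islands
            if not (s1 <= e1 < s2 - 1 and s2 <= e2):
                raise ValueError("islands must be disjoint with a gap >= 1 block")

    def n_folded_blocks(self) -> int:
        return sum(e - s + 1 for s, e in self.islands)


@dataclass
class EnergyParams:
    """Energetic parameters of the model (all energies J mol^-1).

    xi: mean van der Waals stabilization per atomic native contact.
    dCp: heat-capacity change per native contact (J mol^-1 K^-1).
    T_ref: solvation reference temperature (K).
    dS_conf: conformational entropy per folded residue (J mol^-1 K^-1).
    dS_loop: excess entropy for disordered metal-binding loops.
    """

    xi: float = -40.0
    dCp: float = -0.36
    T_ref: float = 385.0
    dS_conf: float = -13.6
    dS_loop: float = -19.7
    ionic_strength: float = 0.1
    effective_dielectric: float = 29.0
    T: float = 298.0
    R: float = R_GAS
    per_pair_xi: bool = False  # if True, xi counts each residue pair once

    def __post_init__(self) -> None:
        if self.dCp > 0 or self.dS_conf > 0 or self.dS_loop > 0:
            raise ValueError("dCp and entropy values must be <= 0")
        if self.T <= 0 or self.T_ref <= 0:
            raise ValueError("temperatures must be positive")

    def solvation_per_contact(self) -> float:
        T, Tr = self.T, self.T_ref
        return self.dCp * ((T - Tr) - T * math.log(T / Tr))


# SOD1 loop definitions (1-based residue numbering)
LOOP_IV = (49, 82)  # Zn-binding loop
LOOP_VII = (121, 142)  # Cu-binding (electrostatic) loop

VARIANT_NAMES = ("holo", "zn_bound", "cu_bound", "apo")


@dataclass
class VariantScheme:
    """Per-residue conformational entropy map for a metal-occupancy variant.

    The metal-free loops pay ``dS_loop`` per residue instead of ``dS_conf``:
    holo orders both loops, zn_bound orders only the Zn loop, cu_bound only
    the Cu loop, apo neither.  Prolines are always assigned zero entropy.
    """

    name: str
    loop_zn: tuple[int, int] = LOOP_IV
    loop_cu: tuple[int, int] = LOOP_VII
    prolines: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"variant must be one of {VARIANT_NAMES}")

    def disordered_loops(self) -> list[tuple[int, int]]:
        loops = []
        if self.name in ("cu_bound", "apo"):
            loops.append(self.loop_zn)  # Zn absent -> Zn loop disordered
        if self.name in ("zn_bound", "apo"):
            loops.append(self.loop_cu)  # Cu absent -> Cu loop disordered
        return loops

    def entropy_map(self, residue_positions: list[int], p: EnergyParams) -> np.ndarray:
        """Entropy dS per residue (J mol^-1 K^-1) for 1-based positions."""
        dS = np.full(len(residue_positions), p.dS_conf, dtype=float)
        for lo, hi in self.disordered_loops():
            for k, pos in enumerate(residue_positions):
                if lo <= pos <= hi:
                    dS[k] = p.dS_loop
        for k, pos in enumerate(residue_positions):
            if pos in self.prolines:
                dS[k] = 0.0
        return dS


@dataclass
class LandscapeResult:
    """Partition function, per-residue P_fold, free-energy profile F(n), and
    the residue-by-n folding probability matrix."""

    log_Z: float
    P_fold: np.ndarray  # (n_residues,)
    profile: np.ndarray  # (n_blocks + 1,) F(n) in J/mol; F relative to unfolded
    P_matrix: np.ndarray  # (n_residues, n_blocks + 1)
    n_blocks: int
    variant: str = ""

    @property
    def Z(self) -> float:
        return math.exp(self.log_Z)


def count_microstates(n_units: int) -> int:
    """Closed-form microstate count 2*C(n+1,4) + C(n+1,2) + 1."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return 2 * math.comb(n_units + 1, 4) + math.comb(n_units + 1, 2) + 1


def enumerate_microstates(n_blocks: int) -> Iterator[Microstate]:
    """Deterministic lexicographic stream of all restricted microstates."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    yield Microstate(islands=())
    for s1 in range(n_blocks):
        for e1 in range(s1, n_blocks):
            yield Microstate(islands=((s1, e1),))
    for s1 in range(n_blocks):
        for e1 in range(s1, n_blocks):
            for s2 in range(e1 + 2, n_blocks):
                for e2 in range(s2, n_blocks):
                    for inter in (False, True):
                        yield Microstate(
                            islands=((s1, e1), (s2, e2)), interacting=inter
                        )


# ---------------------------------------------------------------------------
# energy evaluation


def _block_matrices(
    cm: ContactMap,
    q: ChargeSet,
    bs: BlockScheme,
    vs: VariantScheme,
    p: EnergyParams,
    residue_positions: list[int] | None = None,
):
    """Precompute the symmetric block-pair interaction matrix M (J/mol),
    its 2-D prefix sum, its diagonal cumulative sum, and the per-block
    entropy penalty cumulative sum."""
    if cm.n_residues != bs.n_residues:
        raise ValueError(
            f"contact map has {cm.n_residues} residues but block scheme {bs.n_residues}"
        )
    nb = bs.n_blocks
    r2b = bs.residue_to_block()
    M = np.zeros((nb, nb), dtype=float)

    solv = p.solvation_per_contact()
    for i, j, n_ij in cm.contacts:
        mult = 1.0 if p.per_pair_xi else float(n_ij)
        e = mult * p.xi + n_ij * solv
        a, b = r2b[i], r2b[j]
        M[a, b] += e
        if a != b:
            M[b, a] += e

    if q.charges:
        kappa = debye_kappa(p.ionic_strength, p.effective_dielectric, p.T)
        idx = sorted(q.charges)
        for ii, i in enumerate(idx):
            for j in idx[ii + 1 :]:
                if j - i < cm.min_separation:
                    continue
                r_ij = float(np.linalg.norm(q.centroids[i] - q.centroids[j]))
                if r_ij <= 0:
                    continue
                e_kcal = (
                    COULOMB_KCAL
                    * q.charges[i]
                    * q.charges[j]
                    / (p.effective_dielectric * r_ij)
                    * math.exp(-kappa * r_ij)
                )
                e = e_kcal * KCAL_TO_J
                a, b = r2b[i], r2b[j]
                M[a, b] += e
                if a != b:
                    M[b, a] += e

    positions = residue_positions or list(range(1, bs.n_residues + 1))
    dS = vs.entropy_map(positions, p)
    # entropy penalty per block: -T * sum(dS) over residues in the block
    block_pen = np.zeros(nb)
    for k in range(nb):
        lo, hi = bs.boundaries[k], bs.boundaries[k + 1]
        block_pen[k] = -p.T * dS[lo:hi].sum()

    P2 = np.zeros((nb + 1, nb + 1))
    P2[1:, 1:] = np.cumsum(np.cumsum(M, axis=0), axis=1)
    diag_cum = np.concatenate([[0.0], np.cumsum(np.diag(M))])
    pen_cum = np.concatenate([[0.0], np.cumsum(block_pen)])
    return P2, diag_cum, pen_cum


def _rect(P2: np.ndarray, a1, a2, b1, b2):
    """Submatrix sum of M over rows a1..a2, cols b1..b2 (inclusive)."""
    return P2[a2 + 1, b2 + 1] - P2[a1, b2 + 1] - P2[a2 + 1, b1] + P2[a1, b1]


def _island_energy(P2, diag_cum, s, e):
    # sum over ordered pairs a<=b within [s, e] of M[a, b]
    full = _rect(P2, s, e, s, e)
    diag = diag_cum[e + 1] - diag_cum[s]
    return 0.5 * (full + diag)


def microstate_free_energy(
    m: Microstate,
    cm: ContactMap,
    q: ChargeSet,
    bs: BlockScheme,
    vs: VariantScheme,
    p: EnergyParams,
    residue_positions: list[int] | None = None,
) -> float:
    """Free energy (J/mol) of one microstate relative to the unfolded state."""
    P2, diag_cum, pen_cum = _block_matrices(cm, q, bs, vs, p, residue_positions)
    e = 0.0
    for s, t in m.islands:
        e += _island_energy(P2, diag_cum, s, t) + (pen_cum[t + 1] - pen_cum[s])
    if m.interacting and len(m.islands) == 2:
        (s1, e1), (s2, e2) = m.islands
        e += _rect(P2, s1, e1, s2, e2)
    return e


def _state_arrays(n_blocks: int):
    """All microstates as parallel arrays (s1, e1, s2, e2, interacting);
    -1 sentinels where an island is absent.  Enumeration order matches
    :func:`enumerate_microstates`."""
    s1l, e1l, s2l, e2l, intl = [], [], [], [], []
    for st in enumerate_microstates(n_blocks):
        if not st.islands:
            s1l.append(-1); e1l.append(-1); s2l.append(-1); e2l.append(-1)
        elif len(st.islands) == 1:
            (a, b), = st.islands
            s1l.append(a); e1l.append(b); s2l.append(-1); e2l.append(-1)
        else:
            (a, b), (c, d) = st.islands
            s1l.append(a); e1l.append(b); s2l.append(c); e2l.append(d)
        intl.append(st.interacting)
    return (
        np.array(s1l), np.array(e1l), np.array(s2l), np.array(e2l),
        np.array(intl, dtype=bool),
    )


def ensemble(
    cm: ContactMap,
    q: ChargeSet,
    bs: BlockScheme,
    vs: VariantScheme,
    p: EnergyParams,
    residue_positions: list[int] | None = None,
) -> LandscapeResult:
    """Accumulate the restricted ensemble into landscape observables.

    All weights are handled in log space; the fully unfolded state has
    weight 1 by construction (dF = 0)."""
    P2, diag_cum, pen_cum = _block_matrices(cm, q, bs, vs, p, residue_positions)
    nb = bs.n_blocks
    s1, e1, s2, e2, inter = _state_arrays(nb)

    dF = np.zeros(len(s1))
    has1 = s1 >= 0
    has2 = s2 >= 0

    def island_vec(s, e, mask):
        out = np.zeros(len(s))
        ss, ee = s[mask], e[mask]
        full = (
            P2[ee + 1, ee + 1] - P2[ss, ee + 1] - P2[ee + 1, ss] + P2[ss, ss]
        )
        diag = diag_cum[ee + 1] - diag_cum[ss]
        out[mask] = 0.5 * (full + diag) + (pen_cum[ee + 1] - pen_cum[ss])
        return out

    dF += island_vec(s1, e1, has1)
    dF += island_vec(s2, e2, has2)
    cross = has2 & inter
    if cross.any():
        a1, b1, a2, b2 = s1[cross], e1[cross], s2[cross], e2[cross]
        dF[cross] += (
            P2[b1 + 1, b2 + 1] - P2[a1, b2 + 1] - P2[b1 + 1, a2] + P2[a1, a2]
        )

    RT = p.R * p.T
    logw = -dF / RT
    log_Z = float(logsumexp(logw))
    w = np.exp(logw - log_Z)  # normalized weights

    # per-block folding probability via difference arrays
    diff = np.zeros(nb + 1)
    for s, e, mask in ((s1, e1, has1), (s2, e2, has2)):
        np.add.at(diff, s[mask], w[mask])
        np.add.at(diff, e[mask] + 1, -w[mask])
    p_block = np.cumsum(diff[:nb])

    r2b = bs.residue_to_block()
    P_fold = np.clip(p_block[r2b], 0.0, 1.0)

    # free-energy profile over n structured blocks
    nf = np.where(has1, e1 - s1 + 1, 0) + np.where(has2, e2 - s2 + 1, 0)
    log_by_n = np.full(nb + 1, -np.inf)
    np.logaddexp.at(log_by_n, nf, logw)
    profile = np.where(np.isfinite(log_by_n), -RT * log_by_n, np.inf)

    # P(residue folded | n structured blocks)
    diff2 = np.zeros((nb + 1, nb + 1))
    for s, e, mask in ((s1, e1, has1), (s2, e2, has2)):
        np.add.at(diff2, (nf[mask], s[mask]), w[mask])
        np.add.at(diff2, (nf[mask], e[mask] + 1), -w[mask])
    block_by_n = np.cumsum(diff2[:, :nb], axis=1)
    w_by_n = np.exp(log_by_n - log_Z)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(w_by_n[:, None] > 0, block_by_n / w_by_n[:, None], 0.0)
    P_matrix = np.clip(cond[:, r2b].T, 0.0, 1.0)  # (n_residues, nb+1)

    return LandscapeResult(
        log_Z=log_Z,
        P_fold=P_fold,
        profile=profile,
        P_matrix=P_matrix,
        n_blocks=nb,
        variant=vs.name,
    )


def stability(res: LandscapeResult, p: EnergyParams) -> float:
    """Folding stability dG_NU = F(unfolded basin) - F(folded basin), J/mol.

    Basins are split at the highest interior maximum of the profile F(n);
    with no interior barrier the end states F(0) and F(n_max) are used."""
    F = res.profile
    RT = p.R * p.T
    n = len(F) - 1
    finite = np.isfinite(F)
    interior = np.arange(1, n)
    interior = interior[finite[interior]]
    split = None
    if interior.size:
        k = interior[np.argmax(F[interior])]
        if F[k] > F[0] and F[k] > F[n]:
            split = int(k)
    if split is None:
        logger.info("no interior barrier in profile; using end-state fallback")
        return float(F[0] - F[n])
    lo = np.arange(0, split)
    hi = np.arange(split + 1, n + 1)
    lo = lo[finite[lo]]
    hi = hi[finite[hi]]
    F_U = -RT * logsumexp(-F[lo] / RT)
    F_F = -RT * logsumexp(-F[hi] / RT)
    return float(F_U - F_F)


def calibrate_xi(
    cm: ContactMap,
    q: ChargeSet,
    bs: BlockScheme,
    vs: VariantScheme,
    p: EnergyParams,
    target_stability: float = 25_000.0,
    bracket: tuple[float, float] = (-12_000.0, 0.0),
    tol: float = 1.0,
    max_iter: int = 200,
    residue_positions: list[int] | None = None,
) -> float:
    """Deterministic bisection for the xi that yields the target stability.

    Stability is monotonically increasing as xi becomes more negative; the
    bracket must produce a sign change of (stability - target)."""

    def g(xi: float) -> float:
        res = ensemble(cm, q, bs, vs, replace(p, xi=xi), residue_positions)
        return stability(res, p) - target_stability

    lo, hi = bracket
    g_lo, g_hi = g(lo), g(hi)
    if abs(g_lo) < tol:
        return lo
    if abs(g_hi) < tol:
        return hi
    if g_lo * g_hi > 0:
        raise ValueError(
            f"no sign change in bracket {bracket}: g({lo})={g_lo:.1f}, "
            f"g({hi})={g_hi:.1f}; widen the bracket"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        if abs(g_mid) < tol:
            return mid
        if g_lo * g_mid < 0:
            hi, g_hi = mid, g_mid
        else:
            lo, g_lo = mid, g_mid
    return 0.5 * (lo + hi)


def early_folding_region(
    res: LandscapeResult, n_quantile: float = 0.25, top_fraction: float = 0.3
) -> set[int]:
    """Residues (0-based positions) that fold earliest along the reaction
    coordinate: the top ``top_fraction`` of residues by conditional folding
    probability at n = round(n_quantile * n_blocks) structured blocks."""
    n = max(1, int(round(n_quantile * res.n_blocks)))
    col = res.P_matrix[:, n]
    k = max(1, int(round(top_fraction * len(col))))
    order = np.argsort(-col, kind="stable")
    return set(int(i) for i in order[:k])


def region_overlap(a: set[int], b: set[int]) -> float:
    """Jaccard overlap between two residue sets."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
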