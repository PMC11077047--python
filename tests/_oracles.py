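"""Independent brute-force oracles used to cross-check the solvers.

The equilibrium oracle shares no algebra with the package: DNA complexes
are built by explicit enumeration of every site-by-site configuration
(each of the n_s dimer-sites empty or occupied by a dimer in a specific
zinc state), and the two conservation unknowns are found by plain nested
bisection on log-transformed brackets.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

N_SITES_ZN = 6
_DECADES = 120.0


def _dna_configs(n_s: int) -> np.ndarray:
    """All site configurations: 0 = empty, 1..7 = dimer in zinc state 0..6."""
    return np.array(list(itertools.product(range(8), repeat=n_s)), dtype=int)


def _bisect_log(f, ln_hi: float, decades: float = _DECADES, iters: int = 120):
    """Root of increasing f on [ln_hi - decades*ln10, ln_hi] by bisection."""
    lo = ln_hi - decades * math.log(10.0)
    hi = ln_hi
    if f(math.exp(lo)) > 0:
        return math.exp(lo)
    if f(math.exp(hi)) < 0:
        return math.exp(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(math.exp(mid)) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-14:
            break
    return math.exp(0.5 * (lo + hi))


def brute_force_equilibrium(
    K_Zn: float,
    K_dna,
    n_s: int,
    P_total: float,
    D_total: float,
    L_value: float,
    zinc_mode: str = "total",
) -> dict:
    """Nested-bisection equilibrium solve with explicit DNA-state enumeration.

    Returns L_free, p_free (7-vector), d_m (complex concentrations by
    number of bound dimers) and bound_by_state.
    """
    K_dna = np.asarray(K_dna, dtype=float)
    cfgs = _dna_configs(n_s)
    occupied = cfgs > 0
    state_idx = np.where(occupied, cfgs - 1, 0)
    n_bound = occupied.sum(axis=1)
    zn_of_state = np.arange(N_SITES_ZN + 1)

    def species(L_free: float, p0: float):
        x = K_Zn * L_free
        p = np.array([p0 * math.comb(N_SITES_ZN, i) * x**i for i in range(N_SITES_ZN + 1)])
        site_w = np.where(occupied, (K_dna * p)[state_idx], 1.0)
        w = site_w.prod(axis=1)
        Zd = w.sum()
        d_cfg = D_total * w / Zd if D_total > 0 else np.zeros(len(w))
        return p, d_cfg

    def protein_used(L_free: float, p0: float) -> float:
        p, d_cfg = species(L_free, p0)
        return p.sum() + float((d_cfg * n_bound).sum())

    def solve_p0(L_free: float) -> float:
        if P_total == 0.0:
            return 0.0
        return _bisect_log(lambda p0: protein_used(L_free, p0) - P_total, math.log(P_total))

    def zinc_used(L_free: float) -> float:
        p0 = solve_p0(L_free)
        p, d_cfg = species(L_free, p0)
        zn_free_dimers = float((zn_of_state * p).sum())
        zn_cfg = np.where(occupied, zn_of_state[state_idx], 0).sum(axis=1)
        return zn_free_dimers + float((d_cfg * zn_cfg).sum())

    if zinc_mode == "free_clamped":
        L_free = L_value
    elif L_value == 0.0 or P_total == 0.0:
        L_free = 0.0 if P_total > 0 else L_value
    else:
        L_free = _bisect_log(lambda L: L + zinc_used(L) - L_value, math.log(L_value))

    p0 = solve_p0(L_free)
    p, d_cfg = species(L_free, p0)
    d_m = np.array([d_cfg[n_bound == m].sum() for m in range(n_s + 1)])
    bound_by_state = np.zeros(N_SITES_ZN + 1)
    for c, d in zip(cfgs, d_cfg):
        for site in c:
            if site > 0:
                bound_by_state[site - 1] += d
    return {"L_free": L_free, "p_free": p, "d_m": d_m, "bound_by_state": bound_by_state}


def wiseman_cumulative_bound(L_total: float, site_conc: float, K: float) -> float:
    """Closed-form 1:1 bound ligand for total ligand vs a single site pool."""
    b = L_total + site_conc + 1.0 / K
    return 0.5 * (b - math.sqrt(b * b - 4.0 * L_total * site_conc))


def draw_random_linkage(rng: np.random.Generator) -> dict:
    """One random parameter draw for the oracle-equivalence sweep."""
    K_Zn = 10 ** rng.uniform(9, 14)
    ks = np.sort(10 ** rng.uniform([2, 5, 5], [5, 10, 10]))
    K_low, K_4, K_6 = ks
    n_s = int(rng.integers(1, 4))
    k3 = math.sqrt(K_low * K_4)
    k5 = math.sqrt(K_4 * K_6)
    K_dna = (K_low, K_low, K_low, k3, K_4, k5, K_6)
    return {
        "K_Zn": K_Zn,
        "K_dna": K_dna,
        "n_s": n_s,
        "P_total": 10 ** rng.uniform(-9, -5),
        "D_total": 10 ** rng.uniform(-9, -5),
        "L_value": 10 ** rng.uniform(-9, -5),
    }
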