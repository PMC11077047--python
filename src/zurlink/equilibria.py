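"""Linked zinc-binding / DNA-binding equilibria of the Zur dimer.

The model couples two sets of equilibria:

* A Zur dimer carries six equivalent, independent regulatory zinc sites
  (per-site association constant ``K_Zn``).  A dimer with ``i`` zinc ions
  bound -- the state ``PL_i`` -- occurs with the binomial degeneracy
  ``C(6, i)``, so the free-dimer ensemble is
  ``p_i = p_0 * C(6, i) * (K_Zn * L_free)**i``.

* Each zinc-occupancy state ``PL_i`` binds one DNA dimer-site with its own
  association constant ``K_i`` (``K_0 <= ... <= K_6``; DNA binding is
  activated by zinc).  A DNA probe carries ``n_s`` independent, identical
  dimer-sites (2 for the znuA operator, 3 for zitB), so the probability
  that ``m`` of them are occupied is binomial in the site-binding weight
  ``s = sum_i K_i * p_i``:  ``d_m = D_total * C(n_s, m) * s**m / (1+s)**n_s``.

No explicit cooperativity between DNA-bound dimers is invoked; the entire
zinc -> DNA activation is carried by the ``K_i`` ladder.  Given totals of
dimer, DNA and zinc, the functions here solve mass conservation exactly and
return the full species composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "N_ZINC_SITES",
    "LinkageParams",
    "MixtureTotals",
    "SolveOptions",
    "SpeciesState",
    "EquilibriumError",
    "solve_state",
    "zinc_titration_profile",
    "protein_titration_profile",
]

#: Regulatory zinc sites per Zur dimer (three per protomer).
N_ZINC_SITES = 6

_BINOM_ZN = np.array([math.comb(N_ZINC_SITES, i) for i in range(N_ZINC_SITES + 1)], dtype=float)


class EquilibriumError(RuntimeError):
    """Raised when the mass-conservation solve fails to converge."""


@dataclass(frozen=True)
class LinkageParams:
    """Interaction constants of the coupled zinc/DNA binding model.

    Parameters
    ----------
    K_Zn
        Per-site zinc association constant of the dimer (M^-1).
    K_dna
        The seven DNA association constants ``K_0 .. K_6`` (M^-1), one per
        zinc-occupancy state ``PL_i`` of the dimer, for a single DNA
        dimer-site.  Must be non-negative and non-decreasing in ``i``.
    n_dna_sites
        Number of independent dimer-binding sites on the DNA probe
        (2 for znuA, 3 for zitB).
    """

    K_Zn: float
    K_dna: tuple[float, ...]
    n_dna_sites: int

    def __post_init__(self) -> None:
        if not self.K_Zn > 0:
            raise ValueError(f"K_Zn must be positive, got {self.K_Zn}")
        kd = tuple(float(k) for k in self.K_dna)
        if len(kd) != N_ZINC_SITES + 1:
            raise ValueError(f"K_dna must have {N_ZINC_SITES + 1} entries, got {len(kd)}")
        if any(k < 0 for k in kd):
            raise ValueError("all K_dna must be >= 0")
        if any(kd[i + 1] < kd[i] for i in range(N_ZINC_SITES)):
            raise ValueError("K_dna must be non-decreasing in zinc occupancy")
        if self.n_dna_sites not in (1, 2, 3):
            raise ValueError(f"n_dna_sites must be 1, 2 or 3, got {self.n_dna_sites}")
        object.__setattr__(self, "K_dna", kd)

    @classmethod
    def from_anchors(
        cls,
        *,
        K_4: float,
        K_6: float,
        K_low: float = 1e4,
        K_Zn: float = 2.3e13,
        n_dna_sites: int = 2,
        odd_state_rule: Literal["geometric", "previous"] = "geometric",
    ) -> "LinkageParams":
        """Build the full ``K_0..K_6`` ladder from the measurable anchors.

        ITC pins the DNA affinity of the 4-zinc state (``K_4``); the
        zinc-saturated affinity ``K_6`` is the model's free parameter; the
        low-occupancy states ``PL_0..PL_2`` are assigned the subtle affinity
        ``K_low`` (default 1e4 M^-1).  The odd states not anchored by any
        measurement are filled by *odd_state_rule*:

        - ``"geometric"`` (default): ``K_3 = sqrt(K_2*K_4)``,
          ``K_5 = sqrt(K_4*K_6)`` -- smooth monotone interpolation.
        - ``"previous"``: ``K_3 = K_2``, ``K_5 = K_4`` -- hold at the lower
          even state.
        """
        if odd_state_rule == "geometric":
            k3 = math.sqrt(K_low * K_4)
            k5 = math.sqrt(K_4 * K_6)
        elif odd_state_rule == "previous":
            k3, k5 = K_low, K_4
        else:
            raise ValueError(f"unknown odd_state_rule {odd_state_rule!r}")
        return cls(
            K_Zn=K_Zn,
            K_dna=(K_low, K_low, K_low, k3, K_4, k5, K_6),
            n_dna_sites=n_dna_sites,
        )


@dataclass(frozen=True)
class MixtureTotals:
    """Total concentrations defining a mixture (all molar).

    ``zinc_mode="total"`` treats ``L_value`` as total zinc and conserves it;
    ``zinc_mode="free_clamped"`` clamps free zinc at ``L_value`` (buffered
    zinc), in which case total zinc is an output, not an input.
    """

    P_total: float
    D_total: float
    L_value: float
    zinc_mode: Literal["total", "free_clamped"] = "total"

    def __post_init__(self) -> None:
        for name in ("P_total", "D_total", "L_value"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.zinc_mode not in ("total", "free_clamped"):
            raise ValueError(f"unknown zinc_mode {self.zinc_mode!r}")


@dataclass(frozen=True)
class SolveOptions:
    """Numerical controls for the mass-conservation solve."""

    rtol: float = 1e-12
    max_iter: int = 200
    #: decades below the analytic upper bound searched for each log unknown
    bracket_decades: float = 120.0

    def __post_init__(self) -> None:
        if not self.rtol > 0:
            raise ValueError("rtol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.bracket_decades > 0:
            raise ValueError("bracket_decades must be > 0")


@dataclass(frozen=True)
class SpeciesState:
    """Full equilibrium composition returned by :func:`solve_state`.

    ``p_free[i]`` is the concentration of the free dimer state ``PL_i``
    (binomial degeneracy included); ``d_complex[m]`` the concentration of
    DNA carrying ``m`` bound dimers; ``bound_by_state[i]`` the concentration
    of DNA-bound dimers that are in zinc state ``i``; ``site_occupancy`` the
    fraction of DNA dimer-sites occupied.
    """

    L_free: float
    p_free: np.ndarray
    d_complex: np.ndarray
    site_occupancy: float
    bound_by_state: np.ndarray
    P_total: float
    D_total: float
    L_total: float
    params: LinkageParams = field(repr=False)

    @property
    def dna_fractions(self) -> np.ndarray:
        """Fractions of total DNA with 0..n_s dimers bound (sums to 1)."""
        if self.D_total == 0:
            out = np.zeros_like(self.d_complex)
            out[0] = 1.0
            return out
        return self.d_complex / self.D_total

    @property
    def bound_dimer_total(self) -> float:
        """Total concentration of DNA-bound dimers."""
        return float(self.bound_by_state.sum())

    @property
    def zinc_bound(self) -> float:
        """Zinc held by free and DNA-bound dimers (M)."""
        i = np.arange(N_ZINC_SITES + 1)
        return float((i * self.p_free).sum() + (i * self.bound_by_state).sum())


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------


def _state_weights(params: LinkageParams, L_free: float) -> tuple[np.ndarray, float, float]:
    """Return (g, Z, sigma): unnormalized state weights g_i = C(6,i) x^i,
    the zinc-binding partition function Z = (1+x)^6 and the DNA-weight
    coefficient sigma = sum_i K_i g_i, with x = K_Zn * L_free."""
    x = params.K_Zn * L_free
    g = _BINOM_ZN * np.power(x, np.arange(N_ZINC_SITES + 1))
    Z = (1.0 + x) ** N_ZINC_SITES
    sigma = float(np.dot(np.asarray(params.K_dna), g))
    return g, Z, sigma


def _p0_single_class(
    Z: float, sigma: float, n_s: int, P_total: float, D_total: float
) -> float:
    """Closed-form p_0 from dimer conservation for one DNA site-class.

    P_T = p0*Z + D_T*n_s*(p0*sigma)/(1 + p0*sigma) is quadratic in p0:
    Z*sigma*p0^2 + (Z + sigma*(n_s*D_T - P_T))*p0 - P_T = 0.
    """
    if P_total == 0.0:
        return 0.0
    if sigma == 0.0 or D_total == 0.0:
        return P_total / Z
    a = Z * sigma
    b = Z + sigma * (n_s * D_total - P_total)
    disc = math.sqrt(b * b + 4.0 * a * P_total)
    if b >= 0.0:
        return 2.0 * P_total / (b + disc)
    return (disc - b) / (2.0 * a)


def _zinc_bound_at(params: LinkageParams, L_free: float, P_total: float, D_total: float) -> float:
    """Zinc sequestered by protein (free + DNA-bound) at a given free zinc."""
    g, Z, sigma = _state_weights(params, L_free)
    p0 = _p0_single_class(Z, sigma, params.n_dna_sites, P_total, D_total)
    i = np.arange(N_ZINC_SITES + 1)
    zn_free_dimers = p0 * float(np.dot(i, g))
    if sigma > 0.0 and D_total > 0.0 and p0 > 0.0:
        s = p0 * sigma
        theta = s / (1.0 + s)
        # bound dimers distribute over zinc states in proportion to K_i * g_i
        kg = np.asarray(params.K_dna) * g
        zn_bound_dimers = params.n_dna_sites * D_total * theta * float(np.dot(i, kg)) / sigma
    else:
        zn_bound_dimers = 0.0
    return zn_free_dimers + zn_bound_dimers


def _compose_state(
    params: LinkageParams,
    totals: MixtureTotals,
    L_free: float,
    L_total: float,
) -> SpeciesState:
    g, Z, sigma = _state_weights(params, L_free)
    n_s = params.n_dna_sites
    p0 = _p0_single_class(Z, sigma, n_s, totals.P_total, totals.D_total)
    p_free = p0 * g
    s = p0 * sigma
    theta = s / (1.0 + s) if s > 0 else 0.0
    m = np.arange(n_s + 1)
    binom_d = np.array([math.comb(n_s, int(mm)) for mm in m], dtype=float)
    if totals.D_total > 0:
        d_complex = totals.D_total * binom_d * s**m / (1.0 + s) ** n_s
    else:
        d_complex = np.zeros(n_s + 1)
    if s > 0 and totals.D_total > 0:
        kg = np.asarray(params.K_dna) * g
        bound_by_state = n_s * totals.D_total * theta * (p0 * kg) / s
    else:
        bound_by_state = np.zeros(N_ZINC_SITES + 1)
    return SpeciesState(
        L_free=L_free,
        p_free=p_free,
        d_complex=d_complex,
        site_occupancy=theta,
        bound_by_state=bound_by_state,
        P_total=totals.P_total,
        D_total=totals.D_total,
        L_total=L_total,
        params=params,
    )


def _check_conservation(state: SpeciesState, totals: MixtureTotals, opts: SolveOptions) -> None:
    if totals.D_total > 0:
        err_d = abs(state.d_complex.sum() - totals.D_total) / totals.D_total
        if err_d > 1e-10:
            raise EquilibriumError(f"DNA conservation violated (rel err {err_d:.2e})")
    if totals.P_total > 0:
        p_tot = state.p_free.sum() + state.bound_dimer_total
        err_p = abs(p_tot - totals.P_total) / totals.P_total
        if err_p > 1e-8:
            raise EquilibriumError(f"dimer conservation violated (rel err {err_p:.2e})")
    if totals.zinc_mode == "total" and totals.L_value > 0:
        err_l = abs(state.L_free + state.zinc_bound - totals.L_value) / totals.L_value
        if err_l > 1e-8:
            raise EquilibriumError(f"zinc conservation violated (rel err {err_l:.2e})")


def solve_state(
    params: LinkageParams,
    totals: MixtureTotals,
    opts: SolveOptions = SolveOptions(),
) -> SpeciesState:
    """Solve the coupled zinc/DNA equilibria for one mixture.

    In ``free_clamped`` mode free zinc is fixed at ``totals.L_value`` and
    only dimer conservation is solved (closed form).  In ``total`` mode the
    zinc-conservation residual is a strictly increasing function of free
    zinc, bracketed on a log grid and solved with Brent's method; the dimer
    balance is closed-form at every trial point.

    Returns the unique equilibrium composition; raises
    :class:`EquilibriumError` on non-convergence or conservation failure.
    """
    if totals.zinc_mode == "free_clamped":
        L_free = totals.L_value
        state = _compose_state(params, totals, L_free, L_free + _zinc_bound_at(params, L_free, totals.P_total, totals.D_total))
        _check_conservation(state, totals, opts)
        return state

    L_T = totals.L_value
    if L_T == 0.0 or totals.P_total == 0.0:
        # no zinc, or no protein to sequester it
        L_free = 0.0 if totals.P_total > 0 else L_T
        state = _compose_state(params, totals, L_free, L_T)
        _check_conservation(state, totals, opts)
        return state

    def residual(u: float) -> float:
        L = math.exp(u)
        return L + _zinc_bound_at(params, L, totals.P_total, totals.D_total) - L_T

    hi = math.log(L_T)
    lo = hi - opts.bracket_decades * math.log(10.0)
    if residual(lo) > 0:
        # essentially all zinc is free already at the bracket floor
        raise EquilibriumError("failed to bracket free zinc (pathological parameters)")
    try:
        u = brentq(residual, lo, hi, rtol=1e-15, maxiter=opts.max_iter)
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise EquilibriumError(f"free-zinc root find failed: {exc}") from exc
    L_free = math.exp(u)
    state = _compose_state(params, totals, L_free, L_T)
    _check_conservation(state, totals, opts)
    return state


# ---------------------------------------------------------------------------
# multi-site-class solve (used by the promoter-activation module)
# ---------------------------------------------------------------------------


def solve_multiclass(
    K_Zn: float,
    site_classes: Sequence[tuple[int, Sequence[float]]],
    P_total: float,
    D_total: float,
    L_value: float,
    zinc_mode: Literal["total", "free_clamped"] = "free_clamped",
    opts: SolveOptions = SolveOptions(),
) -> dict:
    """Solve the equilibrium with several independent DNA site classes.

    Each class ``(n_sites, K_dna)`` contributes ``n_sites`` identical,
    independent dimer-sites per DNA molecule with its own ``K_0..K_6``
    affinity ladder.  Returns a dict with ``L_free``, ``p_free`` (array),
    ``theta`` (per-class site occupancies), ``bound`` (per-class bound-dimer
    concentrations) and ``L_total``.
    """
    classes = [(int(n), np.asarray(K, dtype=float)) for n, K in site_classes]
    for n, K in classes:
        if len(K) != N_ZINC_SITES + 1:
            raise ValueError("each site class needs 7 affinities K_0..K_6")

    i_arr = np.arange(N_ZINC_SITES + 1)

    def inner(L_free: float) -> tuple[float, np.ndarray, list[float]]:
        """Solve dimer conservation at fixed free zinc; returns (p0, g, sigmas)."""
        x = K_Zn * L_free
        g = _BINOM_ZN * np.power(x, i_arr)
        Z = float(g.sum())
        sigmas = [float(np.dot(K, g)) for _, K in classes]
        if P_total == 0.0:
            return 0.0, g, sigmas

        def f(p0: float) -> float:
            tot = p0 * Z
            for (n, _), sig in zip(classes, sigmas):
                s = p0 * sig
                tot += D_total * n * s / (1.0 + s)
            return tot - P_total

        hi = P_total / Z
        if f(hi) <= 0:
            return hi, g, sigmas
        # solve on log(p0): brentq's absolute xtol is meaningless at the
        # ~1e-50 M scale p0 can reach when zinc loading is high
        u_hi = math.log(hi)
        u_lo = u_hi - opts.bracket_decades * math.log(10.0)
        if f(math.exp(u_lo)) > 0:
            raise EquilibriumError("failed to bracket free dimer")
        u = brentq(lambda uu: f(math.exp(uu)), u_lo, u_hi, rtol=1e-15, maxiter=10 * opts.max_iter)
        return math.exp(u), g, sigmas

    def zinc_bound(L_free: float) -> float:
        p0, g, sigmas = inner(L_free)
        zn = p0 * float(np.dot(i_arr, g))
        for (n, K), sig in zip(classes, sigmas):
            if sig > 0 and p0 > 0 and D_total > 0:
                s = p0 * sig
                theta = s / (1.0 + s)
                zn += n * D_total * theta * float(np.dot(i_arr, K * g)) / sig
        return zn

    if zinc_mode == "free_clamped":
        L_free = L_value
        L_total = L_free + zinc_bound(L_free)
    else:
        if L_value == 0.0 or P_total == 0.0:
            L_free, L_total = (0.0 if P_total > 0 else L_value), L_value
        else:
            def residual(u: float) -> float:
                L = math.exp(u)
                return L + zinc_bound(L) - L_value

            hi = math.log(L_value)
            lo = hi - opts.bracket_decades * math.log(10.0)
            if residual(lo) > 0:
                raise EquilibriumError("failed to bracket free zinc")
            L_free = math.exp(brentq(residual, lo, hi, rtol=1e-15, maxiter=opts.max_iter))
            L_total = L_value

    p0, g, sigmas = inner(L_free)
    thetas, bound = [], []
    for (n, K), sig in zip(classes, sigmas):
        s = p0 * sig
        theta = s / (1.0 + s) if s > 0 else 0.0
        thetas.append(theta)
        bound.append(n * D_total * theta)
    return {
        "L_free": L_free,
        "L_total": L_total,
        "p_free": p0 * g,
        "theta": np.array(thetas),
        "bound": np.array(bound),
    }


# ---------------------------------------------------------------------------
# titration profiles
# ---------------------------------------------------------------------------

import pandas as pd  # noqa: E402  (kept below the numerical core)

_FRACTION_COLUMNS = ["frac_free", "frac_1to1", "frac_2to1", "frac_3to1"]


def _fraction_row(state: SpeciesState) -> dict:
    fr = state.dna_fractions
    row = {col: 0.0 for col in _FRACTION_COLUMNS}
    for m, f in enumerate(fr):
        row[_FRACTION_COLUMNS[m]] = float(f)
    return row


def zinc_titration_profile(
    params: LinkageParams,
    P_total: float,
    D_total: float,
    zinc_grid: Sequence[float],
    zinc_mode: Literal["total", "free_clamped"] = "total",
    opts: SolveOptions = SolveOptions(),
) -> pd.DataFrame:
    """DNA-species fractions as a function of zinc.

    Returns one row per zinc value with columns ``zinc_total_M``,
    ``frac_free``, ``frac_1to1``, ``frac_2to1``, ``frac_3to1`` (fractions of
    total DNA; columns beyond ``n_dna_sites`` are zero).  The grid must be
    sorted ascending.
    """
    grid = [float(z) for z in zinc_grid]
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("zinc_grid must be sorted ascending")
    rows = []
    for z in grid:
        totals = MixtureTotals(P_total=P_total, D_total=D_total, L_value=z, zinc_mode=zinc_mode)
        try:
            state = solve_state(params, totals, opts)
        except EquilibriumError as exc:
            raise EquilibriumError(f"solve failed at zinc = {z:g} M: {exc}") from exc
        rows.append({"zinc_total_M": z, **_fraction_row(state)})
    return pd.DataFrame(rows)


def protein_titration_profile(
    params: LinkageParams,
    D_total: float,
    zinc_equivalents_per_dimer: float,
    molar_ratio_grid: Sequence[float],
    opts: SolveOptions = SolveOptions(),
) -> pd.DataFrame:
    """DNA-species fractions as the dimer:DNA molar ratio is raised.

    Zinc is co-titrated with the protein: at every grid point total zinc is
    ``zinc_equivalents_per_dimer * P_total`` (the Zur->DNA ITC design).
    Returns columns ``molar_ratio``, ``frac_free`` ... ``frac_3to1``.
    """
    rows = []
    for r in molar_ratio_grid:
        if r < 0:
            raise ValueError("molar ratios must be >= 0")
        P = float(r) * D_total
        totals = MixtureTotals(
            P_total=P,
            D_total=D_total,
            L_value=zinc_equivalents_per_dimer * P,
            zinc_mode="total",
        )
        try:
            state = solve_state(params, totals, opts)
        except EquilibriumError as exc:
            raise EquilibriumError(f"solve failed at molar ratio {r:g}: {exc}") from exc
        rows.append({"molar_ratio": float(r), **_fraction_row(state)})
    return pd.DataFrame(rows)
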