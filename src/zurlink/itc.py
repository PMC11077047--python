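"""Forward simulation and nonlinear fitting of integrated ITC isotherms.

Covers the binding systems used in the Zur study:

``single_class``
    n identical, independent sites per macromolecule (the workhorse model
    used to quantify stoichiometry, affinity and enthalpy).
``three_site``
    three site classes x 2 sites per dimer with separate constants, used
    to probe how much affinity heterogeneity a monophasic curve tolerates.
``competitive``
    the exact Zn/EGTA displacement system: titrant zinc arrives pre-bound
    to a chelator that is present at the same concentration in syringe and
    cell, and the protein strips it; the single-class fit of such a curve
    yields the *apparent* affinity, which :func:`chelator_correction`
    converts to the intrinsic one.
``dna_oligomer``
    Zur (carrying a fixed number of zinc equivalents per dimer) titrated
    into DNA, using the full linked-equilibria model of
    :mod:`zurlink.equilibria`.

All heats are kcal per mole of injectant, exothermic negative; all
concentrations molar; volumes in litres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

from .equilibria import (
    EquilibriumError,
    LinkageParams,
    MixtureTotals,
    solve_state,
)

__all__ = [
    "TitrationProtocol",
    "SingleClassSystem",
    "ThreeSiteSystem",
    "CompetitiveSystem",
    "DnaOligomerSystem",
    "BindingSystem",
    "Isotherm",
    "FitResult",
    "FitError",
    "simulate_isotherm",
    "fit_isotherm",
    "chelator_correction",
    "apparent_from_intrinsic",
    "conditional_chelator_constant",
    "monophasicity_bound",
    "EGTA_LOG_K_ABS",
    "EGTA_PKA",
]

#: Absolute Zn-EGTA stability constant (log10) and the two terminal
#: carboxyl/amine pKa values used for the pH-conditional correction.
EGTA_LOG_K_ABS = 12.6
EGTA_PKA = (9.40, 8.79)


class FitError(RuntimeError):
    """Raised when an isotherm fit fails or is unidentifiable."""


# ---------------------------------------------------------------------------
# protocol and data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule and cell contents of one titration.

    ``cell_macromolecule`` is the concentration of the cell-resident
    binding partner (dimeric protein for zinc titrations, DNA for
    protein-into-DNA titrations).  ``cell_chelator`` is the total chelator
    concentration; it is assumed matched between cell and syringe buffer
    (the standard way displacement experiments are set up), so it does not
    dilute as the titration proceeds.
    """

    syringe_conc: float
    cell_macromolecule: float
    injection_volumes: tuple[float, ...] = tuple([2e-6] * 19)
    V0: float = 200e-6
    cell_chelator: float = 0.0
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if not self.V0 > 0:
            raise ValueError("V0 must be > 0")
        if len(self.injection_volumes) == 0:
            raise ValueError("at least one injection is required")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be > 0")
        for name in ("syringe_conc", "cell_macromolecule", "cell_chelator"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "injection_volumes", tuple(float(v) for v in self.injection_volumes))

    def schedule(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (dV, cumulative injected volume, per-injection moles)."""
        dv = np.asarray(self.injection_volumes)
        return dv, np.cumsum(dv), dv * self.syringe_conc


@dataclass(frozen=True)
class SingleClassSystem:
    """n identical independent sites, per-site constant K (M^-1), enthalpy
    dH (kcal per mol of ligand bound)."""

    n: float
    K: float
    dH: float

    variant = "single_class"

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("n must be > 0")
        if not self.K > 0:
            raise ValueError("K must be > 0")


@dataclass(frozen=True)
class ThreeSiteSystem:
    """Three site classes with 2 sites each per dimer (dimer symmetry),
    random non-sequential filling."""

    K_sites: tuple[float, float, float]
    dH_sites: tuple[float, float, float]

    variant = "three_site"

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.K_sites):
            raise ValueError("all K_sites must be > 0")
        object.__setattr__(self, "K_sites", tuple(float(k) for k in self.K_sites))
        object.__setattr__(self, "dH_sites", tuple(float(h) for h in self.dH_sites))


@dataclass(frozen=True)
class CompetitiveSystem:
    """Protein with n intrinsic sites competing with a chelator for zinc.

    ``dH_chel`` is the enthalpy of zinc binding to the chelator; injected
    zinc is assumed pre-equilibrated with the chelator in the syringe, so
    the observed displacement heat per mole transferred to the protein is
    ``dH_int - dH_chel``.
    """

    n: float
    K_int: float
    dH_int: float
    K_chel: float
    dH_chel: float = 0.0

    variant = "competitive"

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("n must be > 0")
        if not self.K_int > 0 or not self.K_chel > 0:
            raise ValueError("K_int and K_chel must be > 0")


@dataclass(frozen=True)
class DnaOligomerSystem:
    """Zur dimer (with fixed zinc equivalents co-injected) titrated into
    DNA; heats from the linked-equilibria model, ``dH_site`` kcal per mole
    of dimer binding a DNA site."""

    linkage: LinkageParams
    zinc_eq_per_dimer: float
    dH_site: float

    variant = "dna_oligomer"

    def __post_init__(self) -> None:
        if self.zinc_eq_per_dimer < 0:
            raise ValueError("zinc_eq_per_dimer must be >= 0")


BindingSystem = Union[SingleClassSystem, ThreeSiteSystem, CompetitiveSystem, DnaOligomerSystem]


@dataclass(frozen=True)
class Isotherm:
    """Integrated, normalized titration data.

    ``ndh`` is the heat of each injection normalized per mole of injectant
    (kcal/mol); ``molar_ratio`` the cumulative injectant over cell
    macromolecule, both corrected for displacement-cell dilution.
    """

    molar_ratio: np.ndarray
    ndh: np.ndarray
    injection_volumes: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        mr = np.asarray(self.molar_ratio, dtype=float)
        q = np.asarray(self.ndh, dtype=float)
        dv = np.asarray(self.injection_volumes, dtype=float)
        if not (len(mr) == len(q) == len(dv)):
            raise ValueError("molar_ratio, ndh and injection_volumes must have equal length")
        if not np.all(np.isfinite(mr)) or not np.all(np.isfinite(q)):
            raise ValueError("isotherm values must be finite")
        if np.any(np.diff(mr) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")
        object.__setattr__(self, "molar_ratio", mr)
        object.__setattr__(self, "ndh", q)
        object.__setattr__(self, "injection_volumes", dv)

    def __len__(self) -> int:
        return len(self.ndh)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection": np.arange(1, len(self) + 1),
                "inj_volume_L": self.injection_volumes,
                "molar_ratio": self.molar_ratio,
                "ndh_kcal_per_mol": self.ndh,
            }
        )


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters of one isotherm fit."""

    system: BindingSystem
    params: dict
    stderr: dict
    rss: float
    residuals: np.ndarray
    converged: bool
    ndata: int = 0

    def to_dict(self) -> dict:
        out = {
            "variant": self.system.variant,
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: (None if v is None else float(v)) for k, v in self.stderr.items()},
            "rss": float(self.rss),
            "converged": bool(self.converged),
        }
        if self.system.variant == "single_class":
            out["n"] = float(self.params["n"])
            out["K_Minv"] = float(self.params["K"])
            out["dH_kcal_per_mol"] = float(self.params["dH"])
            out["se_n"] = out["se"].get("n")
            out["se_K_Minv"] = out["se"].get("K")
            out["se_dH_kcal_per_mol"] = out["se"].get("dH")
        return out


# ---------------------------------------------------------------------------
# per-composition equilibrium solves (cell contents -> bound species)
# ---------------------------------------------------------------------------


def _bound_single_class(n: float, K: float, M: float, L_T: float) -> float:
    """Ligand bound to n*M sites with per-site K; closed-form quadratic."""
    S = n * M
    if L_T == 0.0 or S == 0.0:
        return 0.0
    b = 1.0 + K * (S - L_T)
    disc = math.sqrt(b * b + 4.0 * K * L_T)
    L_f = 2.0 * L_T / (b + disc) if b >= 0 else (disc - b) / (2.0 * K)
    return L_T - L_f


def _free_ligand_multisite(classes: Sequence[tuple[float, float]], L_T: float) -> float:
    """Free ligand given site classes [(site_conc, K), ...]; Brent in log space."""
    if L_T == 0.0:
        return 0.0

    def f(u: float) -> float:
        L = math.exp(u)
        tot = L
        for S, K in classes:
            tot += S * K * L / (1.0 + K * L)
        return tot - L_T

    hi = math.log(L_T)
    lo = hi - 80.0 * math.log(10.0)
    if f(lo) > 0:
        return math.exp(lo)
    return math.exp(brentq(f, lo, hi, rtol=1e-15, maxiter=500))


def _cell_heat_content(system: BindingSystem, protocol: TitrationProtocol,
                       X: float, M: float) -> float:
    """Enthalpy content of the cell (kcal per litre of cell volume) at total
    titrant X and cell-macromolecule M, relative to the injected state."""
    if isinstance(system, SingleClassSystem):
        return system.dH * _bound_single_class(system.n, system.K, M, X)
    if isinstance(system, ThreeSiteSystem):
        classes = [(2.0 * M, K) for K in system.K_sites]
        L_f = _free_ligand_multisite(classes, X)
        return sum(
            dH * 2.0 * M * K * L_f / (1.0 + K * L_f)
            for K, dH in zip(system.K_sites, system.dH_sites)
        )
    if isinstance(system, CompetitiveSystem):
        C = protocol.cell_chelator
        classes = [(system.n * M, system.K_int), (C, system.K_chel)]
        L_f = _free_ligand_multisite(classes, X)
        bound_P = system.n * M * system.K_int * L_f / (1.0 + system.K_int * L_f)
        bound_C = C * system.K_chel * L_f / (1.0 + system.K_chel * L_f)
        # reference state: injected zinc arrives bound to the chelator
        f_syringe = _syringe_chelated_fraction(system, protocol)
        return system.dH_int * bound_P + system.dH_chel * (bound_C - f_syringe * X)
    if isinstance(system, DnaOligomerSystem):
        totals = MixtureTotals(
            P_total=X,
            D_total=M,
            L_value=system.zinc_eq_per_dimer * X,
            zinc_mode="total",
        )
        state = solve_state(system.linkage, totals)
        return system.dH_site * state.bound_dimer_total
    raise TypeError(f"unknown binding system {type(system).__name__}")


def _syringe_chelated_fraction(system: CompetitiveSystem, protocol: TitrationProtocol) -> float:
    """Fraction of syringe zinc pre-bound to the chelator."""
    C = protocol.cell_chelator
    if C == 0.0:
        return 0.0
    L_f = _free_ligand_multisite([(C, system.K_chel)], protocol.syringe_conc)
    return 1.0 - L_f / protocol.syringe_conc if protocol.syringe_conc > 0 else 0.0


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def simulate_isotherm(system: BindingSystem, protocol: TitrationProtocol) -> Isotherm:
    """Simulate the integrated, normalized isotherm for one titration.

    Standard displacement-cell bookkeeping: after cumulative injected
    volume ``dV``, cell-origin species are scaled by
    ``(1 - dV/2V0) / (1 + dV/2V0)`` and titrant accumulates as
    ``X = X_syr * (dV/V0) / (1 + dV/2V0)``.  The heat of injection ``j`` is
    the increment of the cell's enthalpy content plus the volume-
    displacement correction ``(dV_j/V0) * (Q_j + Q_(j-1))/2``, normalized
    per mole injected.
    """
    dv, dv_cum, moles = protocol.schedule()
    V0 = protocol.V0
    M0 = protocol.cell_macromolecule

    q_prev = 0.0
    ndh = np.empty(len(dv))
    ratio = np.empty(len(dv))
    for j, (dvj, dcum, nj) in enumerate(zip(dv, dv_cum, moles)):
        f_cell = (1.0 - dcum / (2 * V0)) / (1.0 + dcum / (2 * V0))
        M = M0 * f_cell
        X = protocol.syringe_conc * (dcum / V0) / (1.0 + dcum / (2 * V0))
        q = V0 * _cell_heat_content(system, protocol, X, M)
        dq = q - q_prev + (dvj / V0) * 0.5 * (q + q_prev)
        ndh[j] = dq / nj if nj > 0 else 0.0
        ratio[j] = X / M if M > 0 else np.inf
        q_prev = q
    return Isotherm(molar_ratio=ratio, ndh=ndh, injection_volumes=dv)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOGK_MIN, _LOGK_MAX = 0.0, 16.0
_N_MAX = 12.0


def _make_params(initial: BindingSystem) -> lmfit.Parameters:
    p = lmfit.Parameters()
    if isinstance(initial, SingleClassSystem):
        p.add("n", value=initial.n, min=1e-3, max=_N_MAX)
        p.add("logK", value=math.log10(initial.K), min=_LOGK_MIN, max=_LOGK_MAX)
        p.add("dH", value=initial.dH, min=-100, max=100)
    elif isinstance(initial, ThreeSiteSystem):
        for i, (K, dH) in enumerate(zip(initial.K_sites, initial.dH_sites), start=1):
            p.add(f"logK{i}", value=math.log10(K), min=_LOGK_MIN, max=_LOGK_MAX)
            p.add(f"dH{i}", value=dH, min=-100, max=100)
    elif isinstance(initial, CompetitiveSystem):
        p.add("n", value=initial.n, min=1e-3, max=_N_MAX)
        p.add("logK", value=math.log10(initial.K_int), min=_LOGK_MIN, max=_LOGK_MAX + 2)
        p.add("dH", value=initial.dH_int, min=-100, max=100)
    elif isinstance(initial, DnaOligomerSystem):
        p.add("logK4", value=math.log10(initial.linkage.K_dna[4]), min=_LOGK_MIN, max=_LOGK_MAX)
        p.add("dH", value=initial.dH_site, min=-100, max=100)
    else:
        raise TypeError(f"unknown binding system {type(initial).__name__}")
    return p


def _system_from_params(initial: BindingSystem, p: lmfit.Parameters) -> BindingSystem:
    if isinstance(initial, SingleClassSystem):
        return SingleClassSystem(n=p["n"].value, K=10 ** p["logK"].value, dH=p["dH"].value)
    if isinstance(initial, ThreeSiteSystem):
        return ThreeSiteSystem(
            K_sites=tuple(10 ** p[f"logK{i}"].value for i in (1, 2, 3)),
            dH_sites=tuple(p[f"dH{i}"].value for i in (1, 2, 3)),
        )
    if isinstance(initial, CompetitiveSystem):
        return CompetitiveSystem(
            n=p["n"].value,
            K_int=10 ** p["logK"].value,
            dH_int=p["dH"].value,
            K_chel=initial.K_chel,
            dH_chel=initial.dH_chel,
        )
    if isinstance(initial, DnaOligomerSystem):
        lad = initial.linkage
        k4_old = lad.K_dna[4]
        k4 = 10 ** p["logK4"].value
        scale = k4 / k4_old
        # rescale the zinc-activated tail of the ladder, keep K_0..K_2
        kd = list(lad.K_dna)
        kd[3] = math.sqrt(kd[2] * k4)
        kd[4] = k4
        kd[5] = lad.K_dna[5] * scale
        kd[6] = lad.K_dna[6] * scale
        new_linkage = LinkageParams(K_Zn=lad.K_Zn, K_dna=tuple(kd), n_dna_sites=lad.n_dna_sites)
        return DnaOligomerSystem(
            linkage=new_linkage,
            zinc_eq_per_dimer=initial.zinc_eq_per_dimer,
            dH_site=p["dH"].value,
        )
    raise TypeError


def _canonical_params(system: BindingSystem) -> dict:
    if isinstance(system, SingleClassSystem):
        return {"n": system.n, "K": system.K, "dH": system.dH}
    if isinstance(system, ThreeSiteSystem):
        return {
            **{f"K{i}": k for i, k in enumerate(system.K_sites, start=1)},
            **{f"dH{i}": h for i, h in enumerate(system.dH_sites, start=1)},
        }
    if isinstance(system, CompetitiveSystem):
        return {"n": system.n, "K": system.K_int, "dH": system.dH_int}
    if isinstance(system, DnaOligomerSystem):
        return {"K4": system.linkage.K_dna[4], "dH": system.dH_site}
    raise TypeError


def fit_isotherm(
    data: Isotherm,
    protocol: TitrationProtocol,
    initial: BindingSystem,
    discard_first: bool = False,
) -> FitResult:
    """Least-squares fit of the forward model to an isotherm.

    *initial* selects the model variant and supplies the starting guess
    (for ``competitive``, its chelator constants are held fixed; for
    ``dna_oligomer``, the zinc-activated tail of the affinity ladder is
    scaled through ``K_4``).  Association constants are fitted on a log10
    scale with trust-region least squares.

    Raises :class:`FitError` when the data carry no signal (all heats
    ~zero) or the optimizer fails.
    """
    if len(data) < 5:
        raise FitError("need at least 5 data points to fit")
    y = data.ndh.copy()
    mask = np.ones(len(y), dtype=bool)
    if discard_first:
        mask[0] = False
    if np.max(np.abs(y[mask])) < 1e-12:
        raise FitError("all heats are zero: parameters unidentifiable")

    def residual(p: lmfit.Parameters) -> np.ndarray:
        try:
            sim = simulate_isotherm(_system_from_params(initial, p), protocol)
        except (EquilibriumError, ValueError):
            return np.full(mask.sum(), 1e6)
        return (sim.ndh - y)[mask]

    params = _make_params(initial)
    try:
        out = lmfit.minimize(residual, params, method="least_squares")
    except Exception as exc:
        raise FitError(f"optimizer failure: {exc}") from exc
    if not out.success:
        raise FitError(f"fit did not converge: {out.message}")

    best = _system_from_params(initial, out.params)
    res = residual(out.params)
    rss = float(np.sum(res**2))

    # map standard errors from the internal (log-K) parametrization
    stderr: dict = {}
    canon = _canonical_params(best)
    for name in canon:
        stderr[name] = None
    if out.errorbars:
        ln10 = math.log(10.0)
        for pname, par in out.params.items():
            if par.stderr is None:
                continue
            if pname.startswith("logK"):
                idx = pname[4:]
                key = f"K{idx}" if idx else "K"
                if key in canon:
                    stderr[key] = canon[key] * ln10 * par.stderr
            elif pname in canon:
                stderr[pname] = par.stderr
    return FitResult(
        system=best,
        params=canon,
        stderr=stderr,
        rss=rss,
        residuals=res,
        converged=bool(out.success),
        ndata=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# chelator competition correction
# ---------------------------------------------------------------------------


def conditional_chelator_constant(
    pH: float = 7.8,
    log_K_abs: float = EGTA_LOG_K_ABS,
    pKa: Sequence[float] = EGTA_PKA,
) -> float:
    """pH-conditional metal-chelator constant from the absolute constant.

    K_cond = K_abs / alpha with the protonation factor
    alpha = 1 + 10^(pKa1-pH) + 10^(pKa1+pKa2-2pH) (terminal pKa values).
    Defaults give log K' = 9.97 for Zn-EGTA at pH 7.8.
    """
    pka1, pka2 = sorted(pKa, reverse=True)
    alpha = 1.0 + 10.0 ** (pka1 - pH) + 10.0 ** (pka1 + pka2 - 2.0 * pH)
    return 10.0**log_K_abs / alpha


def chelator_correction(
    K_app: float,
    chelator_conc: float,
    K_chel: float,
    dH_app: Optional[float] = None,
    dH_chel: Optional[float] = None,
) -> Union[float, tuple[float, float]]:
    """Apparent -> intrinsic affinity in the excess-chelator limit.

    ``K_int = K_app * (1 + K_chel * [chelator])``; when enthalpies are
    given, ``dH_int = dH_app + dH_chel`` is returned as a second value.
    """
    for name, v in (("K_app", K_app), ("chelator_conc", chelator_conc), ("K_chel", K_chel)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    K_int = K_app * (1.0 + K_chel * chelator_conc)
    if dH_app is not None and dH_chel is not None:
        return K_int, dH_app + dH_chel
    return K_int


def apparent_from_intrinsic(
    K_int: float,
    chelator_conc: float,
    K_chel: float,
    dH_int: Optional[float] = None,
    dH_chel: Optional[float] = None,
) -> Union[float, tuple[float, float]]:
    """Inverse of :func:`chelator_correction`."""
    K_app = K_int / (1.0 + K_chel * chelator_conc)
    if dH_int is not None and dH_chel is not None:
        return K_app, dH_int - dH_chel
    return K_app


# ---------------------------------------------------------------------------
# monophasicity (heterogeneity tolerance) analysis
# ---------------------------------------------------------------------------


def monophasicity_bound(
    protocol: TitrationProtocol,
    base_K: float,
    dH: float,
    noise_sigma: float,
    fold_spreads: Sequence[float],
    alpha: float = 0.05,
) -> dict:
    """How much three-site affinity heterogeneity a monophasic curve hides.

    For each fold-spread ``r`` the three site classes are placed at
    ``base_K / sqrt(r)``, ``base_K`` and ``base_K * sqrt(r)`` (equal
    enthalpies), the exact three-site curve is simulated, fitted with the
    single-class model, and the systematic residual is compared with the
    measurement noise: with known per-point noise ``noise_sigma`` the
    residual sum of squares of a correct model follows
    ``sigma^2 * chi2(N - p)``, so a spread is called ``"detectable"`` when
    ``RSS_systematic + sigma^2*(N-p)`` exceeds the upper ``alpha`` quantile
    of that distribution, and ``"indistinguishable"`` otherwise.

    Returns ``{"classification": {spread: label}, "max_tolerated": float}``
    where ``max_tolerated`` is the largest spread classified
    indistinguishable (nan if none).
    """
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be > 0")
    if any(r < 1 for r in fold_spreads):
        raise ValueError("fold_spreads must be >= 1")

    classification: dict = {}
    n_points = len(protocol.injection_volumes)
    dof = n_points - 3  # single-class model: n, K, dH
    threshold = noise_sigma**2 * chi2.ppf(1.0 - alpha, dof)
    for r in fold_spreads:
        spread = math.sqrt(float(r))
        truth = ThreeSiteSystem(
            K_sites=(base_K / spread, base_K, base_K * spread),
            dH_sites=(dH, dH, dH),
        )
        curve = simulate_isotherm(truth, protocol)
        guess = SingleClassSystem(n=6.0, K=base_K, dH=dH)
        fit = fit_isotherm(curve, protocol, guess)
        stat = fit.rss + noise_sigma**2 * dof
        classification[float(r)] = "detectable" if stat > threshold else "indistinguishable"
    tolerated = [r for r, lab in classification.items() if lab == "indistinguishable"]
    return {
        "classification": classification,
        "max_tolerated": max(tolerated) if tolerated else float("nan"),
    }
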