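"""Band-fraction prediction and DNA-binding-constant estimation for EMSA.

The experiment these functions describe: increasing amounts of Zur dimer
are incubated with a fixed, fluorescently labelled zitB DNA probe under
excess zinc (>6 equivalents per dimer), so every dimer is treated as
fully zinc-loaded (PL_6); the gel resolves free DNA, the 2:1 and the 3:1
(dimer:DNA) complexes, whose fractions are quantified from band
intensities.  Two species models are offered:

``per_site``
    three identical independent dimer-sites per DNA, one per-site
    association constant ``K_site``; complex fractions are binomial in the
    site-binding weight ``x = K_site * P_free``.
``stepwise``
    explicit overall constant ``beta_2`` (M^-2) for ``D + 2P = DP2`` and a
    stepwise constant ``K_3`` (M^-1) for ``DP2 + P = DP3`` (no 1:1 species,
    mirroring the bands actually observed).

Free dimer is always solved self-consistently (protein depletion matters:
the DNA site capacity is comparable to the Zur concentrations used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BandFractionTable",
    "OligomerConstants",
    "EmsaFitError",
    "predict_band_fractions",
    "fit_band_constants",
]


class EmsaFitError(RuntimeError):
    """Raised when band-constant estimation is unidentifiable or fails."""


@dataclass(frozen=True)
class OligomerConstants:
    """DNA-binding constants of the oligomeric Zur-DNA complexes."""

    variant: Literal["per_site", "stepwise"]
    K_site: Optional[float] = None
    beta_2: Optional[float] = None
    K_3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant == "per_site":
            if self.K_site is None or self.K_site < 0:
                raise ValueError("per_site model needs K_site >= 0")
        elif self.variant == "stepwise":
            if self.beta_2 is None or self.K_3 is None or self.beta_2 < 0 or self.K_3 < 0:
                raise ValueError("stepwise model needs beta_2 >= 0 and K_3 >= 0")
        else:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def dissociation_constants(self) -> dict:
        """Dissociation-constant equivalents (M) of the fitted constants."""
        if self.variant == "per_site":
            return {"Kd_site": math.inf if self.K_site == 0 else 1.0 / self.K_site}
        out = {}
        out["Kd2_overall_M2"] = math.inf if self.beta_2 == 0 else 1.0 / self.beta_2
        out["Kd3_step"] = math.inf if self.K_3 == 0 else 1.0 / self.K_3
        return out


@dataclass(frozen=True)
class BandFractionTable:
    """Quantified band fractions of one protein-titration gel.

    ``data`` columns: ``p_total_M`` plus fraction columns ``f_free``,
    ``f_2to1``, ``f_3to1`` and optionally ``f_1to1`` and per-record
    ``sigma``.  Listed fractions must sum to 1 per record.
    """

    data: pd.DataFrame
    D_total: float
    zinc_condition: str = "excess (>6 eq per dimer)"

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = ["p_total_M", "f_free", "f_2to1", "f_3to1"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"BandFractionTable missing columns: {missing}")
        fcols = self.fraction_columns(df)
        vals = df[fcols].to_numpy()
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")
        sums = vals.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if len(bad):
            raise ValueError(f"fractions do not sum to 1 at rows {bad.tolist()}")
        if not self.D_total >= 0:
            raise ValueError("D_total must be >= 0")
        object.__setattr__(self, "data", df)

    @staticmethod
    def fraction_columns(df: pd.DataFrame) -> list[str]:
        cols = ["f_free", "f_2to1", "f_3to1"]
        if "f_1to1" in df.columns:
            cols.insert(1, "f_1to1")
        return cols


# ---------------------------------------------------------------------------
# forward prediction
# ---------------------------------------------------------------------------

_N_SITES = 3  # dimer-sites per zitB probe


def _species_fractions_per_site(K: float, P_free: float) -> np.ndarray:
    x = K * P_free
    m = np.arange(_N_SITES + 1)
    binom = np.array([math.comb(_N_SITES, int(i)) for i in m], dtype=float)
    return binom * x**m / (1.0 + x) ** _N_SITES


def _species_fractions_stepwise(beta_2: float, K_3: float, P_free: float) -> np.ndarray:
    w2 = beta_2 * P_free**2
    w3 = w2 * K_3 * P_free
    Z = 1.0 + w2 + w3
    return np.array([1.0 / Z, 0.0, w2 / Z, w3 / Z])


def _bound_per_dna(constants: OligomerConstants, P_free: float) -> float:
    if constants.variant == "per_site":
        fr = _species_fractions_per_site(constants.K_site, P_free)
    else:
        fr = _species_fractions_stepwise(constants.beta_2, constants.K_3, P_free)
    return float(np.dot(np.arange(_N_SITES + 1), fr))


def _solve_free_dimer(constants: OligomerConstants, P_total: float, D_total: float) -> float:
    """Self-consistent free dimer with protein depletion by DNA binding."""
    if P_total == 0.0:
        return 0.0

    def f(u: float) -> float:
        P = math.exp(u)
        return P + D_total * _bound_per_dna(constants, P) - P_total

    hi = math.log(P_total)
    if f(hi) <= 0:  # no depletion (e.g. zero affinity)
        return P_total
    lo = hi - 80.0 * math.log(10.0)
    if f(lo) > 0:
        return math.exp(lo)
    try:
        return math.exp(brentq(f, lo, hi, rtol=1e-15, maxiter=500))
    except Exception as exc:  # pragma: no cover
        raise EmsaFitError(f"free-dimer solve failed: {exc}") from exc


def predict_band_fractions(
    constants: OligomerConstants,
    P_total_grid: Sequence[float],
    D_total: float,
    include_1to1: bool = True,
) -> BandFractionTable:
    """Predict band fractions over a protein-titration grid.

    All protein is treated as fully active (excess-zinc assumption).  For
    the ``per_site`` model the binomial 1:1 species exists; it is reported
    in an ``f_1to1`` column unless ``include_1to1=False``, in which case it
    is folded into ``f_free`` (unresolved faint band).  The ``stepwise``
    model has no 1:1 species by construction.
    """
    rows = []
    for P in P_total_grid:
        if P < 0:
            raise ValueError("protein concentrations must be >= 0")
        P_free = _solve_free_dimer(constants, float(P), D_total)
        if constants.variant == "per_site":
            fr = _species_fractions_per_site(constants.K_site, P_free)
        else:
            fr = _species_fractions_stepwise(constants.beta_2, constants.K_3, P_free)
        row = {"p_total_M": float(P), "f_free": fr[0], "f_2to1": fr[2], "f_3to1": fr[3]}
        if include_1to1:
            row["f_1to1"] = fr[1]
        else:
            row["f_free"] = fr[0] + fr[1]
        rows.append(row)
    cols = ["p_total_M", "f_free"] + (["f_1to1"] if include_1to1 else []) + ["f_2to1", "f_3to1"]
    return BandFractionTable(data=pd.DataFrame(rows)[cols], D_total=D_total)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_band_constants(
    table: BandFractionTable,
    variant: Literal["per_site", "stepwise"] = "per_site",
) -> tuple[OligomerConstants, dict]:
    """Estimate oligomeric DNA-binding constants from band fractions.

    Weighted least squares over all fraction columns present in the table
    (per-record ``sigma`` honoured when present, equal weights otherwise);
    association constants are fitted on a log10 scale.  Returns the
    constants and a dict with standard errors, dissociation-constant
    equivalents and the residual sum of squares.

    Raises :class:`EmsaFitError` when the titration does not bracket the
    binding transition (all records mostly free or mostly bound).
    """
    df = table.data
    if len(df) < 4:
        raise EmsaFitError("need >= 4 protein concentrations to fit")
    if df.f_free.min() > 0.7 or df.f_free.max() < 0.3:
        raise EmsaFitError(
            "binding transition not bracketed by the titration: "
            f"f_free spans [{df.f_free.min():.2f}, {df.f_free.max():.2f}]"
        )
    fcols = BandFractionTable.fraction_columns(df)
    y = df[fcols].to_numpy()
    weights = 1.0 / df["sigma"].to_numpy()[:, None] if "sigma" in df.columns else 1.0
    p_grid = df["p_total_M"].to_numpy()

    # initial guess: per-site constant from the half-free point
    p_mid = float(np.interp(0.5, df.f_free.to_numpy()[::-1], p_grid[::-1]))
    p_mid = max(p_mid, 1e-12)

    params = lmfit.Parameters()
    if variant == "per_site":
        params.add("logK", value=-math.log10(p_mid), min=0, max=16)
    elif variant == "stepwise":
        params.add("logB2", value=-2 * math.log10(p_mid), min=0, max=32)
        params.add("logK3", value=-math.log10(p_mid), min=0, max=16)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    def build(p: lmfit.Parameters) -> OligomerConstants:
        if variant == "per_site":
            return OligomerConstants(variant="per_site", K_site=10 ** p["logK"].value)
        return OligomerConstants(
            variant="stepwise", beta_2=10 ** p["logB2"].value, K_3=10 ** p["logK3"].value
        )

    def residual(p: lmfit.Parameters) -> np.ndarray:
        pred = predict_band_fractions(
            build(p), p_grid, table.D_total, include_1to1="f_1to1" in fcols
        ).data[fcols].to_numpy()
        return ((pred - y) * weights).ravel()

    out = lmfit.minimize(residual, params, method="least_squares")
    if not out.success:
        raise EmsaFitError(f"fit did not converge: {out.message}")
    best = build(out.params)
    ln10 = math.log(10.0)
    se = {}
    if out.errorbars:
        for pname, par in out.params.items():
            if par.stderr is not None:
                key = {"logK": "K_site", "logB2": "beta_2", "logK3": "K_3"}[pname]
                val = getattr(best, key)
                se[key] = val * ln10 * par.stderr
    info = {
        "stderr": se,
        "rss": float(np.sum(residual(out.params) ** 2)),
        "dissociation_constants": best.dissociation_constants,
    }
    return best, info
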