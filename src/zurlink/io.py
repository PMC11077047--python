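"""File formats and run-configuration schema.

CSV dialects (all concentrations molar, '.' decimal separator, 12
significant digits on write):

* isotherm:        injection, inj_volume_L, molar_ratio, ndh_kcal_per_mol
* band fractions:  p_total_M, f_free[, f_1to1], f_2to1, f_3to1[, sigma]
* populations:     zinc_total_M | molar_ratio, frac_free, frac_1to1,
                   frac_2to1, frac_3to1
* activation:      free_zinc_M, theta_zurbox, theta_up, frac_PL6,
                   expression_proxy

Fit results are serialized to JSON; run configurations are YAML or JSON
validated by a strict (unknown-keys-rejected) pydantic schema before any
computation starts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .activation import ActivationProfile, PromoterModel
from .emsa import BandFractionTable
from .equilibria import LinkageParams, SolveOptions
from .itc import (
    CompetitiveSystem,
    DnaOligomerSystem,
    FitResult,
    Isotherm,
    SingleClassSystem,
    ThreeSiteSystem,
    TitrationProtocol,
)

__all__ = [
    "FileFormatError",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "read_band_table_csv",
    "write_band_table_csv",
    "read_population_csv",
    "write_population_csv",
    "read_profile_csv",
    "write_profile_csv",
    "write_fit_result_json",
    "read_fit_result_json",
    "RunConfig",
    "load_config",
    "PROMOTER_SHORTCUTS",
]

_FLOAT_FMT = "%.12g"


class FileFormatError(ValueError):
    """Malformed input file; the message names the offending row/column."""


#: Named promoter shortcuts (site count and ITC-anchored K_4).
PROMOTER_SHORTCUTS = {
    "znuA": {"n_dna_sites": 2, "K_4": 8.7e5},
    "zitB": {"n_dna_sites": 3, "K_4": 1.8e6},
}


def _read_csv(path, required: list[str], label: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FileFormatError(f"cannot parse {label} CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{label} CSV {path} is missing column(s): {', '.join(missing)}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise FileFormatError(
                f"{label} CSV {path}: non-numeric value(s) in column '{col}' at row(s) {bad}"
            )
    return df


# --------------------------------------------------------------- isotherms


def read_isotherm_csv(path) -> Isotherm:
    df = _read_csv(path, ["injection", "inj_volume_L", "molar_ratio", "ndh_kcal_per_mol"], "isotherm")
    mr = df["molar_ratio"].to_numpy()
    if np.any(np.diff(mr) <= 0):
        bad = int(np.where(np.diff(mr) <= 0)[0][0]) + 1
        raise FileFormatError(f"isotherm CSV {path}: molar_ratio not strictly increasing at row {bad}")
    return Isotherm(
        molar_ratio=mr,
        ndh=df["ndh_kcal_per_mol"].to_numpy(),
        injection_volumes=df["inj_volume_L"].to_numpy(),
    )


def write_isotherm_csv(iso: Isotherm, path) -> None:
    iso.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


# ----------------------------------------------------------- band fractions


def read_band_table_csv(path, D_total: float, zinc_condition: str = "excess (>6 eq per dimer)") -> BandFractionTable:
    df = _read_csv(path, ["p_total_M", "f_free", "f_2to1", "f_3to1"], "band-fraction")
    return BandFractionTable(data=df, D_total=D_total, zinc_condition=zinc_condition)


def write_band_table_csv(table: BandFractionTable, path) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------- population / profile CSV


def read_population_csv(path) -> pd.DataFrame:
    df = _read_csv(path, ["frac_free", "frac_1to1", "frac_2to1", "frac_3to1"], "population")
    if "zinc_total_M" not in df.columns and "molar_ratio" not in df.columns:
        raise FileFormatError(
            f"population CSV {path} needs a 'zinc_total_M' or 'molar_ratio' column"
        )
    return df


def write_population_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_profile_csv(path) -> pd.DataFrame:
    return _read_csv(
        path,
        ["free_zinc_M", "theta_zurbox", "theta_up", "frac_PL6", "expression_proxy"],
        "activation-profile",
    )


def write_profile_csv(profile: Union[ActivationProfile, pd.DataFrame], path) -> None:
    df = profile.data if isinstance(profile, ActivationProfile) else profile
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------------- fit results


def write_fit_result_json(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_fit_result_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- RunConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolSection(_Strict):
    syringe_conc_M: float = Field(gt=0)
    cell_macromolecule_M: float = Field(ge=0)
    n_injections: int = Field(default=19, ge=1)
    injection_volume_L: float = Field(default=2e-6, gt=0)
    V0_L: float = Field(default=200e-6, gt=0)
    cell_chelator_M: float = Field(default=0.0, ge=0)
    temperature_C: float = 25.0

    def to_protocol(self) -> TitrationProtocol:
        return TitrationProtocol(
            syringe_conc=self.syringe_conc_M,
            cell_macromolecule=self.cell_macromolecule_M,
            injection_volumes=tuple([self.injection_volume_L] * self.n_injections),
            V0=self.V0_L,
            cell_chelator=self.cell_chelator_M,
            temperature_C=self.temperature_C,
        )


class SingleClassSection(_Strict):
    n: float = Field(gt=0)
    K_Minv: float = Field(gt=0)
    dH_kcal_per_mol: float

    def build(self) -> SingleClassSystem:
        return SingleClassSystem(n=self.n, K=self.K_Minv, dH=self.dH_kcal_per_mol)


class ThreeSiteSection(_Strict):
    K_Minv: tuple[float, float, float]
    dH_kcal_per_mol: tuple[float, float, float]

    @model_validator(mode="after")
    def _positive(self):
        if any(k <= 0 for k in self.K_Minv):
            raise ValueError("all three-site constants must be > 0")
        return self

    def build(self) -> ThreeSiteSystem:
        return ThreeSiteSystem(K_sites=self.K_Minv, dH_sites=self.dH_kcal_per_mol)


class CompetitiveSection(_Strict):
    n: float = Field(gt=0)
    K_int_Minv: float = Field(gt=0)
    dH_int_kcal_per_mol: float
    K_chel_Minv: float = Field(gt=0)
    dH_chel_kcal_per_mol: float = 0.0

    def build(self) -> CompetitiveSystem:
        return CompetitiveSystem(
            n=self.n,
            K_int=self.K_int_Minv,
            dH_int=self.dH_int_kcal_per_mol,
            K_chel=self.K_chel_Minv,
            dH_chel=self.dH_chel_kcal_per_mol,
        )


class LinkageSection(_Strict):
    K_Zn_Minv: float = Field(gt=0)
    n_dna_sites: int
    K_4_Minv: Optional[float] = Field(default=None, gt=0)
    K_6_Minv: Optional[float] = Field(default=None, gt=0)
    K_low_Minv: float = Field(default=1e4, gt=0)
    K_dna_Minv: Optional[tuple[float, ...]] = None
    odd_state_rule: Literal["geometric", "previous"] = "geometric"

    @model_validator(mode="after")
    def _complete(self):
        if self.K_dna_Minv is None and (self.K_4_Minv is None or self.K_6_Minv is None):
            raise ValueError("give either the full K_dna_Minv ladder or K_4_Minv and K_6_Minv")
        return self

    def build(self) -> LinkageParams:
        if self.K_dna_Minv is not None:
            return LinkageParams(
                K_Zn=self.K_Zn_Minv, K_dna=self.K_dna_Minv, n_dna_sites=self.n_dna_sites
            )
        return LinkageParams.from_anchors(
            K_4=self.K_4_Minv,
            K_6=self.K_6_Minv,
            K_low=self.K_low_Minv,
            K_Zn=self.K_Zn_Minv,
            n_dna_sites=self.n_dna_sites,
            odd_state_rule=self.odd_state_rule,
        )


class DnaOligomerSection(_Strict):
    linkage: LinkageSection
    zinc_eq_per_dimer: float = Field(ge=0)
    dH_site_kcal_per_mol: float

    def build(self) -> DnaOligomerSystem:
        return DnaOligomerSystem(
            linkage=self.linkage.build(),
            zinc_eq_per_dimer=self.zinc_eq_per_dimer,
            dH_site=self.dH_site_kcal_per_mol,
        )


class PromoterSection(_Strict):
    zurbox: LinkageSection
    N_up: int = 3
    K_up_Minv: Optional[float] = Field(default=None, gt=0)
    P_total_M: float = Field(default=4e-6, gt=0)
    D_total_M: float = Field(default=1e-9, gt=0)
    weights: tuple[float, float, float] = (1.0, 2.0, 9.0)

    def build(self) -> PromoterModel:
        kwargs = dict(
            zurbox=self.zurbox.build(),
            N_up=self.N_up,
            P_total=self.P_total_M,
            D_total=self.D_total_M,
            weights=self.weights,
        )
        if self.K_up_Minv is not None:
            kwargs["K_up"] = self.K_up_Minv
        return PromoterModel(**kwargs)


class ModelSection(_Strict):
    single_class: Optional[SingleClassSection] = None
    three_site: Optional[ThreeSiteSection] = None
    competitive: Optional[CompetitiveSection] = None
    dna_oligomer: Optional[DnaOligomerSection] = None
    linkage: Optional[LinkageSection] = None
    promoter: Optional[PromoterSection] = None

    @model_validator(mode="after")
    def _exactly_one(self):
        given = [k for k in type(self).model_fields if getattr(self, k) is not None]
        if len(given) != 1:
            raise ValueError(f"model section must specify exactly one variant, got {given}")
        return self

    @property
    def kind(self) -> str:
        return next(k for k in type(self).model_fields if getattr(self, k) is not None)

    def build(self):
        return getattr(self, self.kind).build()


class SolverSection(_Strict):
    rtol: float = Field(default=1e-12, gt=0)
    max_iter: int = Field(default=200, ge=1)
    bracket_decades: float = Field(default=120.0, gt=0)

    def to_options(self) -> SolveOptions:
        return SolveOptions(
            rtol=self.rtol, max_iter=self.max_iter, bracket_decades=self.bracket_decades
        )


class NoiseSection(_Strict):
    sigma_ndh_kcal_per_mol: float = Field(default=0.0, ge=0)
    sigma_fraction: float = Field(default=0.0, ge=0)
    seed: int = 0


class OutputSection(_Strict):
    isotherm_csv: Optional[str] = None
    fit_json: Optional[str] = None
    population_csv: Optional[str] = None
    profile_csv: Optional[str] = None
    band_table_csv: Optional[str] = None


class RunConfig(_Strict):
    """Schema-validated run configuration (YAML or JSON)."""

    model: ModelSection
    protocol: Optional[ProtocolSection] = None
    solver: SolverSection = SolverSection()
    noise: NoiseSection = NoiseSection()
    output: OutputSection = OutputSection()


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Raises ``pydantic.ValidationError`` (unknown keys, bad values) before
    any computation starts.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FileFormatError(f"config {path} must be a mapping at top level")
    return RunConfig.model_validate(data)
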