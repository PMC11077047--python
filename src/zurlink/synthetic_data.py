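"""Synthetic datasets with known ground truth for every pipeline stage.

Named presets encode the printed experimental conditions of the study this
package models: zinc titrated from a 2.0 mM syringe into 24 uM dimeric
apo-Zur under 3.0 mM EGTA competition (and the mutant variants with their
reduced stoichiometries), Zur titrated into znuA/zitB DNA carrying 4.0
zinc equivalents per dimer, and the excess-zinc EMSA protein titration.
Every generator is deterministic under a fixed seed and returns the
ground-truth parameters alongside the noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .emsa import BandFractionTable, OligomerConstants, predict_band_fractions
from .equilibria import LinkageParams
from .itc import (
    BindingSystem,
    CompetitiveSystem,
    DnaOligomerSystem,
    Isotherm,
    SingleClassSystem,
    TitrationProtocol,
    simulate_isotherm,
)

__all__ = [
    "Preset",
    "PRESETS",
    "generate_itc_dataset",
    "generate_emsa_dataset",
    "EmsaDesign",
]

#: Intrinsic per-site zinc binding constant of wild-type Zur (M^-1).
_K_ZN_INT = 2.3e13
#: Conditional Zn-EGTA constant at pH 7.8 (M^-1).
_K_EGTA = 9.3e9
#: Default binding enthalpies, kcal/mol (exothermic); the study prints no
#: enthalpy values, so these are typical magnitudes for zinc/protein and
#: zinc/chelator coordination and for protein-DNA association.
_DH_ZN = -10.0
_DH_EGTA = -4.0
_DH_DNA = -8.0


@dataclass(frozen=True)
class Preset:
    """A complete, named ground-truth configuration for one ITC dataset."""

    name: str
    system: BindingSystem
    protocol: TitrationProtocol
    #: additive Gaussian noise on normalized heats, kcal/mol
    sigma_ndh: float
    seed: int = 0


def _zn_egta_preset(name: str, n_sites: float, dimer_conc: float) -> Preset:
    """Zinc into apo-Zur (or mutant) under 3.0 mM EGTA, Fig-1-style."""
    system = CompetitiveSystem(
        n=n_sites, K_int=_K_ZN_INT, dH_int=_DH_ZN, K_chel=_K_EGTA, dH_chel=_DH_EGTA
    )
    protocol = TitrationProtocol(
        syringe_conc=2.0e-3, cell_macromolecule=dimer_conc, cell_chelator=3.0e-3
    )
    # observed displacement heat per injection is dH_int - dH_chel
    return Preset(name=name, system=system, protocol=protocol,
                  sigma_ndh=0.02 * abs(_DH_ZN - _DH_EGTA))


def _dna_preset(name: str, K_4: float, K6_ratio: float, n_dna_sites: int) -> Preset:
    """Zur (4.0 zinc eq per dimer) into 3 uM DNA, Fig-6-style."""
    linkage = LinkageParams.from_anchors(
        K_4=K_4, K_6=K6_ratio * K_4, n_dna_sites=n_dna_sites, K_Zn=_K_ZN_INT
    )
    system = DnaOligomerSystem(linkage=linkage, zinc_eq_per_dimer=4.0, dH_site=_DH_DNA)
    protocol = TitrationProtocol(syringe_conc=150e-6, cell_macromolecule=3e-6)
    return Preset(name=name, system=system, protocol=protocol, sigma_ndh=0.02 * abs(_DH_DNA))


PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        # zinc stoichiometries per dimer: WT 6.0; H36A 4.0; M-site 2.6; D-site 4.0
        _zn_egta_preset("wt_zn_egta", 6.0, 24e-6),
        _zn_egta_preset("h36a_zn_egta", 4.0, 40e-6),
        _zn_egta_preset("msite_zn_egta", 2.6, 65e-6),
        _zn_egta_preset("dsite_zn_egta", 4.0, 53e-6),
        _dna_preset("wt_znua_dna", K_4=8.7e5, K6_ratio=700.0, n_dna_sites=2),
        _dna_preset("wt_zitb_dna", K_4=1.8e6, K6_ratio=4000.0, n_dna_sites=3),
    ]
}


def _ground_truth(preset: Preset, seed: int, sigma: float) -> dict:
    sys = preset.system
    gt: dict = {"preset": preset.name, "seed": int(seed), "sigma_ndh": float(sigma),
                "variant": sys.variant}
    if isinstance(sys, CompetitiveSystem):
        gt.update(n=sys.n, K_int=sys.K_int, dH_int=sys.dH_int,
                  K_chel=sys.K_chel, dH_chel=sys.dH_chel)
    elif isinstance(sys, SingleClassSystem):
        gt.update(n=sys.n, K=sys.K, dH=sys.dH)
    elif isinstance(sys, DnaOligomerSystem):
        gt.update(K_dna=list(sys.linkage.K_dna), K_Zn=sys.linkage.K_Zn,
                  n_dna_sites=sys.linkage.n_dna_sites,
                  zinc_eq_per_dimer=sys.zinc_eq_per_dimer, dH_site=sys.dH_site)
    return gt


def generate_itc_dataset(
    preset: Union[str, Preset],
    seed: int = 0,
    sigma_ndh: Optional[float] = None,
) -> tuple[Isotherm, dict]:
    """Simulate a preset titration and add i.i.d. Gaussian heat noise.

    Identical ``(preset, seed)`` give byte-identical output.  Returns the
    noisy :class:`~zurlink.itc.Isotherm` and a ground-truth record
    (generating parameters, seed, noise level).
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise KeyError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
    sigma = preset.sigma_ndh if sigma_ndh is None else float(sigma_ndh)
    clean = simulate_isotherm(preset.system, preset.protocol)
    rng = np.random.default_rng(seed)
    noisy = clean.ndh + rng.normal(0.0, sigma, size=len(clean)) if sigma > 0 else clean.ndh
    iso = Isotherm(
        molar_ratio=clean.molar_ratio,
        ndh=noisy,
        injection_volumes=clean.injection_volumes,
        noise_sigma=sigma,
    )
    return iso, _ground_truth(preset, seed, sigma)


@dataclass(frozen=True)
class EmsaDesign:
    """Protein-titration design of a synthetic EMSA experiment."""

    P_total_grid: tuple[float, ...] = (10e-9, 30e-9, 100e-9, 300e-9, 1000e-9)
    D_total: float = 65e-9
    include_1to1: bool = True

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.P_total_grid):
            raise ValueError("protein concentrations must be >= 0")
        object.__setattr__(self, "P_total_grid", tuple(float(p) for p in self.P_total_grid))


def generate_emsa_dataset(
    constants: OligomerConstants,
    design: EmsaDesign = EmsaDesign(),
    seed: int = 0,
    sigma_fraction: float = 0.05,
) -> tuple[BandFractionTable, dict]:
    """Noisy band-fraction table from a known species model.

    Multiplicative Gaussian noise (relative sigma ``sigma_fraction``) is
    applied to each fraction, values are clipped to [0, 1] and each record
    renormalized to sum to 1 (band intensities are quantified relative to
    the lane total).  Returns the table and the ground-truth record.
    """
    clean = predict_band_fractions(
        constants, design.P_total_grid, design.D_total, include_1to1=design.include_1to1
    )
    df = clean.data.copy()
    fcols = BandFractionTable.fraction_columns(df)
    if sigma_fraction > 0:
        rng = np.random.default_rng(seed)
        vals = df[fcols].to_numpy()
        vals = vals * (1.0 + rng.normal(0.0, sigma_fraction, size=vals.shape))
        vals = np.clip(vals, 0.0, 1.0)
        vals = vals / vals.sum(axis=1, keepdims=True)
        df[fcols] = vals
    table = BandFractionTable(data=df, D_total=design.D_total)
    gt = {
        "variant": constants.variant,
        "seed": int(seed),
        "sigma_fraction": float(sigma_fraction),
        "D_total": design.D_total,
    }
    if constants.variant == "per_site":
        gt["K_site"] = constants.K_site
    else:
        gt.update(beta_2=constants.beta_2, K_3=constants.K_3)
    return table, gt
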