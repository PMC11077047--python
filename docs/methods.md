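# Methods

## The model

`zurlink` implements a statistical-thermodynamic description of how the
zinc-uptake regulator Zur (a Fur-family homodimer from *Streptomyces
coelicolor*) couples regulatory zinc binding to oligomeric DNA binding,
together with the measurement models (ITC, EMSA) used to parameterize it.

**Zinc tier.** A Zur dimer carries six equivalent, independent regulatory
zinc sites (three per protomer), each with per-site association constant
`K_Zn` (M^-1). The dimer states `PL_i` (i = 0..6 zinc bound) therefore
follow a binomial ladder: with free zinc `L` and apo-dimer concentration
`p_0`,

    p_i = p_0 · C(6, i) · (K_Zn · L)^i ,   Σ_i C(6,i)(K_Zn L)^i = (1 + K_Zn L)^6 .

Site equivalence is justified by the monophasic single-class behaviour of
the zinc titration isotherms; the `monophasicity_bound` analysis (below)
quantifies how much hidden heterogeneity that observation tolerates.

**DNA tier.** A DNA probe carries `n_s` identical, independent dimer-sites
(2 for the znuA operator, 3 for zitB). Each state `PL_i` binds one site
with its own constant `K_i`, non-decreasing in `i` (zinc activates DNA
binding). With the site-binding weight `s = Σ_i K_i p_i`, the probability
that `m` of the `n_s` sites are occupied is binomial,

    d_m / D_total = C(n_s, m) · s^m / (1 + s)^{n_s} ,

and DNA-bound dimers distribute over zinc states in proportion to
`K_i p_i`. No explicit dimer-dimer cooperativity on DNA is invoked; the
entire activation is carried by the `K_i` ladder (any protein-protein
stabilization is implicitly folded into `K_6/K_4`). Detailed balance —
DNA-bound dimers having their zinc affinity enhanced by `K_{i+1}/K_i` — is
automatic in this equilibrium formulation and is verified by tests on the
returned compositions.

**The K_i ladder.** Only three anchors are measurable: the low-occupancy
states `PL_0..PL_2` are assigned a subtle affinity `K_low` (default
1e4 M^-1), `K_4` is pinned to the ITC measurement at 4.0 zinc equivalents
per dimer (8.7e5 M^-1 for znuA, 1.8e6 M^-1 for zitB), and `K_6` is the
model's free parameter (`K_6 = 700·K_4` / `4000·K_4` reproduce the
zinc-driven appearance of the 2:1 / 3:1 complexes). The unanchored odd
states are interpolated; the default `odd_state_rule="geometric"` sets
`K_3 = sqrt(K_2 K_4)` and `K_5 = sqrt(K_4 K_6)` (smooth monotone choice),
with `"previous"` (hold at the lower even state) as the alternative. This
interpolation is a declared assumption, not a measured quantity, and every
entry of the ladder can be overridden.

## Solving mass conservation

Given totals (`P_total`, `D_total`, zinc), the unique equilibrium follows
from two scalars: free zinc `L` and apo-dimer `p_0`. For a single DNA
site-class, dimer conservation

    P_total = p_0 (1 + K_Zn L)^6 + D_total · n_s · (p_0 σ)/(1 + p_0 σ),  σ = Σ K_i C(6,i)(K_Zn L)^i

is an exact quadratic in `p_0`, solved in closed form with the
cancellation-free root formula. In total-zinc mode the remaining unknown
`L` is found by Brent's method on the (strictly increasing) zinc-
conservation residual, bracketed over 120 decades below the total; in
free-clamped (buffered-zinc) mode `L` is an input. With several site
classes (the promoter model) `p_0` is itself found by Brent on
log `p_0` — root-finding is done in log space throughout because species
can sit at ~1e-50 M scales where absolute tolerances are meaningless.
Returned states are checked against conservation (DNA to 1e-10, dimer and
zinc to 1e-8 relative) and the solve fails loudly otherwise. An
independent oracle (explicit enumeration of all `8^{n_s}` site
configurations plus nested bisection) agrees with the solver to better
than 1e-11 relative across 100 random parameter draws spanning
`K_Zn` in [1e9, 1e14], `K_6` in [1e5, 1e10] and totals in [1e-9, 1e-5] M.

## ITC simulation and fitting

Integrated isotherms are simulated with the standard displacement-cell
bookkeeping (active volume `V0` = 200 ul by default, 19 x 2 ul
injections): after cumulative injected volume `dV`, cell-origin species
scale by `(1 - dV/2V0)/(1 + dV/2V0)`, titrant accumulates as
`X_syr (dV/V0)/(1 + dV/2V0)`, and the heat of injection j is the increment
of the cell's enthalpy content plus the volume-displacement correction
`(dV_j/V0)(Q_j + Q_{j-1})/2`, normalized per mole injected (kcal/mol,
exothermic negative). No first-injection discard by default (19 analyzed
injections); a `discard_first` flag exists.

Model variants: `single_class` (closed-form free ligand),
`three_site` (three classes x 2 sites per dimer, random filling, 1-D root
find), `competitive` (exact Zn/chelator displacement) and `dna_oligomer`
(the full linkage model driven through the titration). In the competitive
system the chelator is taken to be present at the same concentration in
syringe and cell — injected zinc arrives pre-bound to EGTA — so the
observed displacement heat per mole transferred to the protein is
`dH_int - dH_chel` and post-saturation heats go to zero, which is how the
experiment is actually run.

Fits are trust-region least squares (lmfit) on log10 K with bounds
K in [1, 1e16] M^-1, n in (0, 12]; noise-free round trips recover the
generating parameters to 1e-4 relative for all variants. All-zero-heat
data raise an explicit unidentifiability error.

**Chelator correction.** `K_int = K_app (1 + K'_chel [EGTA])` with the
conditional constant derived from the absolute Zn-EGTA constant
(log K = 12.6) and terminal pKa values 9.40/8.79 through the protonation
alpha-factor, giving log K' = 9.97 at pH 7.8 (9.3e9 M^-1). These are
literature-standard values, configurable because the exact constants used
in any given analysis may differ. The formula inverts the exact
competitive forward model to within 5% whenever the chelator exceeds the
protein site pool 20-fold (3 mM EGTA vs 144 uM sites: ~21x).

**Monophasicity bound.** To ask how much three-site heterogeneity a
monophasic curve hides, site classes are placed at `K/sqrt(r), K,
K sqrt(r)` for fold-spread `r`, the exact three-site curve is fitted with
the single-class model, and the systematic residual is compared with the
declared per-point noise: since sigma is known, the residual sum of
squares of a correct model follows `sigma^2 chi2(N-3)`, and a spread is
"detectable" when `RSS_sys + sigma^2 (N-3)` exceeds the 95% quantile.
At sigma = 2% of the heat amplitude (typical for the instrument class) a
20-fold spread is indistinguishable and a 1000-fold spread detectable;
the criterion itself (known-sigma chi-square at alpha = 0.05) is this
package's construct.

**DNA-titration stoichiometry.** When zinc-saturated Zur is titrated into
DNA, the single-class fit of the forward curve returns exactly the site
count of the probe (3 for zitB, 2 for znuA). At 4.0 zinc equivalents per
dimer the full `K_6 >> K_4` ladder predicts an interesting artifact:
DNA-bound dimers strip zinc from the free pool (the thermodynamic-cycle
enhancement), so the heat saturates near molar ratio ~4.5 rather than 3
and the apparent stoichiometry is inflated. A fit dominated by the
measured `PL_4` affinity (flat ladder above `K_4`) recovers the printed
stoichiometries to ~15% under the partial-zinc protocol.

## EMSA band fractions

Under excess zinc (>6 eq per dimer) every dimer is treated as `PL_6`.
Two species models: `per_site` (three identical independent sites,
binomial fractions — this is exactly the saturating-zinc limit of the
linkage model, verified cross-module to 1e-8) and `stepwise` (overall
`beta_2` for D + 2P = DP2 and stepwise `K_3` for DP2 + P = DP3, with no
1:1 species, mirroring the three bands actually quantified). Free dimer
is always solved self-consistently because the DNA site capacity
(3 x 65 nM) is comparable to the protein range. Estimation is weighted
least squares over all fraction columns (per-record sigma honoured,
equal weights otherwise) on log10 constants; a titration whose free-DNA
fraction never crosses the transition raises an explicit
"not bracketed" error instead of returning a silent extrapolation.

## Biphasic activation

The zitB promoter is modelled as two independent site classes on one DNA
molecule: the zurbox (3 dimer-sites, full ladder, default `K_6` = 2e9
M^-1 — the low-nanomolar-Kd decade estimated from the excess-zinc EMSA
titration) and `N_up` = 3 upstream sites with the same ladder scaled to
`K_up` for `PL_6`. Free zinc is clamped (cellular zinc is buffered);
`P_total` = 4 uM dimer (the cellular Zur concentration), `D_total` = 1 nM
(single-copy promoter, negligible depletion). The expression proxy is
`E = w0 + w1 theta_zurbox + w2 theta_up` with weights (1, 2, 9).

Phase 1 is reproduced with no further assumptions: the zurbox reaches
half-occupancy at ~1e-14 M free zinc while the bulk Zur pool is still
>99.9% short of full zinc loading (the operator recruits the tiny `PL_6`
sub-population). Phase 2 — upstream occupation — requires the bulk pool
itself to approach saturation.

Two defaults deserve comment. First, because both tiers ride the same
steep (`~x^6`) `PL_6` saturation curve, an upstream affinity only 100x
below `K_6` places the second transition less than a factor 4 in zinc
after the first and the two expression rises merge into a single front.
The default is therefore `K_up = K_6/1000` (2e6 M^-1, i.e. the micromolar
Kd scale expected of the low-affinity upstream sites), which separates the
midpoints ~9-fold and yields a clearly biphasic proxy (two maxima of
dE/dlog L). Second, with weights (1, 2, 9) and a maximal upstream
occupancy of `K_up P/(1 + K_up P)` ~ 0.89, the plateau-to-plateau rise of
phase 2 over phase 1 is ~4-fold; the weights are illustrative mapping
constants, not quantities fitted to the in-vivo expression data. Both are
configurable.

`phase_boundaries` reports the two half-saturation free-zinc values by
monotone interpolation on log zinc; coinciding transitions give ratio 1
with a warning, and unbracketed transitions are an explicit error.

## Synthetic data

Generators emulate: the wild-type zinc titration (2.0 mM ZnCl2 into 24 uM
dimer under 3.0 mM EGTA; 6.0 sites per dimer) and the mutant variants
with their printed stoichiometries (H36A 4.0 at 40 uM, M-site 2.6 at
65 uM, D-site 4.0 at 53 uM); Zur-into-DNA titrations (150 uM dimer with
4.0 zinc eq into 3 uM DNA); and excess-zinc EMSA band tables. Since no
binding enthalpies are printed, defaults are typical magnitudes
(zinc-protein -10, zinc-EGTA -4, dimer-DNA site -8 kcal/mol) — they set
heat scales, not affinities. Noise models: additive Gaussian on
normalized heats (default sigma = 2% of the heat amplitude) and
multiplicative Gaussian (default 5%) on band fractions followed by
clipping and renormalization. Every generator is byte-deterministic under
a fixed `numpy` Generator seed and emits its ground truth alongside the
data.

What the generators do *not* emulate: baseline drift and first-injection
anomalies in ITC, gel-loading and densitometry covariances in EMSA
(noise is i.i.d. across bands before renormalization), protein
inactivation, and zinc buffering by assay components. Parameter-recovery
results on these synthetic data therefore certify the estimators under
the stated noise model, not under every pathology of real instruments.

## Problem sizes and tolerances in the shipped tests

Oracle-equivalence sweeps use 100 random systems (enumeration oracle,
512 DNA configurations at n_s = 3); parameter-recovery studies use 200
ITC replicates (c in [1, 1000], 2% noise; K within 2x in >= 95%) and 100
EMSA replicates (5% noise; K within 3x in >= 90%); activation profiles
use 601-point log grids over 1e-16..1e-10 M free zinc. Equilibrium
compositions are accepted at 1e-10 (DNA) / 1e-8 (dimer, zinc) relative
conservation; fit round trips at 1e-4 relative.

## Known limitations

Everything is equilibrium — no kinetics, no TPEN chelation dynamics, no
mapping from added medium zinc to cytoplasmic free zinc. Inter-dimer
cooperativity, DNA bending and flanking-sequence effects are not modelled
explicitly (they are absorbed into the `K_i` ladder). Temperature is
fixed per run (no van 't Hoff analysis); buffer-ionization enthalpy
differences enter only as an optional additive offset on dH. The odd-state
interpolation rule and the upstream-tier defaults are declared
assumptions that should be revisited if independent measurements of
`K_1, K_3, K_5` or of upstream-site affinities become available.
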