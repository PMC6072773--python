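# Methods

`aaqsp` couples whole-body pharmacokinetics (PK) of anti-inflammatory drugs
to a cellular model of arachidonic-acid (AA) metabolism, scores efficacy by
the suppression of inflammatory mediators, and propagates a
rifampicin-mediated drug–drug interaction (DDI) through the chain. This
note records the models, their assumptions, the parameters that matter, and
what the packaged surrogate components can and cannot show.

## Reduced whole-body PBPK model

The engine integrates amounts (µmol) of a parent drug and its metabolites
over a configurable compartment graph. The default physiology is a 73 kg
adult reduced to: venous and arterial plasma, blood cells, gut lumen, gut
wall, liver (vascular / interstitial / intracellular wells), kidney and a
lumped periphery. Circulation is flow-limited on plasma concentrations
(plasma flows, L/min); the gut wall drains into the liver's vascular well
(portal inflow, first-pass metabolism); organs partition with
tissue:plasma coefficients `Kp`. Organs with sub-compartments exchange
passively at 2 min⁻¹ per litre of organ volume — fast relative to
perfusion, so distribution is effectively equilibrated while metabolism
acts on an explicit intracellular state.

Processes per drug: Michaelis–Menten metabolism (rate
`kcat·E·expr(site)·Cu/(Km+Cu)` on the unbound intracellular concentration
`Cu = fu·C/Kp`), first-order transports between interstitial and
intracellular wells, and first-order renal/hepatic/biliary clearances.
Enzyme expression is liver-normalized and defaults to zero outside the
liver; the packaged physiology gives the gut wall 25% of hepatic CYP3A4
(and 5% CYP2C9), so induction also scales extrahepatic first-pass
metabolism. Each metabolism process carries a cumulative-flux accumulator
state, which makes metabolite mass bookkeeping exactly checkable; mass
balance (system + eliminated = administered) holds to solver tolerance
(< 1e-6 relative, in practice ~1e-15).

Solver: LSODA, rtol 1e-8, atol 1e-10, 1-min dense output; doses are
integration restarts with state jumps (oral doses enter the gut lumen after
the absorption lag; iv doses enter venous plasma).

Unbound concentrations per well: plasma/interstitial `fu·C`; blood cells
`fu_cell·C` with `fu_cell` defaulting to the plasma value (the cellular
unbound fraction of these drugs is not published — declared assumption);
intracellular `fu_cell·C/Kp` (referenced to cell water after
partitioning).

### Drug parameterization

Five drugs ship as versioned YAML: diclofenac, celecoxib, zileuton,
licofelone, rifampicin, with their Fig.-2-style metabolite schemes
(32 ADME processes in total). Three free parameters per drug — absorption
ka, a common scale on metabolic/clearance rates, the peripheral Kp — plus
the absorption lag are calibrated by `scripts/fit_pbpk_params.py` against
single-dose (Cmax, Tmax, AUC∞) anchors: the diclofenac anchors are the
reference simulated values for the 25 mg dissolved formulation (788 ng/ml,
0.40 h, 724 ng·h/ml; the 50 mg row follows by linearity within a few
percent); the other drugs use typical literature values fixed once in the
script. Known limitation: celecoxib's Tmax (1.4 h vs the 2.8 h anchor) —
in a flow-limited reduced model the plasma peak of a highly distributing
lipophilic drug is set by distribution, not elimination; Cmax and AUC match
exactly.

## Arachidonic-acid network and competitive inhibition

Inhibitors enter the network as time-resolved unbound concentrations in
venous blood cells (the cellular network was built for blood-derived
leukocytes and has no finer compartment), delayed by the 5-min oral-cavity
residence: the signal is exactly zero before the onset. Competitive
inhibition scales the Michaelis constant,

    Km_eff(t) = Km · (1 + Σᵢ Iᵢ(t)/Kiᵢ),

with additive combination of multiple inhibitors of one enzyme (the
combination rule for co-treatments is not otherwise defined — declared
choice). Binding affinities (µmol/L, IC50-derived): celecoxib→COX-2 0.017,
diclofenac→COX-2 0.018, licofelone→COX-2 0.032 and →5-LOX 0.056,
zileuton→5-LOX 0.021. COX-1 is out of scope.

The packaged surrogate network (all parameters repo-defined, YAML) is a
reduced topology: constant AA input → COX-2 branch (AA→PGH2→PGE2) and
5-LOX branch (AA→LTA4→ωLTB4), a dominant lumped "other pathways" AA sink,
enzymatic degradation of both mediators, and two regulatory edges (PGE2
positively on COX-2, ωLTB4 negatively on 5-LOX; multiplier `1 ± s·R`
form). Three deliberate properties:

* substrate concentrations sit 2–3 orders of magnitude below Km, so
  inhibition of COX-2/5-LOX operates far from saturation and the
  competitive factor dominates the rate response;
* downstream turnover half-lives are ~7 min — prostaglandin/leukotriene
  turnover is minutes-scale in vivo — so mediator levels track the
  drug signal over the 6-h window;
* the eicosanoid branches consume only a minor share of AA flux
  (re-esterification dominates), so blocking one branch causes only mild
  substrate shunting into the other.

Baseline handling: the network is integrated to steady state (relative
drift < 1e-6/min) or for at most a 24-h burn-in before dosing; the control
for the efficacy score is a paired drug-free simulation from the same
baseline, so any residual drift cancels. Control runs are deterministic
and bit-reproducible.

SBML Level 3 import/export covers the subset needed for such models:
species with initial concentrations, irreversible reactions with explicit
Michaelis–Menten kinetic laws (local `Vmax`/`Km`), constant sources, and
simple mass action; anything else raises an explicit unsupported-construct
error naming the law. The regulatory edges travel in a package annotation.
Round-tripping the surrogate through SBML reproduces simulations
bit-identically.

## Drug efficacy score

For control (c) and drug-treated (d) runs sharing a grid,

    DES(t) = ½ · [ (PGE2_c − PGE2_d)/PGE2_c + (ωLTB4_c − ωLTB4_d)/ωLTB4_c ].

DES ≤ 1 by construction, 0 when treated equals control, and can be mildly
negative when substrate shunting raises the untargeted mediator. Scores at
0.5 h and 6 h are read from one trajectory (no re-simulation). Eleven
scenario configurations ship as YAML: single agents (celecoxib 100 mg,
diclofenac 50 mg, licofelone 200 mg), co-treatments with zileuton 600 mg,
rifampicin pre-treatments (600 mg q.d. × 7 d), the two pain-relief
correlation settings, and the two clinical DDI settings (diclofenac
100 mg after 450 mg × 6 d; celecoxib 200 mg after 600 mg × 5 d) — the
victim doses and regimens of the figure-level and clinical-study analyses
differ and are encoded explicitly.

## CYP induction and the DDI path

A three-stage cascade converts the intracellular liver rifampicin
concentration into an activity fold: PXR occupancy `C/(EC50+C)` with
EC50 = 1.18 µmol/L stimulates mRNA synthesis up to Emax-fold; mRNA drives
enzyme synthesis; the fold is enzyme relative to baseline. The driver is
the *total* intracellular concentration: the EC50 comes from hepatocyte
assays referenced to nominal concentration. Defaults (configurable):
Emax 9, mRNA half-life 6 h, enzyme half-life 36 h — under 600 mg q.d. for
a week the CYP3A4 fold reaches a stable plateau of ~5.8, and after washout
the excess decays with the 36-h enzyme half-life. Other CYPs follow by
increment scaling,

    fold_e(t) = 1 + ratio_e · (fold_3A4(t) − 1),  ratio = 0.18 (CYP2C9),
    0.03 (CYP2J2), 0.02 (CYP1A2),

which preserves fold ≥ 1 and reads the ratios as relative induction
strengths ("analogous" activation is not defined more precisely —
declared interpretation, monotone in the ratio by construction).
Zileuton (CYP3A4 is a minor pathway) and licofelone (CYP2J2 weakly
induced) are left without a DDI analysis, mirroring the negligible-change
conclusion. In victim models every metabolism process of an induced enzyme
has its kcat multiplied by the fold wherever the enzyme is expressed —
including the gut wall. Under pre-treatment the model yields AUC ratios of
0.57 (celecoxib 200 mg) and 0.65 (diclofenac 100 mg), the clinically
observed direction.

The dose-adjustment search brackets and bisects the victim dose multiplier
until the DDI scenario's DES matches the reference scenario's at the
evaluation time (|ΔDES| < 1e-3), verifying monotonicity over the bracket
numerically; results are reported raw and rounded to 0.5-fold steps. The
default evaluation time is 6 h; the reproduction script matches at the
reference's peak-effect time, since the adjustment is meant to restore
*initial* therapeutic efficacy and a 6-h match is degenerate for a drug
as short-lived as diclofenac on this network (see limitations).

## Pain-relief correlation

The Hill model `y = a·x^b/(c^b + x^b)` relates the predicted PGE2 decrease
(control − treated, over 6 h) to placebo-corrected mean pain relief. The
fitted clinical parameterizations (diclofenac a = 2.8, b = 4.4, c = 37.2;
celecoxib a = 2, b = 5.7, c = 43.4) serve as reference values; because the
underlying pain-score tables are not redistributable, fitting is exercised
on synthetic data drawn from these curves. Fitting: bounded nonlinear
least squares with multi-start initialization (8 starts, deterministic
given the seed); 95% CIs by seeded parametric bootstrap (1000 resamples by
default — residual-σ Gaussian noise around the fitted curve, percentile
intervals, widened if necessary to contain the point estimate). Model
selection compares Hill against a hyperbolic Emax (no exponent) and a
through-origin linear model by AIC (Gaussian likelihood, σ profiled out),
with R² and RMSE reported; failed candidates are marked, not fatal.
Degenerate inputs (constant response, constant x, n < 5) raise errors
rather than returning spurious fits.

## Synthetic data

Generators are pure functions of a seeded config: (a) PK observations from
a one-compartment toy with proportional log-normal error
`C_obs = C·exp(ε)`, `ε ~ N(0, CV)` — the standard residual model for
concentration data; (b) pain-relief pairs from a Hill curve plus additive
Gaussian noise; (c) a toy MM network whose uninhibited steady state has the
closed form `S = (J/2)·K/(V − J/2)` per branch (flux balance far below
Km), returned alongside the model as an algebraic oracle. The generators
emulate the statistical structure the analysis assumes, not real-data
features such as inter-individual variability, assay limits of
quantification, or dropout — passing recovery tests therefore demonstrates
correctness of the estimation machinery, not clinical validity.

## Numerical choices

LSODA throughout (stiff-capable, automatic switching); network tolerances
rtol 1e-8 / atol 1e-12; inhibitor onsets are integration breakpoints so the
solver never steps across the Km_eff discontinuity; negative excursions
beyond −1e-6 µmol/L abort with the species named, smaller ones are clipped.
AUC∞ uses trapezoids plus `C_last/λz` with λz from a log-linear fit to the
trailing quarter of the profile; extrapolation is refused (flagged, AUC to
the last point) when the tail does not decay or would contribute more than
half the total. Dose-escalation grids must be sorted fractions in (0, 1];
the final point reproduces the plain scenario run exactly.

## Known limitations

* The surrogate network is a stand-in parameterization, not the published
  leukocyte model: absolute DES values differ from analyses run on that
  model (e.g. single-agent scores here peak near 0.25–0.30 where the
  literature-network analysis reports ~0.46), and the surrogate has no
  long regulatory memory, so diclofenac's efficacy decays to ~0 by 6 h.
  Orderings and directions — celecoxib sustained vs diclofenac transient,
  co-treatment ≥ singles, rifampicin reducing efficacy, monotone dose
  response — are the meaningful desk-scale outputs.
* The reduced physiology has no lungs, skin, muscle/adipose split, or
  mechanistic partition predictions; Kp values are calibration parameters.
* Solid formulations, population variability and CYP2C9 genotypes are out
  of scope; oral dosing assumes the dissolved form.
* The dose-adjustment fold for diclofenac (~1.5) is smaller than the
  literature-network estimate (2.5): the reduced model's peak
  concentration responds less steeply to induced clearance and the
  surrogate lacks the network memory that amplifies the deficit.
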