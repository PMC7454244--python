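# Methods

`qspvct` is a quantitative-systems-pharmacology (QSP) simulator of
microsatellite-stable colorectal cancer (MSS CRC) under an anti-PD-L1
antibody (atezolizumab, 1200 mg Q3W), a CEA×CD3 bispecific T-cell
engager (cibisatamab, 60 mg QW) and their combination, together with the
in-silico machinery around it: Latin-hypercube virtual-patient
generation, physiological plausibility screening, RECIST 1.1 response
classification at day 400, and a biomarker battery (PRCC, Wilcoxon,
ROC/AUC, binned ORR curves).

## Model structure

Four compartments are represented: blood (central), peripheral tissue,
tumor, and the tumor-draining lymph node (TdLN).  The 14-state ODE core
(`model_core`) tracks cancer cells, dying cells and shed antigen, an
APC maturation/migration chain, naive and activated effector T cells
across compartments, and a mirrored regulatory T-cell (Treg) arm.  Fast
surface-binding reactions are treated algebraically at quasi-steady
state (`synapse_binding`) and transduced through Hill functions, so the
state vector stays small while the pharmacology remains mechanistic.
This is a deliberately condensed instantiation of the much larger
published QSP models of this family (tens of ODEs plus algebraic
binding layers); the design target is the reproduction of trial-level
statistics and orderings, not state-count parity.

### Binding layer

Two equilibrium systems are solved per patient on a sites-per-cell
scale, with the antibody concentration treated as an undepleted bath:

* **Checkpoint axis.**  PD-1 binds PD-L1 and PD-L2 (2-D dissociation
  constants `kd_pd1_pdl1`, `kd_pd1_pdl2`); the bivalent anti-PD-L1
  antibody binds PD-L1 from solution (`kd_drug`) and can capture a
  second PD-L1 with its free arm.  The cross-arm step is an avidity
  equilibrium with dissociation `kd_drug·contact_area_scale/χ`, where χ
  is the per-patient cross-arm binding efficiency and
  `contact_area_scale` (sites·cell⁻¹·M⁻¹) is the single documented
  conversion between solution and synapse dissociation scales.  The
  solver eliminates the PD-1/PD-L2 sub-system in closed form and
  bracket-roots on free PD-L1; mass balances are enforced to 1e-8
  relative.  PD-L2 abundance is slaved to PD-L1 through the per-patient
  ratio r_PD-L2 ∈ [0, 0.07], reflecting the reported co-expression of
  the two ligands.
* **TCE trimer.**  The engager binds CEA on the cancer cell and CD3 on
  the T cell; either dimer cross-links into the cytolytic trimer with
  efficiency λ.  The two trimer paths are thermodynamic-cycle
  consistent, which reduces the system to one quadratic solved in
  closed form.  The dose–trimer curve is bell-shaped (hook effect).

Checkpoint and TCE Hill factors act on **fractional receptor
occupancy** — (C_PD1:PDL1 + δ·C_PD1:PDL2)/PD-1_total and
trimer/CD3_total — rather than absolute complex densities.  This makes
drug efficacy depend on engagement rather than on receptor copy number,
which is what keeps blockade effective for receptor-high patients; with
absolute-density Hills the PD-1-high × PD-L1-high corner of the cohort
is unblockable at any dose.  δ ∈ [0, 1] weights the PD-1:PD-L2 complex
inside the checkpoint Hill; the default δ = 1 counts PD-L2 engagement
fully, and the study variant samples δ ~ U[0,1] as an extra cohort
axis.

### Tumor–immune dynamics

Tumor growth is logistic.  Killing is a saturating mass-action term

    K = h_clone · [k_kill_tcr·(1−H_syn) + k_kill_tce·H_TCE·(1−w·H_syn)]
        · Teff_tumor/(C + Teff_tumor + 1) / (1 + k_treg_suppress·H_Treg)

with three structural choices worth stating explicitly:

* **Clonal gating of both routes.**  `h_clone` is a steep Hill in the
  number of activatable T-cell clones (TMB).  It multiplies the TCE
  route as well as the native TCR route: although trimer formation is
  MHC-independent, productive redirected lysis still requires
  tumor-reactive effectors recruited and retained by the antigen
  cascade.  This correlates the responder sets of the two monotherapies
  through TMB, producing responders-to-both (ROB) and the observed
  small net gain of the combination over the sum of monotherapies.
* **Partial checkpoint bypass of the TCE synapse** (weight
  `w_tce_checkpoint` = 0.05): PD-1 ligation attenuates the engineered
  synapse far less than the native one.  With full suppression on both
  routes, checkpoint blockade "unleashes" the TCE in essentially every
  CEA-positive patient and the combination arm responds at twice the
  clinically observed rate.
* **Local synapse-driven Teff expansion.**  Engagement (TCR or trimer)
  drives intratumoral Teff proliferation at `k_pro_teff_tumor`, capped
  at `teff_cap_fraction`·C.  This is the TCE's pharmacodynamic engine —
  without it the engager cannot amplify a sparse infiltrate and the
  cibisatamab arm never responds.  Because the cap is proportional to
  tumor burden, effective killing per cell is scale-free and responses,
  once initiated, run to completion; the trial therefore produces the
  observed strongly bimodal (PR/CR vs PD) outcome distribution with a
  thin SD band.

Priming in the TdLN: mature APCs activate naive T cells at a rate
proportional to TMB; the effector output is amplified by
2^(n_div·(1−H_PD1_LN)), so PD-L1 on APCs removes division rounds and
anti-PD-L1 in the node restores them.  The dying-cell pool is fed both
by killing and by a baseline turnover flux `k_apoptosis`·C; without the
latter the drug-free antigen cascade is identically zero, no patient
carries a measurable infiltrate, and the plausibility screen is
degenerate.  Tregs mirror the effector arm (activation, trafficking, no
killing) and suppress through a Hill in intratumoral Treg density.

### Pharmacokinetics

Both antibodies follow linear two-compartment PK with repeated IV bolus
dosing, evaluated in closed form as superposed bi-exponentials and
injected into the ODE right-hand side as a forcing function; an
ODE-coupled mode exists purely as a cross-check (they agree to 1e-6).
Tumor and TdLN interstitial concentrations are γ-scaled plasma values
(γ_tumor = 0.1, γ_ln = 0.3; no delay).  Atezolizumab defaults
(cl 0.20 L/d, Vc 3.28 L, Vp 3.63 L, Q 0.546 L/d, 145 kDa) and
cibisatamab defaults (cl 0.35 L/d, Vc 3.0 L, Vp 2.5 L, Q 0.35 L/d,
195 kDa) are literature-typical values, not fitted here.  Dosing uses
the half-open convention [first dose, horizon).

### Numerics

LSODA throughout (rtol 1e-6, atol 1e-3 cells), maximum step 1 day while
dosing so no bolus is stepped over.  The checkpoint/TCE Hill factors
depend only on local drug concentration and per-patient receptor
totals, so each simulation precomputes three lookup tables on a
121-point log-concentration grid (10 points per decade; interpolation
error is far below solver tolerance) and the right-hand side reduces to
arithmetic plus three interpolations.  States are floored at zero
inside the RHS; ε = 1 cell guards the killing denominator.  Halving
solver tolerances moves day-400 diameters by well under 0.1 %.

## Virtual population and screening

Sixteen axes are sampled by Latin hypercube (one uniformly jittered
sample per equal-probability stratum, independent permutations per
axis): tumor growth rate and initial diameter (linear), TMB on a log
axis [1, 220] (so normalized 0.8 ≈ 76 clones and the top of the axis
exceeds 200), receptor densities (PD-1, PD-L1 on cancer cells and APCs,
CEA, CD3) and binding affinities on log axes, the cross-arm
efficiencies χ and λ and r_PD-L2 linear, plus infiltration rate, naive
T-cell pool and a Treg-activity multiplier as immune-context axes.

Each draw is grown from a 10⁶-cell seed without drug until the tumor
reaches its sampled diameter (or 2000 days elapse).  Patients whose
tumor never reaches target — too slow, or controlled by their own
immune response — are flagged `no_tumor`; the latter group is
concentrated at high TMB with low checkpoint cover, which is precisely
why the surviving high-TMB patients carry high PD-L1 and respond
strongly to blockade.  Screen bounds (diameter 1–15 cm, blood T cells
500–3000 /µL, intratumoral activated T cells 10²–10⁷ /cm³, Teff/Treg
0.1–50) are clinically motivated placeholders.  Implausible patients
are retained, flagged with every violated bound.

## Trial engine and statistics

Every plausible patient enters each arm from the identical
pre-treatment state.  RECIST 1.1 is simplified to a single synthetic
lesion: percent diameter change at day 400, CR below a 0.2 cm detection
floor, PR ≤ −30 %, PD ≥ +20 % (closed thresholds), SD otherwise; the
"+20 % and ≥5 mm" absolute condition is dropped (no measurement
noise).  A day-400 snapshot is used rather than best overall response.
ORR carries the Agresti-Coull 95 % interval; clinical-scale
uncertainty is assessed by percentile bootstrap at the real trials'
sample sizes (31 and 25 patients, 10 000 draws).  PRCC uses midrank
transforms and residual regressions with the t-approximation for
p-values; Wilcoxon uses exact enumeration for tie-free pooled samples
of ≤12 and the tie-corrected continuity-corrected normal approximation
otherwise; ROC/AUC counts ties as ½ (Mann-Whitney concordance).  No
multiple-testing correction is applied to the per-axis tests (raw
significance stars); a Benjamini-Hochberg pass is easy to add but
defaults off.  Binned ORR curves sort patients by an axis, group
consecutive 20-patient bins from the first patient (trailing remainder
= flagged short bin), and place bins at the mean normalized coordinate
under the axis's sampling scale — log axes normalize in log space,
which is required for the TMB 0.8 ↔ 76 anchor.

## Calibration

The study-level parameter tables behind the published model are spread
over three publications' supplements and are not packaged here; the
defaults in `ModelParams` and `default_parameter_space()` were instead
calibrated, once, against the published trial-level statistics at the
packaged study conditions (400-patient LHS cohort, seed 1): ORRs of
8.2 / 5.2 / 11.2 % (atezolizumab / cibisatamab / combination), an
~80 % progressive-disease fraction in the combination arm, a ~66 %
plausibility yield at 2000 draws, near-zero ORR below normalized TMB
0.8 with ~100 % in the top TMB bin, and a ~1 pp ORR gain with the
δ-weighted PD-L2 variant.  The calibrated state reproduces all of these
within the documented tolerances; the numbers the package actually
produces are computed by `scripts/acceptance.py` and the test suite,
not quoted from anywhere else.

## What the generator does and does not emulate

The virtual population captures between-patient variation in tumor
kinetics, immunogenicity, receptor biology and immune context, with
independent axes (no covariance structure), a single lesion per
patient, no measurement noise, and no on-treatment dropout, toxicity or
death.  Survival-type endpoints (duration of response, PFS) and
myeloid/TAM/MDSC biology are out of scope.  Passing tests therefore
demonstrate internal consistency with the published trial statistics
under these idealized conditions, not predictive validity on real
patients.

## Known limitations

* The SD band is thinner than clinically reported (~1–2 % vs ~8 %):
  with a burden-proportional effector cap, outcomes are nearly binary.
  A stable intermediate tumor–immune equilibrium would require an
  additional negative feedback (e.g. antigen-loss variants or effector
  exhaustion) not present in this condensation.
* Arm-specific plausible-patient counts differ in the published trial
  (1312/1325/1299 from one 2000-VP cohort); here screening is purely
  pre-treatment, so all arms share one denominator.  Patients whose
  integration fails in an arm would be dropped from that arm only, but
  in practice the integrator converges for the whole default cohort.
* PK biodistribution is algebraic (γ-scaled, no delay), and the
  atezolizumab/cibisatamab PK defaults are literature-typical rather
  than study-fitted.
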