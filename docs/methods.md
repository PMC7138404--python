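# Methods

This note documents the models, numerical choices and study designs behind
`vasokin`, and what the phantom validation does and does not demonstrate.

## DCE kinetics: the GCTT model

The tissue impulse response treats the capillary bed as a parallel network
whose transit times follow a gamma distribution with mean `t_c` (s) and
heterogeneity index `alpha_inv` (the squared coefficient of variation of
transit times; shape `alpha = 1/alpha_inv`, scale `theta = t_c*alpha_inv`).
The vascular residue is `R_v(t) = 1 - CDF_gamma(t)`, so `R_v(0) = 1` and
its time integral equals `t_c` (mean-residence-time identity, tested by
quadrature). Tracer extracted with fraction `E_n` enters an interstitial
space of fractional volume `v_e` after transiting the capillary (hence the
extra convolution with the transit-time density `h`) and washes out at
`k_ep,n = E_n*F/v_e`. Two limits anchor the implementation and are used as
closed-form oracles:

* `alpha_inv -> 0`, `E = 0`: plug flow, `C_t = F * int_{t-t_c}^{t} C_a`;
* `t_c -> 0` at fixed `F`, `Ktrans`: the (extended) Tofts model
  `v_b*C_a + Ktrans * int C_a(s) e^{-k_ep (t-s)} ds`.

### Numerics

Convolutions are discrete on the uniform acquisition grid: trapezoid rule
for bounded kernels (`C_a`, `R_v`), and cell-averaged kernels obtained from
CDF differences for the transit-time density `h`, whose pdf diverges at 0
when `alpha < 1` — cell averaging keeps the kernel mass exact and the
scheme stable for every admissible `alpha_inv`. The bolus-arrival delay
`t_d` shifts the AIF by linear interpolation, allowing sub-sample delays.
A grid-refinement test verifies that the discretisation error shrinks as
the grid is refined. If `v_e` is numerically zero the interstitial term
vanishes (the washout rate diverges), which is the correct limit.

### Joint fitting

One bounded trust-region least-squares problem per voxel estimates
(`v_b`, `t_c`, `alpha_inv`, `v_e`, `t_d`, `E_1..E_3`), with the five
hemodynamic parameters shared across boluses. Bounds:
`v_b in [1e-4, 0.5]`, `t_c in [0.5, 60] s`, `alpha_inv in [1e-3, 5]`,
`v_e in [0, 0.7]`, `t_d in [0, 10] s`, `E_n in [0, 0.9]` — physiology plus
identifiability. The 8-parameter problem is multimodal, so the fit uses a
deterministic three-point multistart spanning low/typical/high perfusion
regimes and keeps the best optimum. Goodness of fit is
`r^2 = 1 - SS_res/SS_tot` over the full three-bolus curve; non-convergent
voxels carry an `r^2 = -inf` sentinel. The voxel filter removes
`r^2 < 0.9` (a voxel at exactly 0.9 is retained); the retained fraction is
reported as the perfused percentage and the retained voxel set is reused
for the IVIM medians so both modalities describe the same tissue.

For the precision comparison against single-bolus analysis, each bolus is
also fitted alone on its own time window (20 s of pre-bolus baseline up to
the next injection) with a free constant offset absorbing residual signal
from earlier boluses; the three single-bolus estimates of each shared
parameter are averaged. The joint fit's error SD is compared to this
baseline per parameter.

### Signal-to-concentration conversion

Spoiled-gradient-echo inversion: the pre-injection baseline fixes
`M0 sin(theta)` given a baseline T1 map, the signal ratio is inverted for
`R1(t)`, and `C = (R1 - R1_0)/r1`. Samples outside the invertible range
are flagged, never clamped silently. The conversion is its own module
because acquisition details vary between protocols; the fitting stages
accept concentration curves directly.

## IVIM

The relaxation-weighted two-compartment equation (README) makes the fitted
`f` an absolute volume fraction rather than a TR/TE-dependent apparent one.
Blood constants are fixed at T1 = 2200 ms, T2 = 50 ms; tissue T1/T2 come
from acquired maps (T1 mapping is accepted as an input file — the
acquisition protocol for it is not modelled here). Two conventions exist
for the fast-decay exponent; `dstar_convention="total"` (default) uses
`e^{-b D*}` with the constraint `D* >= D` (implemented by fitting the
excess rate `D* - D >= 0`), `"additive"` uses `e^{-b(D + D*)}`.

Fitting is segmented-initialised bounded NLLS per voxel: a log-linear fit
to the b > 175 s/mm² tail initialises D and the perfusion fraction (via the
extrapolated intercept and the relaxation weights), then all parameters are
refined jointly. The amplitude S(0) is a free nuisance parameter so the
noise on the measured b=0 sample does not propagate into the decay rates.
Bounds: `D in [0, 4e-3]`, `f in [0, 1]`, fast rate up to 1 mm²/s.
Multi-direction acquisitions are combined to the trace-weighted signal by
the geometric mean before fitting (isotropy assumption).

## T2 relaxometry

`S(TE) = S0 e^{-TE/T2}` per voxel, log-linear (signal-weighted)
initialisation followed by a damped Gauss–Newton refinement in the
nonlinear domain — log-domain fitting would amplify noise-floor bias at
late echoes. The iteration is vectorised across voxels (the normal
equations are 2x2), so 10^4 voxels fit in under a second. T2 is bounded to
(0, 2000] ms; flat-decay voxels hit the bound and are flagged, dead voxels
(no positive signal) are flagged unfittable and carry NaN.

## Cast morphometry

The episcopic acquisition produces 14 x 14 x 28 µm voxels; 2 x 2 in-plane
mean aggregation yields the 28 µm isotropic working resolution. Tumor
masks come from sparse 2D ROIs interpolated by linear blending of signed
distance transforms (annotated slices are reproduced exactly). Vessel
segmentation follows the tube-analysis batch convention: intensity
threshold 6 (8-bit scale), morphological closing with a ball of physical
radius 14 µm (one voxel at working resolution), removal of 26-connected
components below 500 voxels, restriction to the tumor mask. The
`VesselRadius = 14 µm` protocol parameter denotes the expected vessel
scale in the original tool; at this resolution it maps to the same
single-voxel structuring element as the closing radius and is carried as
metadata.

Skeletonisation is sequential topology-preserving 3D thinning implemented
in `vasokin.thinning`: border voxels are deleted iff they are simple
points (Malandain–Bertrand characterisation — exactly one 26-connected
foreground component in the 26-neighbourhood and one 6-connected
background component of the 18-neighbourhood touching the centre), with
curve endpoints preserved, six directional passes per iteration and
deletion parallelised over the eight parity subfields (same-subfield
voxels are mutually outside each other's 3³ neighbourhoods, so parallel
deletion equals sequential deletion). This guarantees components, loops
and cavities are preserved; a torus phantom thins to a closed loop.

"Number of vessel segments" is interpreted as skeleton-graph *branches*
(voxels with >= 3 neighbours under 26-connectivity are junctions; removing
junction clusters leaves one component per branch; a junction-free
component counts once), matching what skeleton-analysis tools report. The
alternative reading — connected components — is available via
`segment_definition="components"`. `prune_ends=False` (the protocol
default) keeps terminal spurs. Two limitations of branch counting:
a branch that connects two junction clusters without any intermediate
voxel is not counted, and a tube passing *through* a junction contributes
two branches (its two arms), which is the graph-correct count even though
it was drawn as one primitive.

Vessel density is `n_segments / tumor volume (mm³)` — the density formula
is checked as an exact identity — and the vascular volume fraction is
vessel voxels over tumor voxels. The concordance QC compares each
specimen's cast volume fraction to its DCE-MRI perfused percentage through
the cohort-median ratio (the two quantities live on different scales);
specimens below half the reference ratio are flagged "exclude", missing
MRI counterparts give "undetermined", and the full report is always
emitted rather than silently dropping specimens.

## Statistics

Z-scores use the control group's sample (n−1) SD — control groups of 4–5
animals are typical, and the sample convention makes the control group's
own z-scores exactly mean 0, SD 1. Group comparisons: two-sided
Mann–Whitney U with the exact null for groups up to n = 8 without ties
(normal approximation with tie correction otherwise, flagged), or Welch's
t-test. No multiple-testing correction is applied.

## Synthetic phantoms: what they emulate, and what not

The generators reproduce the acquisitions' sampling schemes exactly
(13 b-values 0–800 s/mm², 50 echoes 8–400 ms, TR/TE 4000/18.5 ms, 28 µm
cast voxels) and drive the same forward models the fitters invert — so
noiseless phantoms are exact fixed points of the fits, and recovery
studies measure estimator behaviour under controlled noise. They do not
simulate MR physics beyond the stated signal equations: no k-space, no
motion, no partial volume, no B1 inhomogeneity, no AIF measurement error,
and tube phantoms are idealised cylinders without radius variation or
imaging point-spread beyond optional Gaussian blur. Passing phantom tests
therefore demonstrates correctness of the numerics and estimators, not
robustness to those real-world effects.

Free protocol parameters the source acquisition does not pin down were
fixed once, on design grounds: gamma-variate boluses (amplitude 0.5 mM,
shape 2.5, decay 3 s — a sharp preclinical first-pass), injections at
60/600/1140 s on a 0–1700 s grid sampled at 2 s. The temporal resolution
and bolus width were chosen by a Cramér–Rao analysis of the joint fit at
SNR 20 (noise SD = peak tissue concentration / SNR): at 2 s / 3 s-decay
the bound implies ~11% relative SD for `t_c` (≈7% median error), i.e. the
shared parameters are identifiable, which is precisely why such protocols
acquire fast dynamic frames. DCE noise is Gaussian in the concentration
domain (the fitting domain); magnitude-MRI phantoms (DWI, multi-echo)
offer Gaussian or Rician noise, and the Rician floor of late echoes is
validated against the analytic Rice mean. DWI phantoms generate
3 directions x 2 averages at the stated per-image SNR and combine them by
the geometric mean exactly as the fitting stage prescribes.

## Validation studies (vasokin.validation)

The joint-fit recovery study uses a *fixed* digital phantom: 200 voxel
truths placed by a deterministic Latin hypercube over the physiological
ranges (internal scramble seed), so that — as in physical phantom
experiments — the seed varies only the noise realisation, not the object
being measured. Problem sizes: 200 three-bolus voxels at SNR 20 (noise SD
= peak tissue concentration / SNR) for the joint-fit recovery study; 100 structureless + 20 clean voxels for the r² filter; 1000 + 200
(avascular) voxels at SNR 50 for IVIM; 10^4 voxels at 2% noise for T2;
tube phantoms of ~110³ voxels for morphometry; 10 specimens (3
under-filled) for QC; 10^4 null replicates for the Welch-t calibration.
Truth distributions cover the physiological ranges above, with the
per-agent extraction ordering E_G5 < E_G2 < E_Dotarem built in — large
dendrimers extract less, which is what makes multi-agent DCE sensitive to
permeability changes. `scripts/acceptance.py` reruns all studies from a
single seed and writes every measured quantity to JSON.

## Known limitations

* The GCTT fit cost is ~0.4 s/voxel; whole-tumor maps at full resolution
  are feasible but benefit from coarse masks or parallel chunking (not
  built in).
* `alpha_inv` and `t_d` are weakly identifiable at realistic SNR (CRLB
  ~40–70% relative); their maps should be read qualitatively.
* Branch counting depends on the thinning's junction geometry within +/- 0
  only for clean phantoms; noisy casts can split junctions into adjacent
  clusters (handled by cluster merging) or create short spurious spurs
  (kept, since `prune_ends=false`).
* The exact Mann–Whitney null is used only for groups up to 8 without
  ties; ties switch to the corrected normal approximation and are flagged.
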