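# Methods

## Model

The chromosome copolymer model treats a chromatin fiber as a linear
bead-spring chain of N beads, each covering 1200 bp (about six nucleosomes
plus linkers). The bead diameter σ = 70 nm is the midpoint of two limiting
estimates implemented in `estimate_monomer_size`: compact packing of six
nucleosome volumes (σ ≈ 6^(1/3)·10 nm ≈ 18 nm) and a worm-like-chain
end-to-end distance R ≈ L·sqrt(2/e) ≈ 136 nm for the six-nucleosome array
(L = 6·(16.5 + 10) nm). Each bead is typed A (active, ChromHMM states
1–11) or B (repressive, states 12–15).

Energy terms (reduced units σ = 1, k_BT = 1 internally):

- **Chain bonds** `U^S`: FENE with Kremer–Grest constants k = 30, R₀ = 1.5
  plus a unit-amplitude WCA core. Together with the pair repulsion this
  prevents chain crossing.
- **Loop bonds** `U^L`: permanent tethers between CTCF anchor beads.
  These are harmonic about the chain-bond rest length (0.9609 σ, k = 30)
  with the restoring force capped at k·1 σ. The cap is the package's
  design choice: collapses start from extended conformations in which
  anchors are separated by hundreds of σ, where a finitely extensible bond
  is undefined; a capped-harmonic tether pulls distant anchors together at
  a constant force (30 k_BT/σ) well below the excluded-volume force scale,
  and behaves as an ordinary stiff bond once anchors are adjacent.
- **Pair term** `U_LJ`: a 12-6 potential split into a unit-amplitude WCA
  core plus an attractive branch scaled by the type-pair well depth
  (ε_AA = ε_BB = ε, ε_AB = ε·9/11), truncated and shifted at 2.5 σ. For
  ε_ab = 1 this is exactly the standard Lennard-Jones potential; for
  ε_ab = 0 it reduces to the athermal (self-avoiding) reference, so the
  excluded volume never vanishes as attraction is tuned. Setting
  eps_ratio = 1 yields the pseudo-homopolymer control in which the pair
  energy is independent of labels.

Chain-bonded and loop-bonded pairs are excluded from the pair term (their
repulsion lives in the bond). No confinement is applied; collapse is
purely attraction-driven.

## Integrators

Custom numba kernels with a cell-list Verlet neighbor list (skin 0.4 σ,
rebuilt on a half-skin displacement criterion; results are verified
independent of the skin).

- **Brownian** (overdamped Euler–Maruyama): x ← x + F·dt/ζ +
  sqrt(2k_BT·dt/ζ)·ξ. Stability requires dt ≪ ζ/k_stiff with k_stiff up to
  ~2·10³ ε₀/σ² for close WCA contacts; dt = 10⁻⁴ (ζ = 1) is the default
  and is used for all production dynamics. dt = 2·10⁻⁴ is marginal in
  dense globules and occasionally ejects a bond from the FENE domain; the
  integrator aborts with the failing step rather than continuing.
- **Langevin** (BAOAB, unit mass): second-order; γ = 0 with fixed initial
  velocities reduces to velocity Verlet (energy drift < 10⁻⁴ per step is
  verified). dt = 0.01. Low friction (γ = 0.1) is used to *sample*
  conformations quickly (collapse preparation, static observables); unit
  friction gives diffusive dynamics on time scales ≫ 1/γ and is used for
  long relaxation runs (χ₄) and collapse kinetics.

This statics/dynamics split mirrors standard practice for dense polymer
models: contact maps, distance maps, P(s) and the contact–distance
exponent λ are ensemble/time averages and are measured on Langevin
sampling runs; MSDs, F_s(k,t), χ₄ and Van Hove functions are measured on
Brownian production runs. Measured at desk scale, λ from a short Brownian
production run is biased high (~6) because pair distances are nearly
frozen over the accessible window, while Langevin sampling runs of ≥ 10³ τ
give λ ≈ 3.8–4.2.

Time mapping: `map_time` converts reduced time to seconds via Stokes drag,
τ = ζσ²/k_BT with ζ = 6πη(σ/2); with η = 0.01 Pa·s (nucleoplasm-like) and
σ = 70 nm, τ ≈ 8 ms. All reduced-scale statements in this package are
exponent-based, not absolute-time-based.

## Synthetic inputs

`synth_annotation` draws alternating A/B blocks with geometric lengths,
defaults mean_block_len = 20 beads (≈ 24 kb, a typical epigenetic-domain
scale) and fraction_A = 0.24 (the active/repressive balance of a
gene-dense human region, roughly one active locus in four).
`synth_loops` draws anchor pairs with exponential spans (default mean 40
beads ≈ 48 kb) at a density of about one loop per 100 beads. These are the
study conditions used by the test-suite ensembles and the acceptance
script. `synth_trajectory` provides static/ballistic/Brownian/caged
analytic fixtures with closed-form MSDs for estimator verification.

What the generator does *not* emulate: real ChromHMM tracks have
long-range correlated state structure and loop anchors cluster at domain
boundaries; passing tests therefore demonstrate correct model mechanics
and estimator behavior under realistic bulk composition, not agreement
with any specific chromosome.

## Observables and numerical choices

- **Contacts**: r_c = 2 σ threshold, pairs counted once per frame. P(s) is
  the mean probability at each separation; a log-binned variant (20
  bins/decade) feeds the two-segment crossover fit, which scans all
  breakpoints and flags degenerate (single-regime) curves.
- **Compartments**: Spearman correlation of contact-map rows with a
  1-bead diagonal exclusion band (near-diagonal contacts are almost
  deterministic and would swamp the ranks), pairwise-complete columns;
  spectral co-clustering of the shifted-nonnegative map; AMI scoring.
  On planted checkerboards at 2:1 contrast the pipeline recovers blocks
  exactly; the pseudo-homopolymer control gives |AMI| < 0.05 against the
  A/B annotation. At N ≈ 320 the *copolymer's own* contact map does not
  yet yield annotation-correlated compartments (a small globule holds a
  single A-cluster on its surface); megabase-scale checkerboards require
  longer chains.
- **TADs**: directionality index with the stated sign(B−A)·χ²-like form;
  beads whose window is truncated by a chain end are set to zero.
  Boundaries are called from persistent sign runs (run length ≥ window/4),
  a deterministic simplification of the original HMM caller.
- **g(r)**: shell histograms normalized by the ideal-gas pair count of a
  finite sphere (the shell-overlap factor 1 − 3x/4 + x³/16, x = r/R, is
  applied; uniform random points give g ≈ 1 at all r). A `min_sep`
  chain-separation exclusion is available because with blocky annotations
  the like-type first peak is otherwise dominated by trivially adjacent
  neighbors; segregation statements use min_sep = 4.
- **Radial density**: ρ_α(r) = ⟨N_α(r)⟩V/(4πr²Δr N_α) with V from r_max
  (default: the largest observed COM distance; 17 σ is the full-scale
  convention).
- **R(s), δR(s)**: R(s) is the root mean squared pair distance at
  separation s; δR(s) is the coefficient of variation over the pair-and-
  frame population (a rod gives δR ≡ 0; duplicated frames add nothing).
- **WLM**: Ward agglomeration applied directly to the mean-distance
  matrix, cophenetic matrix returned. Ward's variance interpretation
  assumes Euclidean input; applying it to a distance matrix is a
  deliberate choice and the output is still a valid ultrametric summary
  (the ultrametric inequality is property-tested).
- **λ**: ridge of the 2-D histogram of (log R_ij, log 1/C_ij) — bin-mean
  abscissa, ≥ 5 pairs per bin — fitted over R ∈ [1 σ, 2 Rg] (below 1 σ the
  core dominates, above 2 Rg the statistics die).
- **Dynamics**: Δ(t) is COM-subtracted by definition. Per-locus MSDs,
  F_s(k,t) and χ₄ additionally accept `com_frame=True`, used in all
  reduced-scale analyses: at N ~ 300–500 the whole-globule diffusion
  D_com = k_BT/(Nζ) is comparable to caged per-locus motion and would
  otherwise drag every exponent toward 1 (irrelevant at N = 10⁴).
  F_s uses the exact isotropic average sin(k·Δr)/(k·Δr). χ₄ is the
  across-trajectory variance of origin-averaged F_s, scaled by N. The
  Van Hove estimator pools all three coordinates (isotropy) and runs its
  Gaussianity KS test on non-overlapping origins so the samples are
  independent; the exponential tail is fitted beyond the 95th percentile
  of |Δx|/γ.
- **Fit windows** (chosen from slope-structure analysis and frozen):
  the MSD exponent uses lags [0.05, 5] τ — after the caging dip in the
  local slope (near lag 0.1 τ) and far below finite-size saturation at
  2Rg². The droplet coarsening window runs from the earliest droplet-count
  maximum (formation complete) to the frame where the mean droplet holds
  80% of the chain (saturation). Droplets are connected components with
  linkage radius 2 σ, |i−j| > 1, minimum 10 beads.

## Desk-scale expectations and limitations

Problem sizes used by the test suite: a shared N = 320 chain (3-seed
Brownian ensembles of 15 τ, 5-seed unit-friction relaxation ensembles of
600 τ, one 1500 τ sampling run), an N = 500 ensemble for the global MSD
exponent and droplet kinetics, and one N = 800 sampling run (Rg-adaptive
collapse) for the two-regime P(s). The acceptance script uses N = 500
with 5 seeds.

At these sizes the collapsed ε = 2.4 globule reproduces the full-scale
phenomenology in weakened form: MSD exponent ≈ 0.5 (vs 0.45 full-scale;
surface loci are a large fraction of a small globule), small-s P(s)
exponent ≈ −0.75 … −0.85, λ ≈ 4, droplet growth ≈ t¹, δR(s) rising then
falling, strong A/B segregation with A on the periphery, single-cell WLM
correlations far below 1, stretched F_s (β ≈ 0.5) and a dominant interior
χ₄ peak. The ε = 1.0 control also collapses (it is still a poor-solvent
chain) and segregates weakly, so liquid-vs-glass distinctions are asserted
as strict contrasts (relaxation-time ratios, stretching ordering,
susceptibility amplitudes) rather than as presence/absence. The
quantitative large-s P(s) exponent −1.25 emerges with chain length; at
N = 1000 the intermediate regime between the crossover and the finite-size
plateau already fits ≈ −1.25 ± 0.1, while the asymptotic regime proper
requires chains several times longer.
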