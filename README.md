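# sptmotion

Classification-based motion analysis for single-particle tracking (SPT).

## The problem

Single-molecule fluorescence tracking in heterogeneous environments —
molecules diffusing through porous catalysts, polymer films, cell
membranes — produces thousands of *short* trajectories with *mixed* motion
behaviour: emitters adsorb and desorb, so a single track may be immobile,
freely mobile, or a hybrid of both. Mean-squared-displacement (MSD)
analysis of individual short tracks is noisy and biased, and fitting one
model to the pooled data only returns a meaningless average.

`sptmotion` implements the population-based workflow for this situation:

1. **Import** localization/tracking tables (CSV/TSV, e.g. DoM ImageJ
   exports) and discard tracks with fewer than five localizations.
2. **Describe** every trajectory by scalar properties: number of points,
   path length, tortuosity, gyration-tensor elongation and orientation,
   positional entropy, minimum bounding circle radius (MBCR), and the
   distance between bounding-circle centre and centre of mass (MBCC–CoM).
3. **Classify** trajectories into motion populations (immobile / hybrid /
   mobile) with a binary threshold tree — authored by hand as JSON, or
   trained from ~100 user-labelled examples by CART induction (Gini
   impurity, at most five splits).
4. **Quantify** each population: time-averaged MSD (T-MSD) per trajectory,
   time–ensemble-averaged MSD (TE-MSD) per population, and the survival
   function of squared displacements with exponential-mixture fitting.

A two-state transient-trapping **simulator** (immobile state D₁ = 0,
mobile state D₂ = 10⁻¹² m² s⁻¹, switching probability 0.02 per frame,
focal-slice visibility, defocus-dependent localization error) generates
synthetic data with ground-truth labels, so the entire pipeline is
testable without external data.

## The model

For one trajectory with positions x₀, x₁, …, x_N at frame interval Δt,

    T-MSD(t_n) = 1/(N−n+1) · Σᵢ |x_{i+n} − x_i|²,   t_n = nΔt

and the TE-MSD averages the per-trajectory T-MSD over the J_n trajectories
long enough to contribute at each delay. For free 2-D normal diffusion
observed with localization error σ and motion-blur coefficient
R ∈ [0, 1/4] (R = 0 instantaneous exposure, R = 1/6 full-frame exposure),

    MSD(t_n) = 4 D t_n + 4(σ² − 2 R D Δt)

so a straight-line fit of the shortest delays gives D from the slope and σ
from the intercept. At fixed delay, normal diffusion implies an
exponential survival function of squared displacements,

    1 − CDF(r², t_n) = exp(−r² / MSD(t_n)),

and multiple decay rates expose hidden sub-populations, which `sptmotion`
quantifies by expectation-maximization fitting of a two-component
exponential mixture.

## Worked example

Simulate a transient-trapping experiment, train a tree on 100 labelled
tracks, classify, and report per-population diffusion constants:

```sh
sptmotion simulate --seed 7 --out tracks.csv --labels-out truth.csv
sptmotion import --table tracks.csv --units m --dt 0.05 \
    --min-localizations 5 --out filtered.csv
sptmotion properties --tracks filtered.csv --out props.csv
# training.csv: 100 rows "id,label" — here taken from truth.csv
sptmotion train --properties props.csv --training training.csv --out tree.json
sptmotion classify --tracks filtered.csv --properties props.csv \
    --tree tree.json --out labelled.csv
sptmotion report --tracks labelled.csv --out report.json
sptmotion cdf --tracks labelled.csv --population mobile --out surv.csv --seed 0
```

which prints, stage by stage:

```
simulated 120 walkers x 300 frames -> 1932 observed trajectories
imported 1932 trajectories, kept 648 after filter
trained tree with 5 splits; resubstitution loss 0.000
mobile: 516; hybrid: 117; immobile: 15
3484 displacements at lag 1; mixture scales 1.59e-15, 1.36e-13
```

and `report.json` contains (abridged):

```
hybrid    n= 117  D =  1.45e-14 ± 2.0e-15 m²/s
immobile  n=  15  D = -2.58e-16 ± 1.5e-16 m²/s   σ = 31 nm
mobile    n= 516  D =  8.93e-13 ± 3.4e-14 m²/s
```

Reading the numbers: the immobile population's D is consistent with zero
(apparent motion is pure localization error); the mobile population's D
sits a few percent below the simulated D₂ = 10⁻¹² m² s⁻¹ because a small
fraction of immobile displacements contaminates the mobile class — visible
directly in the squared-displacement mixture fit, where ~2% of lag-1
displacements follow the fast-decay (immobile) component with scale
~1.6·10⁻¹⁵ m² while the rest follow the mobile component (~1.4·10⁻¹³ m²,
i.e. the lag-1 MSD). Negative per-track D estimates are expected for
noise-dominated tracks and are reported, not clipped.

The same pipeline is available as a library (`sptmotion.simulate_ground_truth`,
`compute_properties`, `train_tree`, `te_msd`, `fit_msd_linear`, …); see the
docstrings and `docs/methods.md`.

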