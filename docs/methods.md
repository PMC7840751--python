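# Methods

## Scope and model

`oraitraffic` reimplements, as a tested pipeline on synthetic data, the
computational core of the finding that the strength of the Orai1 C-terminal
intersubunit coiled coil (CC) controls Orai1 endocytosis during oocyte
meiosis. Four pieces interlock:

1. **Construct panel** (`sequences`): the wild-type human Orai1 plus the
   truncation/point-mutant panel assayed for internalization (1-266, 1-275,
   1-285, F270A, F279A, F270,279A, A277,280L, L273S, Y52,W55A,
   Y52,W55,F270,F279A), all in 1-based full-length UniProt numbering.
2. **CC scoring** (`coils`): sliding heptad-window propensity scoring and a
   two-Gaussian probability calibration.
3. **Stack simulation** (`simulate`) and **quantification** (`quantify`):
   two-channel confocal z-stacks with known ground truth, and the
   marker-peak percent-PM statistic plus PM-plane Pearson colocalization.
4. **Synthesis** (`correlate`, `pipeline`): the per-construct join of max CC
   probability against egg-stage percent-PM and its Pearson correlation.

## Sequences

The full-length hOrai1 (301 aa) ships as a FASTA fixture; unit tests pin
every landmark the analysis indexes into (CBM 52-YPDWIGQSY-60, the FXXΦ
motifs at 270 and 279, L273, A277/A280, C-terminus 260-301). Extracted
fragments keep full-length numbering through `numbering_offset`, so residue
270 of a 260-301 fragment is still residue 270.

The two *Xenopus* isoform C-termini are **synthetic stand-ins** (flagged in
the FASTA headers): the true accession sequences could not be bundled, so
hOrai1-derived sequences were constructed to embody the isoform series'
described properties — F279 not conserved, F270 weakly conserved, and CC
strength ordered xOrai1 > hOrai1 > xOrai2. Results on these fixtures test
the pipeline's discrimination, not the real *Xenopus* proteins.

## Coiled-coil scoring

For a window of `w ∈ {14, 21, 28}` residues placed at every offset, and each
of the 7 heptad frames, the window score is the weighted geometric mean of
per-residue propensities for their frame-assigned heptad positions
(`a`-`g`). Each residue's raw score is the maximum over all covering
placements × frames; terminal residues simply see fewer placements, which is
the natural behaviour on C-terminal fragments. Propensities are the newer
residue table of the classical CC predictor (frequency in two-stranded
coiled coils over database frequency), floored at 1e-4 so hard-zero entries
(e.g. proline) stay finite in log space.

**a/d weighting (default on, weight 2.5).** The core positions `a`/`d`
define coiled-coil packing; up-weighting them is the standard guard against
false positives from charged-residue enrichment at the other five positions.
It matters here: the hOrai1 C-terminus is acidic-rich, and without core
weighting a window that excludes L273 dominates the profile maximum, hiding
the known destabilizing effect of L273S. With weighting, every reported
direction (stabilization by F270A/F279A/F270,279A/A277,280L, destabilization
by L273S, segment retention by 1-285 but not 1-275/1-266) is reproduced at
window 14.

**Probability.** Raw score `s` maps to `p = g_cc(s) / (g_cc(s) + 30·g_g(s))`
where `g_cc`, `g_g` are Gaussian densities of the coiled-coil and globular
score distributions and 30 is the globular prior. The constants per
(matrix, window, weighting) were fitted once by Monte Carlo, 2×10⁵ windows
per class: globular windows drawn iid from database background composition;
CC windows drawn per heptad position from `P(res|pos) ∝ background ×
propensity`, which is the propensity table's own generative reading. The fit
is frozen in `_coils_data.py`. On this calibration `p` is strictly
increasing on the attainable score range (the two-Gaussian ratio's turning
point sits below score 0.2) and saturates in float beyond ~4 SD.

**Absolute scale caveat.** Directional comparisons (mutant vs WT, isoform
ordering) are robust to the matrix/calibration choice; absolute probability
values are not. On this calibration the hOrai1 C-terminal coil scores 0.71
at window 14, which is above the ≤0.4 level the original server reported for
the isoforms — reproducing exact server curves would require the exact
matrix file and options used there, which are not recorded. The segment
threshold (default 0.5, configurable) cleanly separates retained coils
(WT/1-285, ~0.71) from destroyed ones (1-275/1-266, ≤0.40) on this scale.

## Stack simulation

Geometry: z index 0 is the outermost ("surface") slice, increasing inward
("deep"); slices 0.5 µm apart; frames default to 512×512 pixels at 0.25 µm.
The z-order tag travels in the file metadata and its absence is a hard
error, because the statistic is direction-sensitive.

The marker channel is a flat PM sheet with a Gaussian axial profile (σ 0.4
µm) centred on `pm_plane`; a curved-cap variant exists for robustness tests.
The cargo channel splits its total mass exactly: fraction `f` in the
`pm_plane` slice, `1-f` across Gaussian vesicle puncta (radius 0.4 µm)
strictly deeper than the PM (default ≥ 4 slices below; axial tails are
clipped at the PM plane and the vesicle mass renormalized so the ideal-scene
surface/cytoplasm split equals `f` exactly). Both channels are blurred with
an anisotropic Gaussian PSF, then background is added, Poisson shot noise is
applied at `photon_scale`, and zero-clipped Gaussian read noise is added.
Same config + seed gives bit-identical stacks.

Defaults were chosen once to represent the regime in which the marker-peak
statistic is an unbiased estimator, and the known bias terms are worth
stating because they bound that regime:

* **Axial PSF** (σ_z = 0.10 µm default): a symmetric axial blur of the PM
  sheet leaks `P(|X| > z_step/2)`-type tails past the peak slice; under the
  through-peak convention this costs ≈5 points at f=1 for σ_z = 0.15 µm and
  ≈31 points for σ_z = z_step. The default models a deconvolved high-NA
  stack; for thicker PSFs the past-peak convention (surface through peak+1)
  stays within 5 points up to σ_z = z_step, and both regimes are covered by
  tests.
* **Background** (0.25 intensity units ≈ 0.25% of the PM-sheet amplitude):
  a constant offset contributes `bg·n_cyto_slices/total` of spurious
  cytoplasmic signal; the ~90% oocyte readings the statistic was designed
  around imply background well below signal. Optional constant-background
  subtraction is available but off by default, matching the described
  analysis.
* **Read noise** (σ = 0.5): clipping negative excursions at zero rectifies
  read noise into an effective extra background (~0.3 units/pixel at σ=1),
  which is why the default is modest.

What the generator does **not** model: curved oocyte surface by default,
realistic Airy/aberrated PSFs, photobleaching, stage drift, per-cell
heterogeneity of expression. Passing recovery tests therefore show the
statistic is correctly implemented and unbiased under the stated model, not
that it is unbiased on arbitrary real stacks.

Colocalization pairs are built from shared + independent Gaussian fields
mixed to a target Pearson ρ (exact in expectation; ±1 gives deterministic
equality/opposition), then affinely shifted to a positive intensity scale.

## Quantification

The PM is the z slice with maximal slice-summed marker intensity (global
peak per stack, ties toward the outermost slice). Partitions by marker role:

| role | surface | cytoplasm |
|---|---|---|
| `pm_marker`, through-peak (default) | `[0..p]` | `[p+1..]` |
| `pm_marker`, past-peak | `[0..p+1]` | `[p+2..]` |
| `cytoplasmic_marker` (Rab5) | `[0..p-1]` | `[p..]` |
| `caveolin_pm_above` | `[0..p-1]` | `[p..]` |

The two sentences describing the original partition conflict about the
peak-adjacent slice; the through-peak reading is the default because it is
exhaustive and non-overlapping, and the alternative is a flag. Degenerate
partitions (peak at a stack edge) are flagged, not fatal. Percent-PM is
invariant to positive scaling of the cargo channel and to constant offsets
on the marker channel. Group summaries report mean ± SEM (sd/√n, n−1
denominator; n=1 flagged), and group comparisons delegate to SciPy's t
test / one-way ANOVA with the 0.05/0.01/0.001 significance tiers.

## Panel correlation

One Pearson implementation (`stats.pearson_r`) backs both the PM-plane pixel
colocalization and the panel correlation; constant input is a hard error,
never silently 0. The panel join refuses fewer than 3 records. The response
defaults to egg-stage percent-PM, with oocyte−egg internalization as an
option. The end-to-end run maps each isoform's computed CC probability `q`
to a true egg PM fraction `f = 0.2 + 0.6q` (oocytes fixed at 0.9), so the
measured percent-PM is, up to simulation noise, an affine function of `q`
and the recovered r is expected near +1 — a self-consistency check of the
whole chain, not a reproduction of measured biology. With n=3 points the r
carries no meaningful uncertainty and no CI is reported.

## Problem sizes

Tests and the acceptance script simulate 48–128 px frames with 12–16 slices
and 10–20 replicates per condition — large enough that the recovery
envelopes (±5 points percent-PM, ±0.05 colocalization) are dominated by the
model's bias terms rather than sampling noise, while the whole suite runs in
well under a minute of simulation time.

## Known limitations

* Absolute CC probabilities depend on an unrecorded matrix/option choice of
  the original server run; only directions and orderings are claimed.
* The *Xenopus* isoform fixtures are labelled synthetic stand-ins.
* The percent-PM statistic inherits the documented background and axial-PSF
  sensitivities; real stacks with thick PSFs should use the past-peak
  convention and/or background subtraction.
* No segmentation, deconvolution, ROI restriction or per-image
  normalization is applied before summing.
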