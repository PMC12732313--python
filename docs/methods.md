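# Methods

`fkpkit` analyses the evolution and biochemistry of bifunctional
L-fucokinase/GDP-fucose pyrophosphorylases (FKPs) — single polypeptides
carrying an N-terminal pyrophosphorylase (GFPP) domain and a C-terminal
kinase (FUK) domain. Every analysis can be exercised end-to-end on
synthetic data with known ground truth; this note records the models,
the defaults, and what the synthetic data do and do not emulate.

## Domain-architecture classification

Architectures are read off ranked profile-HMM hits to three diagnostic
models: COG2605 (monofunctional fucokinase), PF07959 (GDP-fucose
pyrophosphorylase) and PRK13412 (full-length bifunctional FKP).
"Highest-scoring" is interpreted as bit-score descending with
lexicographic tie-breaks on model id — deterministic, and matching
hmmscan's primary sort. Model ids are matched case-insensitively after
trimming version suffixes (`PF07959.22` → `PF07959`), since real Pfam
hits carry versions. Membership rules:

* **FUK set** — top model in {COG2605, PRK13412}, or PF07959 plus one of
  those two filling the top two ranks.
* **GFPP set** — top model in {PF07959, PRK13412}, or COG2605 plus one
  of those two filling the top two ranks.
* **FKP set** — all three diagnostic models within the top three ranks.
  It follows from the rules that FKP membership implies both of the
  others before length filtering; the test suite asserts this on random
  tables.

Length filters then revoke memberships: minima of 333 (FUK), 406
(GFPP) and 739 (full-length FKP) residues, maximum 1745 for all sets.
The 739 minimum is the default; a 745 variant is available as
`LengthThresholds.figure_preset()`. Proteins with fewer than three hits
can never enter the FKP set; proteins with no hits belong to no set.

## Sequence similarity networks

Edges join proteins whose global pairwise percent identity meets a
threshold. Identity is computed from an affine-gap global alignment
(BLOSUM62, gap open −10, extend −0.5 — conventional protein defaults)
as 100 × matches / alignment length, gap columns included; dividing by
the shorter sequence length instead is a config switch. Keying edges on
percent identity (30–40% range) rather than on server-specific
alignment scores keeps the construction fully reproducible in-repo.
Clusters are connected components, numbered by decreasing size then by
lexicographically smallest member; components below `min_size` (default
2) are labelled unclustered (0). Congruence with phylogenetic clades is
reported as a cluster × clade contingency table with per-cluster purity
(majority-clade fraction) and an overall size-weighted purity.

## Fusion-history phylogenetics

Root positions are modelled as points on edges (the rooting edge is
bisected), which matches midpoint semantics and edge-based rooting
support. Midpoint rooting minimizes the maximum root-to-tip distance;
ties between equally long tip-to-tip paths are broken by the
lexicographically smallest tip pair. Zero-length branches and
polytomies are accepted throughout.

For a tip set S (the fused proteins), the set of monophyly-compatible
root positions is computed from the structure of the unrooted tree: S
is monophyletic under a rooting iff some edge f bipartitions the tips
into exactly S versus the rest, and the root lies on f or anywhere in
the complement component. `min_clade_cover` counts the maximal clades
whose tips all belong to S and which jointly cover S — equal to 1
exactly when S is monophyletic.

Fusion-event parsimony uses unit-cost dynamic programming over ancestral
states (exact on multifurcating trees). The `dollo` mode constrains
histories to at most one 0→1 gain, placed on the branch above the MRCA
of the fused tips; each maximal fully-unfused clade inside that subtree
counts as one loss. All four tree operations are validated against
brute-force oracles (discretized midpoint search at 1e-4, physical
reroot-and-test enumeration, greedy laminar cover, exhaustive ancestral
labelings) on 100 random trees of up to 10 tips.

## Conservation census

Positions of interest are stated on the ungapped coordinates of a
reference sequence (G75, R79, K88 in the pyrophosphorylase domain;
R597, D606, D767 in the kinase domain) and mapped to alignment columns.
A row is excluded when it is gapped at *every* column for reference
positions 1..88 — its alignment effectively starts after the K88
boundary; the boundary residue is included in the window, reading
"aligns only after K88" strictly. "Conserved" means identical residue
(the near-100% kinase positions are described as invariant, implying
identity), and a gap at a scored column counts as non-conserved rather
than excluded, so that proteins genuinely lacking a residue are counted
as lacking it. Rows non-conserved at one or more positions of a subset
can be stratified by clade; fractions sum to 1.

## Enzyme kinetics

The kinase assay couples ADP production to NADH oxidation (pyruvate
kinase / lactate dehydrogenase), read as an absorbance decrease at
340 nm — one NADH per phosphorylated sugar, so a falling trace yields a
positive rate. The pyrophosphorylase assay reads malachite-green
phosphate detection at 635 nm after an inorganic pyrophosphatase splits
the PPi product; each PPi yields two Pi, so the phosphate-appearance
rate is divided by a stoichiometry factor of 2 (configurable). Initial
rates are least-squares slopes over a window (default: first 60 s)
converted through linear standard curves; a window with R² below 0.9
warns but still returns the rate.

Saturation data are fitted to v = kcat·E0·S/(KM + S). Where high
substrate suppresses the rate, the uncompetitive substrate-inhibition
form v = kcat·E0·S/(KM + S + S²/Ki) is used; it peaks at S* = √(KM·Ki).
The inhibition phenomenon is reported without an equation in the
experimental literature this emulates, so the standard uncompetitive
form is adopted. Fits run in log-parameter space — positivity without
box constraints — via Levenberg–Marquardt; 1σ uncertainties come from
the residual-scaled Gauss–Newton covariance mapped back by the delta
method. Least squares is unweighted by default with 1/v² weighting
optional. Initialization: KM = median(S), kcat = max(v)/E0 (scaled up
by 1 + 2√(KM/Ki) for the inhibition model). Model choice between the
two forms uses corrected AIC. On plain saturation data the inhibition
fit is flagged `mm_preferred`; note that with multiplicative noise a
finite likelihood-maximizing Ki is expected in a sizeable minority of
such datasets, so the flag — not the raw Ki estimate — carries the
no-inhibition verdict.

Catalytic efficiency kcat/KM (KM converted to molar) propagates
uncertainty to first order: (σ_eff/eff)² = (σ_kcat/kcat)² + (σ_KM/KM)².
Applied to the published parameter pairs, this reproduces all eight
published efficiency central values at printed precision. The printed
σ values mostly reproduce under quadrature as well, but not all (e.g.
the TxFKP Fuc-1-P row propagates to 2.4×10⁴ against a printed 3×10⁴),
indicating the original error propagation method differed in detail;
the package reports the quadrature value. Mutant activities are
normalized as 100 × mean(mut)/mean(wt) with the replicate standard
deviation scaled by the same factor; means below a detection floor are
flagged N.D. rather than reported as zero.

## Melt-curve analysis

Dye fluorescence versus temperature is smoothed and differentiated with
a Savitzky–Golay filter (window 7, degree 3 by default — instrument
exports are already lightly smoothed). Unfolding transitions are
troughs of the negative first derivative; the most prominent troughs
(default prominence floor: 5% of the series range) outside an optional
exclusion window are kept, refined to sub-grid precision by parabolic
interpolation, and reported ascending as Tm1 < Tm2. The exclusion
window (e.g. 66–70 °C) lets a known co-purifying contaminant transition
be ignored; it defaults to off. When fewer transitions than requested
emerge, shoulder transitions are sought as downward zero-crossings of
the second derivative — local maxima of dF/dT too weak to clear the
prominence threshold — gated at 10% of the maximum slope so baseline
noise cannot inject crossings; the derivative order used is recorded
per Tm. Ligand-induced stabilization ΔTm is the mean ± sd of
per-replicate paired differences (replicates paired in order), not the
difference of means with a pooled sd; for balanced complete pairs the
two means coincide, which the suite checks.

## Synthetic data

All generators are pure functions of (config, seed) via
`numpy.random.Generator`; identical seeds give byte-identical output
files.

* **Families.** Ancestor sequences are uniform-random over the 20 amino
  acids; family members are point-mutated copies (uniform substitution
  to one of the other 19 residues, no indels), and fused proteins are
  mutated copies of GFPP-ancestor + linker + FUK-ancestor. Default
  substitution rate 0.15 per site puts within-family identity near 72%
  and cross-architecture identity (fused versus monofunctional) near
  33–37%, so a 40% identity threshold separates the three families —
  the regime the SSN tests exercise. Domain lengths (450/20/400)
  clear the length filters.
* **Hit tables.** Mean bit scores encode the true architecture (e.g. a
  fused protein scores 150/130/120 on PRK13412/COG2605/PF07959); five
  decoy models at score 30 keep ranking nontrivial, and for
  monofunctional families the runner-up is a decoy so the two-model
  rules cannot misfire at zero noise. Gaussian score noise is
  configurable. E-values and domain coordinates are not emulated.
* **Fusion trees.** Random bifurcating topologies by successive joins,
  uniform branch lengths in [0.05, 0.5]. One internal branch carries
  the single 0→1 gain (the fused subtree is built as a clade so the
  gain branch exists by construction); losses are placed on distinct
  pendant branches inside the gained clade, keeping tip-count
  arithmetic exact, and must leave at least one fused tip.
* **Kinetics.** Rates are the model curves under multiplicative
  Gaussian noise with configurable CV (default 5%, the constant-CV
  behaviour of plate-reader assays), truncated at zero.
* **Melt curves.** Transitions are logistic sigmoids (standard
  two-state unfolding shape) on a 20–95 °C grid at 0.5 °C steps, with
  optional post-peak decay and Gaussian noise (default curves use sd
  2 AU against amplitudes of 500–700, about 0.3–1% of amplitude).
* **Census alignment.** 186 rows plus a reference; 15 rows are gapped
  across the first 200 columns (to be removed by the exclusion rule)
  and drawn from clade C. Per-column identity to the reference is 0.8
  background; at the pyrophosphorylase anchors it is 0.18 for clade C
  rows and 0.96 otherwise, and 0.995 at the kinase anchors. With clade
  sizes 45/46/95 these defaults put expected pyrophosphorylase-anchor
  conservation near 60%, kinase-anchor conservation near 100%, and
  ~88% of lacking rows in clade C — the regime the census analysis is
  designed to measure.

What the synthetic data do **not** emulate: site-rate heterogeneity,
indels within families, realistic substitution matrices, HMM E-values,
coupled-assay lag phases, or instrument drift in melt curves. Passing
tests therefore demonstrate correctness of the algorithms under the
stated statistical structure, not robustness to every artefact of real
sequence databases or plate readers.

## Problem sizes and numerical choices

The oracle comparisons run on 100 random trees of 4–10 tips (exhaustive
parsimony is exponential in internal nodes, and 10 tips keeps the
enumeration exact and fast); parameter-recovery simulations use 200
datasets of 8 substrate levels × 3 replicates; the demonstration
pipeline simulates 15–24 proteins. Midpoint ties use a 1e-12 length
tolerance; the brute-force midpoint oracle discretizes edges at 1e-4.
Nonlinear fits use xtol = ftol = 1e-14 so noiseless recovery is exact
to ~1e-6 relative. Degenerate designs (fewer than 3 distinct substrate
levels, or fewer than 5 for the inhibition model) are rejected rather
than fitted.

## Known limitations

* The SSN identity definition (denominator, gap treatment) is a
  package choice; absolute thresholds are not comparable to
  alignment-score-based thresholds used by external SSN servers.
* Dollo counting assumes the gain sits immediately above the MRCA of
  fused tips; histories with a deeper gain plus extra losses are never
  more parsimonious under unit costs, but are not enumerated.
* kcat/KM σ propagation is first-order; for large relative errors
  (≥50%) the implied symmetric interval is a rough summary.
* Tm extraction assumes a uniform temperature grid and at most three
  transitions per curve.
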