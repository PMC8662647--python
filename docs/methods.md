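# Methods

This note documents the models, numerical choices and known limitations
behind each stage of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Locus integrity screening

**Model.** A candidate locus is the genomic segment between the
annotated *UBE2J2* and *ACAP3* anchors, reverse-complemented to
gene-forward orientation when the anchors sit on the minus strand.
Each exon of a reference gene model is placed by local alignment with
affine gaps (match +2, mismatch −3, open −5, extend −2 — explicit
defaults, since interactive alignment tools report no scores); an exon
counts as mapped at ≥ 60 % identity over ≥ 50 % of its length, and the
mapped set is chained to the best-scoring colinear, non-overlapping
subset (weighted longest-increasing-subsequence DP; verified in tests
against exhaustive subset enumeration on small loci). Coordinates are
0-based half-open internally; GFF3 output is 1-based inclusive.

**Lesion calls.**

* *Splice sites*: canonical GT donor / AG acceptor; any other
  dinucleotide flanking a mapped exon is a disruption. Terminal exons
  have no outer splice site.
* *Frameshift*: the **net** per-exon indel length (insertions minus
  deletions) ≢ 0 (mod 3). The net rather than summed length is used so
  that an exon carrying offsetting indels (+1/−1) is not miscalled;
  in-frame indels (net ≡ 0) are tolerated as benign.
* *Premature stop*: an in-frame stop codon at least one codon upstream
  of the reference stop, where "in frame" means the cumulative net
  shift at that position is ≡ 0 (mod 3) — stop codons appearing
  downstream of a frameshift are consequences of that frameshift and
  are not double-reported.
* *Missing exon*: a reference exon with no placement above thresholds.
* *Status*: `absent` below 3 mapped exons (distinguishing decayed but
  traceable loci from complete absence), `pseudogene` at ≥ 1 lesion,
  else `intact`.
* *Ambiguity*: an exon whose mapped segment is > 20 % `N` is reported
  `unresolved` and contributes no lesions.

**Exon fusion.** A configured exon pair (default 11/12) is fused when
both inner splice sites are non-canonical and the intervening segment
has length ≡ 0 (mod 3) and introduces no in-frame stop into the spliced
transcript (junction codons included). The fusion check runs before
splice-lesion calls so a clean in-frame fusion — a feature, not a
defect — is not reported as two splice lesions. The retained segment is
spliced into the reconstructed CDS; inserted residues = length / 3.

**Limits.** The screen assumes exon order is preserved (no inversions
or duplications) and that lesions are local; it does no de novo gene
prediction. Very short exons in highly diverged loci can in principle
produce spurious sub-threshold placements; the chaining step and the
3-exon absence floor keep these from flipping the status.

## Gene composition

GC is the percentage of G/C among unambiguous bases (`N` excluded from
numerator and denominator). GC3 is the GC of the third-position string
of the CDS, **including** the terminal stop codon by default (the
convention is ambiguous in the field; a flag excludes it). The
gene-size span runs from the designated start codon through the stop
codon, introns included. Coding length is reported in nucleotides.

## Loss phylogenetics

Dollo parsimony with the gene present above the root: a single origin,
irreversible loss. The minimal labelling marks an internal node present
iff any descendant tip is present; each parent-present → child-lost
edge is one independent loss. Polytomies need no special handling, and
a tree whose tips are all lost counts one loss on the root edge.
Correctness is pinned against exhaustive enumeration of all
Dollo-consistent labelings on random 8-tip trees. Note that the loss
count is **not** monotone under present→lost tip flips: flipping the
last present tip inside a clade merges adjacent loss events and can
lower the count; the property tests assert the correct bound (a flip
adds at most one loss). Pseudogene and absent states both map to
"lost" — the distinction matters for family summaries, not for
counting. The packaged fixtures encode the 51 screened genomes
(8 flagged invasive), their families and clades, and a species-resolved
family phylogeny with polytomies where relationships are unresolved.

## Voltage-clamp statistics

Sign convention: inward currents negative; SSI and fold change are
computed on magnitudes with signs reported alongside.

* **ΔI_ami** — mean plateau current (trailing 10 s of the epoch,
  configurable) of the drug-free epoch minus the amiloride epoch in the
  same solution; invariant to constant leak.
* **SSI** — from a 1 → 90 mM Na⁺ switch: the peak is the signed
  extremum within 30 s of the switch on a lightly smoothed trace (1-s
  centered moving average; a raw extremum over ~300 noisy samples would
  bias the peak by the expected maximum of the noise, ≈ 3σ, which at
  σ = 0.05 µA on a 6 µA response inflates SSI by > 1 percentage point).
  The 3-min value is the sample nearest t_switch + 180 s, unsmoothed,
  so zero-noise constructions are recovered exactly.
* **IC₅₀** — least squares on `baseline + span·cʰ/(cʰ + IC₅₀ʰ)` with
  the Hill coefficient fixed at 1 by default (classical amiloride block
  is near-Michaelian; a free-h fit is available). IC₅₀ is parameterized
  on the log scale for positivity. Non-monotonic series (a back-step
  exceeding 25 % of the span) raise a diagnostic warning.
* **Na⁺ activation** — signed Michaelis–Menten `I = V_max·[Na]/(K_M +
  [Na])`, K_M log-parameterized.
* **ANCOVA** — equal slopes across groups is tested as the F-test on
  the group × log₁₀[Na⁺] interaction in the pooled linear model, the
  standard equivalence. Degenerate zero-residual cases return F = 0
  (identical groups) rather than 0/0.
* **Slope conductance** — OLS slope of unitary current (pA) on holding
  potential (mV) within −100…−20 mV (points outside are dropped with a
  warning), reported in pS (×1000).

## Habitat aridity

**Extraction.** The aridity index (AI, precipitation over reference
evapotranspiration; lower is drier) of an occurrence is the median of
all raster cells whose centers lie within a Euclidean 0.02° radius of
the record — degree space, matching the stated protocol, not geodesic
meters. No-data cells are excluded; an all-no-data neighbourhood yields
NaN with a flag. Climate classes follow the generalized scheme:
hyper-arid < 0.03 ≤ arid < 0.2 ≤ semi-arid < 0.5 ≤ dry sub-humid
< 0.65 ≤ humid. Rasters are plain-text ESRI ASCII grids (no GeoTIFF
dependency in this environment).

**Cleaning.** Filters apply in a fixed order — georeferencing, year ≥
1900, study-species list, invasive flags, range polygon, marine mask —
each reporting its removal count; counts always sum to the input size.
Duplicate coordinates are deliberately not deduplicated.

**Gamma GLMM.** For AI `y_ij` of species *i*:
`y_ij | b_i ~ Gamma(ν, μ_ij/ν)`, `log μ_ij = β₀ + β₁·gene_i + b_i`,
`b_i ~ N(0, σ²)`, with shape ν shared. The marginal likelihood
integrates `b_i` out per species by **adaptive** Gauss–Hermite
quadrature: each one-dimensional integral is centered at the species'
posterior mode (Newton on the concave log-integrand, closed-form
derivatives via the sufficient statistics n, Σlog y, Ση, Σy·e^(−η))
and scaled by the curvature there. Plain quadrature centered at zero is
*not* adequate here — with ~25 observations per species the integrand
is a narrow peak far from zero, and the resulting error differs between
null and full models enough to visibly inflate the likelihood-ratio
statistic. The adaptive scheme matches brute-force numeric integration
to ~1e-9 (tested) and, with the sufficient-statistic factorization,
costs O(species × nodes) per likelihood evaluation regardless of the
number of observations. All parameters (β, log σ, log ν) are maximized
jointly by ML (L-BFGS-B with a Nelder–Mead polish; the full model is
warm-started at the null optimum so the LRT statistic is never negative
by optimizer noise). `log σ` and `log ν` are clipped to wide bounds so
degenerate inputs (e.g. zero within-species variance, which drives
ν → ∞) terminate cleanly.

The LRT compares null (random intercepts only) and full (+ gene
presence) ML fits, χ² with 1 df. Species-within-clade nesting adds an
outer plain quadrature over the clade intercept (few clades, smooth
integrand); a fit whose outer SD collapses below 10⁻³ is treated as
singular and the species-only model is used, mirroring standard mixed-
model practice. r² follows the marginal/conditional variance
decomposition on the latent scale with observation-level variance
trigamma(ν); "variance explained by species effects" maps to the
conditional r² of the null model.

**Note on lme4.** R's `glmer` was evaluated as a cross-check and found
not to maximize this marginal likelihood for Gamma families (its
optimum scores far below the quadrature-verified optimum on identical
data), so the independent oracle in the tests is direct numeric
integration, not lme4.

## Synthetic data

Generators are pure functions of their spec; the seed is split into
named substreams (CRC-stable, not Python's salted `hash`) so adding a
lesion to a plan does not perturb the underlying gene sequence.

* **Loci** — a 12-exon gene (labels 2–13, lengths 63–300 nt with a long
  terminal exon, GC target 0.58 reflecting the compact GC-rich gene
  this models), GT…AG introns of 150–400 nt, flanking 300-nt anchor
  genes and 150-nt spacers. Lesions are planted by direct sequence
  edits at recorded coordinates; the fusion plan replaces the exon
  11/12 intron with a stop-free in-frame segment whose terminal
  dinucleotides are forced non-canonical. An `absent` locus is pure
  random sequence between the anchors.
* **Traces** — piecewise: 90 mM baseline, amiloride block, washout,
  1 mM reference, then a Na⁺ switch whose response peaks instantly,
  holds a 2-s plateau (so the smoothed peak detector is exact at zero
  noise) and decays single-exponentially (τ = 30 s), calibrated so the
  180-s point hits the SSI target exactly; Gaussian noise (default
  σ = 0.05 µA) is added last. Only the peak and 180-s values matter for
  SSI, so the decay shape is a modelling convenience, not a claim about
  channel kinetics.
* **Habitat** — per-species mean AI `exp(β₀ + β₁·gene + b_i)` with
  gamma shape 4 (log-scale residual SD ≈ 0.53) and species SD 0.53, so
  random effects explain roughly half the latent variance as in the
  real data; intercept e^β₀ ≈ 0.45 (semi-arid). Each observation
  occupies its own raster cell (cell size 0.05° > 2 × the 0.02°
  radius), painted with exactly the drawn AI, so median extraction
  returns the draw unchanged and round-trips are exact.

**What a green test does not establish.** The synthetic world has no
alignment ambiguity from deep divergence, no GBIF sampling bias or
spatial autocorrelation, no correlated trace drift, and no phylogenetic
signal in the habitat model beyond the species intercepts. Green tests
establish that the estimators recover what the stated models plant —
not that the published measurements are reproduced, which would require
the original recordings and the full occurrence extract.

## Scaling of stochastic checks

The type-I-error acceptance check runs 1,000 null GLMM simulations at
40 species × 25 observations rather than the study's ~5,000
observations per species: the LRT's calibration is governed by the
number of species-level clusters (40, matching the study's scale), and
the smaller per-species count keeps the check inside a desk-time
budget. The sufficient-statistic likelihood makes per-species cost
independent of observation count anyway.
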