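# Methods

`siteabpp` implements the computational core of site-specific competitive
activity-based protein profiling (ABPP): given per-protease tables of
probe-modified peptides with label-free intensities across an inhibitor
dose series, it resolves each peptidoform to the exact covalently labeled
protein residue, pools the evidence into binding-site groups, and estimates
per-site apparent IC50s with confidence intervals.

## Site localization

A covalent probe (the pan-kinase probe targeted here carries a sulfonyl
fluoride warhead and leaves a clicked phosphonate adduct of 754.2532 Da on
lysine, and also tyrosine) is reported by the search engine as a variable
modification at a position inside the identified peptide. The labeled
residue in the proteome is then

    residue = peptide_start + in-peptide position − 1

with 1-based inclusive coordinates throughout — "lysine 646" means position
646 of the canonical sequence.

Peptide localization is exact substring search over the whole proteome,
because the nonspecific protease path (pepsin) places peptide termini
anywhere: enumerating all nonspecific peptides is combinatorial, whereas
locating the observed ones is cheap. The index concatenates all sequences
with a separator and scans with `str.find`; it is contractually identical
to a naive per-record scan, which the test suite enforces by comparison
against that oracle. I and L are distinct characters (the search engine
reports the database-resolved sequence); a flag can enable I=L equivalence.
Non-canonical residues (X/U/B/Z) never match. Tryptic and chymotryptic
peptides are enumerated positionally from the cleavage rules (K/R and
F/L/Y/W respectively, C-terminal cleavage, no proline suppression by
default, ≤2 missed cleavages, length 5–30), validated against brute-force
substring enumeration and against an independent library digester.

A peptide whose sequence occurs in several proteins — common for homologous
kinase ATP pockets — forms a *multi-protein site group* keyed by its full
sorted member set, rather than being apportioned to one member. Unique and
shared sites therefore never mix in one group, shared sites count once in
site tallies, and expand to their members only for distinct-protein
tallies. A rare peptidoform carrying two probe adducts contributes its full
intensity to both residues' groups and both groups are flagged; splitting
the intensity would invent an apportionment the data do not support.

## Quantification

Peptidoforms must be present (any positive intensity; label-free tables
write 0 for "not quantified", which is treated as missing, never as zero
signal) in at least two vehicle-control (DMSO) replicates of their own
protease. Surviving peptidoform intensities are summed per site and sample;
a site-sample with no surviving evidence stays missing and is excluded from
fits rather than imputed. Conservation — per sample, the matrix total
equals the retained single-site peptide total — is asserted on every run.
Intensities are consumed as-is: label-free normalization belongs to the
upstream search engine; an optional per-sample median centering exists but
is off by default.

## Dose-response model

The response is the log2 site intensity (the quantity such experiments plot
and fit). For inhibitor concentration `c`:

    y(c) = bottom + (top − bottom) / (1 + (c / IC50)^h)

fitted in concentration space so the DMSO control (dose 0) anchors the top
plateau exactly — no pseudo-dose is invented for the control. Internally
the fit is parameterized by log10(IC50); the Hill slope is free within
[0.1, 10]. Optimization is trust-region least squares with an analytic
Jacobian and deterministic multi-start (log10 IC50 started at every tested
dose, slope variations at the geometric mid-dose; plateau starts from the
mean responses at the extreme doses), followed by a high-precision polish
of the best minimum. On a near-flat series the IC50/Hill directions are
unidentifiable and the trust region converges slowly; iteration-capped
minima are kept (flagged `iteration_capped`) rather than discarded, and
`not_fit` is reserved for genuine failure (fewer than four distinct dose
levels, or non-finite results from every start).

The 95% interval is a t-interval on log10(IC50) from the residual-variance
scaled parameter covariance (Gauss–Newton approximation), back-transformed
to nM — hence asymmetric in concentration, as printed dose-response
intervals are. A 1,000-replicate Monte-Carlo calibration at the default
design measures empirical coverage ≈ 0.92–0.95.

### Competed / stable classification

A site is *competed* when (i) the 4PL beats the constant model in an
extra-sum-of-squares F-test at p < 0.05, (ii) the fitted drop is ≥ 1 log2
unit (two-fold), and (iii) the IC50 is within one decade of the tested
range; *stable* when the F-test is not significant; *ambiguous* otherwise
(significant but shallow, or out-of-range midpoint). These thresholds are
this package's operational definitions — site-level competition studies
report such calls without printing criteria. IC50s outside the tested
range are reported but flagged `extrapolated`.

### What the fitted IC50 estimates

Competition acts multiplicatively on intensity: the expected intensity is
`base × [b + (1−b)/(1+(c/K)^h)]` with `b` the fraction remaining at full
competition. After log2 transform this curve is *not* a 4PL, and the 4PL
fitted to log2 data estimates the dose at which the log2 signal sits midway
between its plateaus, which is exactly

    K_log2 = K · b^(−1/(2h))

(the half-log2-drop dose; derivation: solve b + (1−b)/(1+x) = √b giving
x = b^(−1/2)). For b = 0.1 and h = 1 this is ≈ 3.2 K. All recovery
metrics in the synthetic harness therefore score the fitted IC50 against
`K_log2`, its own estimand; with noise-free data the pipeline recovers it
to ~0.001 log10 units. Users comparing fitted values with occupancy-scale
IC50s should keep this transformation in mind (it applies equally to any
analysis that fits log-transformed intensities, including the standard
Prism-style workflow this reproduces).

## Synthetic data generator

The generator emulates the statistical structure of per-protease modified-
peptide quantification tables so every stage is testable without external
data. Defaults mirror a triplicate competition experiment:

| parameter | default | rationale |
| --- | --- | --- |
| dose ladder | 1, 3.16, 10, 31.6, 100, 316, 1000 nM + DMSO | half-log ladder, 7 concentrations + vehicle control |
| replicates | n = 3 | triplicate biological replicates |
| proteases | trypsin + pepsin | the complementary pair used for dual-protease site profiling |
| proteome | 50 proteins, 200–400 aa, vertebrate-like composition | enough K/R and F/L/Y/W density for both digestion modes |
| sites | 100; 70% K / 30% Y; ≥40 aa apart | roughly the per-run kinome-site scale; K:Y ratio close to the observed site inventory |
| competed fraction | 0.1 | a selective inhibitor hits a small fraction of probe sites |
| true IC50 | log-uniform 3–300 nM | inside the ladder |
| Hill slope | uniform 0.7–2.0 | plausible competition slopes |
| competed plateau `b` | uniform 0.02–0.25 | 2–5.6 log2-unit drops |
| peptide bases | log-uniform 1e6–1e9 | three orders of magnitude of peptidoform abundance |
| noise CV | 0.2 (multiplicative log-normal) | typical label-free replicate CV |
| missing-at-random | 0.05 per entry | residual missingness after match-between-runs |
| run-effect scale | log-normal σ = 0.05 per sample | small per-run intensity shifts |

Each unique site gets 1–2 rule-valid tryptic peptides (missed-cleavage
length variants) and 1–3 arbitrary-boundary peptic peptides, every planned
peptide verified to match exactly its intended proteins. A configurable
number of proteins is duplicated into diverged homologs whose site-covering
peptides stay identical, producing shared peptides and multi-protein site
groups; homolog-shared sites keep exactly one protected peptide per
protease so all their evidence remains shared.

What the generator does **not** emulate: intensity-dependent missingness is
available but off by default (real data lose low-abundance peptides first,
and competed sites at high doses go below the detection limit — the ND
cells of real heatmaps); chromatographic or charge-state effects;
normalization artifacts; FDR-level identification errors; isotope or
modification-localization ambiguity (site positions are taken as reported).
Passing recovery tests therefore demonstrates correctness of the mapping,
aggregation and fitting machinery under a faithful noise model — not
robustness to search-engine errors upstream.

## Known behavior and limitations

- With the 1 nM–1 µM ladder, competed sites whose half-log2-drop dose
  `K·b^(−1/(2h))` approaches or exceeds 1 µM have an unobserved bottom
  plateau; their IC50 estimates are information-limited, with wide
  asymmetric intervals and a heavy error tail (the fraction of competed
  fits within ±0.3 log10 of truth sits near 0.88 at the default design,
  dropping to ~0.79 once missing-at-random dropout is added, because a
  dropped member peptidoform produces a discrete jump in the summed log2
  signal). Median accuracy is unaffected (~0.08 log10).
- The extra-sum-of-squares F-test is mildly conservative here (the bounded
  nonlinear alternative cannot always exploit its nominal three extra
  degrees of freedom), so false competed calls on stable sites are rare
  (specificity ≈ 0.99).
- Fits are independent per protease and per site; no shared-plateau or
  global model, no Bayesian shrinkage.
- Residue numbering assumes the canonical database isoform.
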