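# Methods

This note documents the models, numerical choices and known limits of
glomesieve. It covers what each stage assumes, which defaults matter, and
what passing the test suite does and does not demonstrate about field data.

## In-silico PCR (`primer_scan`)

A primer binds where every position matches under IUPAC-set semantics —
two codes match whenever their base sets intersect — with at most
`max_mismatches` (default 3) mismatches overall and **zero** mismatches in
the `protected_3prime` (default 5) residues nearest the 3' end, where
polymerase extension is most sensitive. Minus-strand sites are found by
scanning the reverse complement of the primer on the plus strand, with the
protected zone mirrored to the pattern start. Known Illumina adapter
prefixes are stripped from primer sequences at construction because they
are non-genomic.

Coordinates are 0-based half-open internally and 1-based inclusive in
reports (GenBank convention). All forward/reverse pairings up to a 2000 bp
ceiling are reported rather than "shortest amplicon wins", because rDNA
arrays contain repeated binding sites. Specificity is assessed by the
amplicon length window (default 330–480 bp, the band window that separates
Glomeromycota products from shorter Asco-/Basidiomycota amplicons), not by
annealing. No thermodynamic scoring is attempted.

The scanner is vectorised (sliding-window bit masks); the test suite checks
it against an exhaustive position-by-position oracle, exactly, on hundreds
of random templates.

## Read processing (`read_pipeline`)

Pairs merge at the ungapped overlap (≥ 16 bp) maximising matches;
disagreements resolve toward the higher-quality base and pairs whose best
overlap exceeds 10 % mismatches are rejected. Merged reads with expected
errors `Σ 10^(−Q/10)` above 1.0 are discarded — a conventional rule chosen
because the upstream batch only names "quality" filtering; it is a
configurable parameter. The size filter retains 300–470 bp inclusive
(the screen removes reads *shorter than* 300 and *longer than* 470).

Clustering is abundance-greedy centroid clustering at a 0.02 cutoff:
dereplicated sequences, sorted by abundance (lexicographic tie-break), join
the first centroid at ≥ 98 % identity, where identity is matches over
alignment columns with terminal gaps excluded (vsearch-like semantics),
computed from a global alignment with free end gaps. Equal-length pairs are
prescreened by Hamming identity: at or above the threshold the gap-free
alignment is already identity-optimal, and more than 5 points below it gaps
cannot close the deficit for single-locus amplicons, so the full aligner
runs only in that borderline band. Chimera screening is deliberately
upstream of this module; it consumes pre-screened reads.

## Placement (`placement`, `phylo`)

The substitution model is GTR+Γ+I: 4 equal-probability gamma categories
whose rates are the means of the quantile slices of a Gamma(α, 1/α)
distribution, plus an invariant class of weight `p_inv` at rate zero; rates
are normalised so the mixture mean is 1 per unit branch length. Transition
matrices come from the eigendecomposition of the symmetrised rate matrix.
Felsenstein pruning uses per-node, per-column log rescaling against
underflow.

Model parameters are either supplied (JSON config) or estimated by
maximising the reference-tree likelihood with fixed topology and branch
lengths (L-BFGS-B over log-exchangeabilities with GT fixed at 1, frequency
logits, log gamma shape, and a logit-bounded invariant proportion).

Each query must already be aligned to the reference columns — the engine
verifies the column count and never computes an alignment, since a general
profile aligner (MAFFT et al.) is an external step. A fast pass attaches
the query at every edge midpoint with a pendant branch equal to the mean
branch length; edges are then refined (bounded scalar optimisation of
attachment position and pendant length, tolerance 1e−6, two coordinate
rounds) until the cumulative fast-pass LWR reaches 0.99, with at least 3
edges refined. LWRs are normalised over **all** edges, and placements are
retained best-first until cumulative LWR ≥ 0.99, so the retained mass lies
in [0.99, 1]. `distal_length` is measured from the attachment point to the
edge's distal (child-side) node.

jplace edge numbers follow the order of appearance of edges in the emitted
newick string; reading validates that tags in a file agree with that
numbering. Reference trees from the fixture generator carry a
trifurcating root (2n−3 edges), so no artificial root edge exists to place
on.

Per-edge log-likelihoods are verified against a naive pruning
implementation (nested recursion, `expm` transition matrices, no rescaling)
to 1e−8 on 6-leaf trees.

## Taxonomic assignment (`assignment`)

Per query, edge LWR mass accumulates clade-wise on the jplace tree as
rooted: the mass on an edge counts toward the clade below it, and every
clade's score is its subtree total. The assignment is the lineage shared by
all leaves of the *smallest* clade whose mass reaches the threshold
(default 0.9, required to be in (0.5, 1] so the winner is unique); ties
prefer fewer leaves, then the deeper node. Queries resolvable only at the
root become `Glomeromycota_unclassified`. Cumulative subtree mass (not
best-hit mass) is used, matching the accumulation semantics of placement
toolkits. Clusters sharing a species-level lineage merge into one
taxonomic unit; units above species rank stay distinct under their partial
lineage. Rare-unit thresholds are strict: species units with < 10 reads and
non-species units with < 100 reads are dropped, then samples with < 100
remaining reads are excluded. Pseudogene exclusion is out of scope and
handled by an input blacklist if needed.

## Alpha diversity (`alpha`)

All estimators are computed on 1000 subsamples of 100 reads drawn without
replacement (multivariate hypergeometric), reported as mean ± SD; samples
below the subsample size are skipped with a warning. Chao1 is the
bias-corrected form; ACE uses the conventional rare-abundance cutoff of 10
(falling back to Chao1 when the rare class is all singletons); evenness is
`H/ln S` with the single-species case defined as 1; Good's coverage is
computed after rare-unit filtering (flagged here because coverage before
filtering would be lower). Boneh's estimator is implemented as the plug-in
prediction `Σ_i e^{−n_i}(1 − e^{−n_i m/n})` for a follow-up sample of
`m = 100` reads — the first-order form of the published predictor, without
its small-sample bias correction; it is a mild lower bound, consistent with
the small integer values this quantity takes at these subsample sizes.

Rarefaction is analytic (hypergeometric expectation), not Monte Carlo.
Group comparison uses PERMANOVA (permutation pseudo-F on Euclidean
distances between per-sample estimator vectors, 9999 permutations),
per-estimator Kruskal–Wallis, and pairwise Mann–Whitney with Bonferroni
correction summarised as a compact letter display (greedy insertion with
absorption).

## Beta diversity (`beta`)

Yue–Clayton dissimilarity is computed on relative abundances; AMOVA is the
permutation pseudo-F from squared distances (within-group sums divided by
group size, mothur convention — the statistic coincides with PERMANOVA and
is cross-checked against scikit-bio in the tests); HOMOVA is the
Bartlett-style B statistic on within-group dispersions with a permutation
p. NMDS wraps non-metric MDS (20 restarts, 500 iterations, tolerance 1e−7),
centres and principal-rotates the best configuration, and reports Kruskal
stress-1 recomputed by isotonic regression; per-axis Spearman vectors are
available for species and metadata.

Metastats tests two groups per unit: Welch t on relative abundances with a
label-permutation p-value, Fisher's exact test on pooled counts for sparse
units (< 8 pooled reads, the original method's rule), and
Benjamini–Hochberg q-values (chosen over Storey's estimator for
determinism).

The DMM is fitted by EM: responsibilities from Dirichlet-multinomial log
densities, component parameters by the weighted fixed-point update
(warm-started across EM steps and polished to 1e−12 at convergence),
k-means on relative abundances for initialisation. Model selection
minimises a Laplace-approximated negative log evidence in log-α space with
a vague Normal(0, 10²) prior: posterior curvature is the numeric
log-likelihood Hessian diagonal plus the prior precision, so directions the
data leave flat (e.g. an emptied component) fall back to the prior and are
penalised rather than rewarded. The candidate range is k = 1…6 by default
— comfortably above the three metacommunities the planted design carries.
Per-component influential units are ranked by the absolute difference
between the component's mean composition and the single-component fit.

## Placement analytics (`analytics`)

Mass trees sum each sample's per-edge LWR, optionally weighted by cluster
counts; per-sample totals are conserved through every transformation until
explicit normalisation. Edge imbalance is distal-minus-proximal mass on
unit-normalised samples with the edge's own mass counted as distal and the
jplace root as the proximal reference — the orientation is fixed so signs
reproduce. Edge PCA is the SVD of the centred imbalance matrix; k-means
(k-means++ with 50 restarts) runs on the same imbalance vectors, normalised
masses by default. Per-edge Spearman correlations with covariates use a
label-permutation p and BH correction across edges per variable; constant
edges or covariates are reported missing.

Placement-factorization computes, per candidate edge, the isometric
log-ratio balance `y = √(n_D n_P/(n_D+n_P)) · ln(g_D/g_P)` of
geometric-mean masses (pseudocount 0.65 × the smallest nonzero mass guards
the geometric means) and fits a Gaussian identity-link GLM of y on the
covariates; the winning edge maximises the fraction of null deviance
explained. Each winner splits its tree region, and later factors search
only within unsplit regions; the winning edge itself leaves the candidate
pool. Balances are real-valued, which is why the Gaussian family is the
default.

## The synthetic study (`fixtures`, `workflow`)

The generator emulates the field design the analyses assume: two sites
(contaminated / control), two host plants, root and soil matrices, 12
replicates each (96 samples). Community structure is a three-component
Dirichlet-multinomial metacommunity model — the contaminated groups share
one component whose expected composition concentrates 85 % inside a planted
clade (the "generalist" clade, chosen deterministically as the edge whose
subtree is closest to a third of the taxa), while the control groups split
by host plant over the remaining taxa. Component concentration defaults
to 50, giving realistic within-group compositional spread while keeping the
three components recoverable. Metadata draws phenol (98–2814 mg kg⁻¹) and
PAHs (40–538 mg kg⁻¹) uniformly within the observed field ranges at the
contaminated site (zero at the control site), and the remaining covariates
(pH in water and KCl, moisture, organic matter, total N) from per-site
truncated normals centred on the field means; within-site covariate
correlation is exposed as a parameter rather than asserted, since no value
is established for it.

Reads are substitution-only copies of reference alignment rows (no indels,
no chimeras, no rDNA copy-number variation), so simulated queries are
already in reference column space and placement needs no external aligner.
Base qualities are a constant Q35, modelling post-merge consensus quality
independently of the injected substitution rate. Consequences: clustering
and placement recovery results on fixtures certify the algorithms under the
stated model, not robustness to indel-rich or chimeric field libraries;
likewise, the planted richness contrast between sites is milder than field
surveys report, so alpha-diversity comparisons here demonstrate calibration
and power of the tests, not effect-size realism.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; every artefact is reproducible
byte-for-byte.

## Problem sizes

Default analysis sizes were chosen at desk scale: studies of 12–16 taxa,
96 samples and 250–300 reads per sample; 6-leaf trees for likelihood-oracle
comparisons; 1000 draws with 199 permutations for null calibrations
(199 permutations make "p ≤ 0.05" an exact 5 % event under
exchangeability). The complete acceptance analysis runs in about a minute
on one CPU.

## Known limitations

- No de-novo multiple sequence alignment and no ML tree inference: the
  reference alignment/tree are inputs, query alignment is consumed.
- The expected-error quality rule is a documented stand-in for an
  unpublished upstream filter configuration.
- Boneh's estimator omits the original bias-correction term (see above).
- DMM evidence uses a diagonal-curvature Laplace approximation with a vague
  prior, not the full Hessian.
- Heat trees are numeric edge annotations; no graphical rendering.
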