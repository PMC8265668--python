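# Methods

## Problem setting

Low-microbial-biomass 16S rRNA amplicon samples — mosquito gut and
reproductive-tract tissues are the motivating case — carry so little template
DNA that background DNA from extraction kits, reagents and the laboratory
(the "kitome") can contribute a large share of the sequenced reads. Negative
controls (blanks and extraction controls) sequenced alongside the tissues are
the reference for identifying this contamination, but they are themselves
imperfect: true resident taxa (e.g. endosymbionts such as *Wolbachia*) leak
into controls through well-to-well contamination and index switching, so
"present in a control" does not imply "contaminant".

`ampliclean` implements a clustering-free, abundance-based screening and
removal strategy at the ASV level, a prevalence-based classifier for
cross-checking, and the machinery to quantify how removal changes community
diversity and structure.

## Screening model

For a sample subset $S$ (the negative controls of one data set, or one tissue
type), the *overall relative abundance* of feature $f$ is pooled:

$$a_S(f) = \frac{\sum_{s \in S} c_{fs}}{\sum_{g}\sum_{s \in S} c_{gs}}$$

Pooling (rather than averaging per-sample proportions) is the only reading
that stays well-defined when a data set has a single control, which is common
in deposited studies. A feature is a *candidate contaminant at threshold
$\tau$* when $a_{\text{controls}}(f) \ge \tau$ (inclusive), with
$\tau \in \{1\%, 5\%, 10\%\}$ by default; candidate sets are therefore nested
in $\tau$. The *full-removal* set is every feature with a nonzero control
count. No control-vs-tissue abundance ratio is used: the classification
depends on the controls alone.

The shared-burden summary reports, per (data set, tissue, $\tau$): the number
of candidates, the number also detected (pooled count > 0) in the tissue
subset, and the summed tissue relative abundance of those shared candidates.
Report percentages are rounded half-up to two decimals; internal values are
unrounded.

A packaged worked example (`ampliclean.printed_abundance_blocks()`) carries
the per-ASV control/tissue percent abundances of five published mosquito data
sets; recomputing the shared-burden summaries from it reproduces the
published cells to within the two-decimal rounding of the inputs. Two printed
cells are internally inconsistent with their own per-ASV block and are
reported as recomputed here: the Anopheles1 gut $\tau=10\%$ row (shared count
exceeds the candidate count in print; we report 2 shared of 2) and two
percentages that differ by 0.01–0.10 due to rounding of the printed inputs.

## Prevalence-based classifier

For comparison, each feature's presence (count $\ge$ `detect_min`, default 1)
is tabulated in controls vs experimental samples and scored one-sidedly for
*higher prevalence in controls*: a chi-square test on the 2×2 table (no
continuity correction) halved and directed by the sign of the prevalence
difference; whenever any expected cell is below 5, the one-sided Fisher exact
test (hypergeometric upper tail) is used instead. Degenerate margins (present
everywhere or nowhere) score $P = 1$; experimental-enriched features are
clamped to $P \ge 0.5$, so they are never classified. A feature is called at
threshold $P^*$ when $P < P^*$ (strict); $P^* = 0.1$ and $0.5$ are the
conventional choices. The exact branch is verified against a rational
enumeration of the hypergeometric tail for all group sizes up to 12.

This score is a fresh implementation of the prevalence idea, not a port of
any particular software: absolute $P$ values may differ from other tools,
but the ordering, monotonicity (more control presence at fixed margins never
raises $P$) and the nesting of call sets across $P^*$ hold by construction.

The classifier's blind spot is structural: once bleed-through is strong
enough that contaminants are detected in essentially every tissue sample,
both margins saturate and $P \to 1$. The recovery study below therefore
evaluates it in its informative regime (low bleed), and the analysis scripts
show the saturated regime explicitly.

## Removal treatments and diversity

Five treatments produce experimental-samples-only subsets: no removal, full
removal, and removal at $\tau \in \{1, 5, 10\}\%$. Removal is feature-global
within a data set and counts are not re-normalized afterwards (rarefaction,
when requested, happens upstream). Per-sample removed-read fractions are
monotone across treatments by nesting.

Alpha diversity per sample: observed richness $S$, Shannon entropy
$H = -\sum p_i \ln p_i$ (natural log, base configurable) and Pielou's
evenness $J = H / \ln S$, reported as missing when $S \le 1$. Beta diversity:
Jaccard distance on presence/absence and Bray-Curtis dissimilarity on counts
(both in $[0,1]$; on binarized data Bray-Curtis equals the Sørensen distance,
with $J_d = 2B/(1+B)$). Diversity is computed at the feature (ASV) level;
post-removal re-clustering of sequences into OTUs would require the reads
themselves and is out of scope — this shifts absolute diversity values but
not the within-data-set treatment contrasts the analysis is built on.

## Treatment comparison

Treatments are compared within a data set with paired tests: pairing is by
sample for alpha metrics and by unordered sample pair for beta metrics. The
paired differences are gated through a Shapiro-Wilk test at $\alpha = 0.05$
(the differences, not the per-subset values, are the object the paired test
makes assumptions about): paired *t* when normality is not rejected,
Wilcoxon signed-rank otherwise (zeros dropped; exact null for $n \le 25$
without ties, normal approximation with tie correction above; an all-equal
nonzero difference vector falls back to an exact two-sided sign test since
both the *t* and rank statistics then have zero variance). Identical vectors
give a degenerate comparison with $p = 1$. Raw p-values are reported with
asterisk bands (\* 0.05–0.005, \*\* 0.005–0.0005, \*\*\* < 0.0005); a Holm
correction is available but off by default. Letter displays are built from
the maximal cliques of the non-significance graph in a deterministic
treatment order, so two treatments share a letter exactly when they do not
differ significantly.

## Synthetic data generator

`GeneratorConfig`/`generate` draw one data set with known truth:

* **Contaminant pool** over `n_contam_features` (default 60): one dominant
  member at `dominant_share` (default 20% — control pools in deposited
  mosquito data sets are typically dominated by a single ASV at 20–60%) plus
  a Dirichlet(`contam_alpha` = 1) tail.
* **True community** over `n_true_features` (default 80): a log-normal base
  profile (σ = 1.5) perturbed per sample by a second log-normal factor
  (σ = 0.5).
* **Controls** (default 6): $(1-\varepsilon_{cross})\,\text{pool} +
  \varepsilon_{cross}\,\text{base true profile}$ with
  $\varepsilon_{cross} = 1\%$, emulating cross-contamination into blanks.
* **Tissue samples** (default 23): $(1-\varepsilon_i)\,\text{true}_i +
  \varepsilon_i\,\text{pool}$ with per-sample bleed $\varepsilon_i \sim
  \text{Beta}$ (mean 0.30, concentration 10), matching the 10–67% shared-read
  burdens seen in real tissue data sets.
* Counts are multinomial at a per-sample depth (default 25,000, the usual
  normalization depth), so column totals are exact; singletons are injected
  by swapping single reads (rate 0.02 per feature), preserving totals.
* An optional `endosymbiont_share` pins one true feature at a fixed high
  tissue share to emulate a *Wolbachia*-like resident that appears at trace
  level in controls.

Pool parameters were chosen so the pool's entropy is at or above the true
community's: removing the full pool then lowers each sample's Shannon
entropy as well as its richness (mixture-entropy decomposition over disjoint
supports), which is the regime the removal-impact study asserts. What the
generator does **not** emulate: taxonomic structure, batch effects between
extraction rounds, chimeras/index-switching at the read level, and
compositional correlation between true and contaminant taxa. Passing
recovery tests therefore demonstrate internal consistency of the machinery
under the stated contamination model, not performance guarantees on real
data.

## Simulation studies and their scales

* **Threshold recovery** — with $\varepsilon_{cross}=0$ the classifier must
  return *exactly* the pool features at/above $\tau$ (realized pooled control
  abundance); 20 seeds, exact set identity.
* **Prevalence recall** — 40 tissue samples vs 6 controls, constant bleed
  $5\times10^{-4}$ at depth 2,000 (the informative low-bleed regime; the
  spec-level bound is $\varepsilon \le 0.05$), recall of $\ge 1\%$-control
  pool features at $P^*=0.5$, pooled over 20 seeds; observed 1.00.
* **Removal impact** — 50 seeds at generator defaults; the dominant
  contaminant always exceeds 10% of control reads; full removal lowered
  richness and Shannon for every sample in every seed and the paired
  contrast vs non-removal was significant in 100% of seeds.
* **Type-I calibration** — 200 replicates with zero contamination
  ($\varepsilon_{bleed}=\varepsilon_{cross}=0$, depth 2,000). The $\tau=1\%$
  treatment then removes features absent from every tissue sample, so the
  two subsets are identical and the null is exactly true; each subset is
  rarefied independently to 1,000 reads to give the comparison the
  resampling noise it sees in practice. Observed rejection rate of the
  Shannon comparison: 0.045 at nominal 0.05.

Study sizes (seeds, depths) are the package's own defaults chosen to make
the studies reproducible in seconds while keeping the binomial error of the
rate estimates well inside the asserted bands.

## Numerical and design choices

* Rarefaction is a multivariate hypergeometric draw (without replacement)
  per sample; samples below the target depth are dropped by default. The
  pipeline normalizes before screening by default (order configurable).
* A singleton is a feature with total count 1 across the whole data set.
* Report rounding is half-up at two decimals, percent scale.
* Threshold comparisons are inclusive ($\ge \tau$); prevalence calls are
  strict ($P < P^*$).
* "Shared with tissue" means nonzero pooled count, with no minimum
  prevalence.
* All randomness flows from explicit integer seeds; child seeds for
  multi-replicate studies are spawned from one master seed.

## Known limitations

* Absolute prevalence scores are implementation-specific (see above); only
  order-based properties are portable across tools.
* The abundance rule inherits the cross-contamination failure mode it is
  designed to expose: an endosymbiont leaking into controls above $\tau$
  would be removed as a contaminant. The generator's endosymbiont option
  exists precisely to demonstrate this.
* Frequency-based (DNA-concentration) contaminant identification is not
  implemented: concentration metadata is generally unavailable for deposited
  data sets.
* Diversity is ASV-level; sequence-level OTU re-clustering after removal is
  upstream/downstream of this package.
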