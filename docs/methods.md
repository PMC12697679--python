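# Methods

## The calibration model

Let X be a raw variant-effect score (an LLR under the package's default
orientation: more negative = more deleterious), Y ∈ {0, 1} the pathogenicity
label, and M₁…M_k binary residue attributes. The package models, within each
subgroup g defined by a combination of attribute values,

    X | Y = 1, g  ~  GMM_path(g),      X | Y = 0, g  ~  GMM_ben(g),
    Y | g         ~  Bernoulli(π_g),

with two-component, diagonal-covariance (trivially so, in 1-D) Gaussian
mixtures fitted by EM. The calibrated probability for a score x in subgroup
g is the pathogenic-source fraction of the equal-frequency histogram bin
containing x, where the histogram is built from synthetic mixture draws
mixed at π_g. This is a plug-in estimate of

    P(Y = 1 | X ∈ bin, g) = π_g f_path(bin) / (π_g f_path(bin) + (1 − π_g) f_ben(bin)),

discretized so that the mapping is monotone step-wise within a subgroup and
every real score (including out-of-range values, via ±∞ sentinel edges)
receives a probability.

**Assumptions.** (i) Class-conditional score distributions are well
approximated by two Gaussian components per class within a subgroup; (ii)
the subgroup priors π_g estimated from sampled labels carry real signal
rather than pure annotation bias; (iii) attributes are binary, possibly
missing, and missingness at inference is uninformative about Y beyond the
node already reached. Violation of (i) degrades calibration smoothly (the
histogram is still monotone in the fitted density ratio); violation of (ii)
propagates label bias into π_g — the pruning thresholds exist precisely to
keep those estimates out of the noise regime.

## The calibration tree

The root split is protein length (long proteins are scored through a
sliding window, a purely technical regime change). Below the root each node
splits greedily on the remaining attribute with the largest
class-conditional divergence, Σ over the two labels of the squared
Jensen–Shannon distance (natural log; each term ∈ [0, ln 2]) between the
attribute-positive and attribute-negative score histograms — 100 equal-width
bins on the min–max-mapped score, every bin smoothed by ε = e⁻¹² and
renormalized. The divergence is estimated on a seeded subsample of at most
400 variants per (side × label) cell, which keeps tree construction O(1) in
node size; ties break by the declared attribute order so construction is
deterministic. An attribute that is constant, or missing a (side, label)
cell inside a node, is skipped there.

Pruning repeatedly removes leaves with < 1600 variants, < 400 pathogenic or
< 400 benign, to a fixpoint; a parent orphaned of both children becomes a
leaf and is re-examined. Since member sets are nested, every surviving node
satisfies the thresholds. Records whose value for a node's split attribute
is missing stay counted at the node but join neither child, mirroring the
inference-time stopping rule.

All surviving nodes are calibrated, a superset of the nodes where inference
can stop (leaves, single-child nodes, and nodes splitting on incompletely
covered attributes); histograms are cheap and this guarantees the mapping
step always finds one.

## Parameter defaults

| parameter | default | rationale |
|---|---|---|
| window / overlap | 1022 / 250 residues | language-model context minus specials; interior windows score their central 522 positions, so consecutive windows overlap by 2 × 250 and scored ranges tile the sequence disjointly |
| disorder cutoff | score > 0.7 | stringent disorder call (~28% of residues vs ~32% at 0.5) |
| low homology | ≤ 10 cluster members | balance between subgroup size and contrast; exposed as a parameter |
| long protein | length > 1022 | beyond the single-window context |
| pruning | 1600 / 400 / 400 | enough for EM fitting and for separate held-out evaluation per node |
| prior sample | 500 labels | normal-approximation 95% CI half-width 0.05 needs n = 385 with no prior on p; 500 adds margin |
| EM sample | 400 per class | AUROC saturates while retaining most tree nodes |
| components K | 2 | BIC plateaus at two components on real score distributions; K is configurable |
| EM settings | k-means init, 1 restart, tol 1e-3, ≤ 100 iterations | standard defaults of the underlying fitter |
| histogram | 40,000 draws, 50 equal-frequency bins | performance plateaus; finer bins only oversplit |
| outlier removal | modified z > 4.25, pooled classes | removes ~0.3% most extreme scores symmetrically before any fitting |
| logistic baselines | 0.1-percentile tail trim, balanced subsample, L-BFGS, ≤ 100 iterations, no penalty | penalty-free fit keeps the slope analytically checkable; weak L2 available behind a flag |
| reliability bins | 10 equal-width on [0, 1]; MCE floor > 50 samples/bin | ECE is count-weighted; MCE ignores unoccupied or tiny bins |

## Numerical choices

- Equal-frequency edges sit at midpoints between consecutive order
  statistics at the cut positions, with ±∞ sentinels outside; per-bin counts
  differ by at most one for distinct values, while heavy ties can merge
  edges (duplicated edges are collapsed). Bins are half-open [lo, hi).
- `round(n_sample · π)` uses banker's rounding for the pathogenic draw
  count; by construction Σ_b count_b · fraction_b equals that count exactly.
- A single master seed drives everything: per-node seeds derive from the
  master seed and the node's path (attribute indices + branch bits fed to a
  seed sequence), so refitting is reproducible regardless of traversal
  order, and fraction / EM / histogram draws use independent spawned
  streams.
- MAD = 0 makes the modified z-score undefined: nothing is removed and a
  warning is emitted. A class whose EM sample is a single point falls back
  to a near-point single component.
- Youden threshold scans midpoints of consecutive distinct scores plus ±∞
  under the "score ≥ threshold ⇒ pathogenic" convention; the smallest
  maximizer wins, for determinism.
- Scores already in [0, 1] are never rescaled by the min–max operator, only
  flipped if the pathogenic mean sits below the benign mean; out-of-range
  tail values are clamped to the [0, 1] endpoints *after* orientation, so
  the transform never consults labels at apply time.
- LLR computation exposes both conventions: the printed form (log-softmax
  of the wild-type-shifted logits, read at the mutant entry — by shift
  invariance equal to the mutant's log-probability) and the raw logit
  difference that log-softmax-then-subtract reduces to algebraically. The
  printed form is the default; their relation is property-tested.

## The synthetic-data generator

`paper_like_config()` draws variants from four disjoint subgroups over the
attributes (disordered, sulfur-binding, interface): disordered (weight 0.30,
prior 0.10), interface (0.07, 0.61), sulfur-binding (0.07, 0.31) and an
unannotated baseline (0.56, 0.385), giving a pooled pathogenic rate of 0.31.
Variants are assigned uniformly to proteins; 47% of proteins are "long"
(> 1022 residues), which sets the `long_protein` attribute; interface
annotations are masked completely at random for 26% of variants, exercising
the inference-time fallback. Wild-type residues are drawn consistently with
the sulfur-binding flag.

Scores emulate LLRs: pathogenic mixtures (components at −9.5/−13.5, sd 0.7)
sit well below benign ones (−3.5/−7.5, sd 0.6), and the benign mixture of
the *disordered* subgroup is shifted 2.5 units down (−6.0/−10.0) — the
class-conditional distribution shift the method exists to correct. The
interface subgroup gets a milder pathogenic shift (−8.5/−12.5). Component
spreads are deliberately narrow relative to their 4-unit separation so the
components are statistically identifiable from the 400-sample EM fits the
pipeline prescribes; the overall class distributions remain broad (sd ≈ 2)
and bimodal, like real LLR histograms.

**What passing on this generator shows — and does not.** It shows the
pipeline's internal consistency: the tree finds the truly shifted attribute,
priors and mixture means are recovered at the stated sample sizes, mapped
probabilities are calibrated per node on fresh draws, cross-subgroup ranking
improves over raw scores, and no seen-vs-unseen gap exists. It does *not*
establish performance on real clinical data: real LLR distributions are not
exact two-Gaussian mixtures, attributes are correlated with each other and
with proteins, annotation bias contaminates priors, and per-protein score
autocorrelation is absent from the generator by design.

## Design choices where the design was open

- **Divergence feature for tree construction:** the score itself (min–max
  mapped), since per-variant entropy vectors are optional inputs; an entropy
  mode is available when such features are supplied.
- **Divergence subsample size:** 400 per class per side, seeded — large
  enough for stable 100-bin histograms, small enough to keep construction
  fast on large nodes.
- **Prior/EM sample pooling:** the 500 prior-estimation labels are drawn from
  the pooled node and reused per class for EM, topped up at random to 400
  per class.
- **Protein-level grouping** (for the residue-vs-protein mutual-information
  contrast) uses equal-width thirds of the observed attribute-fraction
  range; the cut points are configurable.
- **Ensemble prediction** keeps the central 75 of the per-model
  probabilities (trimming both tails equally) and reports their median and
  standard deviation.

## Problem sizes used in the checks

The bundled tests and the acceptance script fit on 50,000 generated
variants, evaluate on 20,000–50,000 held-out variants, use 20 refits for
the leakage comparison, and draw 20,000 scores per node for the
in-model-family calibration check. At these sizes every quantity's sampling
noise is several times smaller than the margin it is checked against.

## Known limitations

- Attributes must be binary; continuous attributes enter only through fixed
  thresholds, and no split-point search is performed.
- Priors inherit whatever annotation bias the calibration labels carry; the
  method narrows, but cannot remove, that bias.
- Per-bin probabilities are step-wise constant; near bin edges two very
  close scores can receive different probabilities (resolution 1/50 of the
  node's score mass by default).
- Equal-frequency binning under heavy score ties can produce uneven bins.
- The sliding-window planner only does index bookkeeping; it does not model
  edge effects of the underlying scorer inside a window.
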