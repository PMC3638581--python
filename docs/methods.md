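# Methods

## Model and assumptions

The pipeline rests on one statistical assumption: *structurally similar
drugs bind functionally related, network-proximal target proteins*. Given a
panel of reference drugs with known structures and target sets, a query
compound's affinity for a candidate gene is estimated without any direct
binding data, purely from the concordance of two vectors indexed by the
panel:

- the **similarity vector** s(q): Tanimoto coefficients between the query's
  fingerprint and each reference drug's fingerprint (drug space);
- the **closeness vector** Φ(g): for each reference drug, the kernel-summed
  shortest-path proximity of the gene to that drug's target set in the
  protein-interaction network (target space), Φ(g, D) = Σ_{t∈D} exp(−d(g,t)²).

The score is the Pearson correlation of the two vectors. If the assumption
holds, genes inside the target module of the query's chemical family receive
high scores; genes elsewhere see no systematic relation. The method is
therefore only as good as the panel: it needs several reference drugs (≥ 3
for the correlation to exist; dozens for stability) spanning chemistry that
covers the query.

The downstream stages make weaker assumptions. The disease network treats a
single interaction hop from seed genes as the relevant neighbourhood — a
deliberate, shallow expansion that keeps the network disease-specific.
Synergy detection assumes the curated pathway model is a faithful summary of
the relevant signalling; it enumerates topological patterns, not kinetics.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| fingerprint kind / length | hashed path, 2048 bits | the standard realization of "chemical similarity" for target prediction; Morgan (r=2) available |
| closeness kernel | exp(−d²) | fast decay: only targets within ~2 hops carry evidence; exp(−d) available |
| correlation | Pearson | concordance on raw scales; Spearman available |
| profile size k | 100 | the operating point of the published precision analysis of the scoring scheme |
| PCA components | 2 | visualization and grouping operate on the leading plane |
| cluster count | 3 | mirrors the three broad chemical classes typical of a formula (saponins, glycosides, alkaloids); a parameter, not a claim |
| expansion depth | 1 hop | a single "fishing" step for interaction partners |
| enrichment alpha | 0.05 | BH-adjusted (FDR) reporting threshold |

Dimensionless throughout; distances are counted in interaction-network hops.

## Degenerate inputs and numerical choices

- Zero-variance similarity or closeness vectors produce a score of exactly 0
  with a `degenerate` flag and sort after all scored genes: no evidence is
  not negative evidence, but it must not displace scored genes.
- Two all-zero fingerprints compare as Tanimoto 1.0 (both featureless) with
  a warning, avoiding 0/0.
- Genes absent from the network, and unreachable gene–target pairs,
  contribute closeness 0 rather than using a finite distance cap:
  disconnection means no evidence.
- Profile ranking breaks ties by (descending score, gene symbol); PCA
  loadings fix signs so each axis's largest-magnitude element is positive;
  k-means uses 10 restarts from a fixed seed. All outputs are
  bit-reproducible across runs and input orderings.
- PCA centres columns but does not scale to unit variance: the projection is
  a plain linear transform of binary columns that share a scale. The
  orthonormality of loadings is enforced by the eigenstructure itself and
  verified to 1e-8 in tests.
- The Fisher test is the one-sided hypergeometric upper tail
  P(X ≥ overlap) (over-representation only); BH adjustment is the standard
  step-up rule, capped at 1, order-restored.

## Synergy mechanism predicates

The four patterns are this package's own formalization, reverse-engineered
from the worked-example pair descriptions; each is an independently testable
predicate on the labelled model. Reachability is restricted to simple
directed paths within one pathway label — crossing labels is precisely what
distinguishes "cross-talk" from "same pathway".

- **same_pathway(u, v)**: u, v distinct targets on one label, one upstream of
  the other, and the cascade continues past the downstream one (the pair
  throttles a route that still regulates something — two hits on a dead-end
  tail are not counted).
- **crosstalk_convergence**: distinct targets on differently-labelled routes
  with a common strict descendant under their respective labels.
- **feedback_loop**: the pair occupies two distinct subunits of a declared
  complex, corroborated by a direct edge into the complex from a non-complex
  target of either partner. Mere co-binding of a complex at two subunits,
  without upstream drive, is not counted — this keeps coincidental
  complex contacts from being read as loop engagement.
- **compensation**: distinct targets on differently-labelled, *non-convergent*
  routes whose direct downstream effectors are distinct, lie outside the
  pair's own target sets, and are functionally related (same complex or
  shared pathway membership). This is the "block one route and the related
  route compensates" reading.

Pair weight counts distinct mechanism kinds (max 4), not raw evidence
records, so permutations of the same evidence do not inflate the weight.

The packaged QLY fixture encodes the five major ingredients' reported
targets and a 14-edge curated model of TNF-, IL1B- and VEGFA-induced NF-κB
activation with the NFKB1-NFKB2-RELA-RELB complex declared as the feedback
loop. Two transcription choices matter and are deliberate: Kurarinone
carries all three of its separately reported targets (AKT1, PTK2, NFKB1),
and Diosgenin carries NFKB2 and RAF1 — the complex subunit paired against
Kurarinone's NFKB1 plus the kinase on the VEGFA branch. RAF1 sits on a
branch parallel to KDR (VEGFA → RAF1 → MAPK1 → RELA) rather than downstream
of KDR, reflecting the reading that the receptor and kinase arms of VEGF
signalling reach the complex independently. Under these predicates the five
major ingredients yield exactly six synergistic pairs of the ten candidates,
with Kurarinone–Diosgenin the only pair carrying two mechanism kinds
(feedback + compensation).

## The synthetic generator

`generate_space` emulates the method's core assumption and nothing more: a
modular interaction network (stochastic-block-model-style — Bernoulli edges
at density 0.15 within each 80-gene module plus a spanning chain, and 120
uniformly random between-module edges), and reference drugs organized into
families that share a random 256-bit fingerprint template (per-drug bit
flips at rate 0.1) and draw 10 targets from their family's module. Defaults
give 5 families × 10 drugs on a 400-gene network. A query perturbs a family
template; its planted truth is that family's whole module.

What it does *not* emulate: real chemistry (fingerprints are abstract bit
sets, not molecule-derived), hub-dominated degree distributions of real
interactomes, noisy or incomplete drug–target annotations, overlapping
target modules, and family structure that correlates only partially with
pharmacology. Passing the planted-recovery tests therefore shows the
inference is correct and well-calibrated *under its own assumption*, not
that the assumption holds for any particular real compound panel. On the
default space, precision-at-100 against an 80-gene planted module has
ceiling 0.8, the random baseline is k·m/N = 0.2, and recovery typically
sits at the ceiling; recovery degrades monotonically as fingerprint noise
grows toward 1.

Null calibration of enrichment uses 25 random 20-gene terms over a 400-gene
background and 200 random 25-gene queries; the family-wise fraction of
simulations with any BH-adjusted p < 0.05 stays at or below the nominal 5%
(the discrete hypergeometric tails make the test conservative).

## Problem sizes

Tests and the acceptance script run on the default synthetic space (50
reference drugs, 400 genes), 20 independent spaces for the recovery rate,
200 null simulations for calibration, and exhaustive-oracle comparisons on
graphs of ≤ 20 nodes and pathway models of ≤ 10 nodes — sizes at which
brute-force enumeration is exact and the full suite completes in well under
a minute.

## Known limitations

- The concordance score has no per-gene significance estimate (no
  permutation p-values); profiles are rankings, not hypothesis tests.
- Enrichment p-values depend on the chosen background (default: the supplied
  interaction network's nodes); numbers from services with proprietary
  backgrounds are not reproducible and no attempt is made to match them.
- The PPI is treated as unweighted and undirected; confidence scores and
  direction are ignored.
- The synergy model is qualitative: no dose–response, no Loewe/Bliss scores,
  and pattern detection is only as complete as the curated model's edges.
- Herb target networks default to induced subgraphs on mapped targets only;
  a `bridge` option adds one-hop connectors, since reasonable conventions
  differ here.
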