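# Methods

## The problem and the model

Public sequence repositories accumulate mislabeled, misidentified and
contaminated records.  For mitochondrial barcode markers (Cytb, CoxI) the
divergence structure of honest data is strongly bimodal: sequences of the
same species rarely differ by more than a few percent, while different
species typically differ by 8–10% or more — the *barcode gap*.  A record
that is simultaneously far from every nominal conspecific (**deep
intraspecific divergence**) and close to some heterospecific (**shallow
interspecific divergence**) — the *paradox* — is therefore a strong
candidate for a labeling error, a sample mix-up, contamination, or an
outdated taxonomy.  `barcodeqc` implements this screen end to end.

## Distance engine

Pairwise divergence uses the Kimura 2-parameter model.  For each unordered
pair, sites where either sequence carries a gap, `N`, or an IUPAC ambiguity
code are excluded (*pairwise deletion*; ambiguity codes are dropped whole
rather than fractionally counted — simpler and conservative).  Over the
remaining `n` sites the transition proportion `P` (A↔G, C↔T) and
transversion proportion `Q` give

    d = -1/2 · ln[(1 - 2P - Q) · √(1 - 2Q)]

When either logarithm argument is non-positive (saturation) or when the
pair shares fewer than `min_overlap` sites (default 300 — below that the
estimator's variance makes nearest-neighbour flags unreliable), the entry
is carried as an explicit *undefined* marker, never a sentinel number.
Downstream consumers must handle the mask: the tree builder refuses
incomplete matrices and offers a greedy pruner (repeatedly dropping the
record with the most undefined partners), chosen over imputation because
imputed distances silently bias the tree.

## Flagging rules

Per sequence, the distance to its nearest conspecific (`d_intra_min`) and
nearest heterospecific (`d_inter_min`) over defined entries drive four
advisory flags:

| flag | condition | default threshold |
|---|---|---|
| `deep_intra` | `d_intra_min > t_deep` | `t_deep = 0.05` |
| `shallow_inter` | `d_inter_min < t_shallow` | `t_shallow = 0.05` |
| `paradox` | both at once | — |
| `identical_cross_species` | `d_inter_min ≤ t_identical` | `t_identical = 0` |

Nearest-neighbour (minimum) rather than mean distances are used: one
contaminant pair is evidence regardless of how many well-behaved
conspecifics exist.  No single cutoff exists in nature — intraspecific
divergence rarely exceeds 5% and interspecific divergence usually exceeds
8% — so 0.05 is a conservative default on both sides; both thresholds are
echoed into every report header.  Evidence is reported as min–max
percentage ranges (one decimal) against the implicated species.  Flags are
advisory, never deletions: a paradox may equally reflect synonymy or a
problematic taxonomy, which only reliable reference material (ideally from
type localities) can resolve.  Species identity is taken at species rank;
subspecies epithets are parsed but ignored for grouping.  Sequences whose
distances are all undefined are reported separately as unevaluable.
Group-level error ratios count distinct flagged accessions over group
totals; the caller chooses which flag types to count (the analysis scripts
use paradox flags, the primary error signature).

## Neighbor-joining summary

The NJ tree is a diagnostic picture of divergence patterning, not a
phylogenetic claim.  Implementation notes: ties in the Q-criterion are
broken by the lowest (row, column) index pair, deterministic across
platforms; negative branch lengths from NJ arithmetic are set to zero with
the difference moved to the adjacent branch of the same join; the root is
trifurcating (unrooted semantics).  Bootstrap supports resample alignment
columns with replacement, rebuild the matrix and tree per replicate, and
report the percentage of completed replicates containing each full-data
bipartition (integer percentages; replicates containing any undefined
distance are skipped and counted; default 1000 replicates, configurable).

## Saturation diagnostics

For each pair and each codon-position class (`all`, `pos12`, `pos3`,
relative to the alignment's frame offset), the transition count `s`,
transversion count `v`, and the K2P distance on that class form one scatter
point.  The x-axis uses the K2P distance for consistency with the distance
engine.  Plateau detection is deliberately descriptive — the least-squares
slope of `s` against `d` inside a high-divergence window (0.15–0.30)
compared with the slope near the origin (0–0.10) — not a formal
information-theoretic saturation test.

## Synthetic data generator

The generator produces the structure the method assumes, with known truth:

- **Species history**: a Yule (pure-birth) tree over `n_species` (default
  20), branch lengths scaled so the mean species-pair path equals
  `inter_depth` (default 0.10 substitutions/site).  Because a mean-scaled
  Yule tree leaves many cherry species far closer than typical barcode
  neighbours, node depths are then floored so that no species pair sits
  closer than `inter_floor` (default 0.10; the flooring moves only the
  too-shallow splits, leaving deeper structure where the Yule draw put it).
  The floor is what makes the generated data exhibit the barcode gap —
  interspecific divergence essentially always above 8% — rather than a
  continuum.  With the floor active the realised mean pair distance is
  ~0.12, slightly above the nominal target; the exact-mean property holds
  with `inter_floor = 0`.
- **Within species**: a star of `seqs_per_species` (default 5) tips at
  depth `intra_depth / 2` (default pair divergence 0.005).  A star rather
  than a coalescent: the flagging method only needs the divergence gap,
  not realistic genealogies.
- **Sequences**: root drawn uniformly over {A, C, G, T}; each branch
  applies the exact K2P transition probabilities for its length
  (transition/transversion rate ratio `kappa`, default 4; matrix
  normalised to one expected substitution per site per unit length).
  Default length 924 sites, a typical trimmed Cytb barcode window.  No
  indels are generated: the pipeline trims to a common window and K2P
  ignores gaps, so indel realism adds nothing testable.
- **Errors**: per-record probabilities for *relabel* (label swapped to a
  random other species), *contaminate* (sequence replaced by a noisy copy
  of a random heterospecific record), and *diverge* (0.15 extra branch
  length).  A truth table records every change.
- **Reproducibility**: one `numpy` generator derived from the seed is
  consumed in the fixed order tree → sequences → errors.

What passing tests on this generator do **not** show: performance on real
data with alignment error, indels, heterogeneous rates across sites and
lineages, uneven species sampling, or paralog (numt) contamination.  The
generator establishes that the rules recover errors when the gap holds;
on real data the gap itself must be inspected (the histogram output).

## Numerical and interface choices

- Coordinates are 0-based, half-open everywhere; frame offsets are
  recomputed on trimming.
- Sequences are upper-cased on read, `U` mapped to `T`; headers follow a
  configurable whitespace template (default `accession binomial group?`,
  accepting both `Genus species` and `Genus_species` forms); unparseable
  headers are skipped into a logged report, never guessed.
- Haplotype collapsing merges records identical over their shared defined
  sites (union–find over pairwise compatibility), so partial sequences can
  join full-length twins.
- The pipeline writes every threshold into each artifact header and a JSON
  manifest sufficient to reproduce the run; identical config and seed give
  byte-identical outputs.

## Problem sizes

The shipped analyses and tests run on 100-sequence datasets (20 × 5) at
924 sites with 100–200 bootstrap replicates, which this implementation
handles in seconds; the vectorised distance engine scales comfortably to a
few thousand sequences.

## Known limitations

- Colluding errors can mask each other: if one record of species B is
  contaminated by species A while another record is relabeled A → B, the
  two corrupt records corroborate as mutual "conspecifics" and the deep-
  intraspecific half of the paradox fails for both (the shallow half still
  fires).  Sensitivity of the paradox flag is therefore slightly below 1
  when error rates are high or species pairs are reused by chance.
- Thresholds are global; groups with unusually fast or slow markers would
  need per-group configuration.
- Only the K2P model is implemented (no p-distance, TN93, GTR, or gamma
  rate correction), matching the method's scope.
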