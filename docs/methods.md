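# Methods

## Detection model

Charge clusters are detected by a windowed exact binomial test. For a
polarity class (positive = {K, R}, negative = {D, E}) with background
per-residue frequency p₀, the charged count k in a window of width w
is Binomial(w, p₀) under an i.i.d. null. Every window position is
evaluated (windows overlap; no multiplicity correction is applied —
α is a per-window level, and the detector is defined operationally by
the triggering rule, not as a calibrated hypothesis test). A window is
significant when its upper tail P(X ≥ k) ≤ α. Residue positions
covered by significant windows are unioned; each maximal contiguous
run, trimmed inward to the first and last residue of the class, is
one reported cluster. Clusters therefore (a) begin and end on a
charged residue, (b) may be shorter than w, and (c) are pairwise
disjoint within one protein and polarity. Each cluster records the
smallest tail probability among its triggering windows
(`min_window_p`), its charged count and its net charge (K+R minus
D+E).

Defaults are w = 20 and α = 10⁻⁵, the classical operating point for
this family of screens. Proteins shorter than w are evaluated as a
single window of width L, so no protein is silently skipped (the
shortest realistic inputs are ~25 aa). Histidine and the ambiguity
letters B, Z, X, U, O, J are neutral: they can never create a
cluster, only dilute one — the conservative choice. The two polarity
scans are fully independent; "mixed" is a protein-level label meaning
the protein carries at least one cluster of each sign.

### Background models

`background_mode` selects the null frequency:

- `proteome` (default): pooled class frequency over all scanned
  records. Stable for short proteins; appropriate when the question is
  "unusual relative to this proteome".
- `per_protein`: one p₀ per record; flags regions unusual relative to
  their own protein, but is noisy for short sequences.
- `fixed`: user-supplied p₀ per polarity, for sensitivity analyses and
  simulation studies with a known truth.

### Numerical notes

Tail probabilities come from the regularized incomplete beta function
(`scipy.stats.binom.sf`), accurate to well over 10 significant digits
for w ≤ 100; the test suite cross-checks them against exact rational
summation. The critical count k*(w, p₀, α) = min{k : P(X ≥ k) ≤ α} is
found by scanning the tail vector; it is non-increasing in α and
non-decreasing in p₀ (property-tested). When even k = w is not
significant, the scan returns no clusters (`critical_count` reports
the condition as unattainable). A candidate region that contains no
class residue after trimming is dropped with a warning; this cannot
occur when k* ≥ 1 but is guarded against degenerate configurations.

## Domain-relative mapping

Domain annotations (a simplified Pfam hit table) are merged per
protein: overlapping or exactly adjacent intervals coalesce, and
intervals are clipped to the protein. A cluster is N-terminal if it
ends before the first merged domain, C-terminal if it starts after
the last, interdomain if wholly inside a gap, and in-domain if fully
covered. A boundary-straddling cluster is assigned by majority
overlap among the domain and whichever flanking regions it touches,
with ties going to the domain — a deterministic substitute for an
assignment rule that such screens rarely state. Proteins without any
domain annotation yield `unannotated` clusters, which are excluded
from the 2×4 location-by-polarity contingency table and reported as a
separate count, so the table plus the excluded count always partition
the clusters.

## Conservation grouping

Two same-polarity clusters from different proteins are "the same"
when their alignment identity reaches a threshold. Identity is
matches / max(length), under global alignment with match +1,
mismatch 0, gap 0 — the maximal match count is the longest common
subsequence, and dividing by the longer length penalizes length
mismatch, so identity 1.0 is exactly string equality. The default
threshold is 1.0: the clearest reading of conservation for this kind
of screen is an identical cluster sequence recurring across strain
variants of a protein, and it makes grouping an equivalence relation
(at 1.0 the implementation buckets by sequence instead of aligning —
the two routes are equivalent and the suite checks this). Connected
components (via the pairwise-similarity graph) spanning ≥ 2 distinct
proteins are conserved groups; each reports its member count,
distinct-protein count, and most frequent member sequence (ties:
lexicographically smallest). Lowering the threshold only ever adds
edges, so conserved membership is monotone in the threshold
(property-tested).

## CPP candidate flag

Positive clusters of 7–30 aa are flagged as cell-penetrating-peptide
candidates: that window is the canonical CPP length range and the
clusters are cationic by construction. The flag is a screen, not a
prediction — anionic clusters are never flagged, and no sequence
model beyond length and polarity is applied.

## Statistics

- Location × polarity tables: Pearson chi-square with
  df = (r−1)(c−1), plus an optional Monte Carlo p-value from ≥ 10⁵
  fixed-margin tables (Patefield sampling, `scipy.stats.random_table`,
  seeded; (b+1)/(m+1) convention). A linear-by-linear trend test is
  deliberately not offered: the four location categories have no
  natural ordering.
- Two-group length comparisons: Welch t-test with a Mann–Whitney U
  companion (protein lengths are heavy-tailed; the nonparametric
  companion guards the parametric p).
- Across families/groups: one-way fixed-effects ANOVA; for two groups
  F equals the squared pooled-variance t statistic (cross-checked to
  1e-9).
- Summaries: per-family and per-genome-group rows (protein counts,
  PCC/NCC counts, mean ± sd of protein and cluster lengths, NCC:PCC
  ratio, undefined when a stratum has no PCC) plus an `all` row;
  additive and permutation-invariant. Sample sd uses ddof = 1; a
  single-member stratum reports sd 0.

## Synthetic proteomes

The generator emulates the screen's study conditions: protein lengths
log-normal with natural-scale mean 475 aa and sd 572 aa, clipped to
[25, 18212]; background residues i.i.d. from a 20-letter composition
with K+R = 0.10 and D+E = 0.12 (`adjust_composition` rescales the
charge classes for calibration studies); plants of 6–61 aa, the
realistic cluster size range; Poisson-placed domain intervals
(mean 1.5/protein, 30–200 aa, overlaps allowed); and a five-family
taxonomy partition for stratified summaries. A plant's interior mixes
polarity-alphabet draws (K vs R, or D vs E, proportional to the
composition) with background draws at the requested charge density;
its first and last residues are always charged. `copies = c` places
the identical segment into c distinct proteins, creating a conserved
group of known size. Same-protein plants are separated by at least
`min_separation` (default w) background residues.

Background residues of the plant's own class inside that separation
flank are resampled to neutral letters. This is what makes planted
coordinates well-defined as ground truth: coverage extends up to
w − k* residues beyond a plant before trimming, so a charged
background residue there would be absorbed into the detection,
shifting its boundary and giving each copy of a conserved plant a
different detected sequence. With neutral flanks a detection trims
exactly to the planted interval. Background-only (null) simulations
are unaffected.

What the generator does **not** emulate: real family-specific
compositions, repeat structure, low-complexity regions other than the
plants themselves, disorder, or evolutionary correlation between
proteins (conserved plants are exact copies, not diverged homologs).
Passing recovery tests therefore demonstrates the detector's
operating characteristics under an i.i.d. background — not
performance on real proteomes, where compositional heterogeneity can
inflate or deflate the effective p₀.

Recovery is scored by greedy one-to-one matching of detections to
planted truths (same protein and polarity) in decreasing interval
Jaccard, with a match requiring Jaccard ≥ 0.5; precision is matched
detections over all detections, recall matched truths over all
truths. Recovery experiments in the validation suite use 100-protein
proteomes with K+R background 0.05 (so k* = 8 at the default scan
settings) and 20 fully charged positive plants per proteome with
lengths evenly spanning 12–61 aa, pooled over 20 seeds — problem
sizes chosen so the whole suite runs comfortably on one CPU while
keeping ~400 plants per estimate.

## Interfaces and determinism

All coordinates in memory and on disk are 1-based inclusive. Tables
are plain TSV with header rows; cluster p-values are written with 17
significant digits so a write/read round-trip is exact. Output rows
are deterministically sorted, every simulation takes a mandatory
seed, and rerunning any command on identical inputs produces
byte-identical tables (the CLI writes a `run_manifest.json` with
input checksums and the package version alongside, which carries the
only timestamp). CLI exit codes: 0 success, 2 usage, 3 input format,
4 internal.

## Known limitations

- The binomial null ignores residue autocorrelation and compositional
  heterogeneity along real proteins; α is per-window, so genome-scale
  screens should expect a handful of false windows per 10⁶ tested.
- The location rule for boundary-straddling clusters and the
  conservation criterion are explicit package decisions; other
  reasonable choices (e.g. assignment by cluster midpoint, or a
  similarity threshold below 1.0) will shift marginal cases.
- Fisher's exact test for r×c tables is approximated by the Monte
  Carlo option rather than exact network enumeration; for the table
  sizes this package targets the chi-square asymptotics are adequate.
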