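# Methods

This note records the models behind each stage, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic-data generators do and do not emulate.

## Coordinates, alphabets, tables

All intervals are 0-based half-open internally; GTF's 1-based inclusive
coordinates are converted at the parse boundary and reproduced exactly on
write-back. Sequences are normalised to uppercase RNA (T→U) on read; for
minus-strand features, reverse complementation happens at sequence
extraction, never at parse time. Tables are tab-separated UTF-8 with a
header; `#` lines are comments; key-column duplicates are format errors.

## Novel pre-miRNA filter

A candidate is a precursor sequence with a dot-bracket structure, its MFE,
and annotated mature/star arm intervals (each ≥16 nt, disjoint). The read
stack is collapsed: one row per distinct (start, end, mismatches) with a
multiplicity count. Criteria, all inclusive:

| criterion | default | unit | note |
|---|---|---|---|
| mature-arm support | ≥ 30 | 0-mismatch reads, weighted | |
| star-arm support | ≥ 10 | 0-mismatch reads, weighted | |
| 5' homogeneity | ≥ 0.50 | fraction of arm reads at modal 5' start | all reads, any mismatch count |
| 3' overhang | 0–4 | nt | measured on the 3'-arm strand |
| folding energy | ≤ −0.2 | kcal/mol/nt | MFE divided by precursor length |
| hairpin loops | ≤ 1 | count | "no internal sub-hairpins" |

Open points resolved here:

- **Read→arm assignment** is not part of the criteria themselves; a read
  joins an arm iff its 5' end lies within ±3 nt of the arm's annotated 5'
  end. The window tolerates Drosha/Dicer 5'-end heterogeneity while
  keeping arms unambiguous (arm starts are ≥16 nt apart).
- **Which arm the homogeneity criterion reads.** The criterion is applied
  to the mature arm by default — the dominant product whose processing
  precision it is meant to capture — and is configurable to the star arm
  or to both (`FilterCriteria.homogeneity_arm`). The denominator counts
  all arm reads regardless of mismatches (only the support criteria are
  restricted to perfect reads); a 0-mismatch-only denominator is
  available behind `homogeneity_zero_mismatch_only`.
- **Sub-hairpins** are operationalised as hairpin-loop count: a hairpin
  loop is a maximal unpaired run closed by a base pair with no pairs
  inside, so any second loop implies an internal sub-hairpin or a
  bifurcated stem. The implementation counts `(\.*)` loop motifs on the
  validated structure; tests check it against an independent pair-table
  enclosure count.
- **Overhang** is the 3'-arm strand's 3' terminus minus the position
  paired with the 5'-arm strand's 5' terminus; a recessed end is negative
  and fails the 0–4 range. If the 5' terminus is unpaired, the first
  paired position within +3 nt anchors the measurement (shift-
  compensated); with no such position the overhang is undefined and the
  criterion fails. Only the 3'-arm end is measured, reading the criterion
  literally.
- A caller-supplied exclusion list of known ncRNA ids substitutes for a
  database cross-search, which is out of scope.

## Target prediction

Seed-match taxonomy over 8-nt target windows (t1 = the 3'-most window
position, opposite miRNA position 1; pairing is strict Watson–Crick):
8mer (t2–t8 pair miRNA 2–8, t1=A), 7mer-m8 (t2–t8 pair, t1≠A), 7mer-A1
(t2–t7 pair, t1=A, m8 unpaired), 6mer (t2–t7 only), off-6mer (t3–t8
only). When a window satisfies several definitions the most specific
class wins, in that order. Overlapping sites are reported separately —
the downstream site-count filter needs a deterministic occurrence count.

**Duplex energy.** The energy model is declared rather than inherited: the
free energy of the best single contiguous helix between the full miRNA
and the site window extended 30 nt upstream on the target (where the
miRNA 3' half can pair), summing Turner-2004 nearest-neighbour stack
energies over Watson–Crick and G:U pairs in every antiparallel register,
plus the intermolecular initiation term (+4.09 kcal/mol) and a +0.45
penalty per helix end closed by A:U or G:U. Bulges, internal loops and
intramolecular structure are ignored; if no arrangement is net
stabilising the convention value is 0, so energies are never positive,
and the value is symmetric in the strands. The stack table (rounded to
0.1 kcal/mol as in the standard parameter distribution) lives in
`_energy_params.py`; the upstream extension, wobble admission and a
seed-region-only variant are configuration (`EnergyConfig`). This is a
deliberate simplification of loop-aware duplex folding: it bounds the
true hybridisation energy from above and suffices for the threshold
semantics of the retention filter.

**Retention filters**, applied in order: drop 6mer/off-6mer sites; drop
sites with energy strictly above −7 kcal/mol (a site at exactly −7.0 is
retained); drop every UTR whose total retained site count across all
miRNAs is below 2; aggregate to one (miRNA, gene) row with site count,
most specific class and strongest energy. The "<2 sites" rule is read as
a per-UTR total over all miRNAs (its literal reading); a per-(miRNA,UTR)
variant sits behind `count_sites_per_pair` because the phrasing admits
both. Filtering is idempotent.

**Longest 3'UTR.** Per gene, the transcript with the maximal spliced
3'UTR length wins; ties break to the lexicographically smallest
transcript id for determinism. Explicit `three_prime_utr`/`3UTR` features
are required; transcripts without them are skipped with a warning.

## Gene set and enrichment

The domain gene set intersects (a) genes up-regulated strictly >1.5-fold
with adjusted p ≤ 0.05 in the focal domain against **both** anterior
domains, with (b) genes annotated to any term of an externally computed
GO enrichment table passing fold ≥ 2 and FDR ≤ 0.05.

Enrichment counts interaction rows: N = all rows, K = rows touching set
genes, n = a miRNA's rows, k = its set-gene rows; p = P(X ≥ k), upper
tail inclusive of the observed k (the standard over-representation
convention — the exclusive variant would make k = 0 ill-behaved). The
raw p drives the ranking (ties break by descending fold enrichment, then
id); a Benjamini–Hochberg column is emitted alongside for transparency
but is not used to rank. A gene-level urn (N = genes in the interaction
universe, K = set genes present) is available via `universe="genes"`
since either parameterisation of the test is defensible; the
interaction-level urn is the default. The tail comes from
`scipy.stats.hypergeom`; tests pin it against exhaustive subset
enumeration and exact integer arithmetic for every urn with N ≤ 25.

## Expression layer

CPM scales each library column to sum to 10⁶. The expression rule is
strictly "above" threshold (CPM > 4.2 small RNA / > 0.38 RNA in ≥ 2
libraries); the boundary behaviour is configurable. DE filtering keeps
|log2fc| ≥ log2(1.5) and padj ≤ 0.05, both inclusive, symmetric in
direction; records with missing padj are dropped with a log message.
Row z-scores use the population (n-denominator) standard deviation;
zero-variance rows become zero with a warning. Spearman correlation uses
midranks for ties. 2^−ΔΔCt is implemented exactly as written.

## Synthetic data

Every generator is a pure function of its spec: one RNG seeded from the
spec, no global state, same seed ⇒ byte-identical output. Truth labels
derive from the spec (or from deterministic properties of the emitted
object, e.g. the realised modal-start fraction), never from running the
component under test.

- **Hairpins**: a stem-loop built from a pair table (stem default 22 nt,
  loop 8 nt), optional internal sub-hairpins, a protruding or recessed 3'
  end realised in the structure, MFE set to the target per-nt energy
  times length and rounded to one decimal as folding tools print it.
  The read stack puts the requested number of perfect reads at the arm
  anchor and spreads the remainder over the next three start positions to
  realise the homogeneity target; infeasible targets (remainder cannot be
  spread without beating the mode) raise a spec error. The 5'-start
  spread is this package's construction — no noise model for read stacks
  exists to copy.
- **UTRs**: background of controlled GC content (default 0.45) with
  planted windows that are the exact reverse-complement patterns of their
  class; the background is resampled (up to 100 attempts) until the
  planted sites are the only classifiable windows, so truth is exact.
  Highly repetitive seeds can make a clean background infeasible — that
  raises a spec error rather than emitting dirty truth.
- **Counts**: negative binomial in mean–dispersion form (dispersion
  default 0.1) over the fixed 3-domain × 2-stage × 2-replicate design,
  gene base means log-normal, planted log2 fold changes applied to the
  focal domain, columns scaled to a common expected depth. Matched
  statistical structure for threshold/filter logic is the goal, not a
  DESeq2 reimplementation.
- **Interactomes**: each (miRNA, gene) pair targeted independently at a
  baseline probability (default 0.05); the planted miRNA's set genes are
  targeted at min(1, enrichment_factor × baseline), realising the
  intended fold enrichment of its target list. With factor 1 nothing is
  planted — the null configuration used for calibration.
- **The toy dataset directory** ties stages together: the count matrix's
  up-regulated genes are the gene set, the DE and GO tables are written
  to reproduce exactly that set, and each realised interaction is
  physically planted as an 8mer plus a 7mer-m8 site in the gene's UTR.
  The miRNA panel is drawn with GC-rich seeds (so every planted seed
  helix clears the −7 kcal/mol cutoff with margin) and screened so that
  no planted window can deterministically contain another panel member's
  match pattern — background resampling then guarantees sequence-level
  prediction recovers the planted interactome exactly. The boosted
  enrichment factor (8) keeps the planted signal decisive at toy size
  (80 genes, 8 miRNAs).

What the generators do **not** emulate: raw reads, adapters, mapping
artefacts, expression-correlated GC or length biases, hairpins with
asymmetric bulged stems, UTR conservation structure, or correlated
miRNA→gene targeting. Passing planted-truth tests therefore demonstrates
the correctness of the computations under their stated assumptions, not
the biological fidelity of any upstream step.

## Problem sizes and numerics

Validation runs use 500 simulated hairpin candidates spanning all
pass/fail combinations, 1000 simulated UTRs plus 10,000 random classifier
windows, and 200 interactome seeds each for power (enrichment factor 3:
the planted miRNA ranks first in ≥95%) and null calibration (factor 1:
one fixed miRNA's p-values across seeds are KS-compatible with uniform).
Exhaustive hypergeometric checks cover every urn with N ≤ 25. These sizes
give exact or near-exact expectations while keeping the whole suite in
seconds on one CPU.

One calibration subtlety: the inclusive upper tail of a discrete test is
conservative (stochastically larger than uniform) by construction, so
null uniformity is assessed on the randomised probability integral
transform, P(X > k) + u·P(X = k) with u ~ Uniform(0,1), which is exactly
uniform when the test is correctly calibrated; the test additionally
bounds the raw p-values' anti-conservative excess. The ranking itself
always uses the standard inclusive p.

Numerical conventions: threshold comparisons are exactly as printed
(inclusive unless the source wording says "above"/">"); generated MFEs
are rounded to 0.1 kcal/mol before the per-nt division so boundary specs
land on representable values; enrichment ranking ties break
deterministically; all file outputs are byte-stable under reruns, which
the pipeline manifest (config hash + input checksums) makes checkable.

## Known limitations

- The duplex energy model has no bulge/internal-loop states; energies for
  sites whose best pairing is discontinuous are conservative
  (less negative). The single external calibration point quoted for this
  kind of model (−7.2 kcal/mol for a specific miRNA:UTR pair) requires
  genome-derived UTR sequence not shipped here; the seed-region-only
  variant exists for recalibration against external data.
- `extract_longest_3utrs` does not derive UTRs from stop-codon/exon
  geometry; annotations must carry explicit 3'UTR features.
- The hairpin filter trusts the supplied arm annotation; it does not
  infer arms from read density.
- Enrichment p-values are raw by design (the ranking statistic); the BH
  column is advisory.
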