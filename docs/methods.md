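# Methods

## Scope and model

`scrapseek` implements two connected procedures for peptide-centric
immunotherapy target work:

1. **Cross-reactivity scan.** A query tumour pMHC (peptide + HLA allele)
   is compared against every same-length window of a normal proteome
   presented on the matched allele. Each candidate receives a positional
   similarity score ΣP, an overall risk score combining ΣP with predicted
   binding affinity *b* (nM IC50) and maximum normal-tissue expression
   *E*\_max, and a flag for empirical presence in a normal-tissue
   immunopeptidome. The output is a ranked report; high ranks are the
   peptides to counter-screen a receptor against.
2. **Discovery funnel.** Immunopeptidomics hits are filtered by predicted
   binding, tumour-specific differential expression against every normal
   tissue, and absence of the parent gene from a benign ligandome, then
   ranked by a composite prioritization score.

No MS/MS identification, HLA typing, binding-engine reimplementation or
structural modelling is attempted; binding predictions enter through a
deterministic `BindingPredictor` contract (external engines are run once
and replayed from a TSV cache).

## Positional similarity scoring

Residue pairs at the same position score 5 (identical), 2 (different
residues, same chemical class) or −2 (otherwise). The default classes are
aliphatic-nonpolar {G,A,V,L,I,P,M}, aromatic {F,W,Y}, polar-uncharged
{S,T,C,N,Q}, positive {K,R,H}, negative {D,E}; the polarity flag marks
residues outside {G,A,V,L,I,P,M,F,W}. The class table is not canonical in
the field, so it lives in a loadable TSV (`AminoAcidTable.from_tsv`) and
alternatives are drop-in. The three-outcome rule folds "different class,
same polarity" into the −2 residual: only three scores exist, and the
table-driven design makes any finer-grained variant a configuration, not a
code change.

Two conventions exist for which positions are scored, and they genuinely
differ:

* `text` (default): position 1 plus positions 3…*n*−1 — the
  anchor-excluding reading (P2 and the C terminus are buried in the MHC
  groove and cannot face a receptor). For a 9-mer: {1,3,4,5,6,7,8},
  giving ΣP ∈ [−14, 35].
* `equation`: positions 3…*n*, the literal reading of writing the sum from
  i = 3 to n. This keeps the C-terminal anchor and drops position 1.

Both are implemented; the anchor-excluding reading is the default because
it is the physically motivated one. The convention used is recorded in
scan metadata.

## Overall score orientation

The printed form of the combined score is ΣP / (*b* × *E*\_max). Note its
direction: *lower* normal expression *raises* the score, so a
similarity-matched peptide from an unexpressed gene outranks one from a
highly expressed gene. The intent of combining "peptide score, binding
affinity and normal tissue expression" into a risk ranking arguably wants
the opposite direction for expression — a cross-reactive peptide is more
dangerous when its source gene is broadly expressed — so an
`expression_weighted` orientation, ΣP × *E*\_max / *b*, is shipped
alongside. The printed form is the default for fidelity; the mode is
always logged in report metadata and the report carries the raw ΣP, *b*
and *E*\_max columns so users can re-rank.

*E*\_max is floored (default 0.01 RPKM) before division: genes absent from
the expression matrix, or with zero measured expression, would otherwise
produce infinite scores. The floor preserves the "unexpressed → high
score" behaviour of the printed formula while keeping arithmetic finite;
missing genes are logged.

Within the scan, ties in overall score break by (ΣP descending, *b*
ascending, peptide lexicographic). The tie-break is a package choice made
so that rankings are bit-reproducible under any input row order; it is
applied through a stable sort and verified by permutation tests.
Self-matches (candidate sequence identical to the query) are reported and
flagged rather than removed, since the query's own occurrence in the
proteome is informative.

## Proteome index

The index windows every protein into fixed-length peptides (8–14 residues;
windows containing non-canonical residues are skipped and counted),
deduplicates windows across proteins with parent-gene-set union — the scan
scores peptides, not loci — and annotates each unique window with
predictor output and *E*\_max (the max over parent genes of the max over
normal tissues). Rows are emitted in lexicographic peptide order, making
the build idempotent and independent of protein input order. Window count
conservation (Σ max(0, len−k+1) = retained occurrences + skipped) is
property-tested.

## Discovery funnel

* **Binding:** keep IC50 ≤ 500 nM. The boundary is inclusive; the
  threshold is a parameter.
* **Differential expression:** computed on log2(FPKM+1). For each gene and
  each normal tissue, lfc = mean(tumour) − mean(tissue) and a two-sided
  Mann–Whitney rank-sum p-value; a gene passes only if lfc ≥ 1 and
  p < 0.01 against *every* tissue. "One log fold" is read as log2 (the
  field's convention for expression fold changes; the base is a
  parameter), and the rank-sum test is the package's choice of a robust
  two-sample test — Welch's t is available by config. No multiple-testing
  correction is applied because the rule is a raw per-tissue threshold
  conjunction, which is already conservative; tissues with fewer than two
  samples are excluded with a warning.
* **Ligandome:** gene-level exclusion — a record is dropped if its parent
  gene appears anywhere in the normal-tissue immunopeptidome, even via a
  different peptide. This deliberately over-excludes (a gene with any
  benign presentation disqualifies all of its peptides) and is kept
  because it is the safety-conservative rule.

Stage outputs are nested subsets by construction; the funnel report
records per-stage record, unique-peptide and unique-gene counts.

**Prioritization** z-scores five factors per unique (peptide, allele) —
minimum tumour lfc, allele population frequency, negated abundance
percentile rank, negated log10 IC50, recurrence across tumours — and takes
a weighted sum (equal weights by default). Missing factors are imputed to
the cohort median and flagged. This is explicitly decision support: the
final shortlisting step in real programmes weighs biological context that
no composite can encode, so all factor columns are emitted for re-ranking.

**Cross-HLA scan** returns the alleles whose predictor percentile rank for
the peptide is at or below a threshold (default 2%), excluding the
discovery allele; alleles the predictor cannot score are listed as
unscored rather than dropped.

**MS1 matched-peptide search** declares a feature a match when its m/z is
within `ppm_tol` (default 10 ppm) of the theoretical m/z at some charge in
{1,2,3} *and* its retention time is within `rt_window_min` (default 1 min)
of a required reference RT. Masses are unmodified monoisotopic sums over a
residue-mass table plus water; no isotope envelopes, modified residues or
RT prediction — the search is a deliberate lower-confidence recurrence
check, not an identification.

## Alanine-scan analysis

Relative binding = (mutant − background)/(wild-type − background), clipped
at 0; positions with relative binding below a threshold are called
contacts, excluding anchors. The threshold defaults to 0.5 — a
half-signal loss as "significant abrogation" — because published scans
report the pattern, not a cutoff; it is a flag on the CLI and printed with
the output.

## Synthetic data

Generators exist so the full system is testable with no external
databases. They are pure functions of (parameters, seed); a root seed fans
out into fixed named substreams, so each fixture regenerates
byte-identically and independently.

* **Proteome:** residues drawn near-uniformly over the 20 canonical amino
  acids. This is intentionally not human composition: the tests need every
  chemical class exercised, and uniform draws give the widest coverage per
  peptide.
* **Toy predictor:** per-allele anchor-position weight tables with one
  preferred residue each, plus a small non-anchor term, mapped
  monotonically onto IC50 ∈ [1, 50000] nM; percentile rank is a monotone
  transform of IC50 within an allele. It reproduces the two properties the
  pipeline relies on — determinism and anchor dominance — and nothing
  else about real binding engines.
* **Planted cross-reactors:** a controlled near-copy of the query inserted
  as its own protein, differing at exactly the requested positions, each
  substitution drawn from a different chemical class (so it scores −2
  wherever scored). The expected ΣP is computed at plant time from the
  residue table. The dominance construction — zero substitutions, IC50
  pinned to the 1 nM lower bound via a predictor overlay, expression
  pinned to 0 so E_max sits at the floor — makes rank 1 a theorem under
  the printed orientation: maximal numerator, minimal denominator.
* **Expression:** per-gene log2 baselines uniform in [1, 4] with unit
  normal sample noise; planted genes gain the effect size in tumour
  samples only. Defaults (20 tumour samples, 20 per tissue, 3 log2-unit
  effect) are the conditions under which the power simulation runs. The
  funnel fixture instead plants *fully separated* expression (tumour
  uniform in [64, 128] FPKM vs normal in [0, 1]) so that the rank-sum
  decision provably agrees with the planted label and stage-set equality
  is a meaningful check rather than a statistical coin flip.
* **MS1 features:** emitted at the theoretical m/z of a random charge
  offset by exactly `jitter_ppm` (random sign) and at the reference RT
  offset by exactly `jitter_rt`, so the acceptance region of the matcher
  can be tested sharply (offsets inside the tolerance always match,
  outside never). Decoy features land far from any planted m/z.

What passing on synthetic data does *not* show: realistic amino-acid
composition or linkage between similarity and binding, real binding-engine
error structure, expression distributions with zero inflation or batch
effects, or chromatographic RT drift. Results on real data depend on the
external predictor and atlases plugged in.

## Numerical and size choices

Scan scoring is vectorised (residues encoded as integers, one 20×20
pair-score gather per scan); correctness is anchored by exact equality
with a pure-python double-loop reference on random indexes up to the sizes
the test suite uses (50 indexes of 200–1500 peptides; the oracle bound in
the suite is 10⁴). Simulation sizes in tests and in
`scripts/acceptance.py` (100 seeds for recovery/power runs, 8–10-gene
proteomes for planted scans) were chosen to keep the full suite in the
tens of seconds while leaving every statistical conclusion
comfortable — the DE power check at a 3 log2-unit effect with n = 20/20
operates at essentially unit power, so its ≥ 95% recall bound is not
near a boundary.

Degenerate inputs: empty proteomes and empty indexes yield empty outputs,
not errors; an all-zero expression gene survives via the E_max floor;
peptides with non-canonical residues are rejected by name at validation
boundaries, and windows containing them are skipped and counted during
indexing.

## Known limitations

* Equal-length, ungapped comparison only; no spliced or non-canonical
  peptides, and no structural surface similarity — a candidate can be
  sequence-dissimilar yet structurally cross-reactive.
* The printed score orientation question (see above) is resolved by
  configuration, not adjudicated.
* Whether *b* should be IC50 or percentile rank in the combined score is
  underdetermined; the package takes nM IC50 and records units.
* The prioritization composite is decision support, not a reproduction of
  any published shortlist.
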