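# Methods

## Predictor

### Training

Inputs are (i) GO annotations — GAF 2.x or a simplified three-column TSV
(`protein_id`, `go_id`, `evidence_code`) — and (ii) a Pfam assignment TSV
(`protein_id`, `pfam_id[, start, end]`). Training proceeds:

1. **Evidence filter.** Only annotations whose evidence code is in the
   allowed set are kept; the default is `{IDA}` ("inferred from direct
   assay"), i.e. experimental localization evidence only. Rows carrying a
   `NOT` qualifier are dropped during GAF parsing: a negated annotation is
   not evidence *for* a compartment.
2. **Compartment mapping.** GO terms are matched **exactly** against an
   11-term vocabulary (nucleus, mitochondrion, vacuole, peroxisome, ER,
   Golgi apparatus, cytosol, plasma membrane, cell plate, plastid,
   extracellular). No ontology-graph propagation is performed — results are
   then reproducible without pinning an ontology release. Users who want
   descendant closure can supply a term→term expansion table
   (`CompartmentVocabulary.expanded`).
3. **Protein-weighted counting.** A protein annotated to the same
   compartment by several assays counts once (set semantics), avoiding
   assay-count bias. For each protein, each **distinct** Pfam it carries is
   credited with each compartment the protein is annotated to; repeated
   copies of a domain within one protein count once.
4. **Normalization.** `ratio(d, c) = count(d, c) / total(d)`. Every
   trained Pfam's ratios sum to 1 (asserted to 1e-9 on every construction);
   Pfams never seen in training are absent from the table rather than
   zero-filled, so "no data" is distinguishable from "ratio zero".

Locus identifiers are normalized before joining tables: AGI loci are
uppercased and splice-variant suffixes (`.1`) stripped; rice RAP loci keep
their canonical `OsNNgNNNNNNN` casing.

Note one consequence of protein-weighted counting: a multi-localized
protein credits *all* its domains with *all* its compartments, so domains
that co-occur with differently localized domains absorb some of each
other's signal. This is inherent to the method, not an artifact; it is why
the compartment-pure recovery guarantees below are stated for
single-domain corpora.

### Scoring and calling

For a query protein, duplicate accessions collapse, domains absent from
the table are excluded from the mean (and reported as skipped), and with
k ≥ 1 usable domains `score(c) = (Π r(d_i, c))^(1/k)`, computed in log
space. k = 1 is special-cased so a single-domain protein's scores equal
its domain's ratios *bit-exactly*. Zero ratios are not smoothed — one zero
factor annihilates a compartment, as the bare geometric mean implies; an
optional additive `smoothing` parameter exists for exploratory use and is
off by default.

The call is the argmax compartment set. Parameters:

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.0 | abstain (`below_threshold`) when the top score is lower; 0 always calls the argmax |
| `tie_tolerance` | 1e-9 | scores within this of the max are co-called; effectively exact ties only, reproducing 50/50 dual calls |
| `smoothing` | 0.0 (fraction) | additive pseudo-ratio before the product |

Statuses: `predicted` (single call), `tie` (≥ 2 co-called), `no_pfam` (the
protein has no domains), `no_data` (domains exist but none trained),
`below_threshold`. Ties are propagated, not abstained: downstream
consumers can choose either convention from the status.

Scores are fractions internally and percentages with one decimal in
human-readable output.

## Evaluation

Truth is multi-label (a protein may genuinely reside in several
compartments). Each compartment is evaluated one-vs-rest: tp if called and
true, fp if called and not true, fn if true and not called, tn otherwise;
tie calls contribute every called compartment. Sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp); zero denominators yield an explicit `None`, never
a silent 0. Proteins with status `no_pfam`/`no_data` are excluded from the
denominators by default and reported as coverage, since the benchmark is
defined over proteins with usable domain data; `include_uncovered=True`
counts them as all-negative calls instead.

The ROC sweep varies the calling threshold over a grid (step 0.01 by
default): at threshold t a protein is called c iff `score(c) ≥ t` **and** c
is among the (tied) argmax scores — this is the predictor's own calling
rule, not a plain score cut, so the curve reflects the deployed decision
procedure. TPR and FPR are therefore non-increasing in t (asserted on
every sweep). AUC is the trapezoid rule over the (FPR, TPR) points sorted
lexicographically and closed with (0,0) and (1,1). When the swept
compartment is every protein's argmax the sweep reduces to a standard ROC;
that case is cross-checked against scikit-learn's `roc_auc_score` in the
test suite. "Cell plate" is retained in training but omitted from the
default reporting set — with ~18 annotated proteins it cannot support
per-class rates.

## Co-expression analysis

Ranked lists are read as TSV (`rank`, `gene_id`, `mutual_rank`), re-sorted
by MR, with duplicate genes rejected by name. MR values are consumed as
published — the package never recomputes MR from expression data, and
never re-derives the top-N cut.

* `average_mutual_rank` is the geometric mean `exp(mean(log mr))`,
  computed over however many bait lists are being compared.
* `intersect_ranked_lists` reports all pairwise counts, the k-way count
  and the shared genes with per-bait MRs and average MR. Bait genes that
  appear in every list are **included** in the shared set and flagged
  `is_bait`, so totals can be read with either convention. The "shared
  fraction" is exposed against both candidate denominators (single list
  length vs. union size), since percentage conventions vary.
* `max_mr` returns the last (largest) MR — the tightness of a bait's
  neighborhood: the lower the Nth gene's MR, the tighter the module.
* `group_by_pfam` groups shared genes by their **full joint** Pfam set (a
  three-domain receptor kinase does not merge with a bare kinase), keeps
  groups whose best member average MR is **strictly below** the cutoff
  (default 70), buckets domain-less genes as "unassigned", counts members
  per species by identifier scheme (AGI/RAP), and, given a trained table,
  attaches the localization call obtained by scoring the group's Pfam set.

## Synthetic data generators

The generators define the conditions under which the package's guarantees
are stated; they are first-class, tested code.

**Annotation corpus** (`CorpusSpec`): each synthetic protein draws a domain
count (default distribution {0: 0.1, 1: 0.6, 2: 0.2, 3: 0.1}), that many
distinct Pfams uniformly from the inventory, and one true compartment per
domain from a row-stochastic conditional p(compartment | pfam); its GO
annotations are emitted in GAF dialect with evidence codes drawn from a mix
(default 85% IDA / 10% ISS / 5% IMP, so the evidence filter is exercised).
Outputs are an annotation GAF, a Pfam TSV, a truth table and a vocabulary
TSV; all are byte-identical under the same (spec, seed). What this
emulates: the conditional structure of domain→compartment enrichment and
multi-localized multi-domain proteins. What it does not: real domain
co-occurrence structure, annotation depth biases, or ontology granularity —
so green tests certify the algorithmic machinery, not field performance on
any particular genome snapshot.

**MR lists** (`MrListSpec`): gene universes are constructed region-wise —
an all-baits core of the designed k-way size, exactly-one-pair regions
making up each designed pairwise overlap, unique fill to the list length —
so realized Venn counts equal the design *exactly*; infeasible designs
(k-way > a pairwise, or overlaps exceeding the list length) raise with the
violated inequality. MR values are ranks jittered by Gaussian noise
(σ = 5 by default), clipped at 1 and re-sorted. Bait genes can optionally
occupy the core (`include_baits`), mirroring real lists where baits
co-express with each other.

**Sizing of the validation runs** (the package's own choices): parameter
recovery uses 10,000 single-domain proteins over 5 Pfams (≈ 2,000 draws
per domain; binomial standard error ≈ 0.01, comfortably inside the ±0.02
check); label-permutation ROC uses 1,000 proteins; the intersection oracle
runs 100 random feasible three-bait designs with list lengths up to a few
hundred. The whole suite runs in a few seconds on one CPU.

## Numerical choices and edge cases

* Geometric means in log space (`math.fsum` of logs) for accuracy; k = 1
  bypasses the exp/log round-trip entirely.
* Ratio-table TSV round-trips bit-exactly (pandas shortest-repr floats).
* Empty inputs are legal wherever meaningful: empty annotation files give
  empty record lists, empty corpora give header-only files, an empty call
  list gives all-zero confusion counts. Empty ranked lists and fewer than
  two lists to intersect are validation errors.
* MR ties at a list's tail keep file order after the stable sort.

## Known limitations

* The predictor is annotation-frequency based: it carries the biases of
  the training snapshot (well-studied compartments dominate) and cannot
  score proteins whose domains lack localized training representatives.
* Evaluating on the training set — the only option without an independent
  localization benchmark — is a best-case characterization; an optional
  exclusion flag supports held-out protocols, but no cross-validation
  scheme is prescribed.
* GO terms are matched exactly; annotations made to descendant terms of a
  vocabulary entry are invisible unless the user supplies an expansion
  table.
* Cross-species comparison is by Pfam group only; no ortholog mapping of
  gene identifiers is attempted.
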