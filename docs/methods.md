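# Methods

This note documents the models, parameter choices and numerical conventions
behind `toxscreen`, and what the synthetic benchmark does and does not show.

## The discovery cascade

The pipeline assumes a de novo transcriptome (no reference genome), library
level abundance estimates from a pseudoaligner, and protein-search results
computed elsewhere. It owns everything after those inputs: ORF screening,
homology-based retention and toxin assignment, redundancy clustering,
normalisation, the tissue-bias statistic, and candidate integration. The
guiding biological assumption is that a genuine toxin should be secreted by
a specific gland, hence strongly biased toward one tissue; requiring both
homology and tissue bias suppresses false positives from each source alone.

### Complete-ORF screen

An ORF is complete when it has an ATG start and an in-frame TAA/TAG/TGA stop
inside the transcript; every ATG pairs with its *first* downstream in-frame
stop, on both strands. Only ATG initiates (no alternative starts), and any N
inside a candidate span disqualifies it — conservative choices that keep the
screen deterministic and oracle-checkable. Coordinates are 0-based,
half-open, on the reported strand's sequence; the span includes the stop
codon, the protein excludes it. The chosen ORF per transcript is the
longest, ties broken by smallest start and then '+' strand. The 20-residue
floor keeps short cysteine-rich peptides (knottins, defensins) while
discarding spurious micro-ORFs. Both-strand scanning is the default and can
be disabled (`both_strands=False`) for stranded assemblies.

### Homology retention and the toxin best-hit rule

Retention requires one hit with e-value strictly below 10⁻⁵ in any
database. Toxin assignment uses the best hit by bit score *pooled across
all databases*: a transcript whose strongest similarity is to a general
protein is not toxin-like even if it also resembles a toxin. A
`per_database` mode (any passing toxin-database hit suffices) is provided
for sensitivity analyses. Bit-score ties break by lower e-value, then
lexicographic subject id, making decisions independent of row order. Hits
are keyed by transcript (the chosen ORF's translation); one decision per
transcript. Bit scores from different databases are compared as given, no
rescaling.

### Redundancy clustering

Identity between two sequences is the number of identically aligned
positions of a global alignment (match +1, mismatch −1, gap open −2,
extend −0.5) divided by the length of the shorter sequence — so an exact
prefix of a longer sequence has identity 1.0. Clustering is greedy and
longest-first (ties by id): each sequence joins the first cluster, in
founding order, whose representative it matches at identity strictly above
0.99, else founds a new cluster. Exactly 0.99 does not cluster. The
representative is therefore always the longest member (ties resolved to the
lexicographically smallest id).

For speed, candidate representatives are screened by a shared-k-mer
inverted index (k = 11) with a conservative count bound, then by edit
distance bounds (if d is the optimal edit distance and Ls the shorter
length, any alignment has between Ls − d and (La + Lb − d)/2 matches);
only undecided pairs reach the exact alignment. The k-mer bound is exact
for substitution- and truncation-type divergence; pathological cases with
many internal indels in the longer sequence could in principle slip past
it, so the screen can be disabled (`prefilter=False`), and the test suite
checks both modes against a brute-force all-pairs oracle.

### Expression and QC

TPM is the standard rate normalisation; an all-zero library yields all-zero
TPM with a warning rather than an error. Effective lengths below 1 nt are
rejected, not clamped. The expression floor (TPM ≥ 1 in ≥ 1 library,
inclusive) runs on cluster representatives. PCA QC selects the 1000 most
variable transcripts by variance of log₂(TPM + 1), centres per transcript,
and reports per-component variance fractions and library coordinates; the
log transform is a documented choice, not an input convention.

### Tissue bias

Per-tissue expression is the mean TPM over the tissue's libraries (a
`fc_mode="max"` alternative uses the single-library maximum). The fold
change is (highest + 0.01) / (second highest + 0.01); the pseudocount
gives tissue-exclusive transcripts a large finite FC (8 TPM in one tissue,
zero elsewhere → 801) instead of a division by zero, and 0.01 TPM is far
below any biologically meaningful signal. Exact ties for the top tissue
resolve lexicographically.

The group test is a one-way ANOVA F-test on log₂(TPM + 0.5) across tissues
with ≥ 2 replicate libraries. It is a transparent stand-in for
bootstrap-based likelihood-ratio machinery in pseudoalignment-native
differential-expression tools and is documented as *not* a numerical
replica of any of them. Tissues with a single library (gonads in the
default design) are excluded from the test but still contribute to the
fold change and can be the top tissue. Degenerate rows: all tested values
equal and non-zero → F = 0, p = 1; zero within-group variance with
separated groups → p = 0; zero expression in *every tested library* → the
test cannot see the transcript at all and p is undefined. That last state
feeds the rescue rule: undefined p with FC ≥ 2 retains the transcript —
the only route by which a gonads-exclusive transcript can surface under
the default design. q-values are Benjamini–Hochberg across all tested
transcripts. Retention is FC ≥ 2 (inclusive) and q < 0.05 (strict).

### Integration, families, knottins

Candidates are the intersection of the toxin-like and upregulated sets.
Domain labels, signal-peptide flags and neurotoxicity predictions are
consumed from external annotators and surfaced without ever filtering;
missing rows yield None-valued fields. One family label per transcript:
with a multi-row domain table the highest-scoring domain wins (ties by
label). Candidates without a domain label report "No prediction".

The knottin check derives its constraint set from the canonical framework
string C-CXC-CC-CXC-CXC-C: 10 cysteines; gaps 2, 6 and 8 of exactly one
residue; gap 4 empty (the CC adjacency); all remaining gaps at least one
residue. Violations are reported individually, so a peptide missing, say,
its second and tenth cysteines is reported as an 8-cysteine signature.

### Report

Every percentage in the summary is half-up rounded (one decimal for
cascade survival, whole numbers for composition shares) with the
unrounded fraction stored alongside, so printed figures such as a 6.7%
survival or a 26% family share are recomputable from their count pairs.
The summary JSON carries every stage count, threshold, the seed and the
package version, and contains no timestamp, so identical runs produce
identical bytes.

## The synthetic-study generator

The generator emulates the design of a five-tissue spider study: midgut
diverticula, silk glands, chelicerae, prosoma and gonads, with three
replicate libraries each except a single gonads library (13 in total). Its
defaults are the benchmark conditions: 2000 transcripts, 50 spiked
toxin-like transcripts upregulated in the midgut at true fold 16, negative
binomial counts with dispersion α = 0.1 in the mean–dispersion
parameterisation (variance = μ + αμ²), transcript lengths uniform on
300–1500 nt, 25% of non-spiked transcripts without a complete ORF, and 5%
near-identical duplicates (< 1% substitutions) to exercise the clustering
stage.

Baseline expression is lognormal around an expected count of 200 at a
1000 nt reference length (σ = 1, mean-normalised), scaled linearly with
effective length (length − 199 nt, floored at 25, mimicking a ~200 nt mean
fragment length) so that TPM is flat in length. Spiked transcripts have
their mean multiplied by the spike fold in the spike tissue only, making
the true tissue-mean ratio equal to the configured fold by construction;
non-spiked transcripts have identical means in every tissue, so the decoy
background is an exact global null. Hit tables give every spiked
transcript its top bit score in the toxin database; decoys receive
stronger general-database hits, optionally weak toxin hits strictly below
them, weak hits above the e-value cutoff, or no hits. One library can be
depth-scaled (factor 0.5) to mimic a shallow outlier library; this is off
by default. Sequences are uniform random nucleotides with a planted
ATG…stop ORF — no codon-usage model, since no downstream stage consumes
codon statistics; ORF-free sequences are constructed by disrupting start
codons until a six-frame scan comes back empty.

What the generator does *not* emulate: read-level sampling and
pseudoalignment uncertainty, isoforms and shared-sequence ambiguity, GC
and positional bias, correlated biological replicates, and realistic
homology score distributions. Passing the benchmark therefore shows that
the cascade's logic, statistics and bookkeeping are correct under the
stated noise model — not that the thresholds are optimal for any real
tissue panel.

## Benchmark scale and observed behaviour

Problem sizes were chosen to keep the full suite inside a few minutes on a
single core: recovery runs 20 independent studies at the default 2000 ×
13 design; the null check runs 20 global-null studies of 800 transcripts;
oracle-equivalence suites use 200 clustering instances of ≤ 50 sequences,
1000 random p-vectors and 500 random sequences. Under the default
conditions the pipeline recovers ≥ 94% of spiked toxins per seed (the
occasional miss is a low-abundance spike whose shot noise inflates the
within-group variance), assigns every recovered spike to the correct
tissue, and admits no decoys; under the global null the q < 0.05 call
rate is far below the nominal 5%.

## Known limitations

- The ANOVA stand-in ignores inferential (bootstrap) variance, so its
  p-values are not comparable to those of count-model tools on real data.
- Greedy clustering is order-dependent by design (longest-first); it
  reproduces the conventional tool's semantics, not an optimal partition.
- Bit scores pooled across databases assume comparable scoring schemes.
- The knottin check reads cysteine spacing only; it does not model
  disulfide connectivity.
- With a single-replicate tissue, a transcript exclusive to that tissue is
  untestable and can only be rescued; its q-value is undefined.
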