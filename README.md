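# toxscreen

Tissue-biased toxin-candidate discovery from assembled transcriptomes.

`toxscreen` is for researchers screening a multi-tissue RNA-seq study of a
venomous (or secondarily venom-less) arthropod for venom-toxin homologs. It
takes an assembled transcriptome, per-library abundance estimates from a
pseudoaligner, and tabular protein-search results against several databases
— one of them a curated animal-toxin set such as ToxProt — and produces a
ranked, family-classified table of toxin-like transcripts with tissue-biased
expression. A synthetic-study generator with known ground truth makes every
stage testable without any external data.

## The method

Candidates emerge from a fixed filtering cascade:

1. **Complete-ORF screen** — keep transcripts with an open reading frame
   carrying both an ATG start and an in-frame stop, translating to ≥ 20
   residues (both strands, all six frames).
2. **Homology retention** — keep transcripts with at least one hit at
   e-value < 10⁻⁵ in any database.
3. **Redundancy clustering** — greedy, longest-first clustering of
   nucleotide sequences at > 99% identity; only cluster representatives
   proceed.
4. **Expression floor** — keep transcripts with TPM ≥ 1 in at least one
   library, where TPM_i = (c_i/ℓ_i) / Σ_j (c_j/ℓ_j) × 10⁶ from counts c and
   effective lengths ℓ.
5. **Toxin assignment** — a transcript is *toxin-like* when its best hit,
   the highest bit score pooled over all databases, lies in the toxin
   database.
6. **Tissue bias** — the fold change FC is the ratio of the highest to the
   second-highest per-tissue expression (tissue-mean TPM, plus a 0.01
   pseudocount). A one-way ANOVA on log₂(TPM + 0.5) across replicated
   tissues gives p-values, Benjamini–Hochberg adjusted to q-values.
   Transcripts with FC ≥ 2 and q < 0.05 are upregulated in their top
   tissue; transcripts the test cannot assess — expressed only in an
   unreplicated tissue — are *rescued* when FC ≥ 2.
7. **Integration** — candidates are the toxin-like ∩ upregulated set,
   classified into protein families by their predicted domain ("No
   prediction" when a hit-positive sequence lacks one). Signal-peptide and
   neurotoxicity predictions from external tools pass through descriptively.

A knottin module renders a peptide's cysteine arrangement (C for cysteine, X
for a single intervening residue, `-` for a variable gap) and checks it
against the canonical 10-cysteine inhibitor-cystine-knot framework
`C-CXC-CC-CXC-CXC-C`.

## Worked example

Simulate the default study — 13 libraries over five tissues (midgut, silk
glands, chelicerae, prosoma, gonads; three replicates each except a single
gonads library), 2000 transcripts of which 50 are midgut-spiked toxin-like
at true fold 16 — and run the full cascade:

```python
import toxscreen as tx

study = tx.generate_study(config=tx.SimulationConfig(seed=0))
pipe = tx.ToxinDiscoveryPipeline().fit(study.to_study_data(), seed=0)

for name, n in pipe.stage_counts_:
    print(f"{name:24s}{n}")

spiked = set(study.spiked_ids())
cand = set(pipe.candidates_.index)
print("recall:", len(cand & spiked) / len(spiked))
print(pipe.candidates_[["family", "top_tissue", "fc", "q_value"]].head(3))
```

prints

```
input                   2000
complete_orf            1512
homology_retained       1053
cluster_representatives 1003
expressed               1003
toxin_like              50
candidates              49
recall: 0.98
                        family top_tissue        fc   q_value
transcript_id
TX000036              defensin     midgut  6.253049  0.008422
TX000112               knottin     midgut  8.826648  0.000547
TX000119       serine protease     midgut  4.275162  0.007039
```

Reading the stage counts: 1512 of 2000 transcripts carry a complete ORF,
1053 of those have homology evidence below the e-value cutoff, 1003
survive redundancy clustering and the TPM floor, 50 are toxin-like by the
best-hit rule, and 49 of them are significantly midgut-upregulated — 98% of
the planted toxins, with no decoy among the candidates.

The same run from a shell:

```bash
toxscreen simulate --seed 0 --outdir study/
toxscreen run --study-dir study/ --outdir results/ --seed 0
```

which writes `candidates.tsv`, `bias.tsv`, `decisions.tsv`, `clusters.tsv`,
`family_by_tissue.tsv` and a machine-readable `summary.json`. Individual
stages are available as `toxscreen screen / cluster / annotate / quantify /
bias`.

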