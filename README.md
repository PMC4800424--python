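# lncstage

Identification of long noncoding RNAs (lncRNAs) from a transcript catalogue
and analysis of how developmentally restricted their expression is, aimed at
transcriptomics researchers working with stage-resolved bulk expression data
(e.g. a *Drosophila melanogaster* developmental time course).

## What it computes

**Discovery funnel.** Candidate transcripts pass, in order:

1. *length filter* — retain transcripts > 200 bp;
2. *maximal-ORF filter* — remove transcripts whose longest open reading
   frame (either strand) encodes > 100 amino acids;
3. *coding-potential prediction* — a logistic regression over four
   alignment-free features (maximal-ORF size, ORF coverage, Fickett TESTCODE
   statistic, in-frame hexamer usage bias); a transcript is noncoding iff its
   coding probability *p* < 0.39 (strictly);
4. *CDS-similarity screen* — remove candidates sharing a seeded, ungapped
   high-identity match with a known coding sequence on either strand;
5. *genomic-context classification* — intergenic iff the transcript interval
   overlaps no protein-coding gene locus.

**Developmental specificity.** Each FPKM row is normalized to a relative
expression profile *p* over the ordered stages; its specificity is the
maximal Jensen–Shannon specificity score

```
JS(p) = max_t [ 1 − √JSD(p, e_t) ],    JSD(p,q) = H((p+q)/2) − (H(p)+H(q))/2
```

with base-2 logarithms, where `e_t` is the idealized profile expressed at
exactly one stage and `H` is Shannon entropy. JS ∈ [0, 1]; JS = 1 means
perfectly stage-restricted expression. Transcripts are also binned into
rank-based expression tertiles (high / moderate / low mean FPKM), profiles
are clustered by k-means with city-block (L1) distance (k = 10 embryonic,
8 larval, 9 pupal), and group contrasts use Fisher's exact test (count
proportions) and the Mann–Whitney U test (JS score distributions), both with
exact small-sample paths.

A fully seeded synthetic-data module generates transcript pools (coding-like
with embedded biased-codon ORFs vs noncoding-like background sequence) and
stage × transcript FPKM matrices (sparse-Dirichlet stage-specific rows vs
broad rows) with ground truth, so the entire pipeline runs and is tested
without any external download.

## Worked example

```python
from lncstage import (preset_config, generate_sequences, generate_expression,
                      train_model_from_corpus, run_discovery, specificity_table,
                      mann_whitney_u)

# train a coding-potential model on one synthetic corpus ...
train_cfg = preset_config("default", seed=8, n_coding=200, n_noncoding=200)
train, truth = generate_sequences(train_cfg)
model, table = train_model_from_corpus(
    [r for r in train if truth.classes[r.transcript_id] == "coding"],
    [r for r in train if truth.classes[r.transcript_id] == "noncoding"],
)

# ... and run the discovery funnel on another
cfg = preset_config("default", seed=9, n_coding=200, n_noncoding=200)
records, truth2 = generate_sequences(cfg)
cds = [r for r in records if truth2.classes[r.transcript_id] == "coding"]
catalog, report = run_discovery(records, cds, None, model, table)
for row in report.rows():
    print(row)
print("catalog size:", len(catalog))

# developmental specificity of a synthetic stage matrix
matrix, designs = generate_expression(cfg)
df, excluded = specificity_table(matrix)
sparse = df.loc[[r for r in df.index if designs.designs[r].startswith("stage")], "js_max"]
broad = df.loc[[r for r in df.index if designs.designs[r] == "broad"], "js_max"]
res = mann_whitney_u(sparse.to_numpy(), broad.to_numpy())
print(f"mean js_max: stage-specific {sparse.mean():.3f}, broad {broad.mean():.3f}")
print(f"Mann-Whitney U = {res.statistic:.0f}, p = {res.p_value:.3g}")
```

which prints:

```
{'stage': 'min_length', 'input': 400, 'retained': 400, 'removed': 0}
{'stage': 'max_orf', 'input': 400, 'retained': 200, 'removed': 200}
{'stage': 'coding_potential', 'input': 200, 'retained': 200, 'removed': 0}
{'stage': 'cds_similarity', 'input': 200, 'retained': 200, 'removed': 0}
catalog size: 200
mean js_max: stage-specific 0.679, broad 0.179
Mann-Whitney U = 180000, p = 2.34e-132
```

The funnel report shows where each transcript left the pipeline: all 200
coding-like transcripts are removed at the maximal-ORF stage (their embedded
ORFs exceed 100 aa by construction), and the 200 noncoding-like transcripts
survive every stage. On the expression side, rows designed as stage-specific
score far higher maximal JS specificity (mean 0.68) than broad rows
(mean 0.18), and the Mann–Whitney test separates the two groups decisively.

The same steps are available from the shell:

```bash
lncstage simulate --preset default --seed 7 --out sim/
lncstage identify --fasta sim/transcripts.fasta --cds cds.fasta --out run/
lncstage specificity --matrix sim/expression.tsv --out run/
lncstage cluster --matrix sim/expression.tsv --stage embryonic --out run/
lncstage stats fisher --table 20,113,64,554
lncstage run-all --seed 7 --out run_all/
```

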