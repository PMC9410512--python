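# gfabric

Genomic-fabric characterization of transcriptomes from small-replicate
expression studies.

Classical differential-expression analysis reduces a transcriptome
comparison to up/down calls on average expression levels — and discards
nearly everything else a replicated experiment measures. `gfabric`
characterizes each condition's transcriptome by three independent feature
families computed across biological replicates (the typical design is 4
animals per group):

* **AVE** — average expression level, in multiples of the condition's
  median gene (the median gene has AVE = 1);
* **REV** — relative expression variability: the mid-interval of the
  chi-square confidence interval of the expression coefficient of
  variation, in percent. Low REV means the cell spends homeostatic effort
  keeping that gene's expression inside a narrow band;
* **COR** — the Pearson correlation of log₂ expression between every pair
  of genes, which defines the significant coordination networks.

For *n* genes this is `2n + n(n−1)/2` values per condition instead of *n* —
for a 10,408-gene study, 54,178,844 values, a 5,206-fold gain over
AVE-only analysis.

From these, the package derives:

| quantity | meaning |
|---|---|
| REC / PREC | expression control of a gene / pathway: `median REV / REV − 1` |
| GCH, GMR | gene commanding height `(REC+1)·exp(4⟨COR²⟩−1)`; the top scorer is the condition's gene master regulator |
| CUT | per-gene fold-change cut-off `1 + 2√(CV_A² + CV_B²)` — stable genes are held to stricter thresholds |
| x, p, call | signed fold change, Welch t-test p-value (log₂ scale), UP/DOWN/NEUTRAL at `|x| ≥ CUT` and `p < 0.05` |
| WIR | weighted individual regulation `AVE_A·sign(x)·(|x|−1)·(1−p)` |
| ITD | individual transcriptomic distance: magnitude of the 3-vector of relative changes in AVE, REV, and averaged COR |
| WPR / PTD | pathway aggregates `(100/{Γ})·√Σ(·)²` over WIR / ITD |
| GER / PRE / CPR | treatment-recovery: category-count recovery, WPR-ratio restoration, PTD-ratio restoration (ideal / positive / null / negative) |
| synergistic / antagonistic / independent | pair coordination at the exact small-n critical correlation (0.950 at n = 4, p < 0.05) |

## Worked example

Every capability has a narrative script under `examples/`. The recovery
analysis (`python examples/05_recovery_metrics.py`) builds a synthetic
reference/disease/treated study whose 40-gene pathway is dysregulated in
disease and partially restored by treatment, and prints:

```
recovery categories (disease letter, treated letter; X = neutral):
{'DX': 7, 'UX': 6, 'XD': 2, 'XU': 2, 'DD': 1, 'XX': 182}

GER (all genes) = 50.00%
GER (designed pathway only) = 66.67%

pathway 'designed_pathway' (40 genes):
  WPR disease -> treated: 109.68 -> 13.34   PRE = 87.84%
  PTD disease -> treated: 41.21 -> 24.41   CPR = 40.76%  (positive)
```

Reading: each gene's two letters are its regulation calls in
disease-vs-reference and treated-vs-reference (D down, U up, X neutral).
On the designed pathway, 12 of 15 regulated genes recovered and 2 were
newly dysregulated, giving a gene expression recovery GER = 66.67%. The
weighted pathway regulation WPR dropped 87.84% (PRE), and the full
transcriptomic distance PTD — which also sees variability and
network changes the calls miss — dropped 40.76% (CPR, a "positive" but
not ideal outcome).

## Command line

The same pipeline is scriptable:

```sh
gfabric simulate --fixture --seed 7 --out study/
gfabric run --config config.yaml            # fabric -> regulation ->
                                            # hierarchy/coordination ->
                                            # pathways -> recovery
gfabric hierarchy --expr study/NN.tsv --condition NN --top 20 --out h.tsv
```

`run` writes every report as TSV plus a `manifest.json` recording all
thresholds used. Input expression tables are TSV/CSV (header = replicate
labels, first column = gene or spot identifiers, optional two-column spot
map); gene sets are GMT.

## Scope

The package starts from positive, already array-normalized expression
tables. It does not download or reprocess public accessions, quantify
microarray images, or render pathway diagrams; and it deliberately applies
no multiple-testing correction to the per-gene and per-pair 0.05
criteria — the expected false-positive count is logged instead (see
`docs/methods.md`).
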