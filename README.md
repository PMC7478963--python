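# subclonekit

Deconvolution of tumor subclones from a **single bulk-sequenced sample**.
Given somatic SNV read counts and an allele-specific copy-number profile,
`subclonekit` infers:

* **tumor purity** — the fraction of tumor cells in the sample,
* the **number of subclones** and each subclone's **cellular prevalence**,
* a **probabilistic assignment of every SNV to a subclone**, and
* candidate **phylogenies** over the subclones, ranked.

It is aimed at cancer-genomics analysts who have somatic variant calls
(e.g. MuTect-style) and Battenberg-like allele-specific copy-number segments
for one tumor sample and want fast, deterministic subclonal reconstruction —
including on regions where copy-number events occurred independently in
different subclones ("multistate" segments). The package also ships a
forward-model tumor simulator and SMC-Het-style scoring metrics, so the whole
stack is verifiable by parameter recovery.

## Model

For an SNV carried by `m` allele copies in a fraction ρ of cells, the expected
variant allele frequency β depends on the copy-number context
(N<sub>major</sub>, N<sub>minor</sub>) and the SNV/CNA timing:

| context | β(ρ) |
|---|---|
| diploid, no CNA | ρ / 2 |
| diploid, SNV before/during CNA | m·ρ / ((N<sub>maj</sub>+N<sub>min</sub>)ρ + 2(1−ρ)) |
| diploid, SNV after CNA | ρ / ((N<sub>maj</sub>+N<sub>min</sub>)ρ + 2(1−ρ)) |
| male X/Y, with CNA | m·ρ / (N<sub>maj</sub>ρ + (1−ρ)) |

Since the event ordering is unobserved, every scenario is inverted and
candidates with ρ > 1 are discarded as impossible. The pooled candidate
prevalences are smoothed with a Gaussian kernel density estimate (Scott's
rule bandwidth, grid resolution 0.001, Nelder–Mead peak refinement); each
density mode is a subclone and the largest mode is the purity. SNVs are then
assigned by binomial likelihood `L_jk = max Binom(m_k; r_k, β̂_jk)` over the
admissible expected frequencies of each subclone, with mixture weights fitted
by EM on `λ = Σ_k ln Σ_j w_j L_jk`. Finally all subclone trees compatible
with the prevalence ordering and sum constraints are enumerated and ranked.

## Worked example

```sh
subclonekit simulate --seed 11 --config sim.cfg --out tumor/   # sim.cfg: n_subclones = 2, purity = 0.8, min_prevalence_gap = 0.3
subclonekit infer --snv tumor/snv.tsv --cna tumor/cna.tsv --out pred/
subclonekit score --truth tumor/truth --pred pred/
```

The `infer` step prints (2000 SNVs, 100× depth, two clones at 0.80/0.10):

```
purity	0.801923
subclones	2
peaks	0.801923	0.10409
```

meaning 80.2% of cells are tumor cells, all tumor cells share the clonal
mutations (prevalence 0.80) and a nested subclone covering 10% of cells
carries its own private mutations. `pred/` holds the five challenge-layout
files (`1A.txt` purity, `1B.txt` clone count, `1C.txt` per-cluster size and
prevalence, `2A.txt` per-SNV cluster, `3A.txt` parent list, `0` = normal
root). `score` compares against the simulator's truth:

```
purity_score	0.998077
nclone_score	1
proportion_score	0.992321
coclustering_score	0.973771
ancestry_score	0.981061
```

Each score is 1 for a perfect call: one minus the purity error; the relative
clone-count error; one minus the mean per-SNV prevalence error; and Pearson
correlations of the SNV co-clustering (`PPᵀ`) and ancestry (`PAPᵀ`) matrices.

The same pipeline is available as a library:

```python
from subclonekit import SimulationConfig, simulate_tumor, run_inference_records

tumor = simulate_tumor(SimulationConfig(n_subclones=2, purity=0.8, seed=11))
result = run_inference_records(tumor.snvs, tumor.segments)
result.model.peaks, result.model.purity, result.best_tree.parent
```

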