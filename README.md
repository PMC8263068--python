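# grslogic

Inference and identifiability analysis of **gene regulatory strategies
(GRSs)** — the combinatorial AND/OR logic by which a gene decodes the
activities of up to three stimulus-induced transcription factors (TFs) —
from stimulus-response timecourse data such as chromatin-associated
RNA-seq of macrophage immune-response genes.

The package is aimed at systems biologists who measure TF activities and
nascent transcription under perturbation panels (knockouts, knockdowns,
dose or timing modulation) and want to know (i) which regulatory logics
their data can in principle distinguish, (ii) how much of the observed
replicate variance is value noise versus timing noise, and (iii) which
logic gate and regulation strengths best explain each gene.

## The model

Nascent mRNA of a gene follows a single linear ODE,

```
dRNA/dt = k_syn · f(t) − k_proc · RNA
f(t)    = (1 − k0) · G(TF1(t), TF2(t), TF3(t)) + k0
```

where `k_syn` is the maximal synthesis rate (RPKM/min), `k_proc` the
processing/chromatin-release rate (1/min), `k0` the basal promoter
activity, and `G ∈ [0, 1]` a thermodynamic logic gate built from
non-cooperative Hill occupancies `h_i = TF_i / (K_d,i + TF_i)`:
AND gates multiply occupancies (`h1·h2·h3`), OR gates take complements
(`1 − (1−h1)(1−h2)(1−h3)`), and the four mixed forms combine both. The 8
triple-TF gates represent all 17 single/dual/triple logics once a null
regulation strength (`K_d ≫ 1`) is allowed for one or two TFs.
Regulation strengths Strong/Medium/Weak correspond to `K_d` = 0.1/1/10
in normalized TF-activity units.

On top of the forward model the package provides:

* **Catalog enumeration** — 8 logics × 27 strength triples = 216
  representative GRSs, reduced to 93 unique, activatable strategies by an
  activatability filter (threshold 1.66 RPKM at full stimulation) and
  logical-equivalence deduplication;
* **Distinguishability analysis** — squared-Euclidean distances between
  normalized panel responses, single/average/complete-linkage trees, and
  cluster counts versus separation threshold;
* **A time–value error model** — per-point variance
  `σ² = α0 + α1·μ + α2·μ² + Slope²·σ_t²` with a mode-matched gamma
  background branch below η = 3 RPKM, pooled maximum-likelihood fitting,
  N/(N−1) bias correction and empirical-Bayes per-point shrinkage;
* **Bayesian model selection** — bounded multi-start L-BFGS-B fitting of
  all 8 gates in log10 parameter space, likelihood-based selection, and
  the 8 → 17 logic mapping via null strengths (`K_d` at the bound 100);
* **Experimental-design evaluation** — log2 likelihood-ratio
  identifiability of every catalog GRS under candidate
  (conditions × replicates) budgets;
* **A measured-data workflow** — TF-activity scaling and cross-condition
  normalization, MAPK-activity inference from immediate-early genes,
  induced-gene selection, basal-offset fitting and NLL-threshold logic
  calls with an NFκB–IRF synergy flag.

## A worked example

`examples/04_fit_single_gene.py` simulates two replicates of a known GRS
("TF1 AND (TF2 OR TF3)", strengths S,M,M) under the 26 amplitude
perturbations, fits the error model and all 8 gates, and prints:

```
NLL per logic gate (lower fits better):
  TF1.(TF2+TF3)         492.3 <- selected
  TF1+(TF2.TF3)        1003.5
  TF1+TF2+TF3          1007.2
  ...
selected logic : TF1.(TF2+TF3)
17-logic label : TF1.(TF2+TF3)
fitted Kd      : [0.056 0.898 0.945]  (truth (0.1, 1.0, 1.0))
```

The correct gate wins by ~500 NLL units and the medium strengths are
recovered within a few percent; the strong `K_d` is recovered within
2-fold, the resolution limit set by duplicate noisy data. The other
examples cover simulation (`01`), catalog distinguishability (`02`), the
error-model benchmark (`03`) and the design study (`05`); each prints a
short interpretation of its numbers. A thin CLI (`grslogic enumerate`,
`noisify`, `estimate-error`, `fit`, `call`, `design`, `fixtures`) wraps
the same functions for shell use.

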