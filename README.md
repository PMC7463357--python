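# glocerna

Identification of functional lncRNA-mediated competing-endogenous-RNA
(ceRNA) pairs from matched normal/tumor expression cohorts, for
transcriptomics researchers studying miRNA-sponge regulation in cancer.

## The method

A lncRNA *l* and a protein-coding gene (PCG) *g* that share miRNA target
sites compete for the same miRNA pool, so their expression should move
together. Given *n* normal/tumor (N/T) matched patients, the per-patient
relative expression of gene *x* in patient *i* is the log2 fold change

    e_x^i = log2(tumor_x^i) - log2(normal_x^i)

and each candidate pair — a lncRNA and a PCG targeted by at least one
common miRNA — is scored by two direction-consistency criteria:

* **Local (DEC score).** Per patient,
  `dec_i(l,g) = +1` if `e_l^i > 1` and `e_g^i > 1`,
  `-1` if `e_l^i < -1` and `e_g^i < -1`, else `0`;
  `DEC(l,g) = Σ_i |dec_i(l,g)|` counts patients in which the pair moves
  concordantly beyond 2-fold. This captures ceRNA coupling that appears
  in only a subset of patients (tumor heterogeneity).
* **Global (correlation).** `cor(l,g)` is the Pearson correlation of
  `(e_l, e_g)` across patients, with p-value from
  `t = cor·sqrt((n-2)/(1-cor²))` on *n − 2* degrees of freedom.

A pair is a **functional ceRNA** iff `DEC > 5` and `cor > 0` and
`p < 0.05` (all strict); the lncRNAs of functional pairs are the
**ce-lncRNAs**. Downstream analytics cover the bipartite ceRNA network
(degree, unnormalized betweenness, lncRNA similarity, cross-cohort
overlap), hypergeometric cancer-hallmark enrichment, Kaplan–Meier /
log-rank survival screening at the mean-expression cutoff,
super-/typical-enhancer (SE/TE) gene assignment, and THZ1-sensitivity
classification with its ceRNA subnetwork. A synthetic-data module
generates every input with planted ground truth.

## Worked example

```sh
python examples/01_identify_cernas.py
```

```
cohort: 800 genes x 20 matched patients
candidate pairs sharing >= 1 miRNA: 1000
functional ceRNA pairs: 100  (ce-lncRNAs: 100)
planted pairs recovered: 100/100  false calls: 0

top pairs by DEC score:
lncrna_id  pcg_id  dec_score      cor      p_value
  LNC0019 PCG0343         20 0.953424 8.269836e-11
  LNC0043 PCG0246         20 0.961455 1.550718e-11
  LNC0051 PCG0414         20 0.929057 3.335540e-09
  LNC0100 PCG0299         20 0.972995 6.578656e-13
  LNC0102 PCG0124         20 0.962418 1.239175e-11
```

The simulated cohort plants 100 ceRNA pairs (4-fold mean effect) among
900 decoy pairs that share miRNAs but not expression; the scorer
recovers all 100 with no false calls. `dec_score = 20` means the pair
moved concordantly beyond 2-fold in every one of the 20 patients; `cor`
and `p_value` quantify the cohort-wide coupling of the two log2FC
profiles. The other `examples/` scripts demonstrate network topology,
hallmark enrichment, the survival screen, enhancer/THZ1 analysis and the
end-to-end pipeline; `glocerna --help` lists the equivalent shell
commands.

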