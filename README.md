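# refstab

Selection and validation of qRT-PCR reference (housekeeping) genes, built
around the workflow used for sugarcane (*Saccharum spontaneum*) female
gametophyte development: transcriptome-based candidate screening, standard-
curve efficiency estimation, stability ranking by **geNorm**, **NormFinder**
and **BestKeeper**, geometric-mean consensus ranking, and validation of
target genes against the chosen references.

It is aimed at molecular biologists who have (a) an RNA-seq expression
matrix (RPKM/FPKM per gene per condition) to shortlist candidates from and
(b) a qPCR Ct table (genes × samples, with condition/replicate metadata) to
rank them with.

## The statistics in brief

* **Screening** — candidate constancy is measured by the coefficient of
  variation CV = SD/mean of RPKM across stages (sample SD, n−1); genes with
  CV < 0.6 are kept and the top N by mean RPKM become qPCR candidates.
* **Efficiency** — a 10-fold dilution series gives the amplification
  efficiency E = 10^(−1/slope) − 1 from the OLS slope of Ct on log10 input.
* **Quantities** — raw Ct becomes a relative quantity
  Q = (1+E)^(−ΔCt), ΔCt = Ct − min Ct of that gene, so each gene's most
  abundant sample has Q = 1.
* **geNorm** — M_j = mean over partners k of SD_samples[log2(Q_j/Q_k)];
  stepwise exclusion of the highest-M gene leaves a tied most-stable pair.
  Pairwise variations V_n/n+1 = SD[log2(NF_n/NF_n+1)] of geometric-mean
  normalization factors decide how many references are needed (V < 0.15 ⇒
  n genes suffice).
* **NormFinder** — a two-way model of log quantities per stage group
  separates intragroup (replicate) variance from intergroup deviations,
  shrinks the latter empirical-Bayes style, and scores each gene by
  |bias| + uncertainty, averaged over groups.
* **BestKeeper** — descriptive statistics on raw Ct: SD, CV% = 100·SD/mean,
  and each gene's Pearson r with the per-sample geometric-mean index.
* **Consensus** — each method's scores are converted to dense ranks
  (ties share a rank: 1,1,2,3,…) and genes are ordered by the geometric
  mean of their three ranks.

## Worked example

Simulate a study-shaped dataset (five ovule stages × three replicates, four
planted stable and two planted unstable genes), then rank and validate:

```sh
refstab simulate --stable 4 --unstable 2 --seed 42 --out-dir demo
refstab consensus --ct demo/ct.tsv --meta demo/meta.tsv --out demo/report.tsv
```

```text
rank  genorm_gene  genorm_score  normfinder_gene  normfinder_score  bestkeeper_gene  bestkeeper_score  consensus_gene  geomean
1     STB01        0.16          STB01            0.26              STB01            0.39 +/- 0.12     STB01           1.00
2     STB04        0.16          STB03            0.28              STB03            0.66 +/- 0.12     STB03           2.00
3     STB03        0.18          STB04            0.30              STB04            0.46 +/- 0.13     STB04           2.08
4     STB02        0.23          STB02            0.31              STB02            0.57 +/- 0.16     STB02           3.63
5     UNS02        1.04          UNS02            0.71              UNS02            5.01 +/- 1.03     UNS02           4.64
6     UNS01        1.23          UNS01            0.94              UNS01            4.72 +/- 1.20     UNS01           5.65
# optimal_n  2
```

All four planted stable genes outrank both unstable ones under every
method; the tied geNorm pair (STB01/STB04, both M = 0.16) shares rank 1,
and the first pairwise variation is already below 0.15, so two reference
genes suffice (`optimal_n = 2`).

The same works from Python, e.g. reproducing the published consensus of the
sugarcane study from its per-method stability columns bundled with the
package:

```python
>>> from refstab.datasets import published_consensus
>>> cons = published_consensus()
>>> cons.order[:3]
['FAB2', 'MOR1', 'MCB1']
>>> round(cons.geomean["FAB2"], 2), round(cons.geomean["TUB6"], 2)
(2.0, 9.32)
```

FAB2 and MOR1 tie at geometric-mean rank 2.00 — the two optimal reference
genes for sugarcane female-gametophyte development.

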