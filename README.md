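# cerna-profiler

Transcriptomic analysis chain for finding long noncoding RNAs associated
with levodopa-induced dyskinesia (LID) in the rat 6-OHDA model of
Parkinson's disease — the ordered condition series **Sham → PD → NLID →
LID**. The package re-implements, as tested, reusable library code:

- **Model-profile clustering** of short expression series (STEM-style):
  every candidate shape over *T* ordered conditions starting at 0 with
  unit steps is enumerated — for *T* = 4 and step bound *c* = 1 that is
  3³ − 1 = **26 profiles** — each gene's log2-ratio series
  *sₜ = log₂((x̄ₜ + ε)/(x̄₀ + ε))* is assigned to its best-Pearson-correlated
  shape, and each profile's gene count is tested against the exhaustive
  4! = 24 condition-permutation null with an upper binomial tail.
  The monotone-decreasing shape (0, −1, −1, −2) is "Profile 3": genes
  falling from Sham to PD and again from NLID to LID.
- **Differential-expression screen**: |log₂FC| ≥ 1 and Benjamini–Hochberg
  FDR ≤ 0.05, with a built-in Welch-t p-value stand-in or externally
  supplied p-values; Fisher-exact (hypergeometric tail) term enrichment.
- **lncRNA candidate filter chain**: spliced length ≥ 200 nt, ≥ 2 exons,
  longest ORF ≤ 300 nt (built-in three-frame finder), CPC < 0,
  CNCI-style score < 0, no Pfam hit.
- **ceRNA network inference**: lncRNA×mRNA pairs at the 99th percentile
  (nearest-rank) of the Pearson-correlation pool, restricted to triplets
  where both members carry a perfect **6mer seed site** — the exact
  reverse complement of the shared miRNA's nucleotides 2–7.
- **Cis/trans target prediction**: genes within 10 kb up- or downstream
  of a lncRNA locus; a k-mer complementarity screen followed by an
  ungapped antisense duplex score for trans targets.
- **qPCR validation statistics**: 2^−ΔΔCt relative quantification
  (GAPDH-normalized, sham-calibrated) and Pearson correlation of
  expression with the AIM dyskinesia score.

Because the study's raw sequencing data are not deposited, the package
ships a **synthetic-data module** that generates all inputs with planted
ground truth (planted profile shapes, planted seed sites, planted
genomic neighborhoods), so every stage is verifiable end-to-end. The
Profile-3 gene lists printed in the study (135 mRNAs, 79 lncRNAs) are
packaged as fixtures.

## Worked example

Run the numbered analyses (each is a thin driver over the library;
outputs land under `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_profile_dynamics.py --seed 1
python analysis/05_networks_targets.py --seed 1
python analysis/06_qpcr_validation.py --seed 1
```

Output from the runs above:

```text
26 candidate model profiles for 4 ordered conditions
profiles with permutation p < 0.05: 1
decreasing profile (0, -1, -1, -2): 76 genes (expected 30.8 under the null, p = 1.91e-12)
planted-gene recall into that profile: 0.98

ceRNA network: 5 triplets; planted recovered 5/5, background 0
cis targets: 6 hits within 10 kb (planted 6/6, false 0)

relative expression of Nonratt023402-like (2^-ddCt, GAPDH-normalized, sham = 1):
   Sham: mean 1.002 (n = 11)
     PD: mean 0.522 (n = 11)
   NLID: mean 0.486 (n = 11)
    LID: mean 0.258 (n = 11)
LID group: Pearson r(Nonratt023402-like expression, AIM score) = -0.895, p = 0.000201, n = 11
```

Reading: of the 26 candidate shapes only the planted decreasing profile
is permutation-significant; 49 of the 50 planted genes land in it (the
76 assigned genes also include flat background genes whose noise best
matches that shape, as expected with 26 candidate shapes and no
similarity floor). The ceRNA stage recovers exactly the five planted
lncRNA–miRNA–mRNA triplets and nothing else, cis prediction recovers
exactly the six planted neighborhoods, and the qPCR stage reproduces the
planted ~1 : 0.5 : 0.5 : 0.25 expression ladder with a strong negative
expression–dyskinesia correlation across the 11 LID animals.

An equivalent single-call driver exists in the library:

```python
from cerna_profiler.pipeline import demo_config, run_pipeline
manifest = run_pipeline(demo_config(seed=1, out_dir="results/demo"))
```

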