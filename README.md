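# scrapseek

Cross-reactivity scoring and tumour-antigen discovery for MHC class I
immunopeptidomics.

Peptide-centric receptors (PC-CARs, affinity-enhanced TCRs) that target a
tumour peptide–HLA complex can cross-react fatally with near-identical
self-peptides presented on healthy tissue. `scrapseek` is a toolkit for the
computational side of making that risk visible before a receptor ever
reaches a cell: it ranks every peptide in the normal proteome by predicted
cross-reactivity against a query tumour pMHC, and it runs the discovery
funnel that nominates tumour-specific peptide targets from immunopeptidomics
data in the first place. It is written for computational immunologists and
immunotherapy groups who work with eluted-ligand mass spectrometry, HLA
binding predictions and tumour/normal expression data.

## The scoring model

A query tumour peptide is compared against every same-length window of the
normal proteome presented on the matched HLA allele. At each receptor-facing
position *i* (position 1 and positions 3…*n*−1; the MHC anchors P2 and the
C terminus are excluded), the residue pair is scored

* **5** — identical residues,
* **2** — different residues of the same chemical class
  (aliphatic-nonpolar, aromatic, polar-uncharged, positive, negative),
* **−2** — otherwise,

and the peptide score is ΣP = Σᵢ Pᵢ (range −14…35 for a 9-mer). Each normal
peptide then receives an overall cross-reactivity score

```
overall = ΣP / (b × E_max)
```

where *b* is its predicted binding affinity to the allele (IC50, nM) and
*E*\_max the maximum expression of its parent gene across normal tissues
(RPKM/FPKM). Candidates are ranked by overall score and flagged T/F
according to whether the peptide has been observed in an empirical
normal-tissue immunopeptidome. An alternative `expression_weighted`
orientation (ΣP × *E*\_max / *b*) is available and always recorded in the
report metadata; see `docs/methods.md` for why both exist.

The discovery funnel filters immunopeptidomics hits by predicted binding
(IC50 ≤ 500 nM), by tumour-specific expression (≥ 1 log2 fold over *every*
normal tissue at rank-sum *P* < 0.01), and by absence of the parent gene
from the benign-tissue ligandome, then ranks survivors by a composite of
expression, allele frequency, peptide abundance, binding and recurrence.
Supporting analyses include alanine-scan contact-residue calling, a
cross-HLA presentation scan, and MS1 matched-peptide search (m/z within a
ppm tolerance, retention time within a window).

Binding prediction itself is pluggable: any engine satisfying the
`BindingPredictor` contract (e.g. NetMHC-class tools run once and cached to
TSV) can be used; a deterministic toy predictor ships in
`scrapseek.synthetic` so the entire pipeline is testable offline.

## Worked example

Generate a synthetic fixture with a planted cross-reactive peptide —
an exact copy of the PHOX2B-derived query QYNPIRTTF inserted into a random
proteome with minimal IC50 (1 nM) and zero normal expression — then scan:

```sh
scrapseek synth --preset scan --seed 42 --out fix
scrapseek scan --query QYNPIRTTF --allele HLA-A24:02 \
    --index fix/index.tsv --ligandome fix/ligandome.tsv \
    --top 5 --out out
head -4 out/report.tsv
```

```
rank  peptide    genes    sum_p  b_nM      E_max    overall_score  in_normal_ligandome  self
1     QYNPIRTTF  PLANTED  35     1.0       0.0      3500.0         F                    T
2     WEEPAENSG  G0007    5      26.2935   7.3395   0.0259         F                    F
3     WTFIVRDNG  G0019    5      18.9614   18.5302  0.0142         F                    F
```

The planted peptide dominates: ΣP = 35 (identical at all seven scored
positions), minimal affinity denominator, and expression at the E_max floor
(0.01) give overall score 35/(1 × 0.01) = 3500, four orders of magnitude
above the best random 9-mer. The `self` flag marks it as an exact sequence
match to the query; the T/F column shows none of these peptides occur in
the (synthetic) normal ligandome. Every run also writes a `manifest.json`
capturing parameters, input digests and stage counts.

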