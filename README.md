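# nucpos

Sequence-based nucleosome positioning: predict which stretches of a
genome are wrapped around histone octamers, from DNA sequence alone.

Nucleosomes (147 bp of DNA around a histone core) and the linker DNA
between them shape the accessibility of eukaryotic genomes. Their
placement is partly encoded in the DNA itself: A/T-rich tracts resist
wrapping while G/C-enriched, periodically patterned sequence favours it.
`nucpos` implements a compact model of that signal for researchers in
chromatin biology and regulatory genomics:

1. **Positioning features.** A sequence and its reverse complement are
   reduced to the W/S alphabet (W = A/T, S = C/G; complementation is the
   identity on W/S). For each of the eight W/S trinucleotides *m* the
   duplex yields a conditional motif probability
   `p_m = N_m / N_X` (X the majority letter of *m*), and the feature
   vector is

   `S(j) = c_j · (147 / (L − 2)) · (1 − p^q − (1−p)^q) / (q − 1)`,  j = 1…8,

   a length-standardised binary **Tsallis entropy** (entropic index
   `q`, default 2) weighted by the conservation coefficient `c_j`
   (1 for W/S-palindromic trimers, whose strand distribution determines
   the complementary strand; 2 otherwise). Duplex counting makes the
   vector exactly strand-invariant and forces `S(2)=S(4)`, `S(6)=S(8)`.
2. **Classification.** An RBF-kernel SVM separates nucleosomal from
   linker sequences in this 8-D space, evaluated by stratified 5-fold
   cross-validation with Accuracy, Sensitivity, Precision, MCC and
   ROC/AUC.
3. **Occupancy.** Geometric centers of the highest- and lowest-scoring
   training fragments define a relative distance
   `d(x) = ‖x−c_neg‖ / (‖x−c_pos‖ + ‖x−c_neg‖)`; every 147-bp window of
   a chromosome is scored, the track is range-normalised, and the
   per-basepair occupancy `P(i)` is the mean score of all windows
   covering basepair *i*.
4. **Peak calling.** Profile maxima become isolated nucleosome calls:
   peaks closer than 147 bp lose the smaller member, peaks below the
   0.5 random level are dropped, survivors span center ± 73 bp.
5. **Map comparison.** Binary coverage maps, per-basepair positional
   accuracy, Pearson map correlation, linker-length distributions and
   within-X-nt center overlap fractions.

A seeded synthetic-data module generates nucleosome-like (G+C-elevated,
~10-bp WW/SS periodicity), linker-like (A/T-rich, variable length)
sequences, scored 50-bp fragment pools and toy genomes with planted
nucleosomes, so the whole stack is testable without downloads.

## Worked example

```python
import numpy as np
from nucpos import (SyntheticSpec, gen_nucleosomal_like, gen_linker_like,
                    feature_matrix, LabeledDataset, cross_validate,
                    positioning_feature_vector)

fv = positioning_feature_vector("ACGTTGCAATAT" * 12)
print(np.round(fv.s, 4))

spec = SyntheticSpec(seed=7)
nuc, link = gen_nucleosomal_like(spec), gen_linker_like(spec)
X = np.vstack([feature_matrix(nuc), feature_matrix(link)])
y = np.array([1] * 200 + [-1] * 200)
rep = cross_validate(LabeledDataset(X, y, [d.id for d in nuc + link]), seed=7)
print(f"pooled AUC {rep.pooled_auc:.4f}  accuracy {rep.pooled_metrics['accuracy']:.4f}")
```

prints

```
[0.5174 0.7655 0.     0.7655 0.     1.0352 0.     1.0352]
pooled AUC 1.0000  accuracy 0.9950
```

The first line is the 8-component feature vector of one 144-bp duplex —
note the exact `S(2)=S(4)` and `S(6)=S(8)` pairing. The second line is
the cross-validated separation of 200 nucleosome-like from 200
linker-like synthetic sequences: essentially perfect, because the
generated classes differ strongly in G+C and motif order.

The same stages run from the shell:

```sh
nucpos simulate --preset benchmark --seed 7 --out sim/
nucpos cv --pos sim/nucleosomal.fa --neg sim/linker.fa --seed 7 --out report/
nucpos simulate --preset genome --seed 11 --out sim/
nucpos simulate --preset fragments --seed 11 --out sim/
nucpos occupancy --genome sim/toy_genome.fa --train sim/fragments.tsv --out toy.wig
nucpos callpeaks --profile toy.wig --out calls.bed
nucpos compare --pred calls.bed --ref sim/planted.bed --length 50000 --out cmp.json
```

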