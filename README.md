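# sigrefit

Signature *refitting* for cancer genomes: estimate how much each known
mutational signature contributed to the somatic mutations observed in a
single tumor sample, and how stable that estimate is.

Somatic mutational processes (UV light, tobacco smoke, defective mismatch
repair, ...) each leave a characteristic pattern over the 96 single-base
substitution channels — a substitution (pyrimidine-centered: C>A, C>G, C>T,
T>A, T>C, T>G) together with its 5′ and 3′ flanking bases, e.g. `T[C>T]A`.
Given a sample's **mutational catalogue** `m` (its vector of 96 channel
frequencies) and a matrix `P` of known signature profiles (96 × N,
column-stochastic, e.g. COSMIC), sigrefit solves the constrained
least-squares problem

    e = argmin ‖m − P e‖₂   subject to  e ≥ 0  (and Σₙ eₙ = 1 by default)

so the exposure vector `e` reports each signature's share of the mutational
load. Around this core the package provides:

- **catalogue construction** from a somatic VCF plus an indexed reference
  FASTA, with strand collapse (purine-reference records are mapped onto the
  pyrimidine strand by reverse complement) and auditable per-reason skip
  counts;
- **bootstrap stability**: resample the catalogue with replacement (R = 1000
  by default), refit every resample, and report min / quartiles / max of each
  signature's exposure — wide intervals flag exposures that are artifacts of
  catalogue noise;
- **trinucleotide normalization**: count the 32 strand-collapsed
  trinucleotide contexts of a genome or a BED-defined exome capture, and
  re-express a catalogue (or the signature matrix) on a common baseline —
  required whenever exome-derived catalogues are fitted against
  genome-calibrated signatures;
- **simulation**: draw catalogues from known signature mixtures or from
  signal-free context availability ("null" catalogues), and measure refit
  accuracy as a function of mutation count;
- **redundancy diagnostics**: pairwise cosine similarity between signatures
  and leave-one-out reconstruction similarity, which identify signatures
  whose exposures are intrinsically unstable because other signatures can
  mimic them.

Exposure estimation needs a few hundred mutations to be reliable; the
package warns whenever a catalogue holds fewer than 125.

## Worked example

Every step is available both as a library call and a subcommand. Using the
built-in, fully hand-tallied toy fixtures:

```sh
sigrefit fixtures --out-dir fx
sigrefit catalogue --vcf fx/toy.vcf --ref fx/toy.fa --out m.tsv
```

```
accepted records: 4
skipped (non_snv): 1
skipped (multiallelic): 1
skipped (non_pass): 0
skipped (ambiguous_context): 2
```

Four biallelic SNVs pass the filters and land in four channels (one of them,
a `G>T` on the reference strand, is strand-collapsed into `C[C>A]T`); an
insertion, a multiallelic record and two records without a clean
trinucleotide context are skipped and accounted for.

Simulate three catalogues of 1000 mutations from a 70/30 mixture of the two
toy signatures, then refit:

```sh
printf 'Toy A\t0.7\nToy B\t0.3\n' > w.tsv
sigrefit simulate --signatures fx/toy_signatures.tsv --weights w.tsv \
        --n 1000 --samples 3 --seed 7 --out sim.tsv
sigrefit fit --catalogue sim.tsv --signatures fx/toy_signatures.tsv \
        --out exposures.tsv
```

```
sim1: Toy A: 68.50%, Toy B: 31.50%
sim2: Toy A: 71.90%, Toy B: 28.10%
sim3: Toy A: 71.70%, Toy B: 28.30%
```

The refit recovers the 70/30 truth up to multinomial sampling noise. How
much of that noise propagates into the estimate is quantified by
bootstrapping the first sample 1000 times:

```sh
sigrefit bootstrap --catalogue sim.tsv --signatures fx/toy_signatures.tsv \
        -R 1000 --seed 7 --out boot.tsv
```

| Signature | original | min | q1 | median | q3 | max |
|-----------|---------:|------:|------:|-------:|------:|------:|
| Toy A | 0.685 | 0.632 | 0.677 | 0.686 | 0.696 | 0.743 |
| Toy B | 0.315 | 0.257 | 0.304 | 0.314 | 0.323 | 0.368 |

The true weight (0.70) lies inside the bootstrap range; the interquartile
range (~±0.01) is the resolution this catalogue size supports. With the same
machinery, `sigrefit context-freq` + `sigrefit normalize` move catalogues or
signature matrices between genome and exome baselines, and
`sigrefit similarity` writes the redundancy diagnostics.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the package end to end on synthetic data with known truth — simulate a
five-signature mixture, refit it, bootstrap one sample, exercise the
normalization round trip, and trace the refit error over catalogue sizes —
printing each intermediate result, and writes the results JSON to `--out`.
All randomness derives from `--seed`.
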