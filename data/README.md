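# Reference data (not bundled)

This directory is the expected home of third-party reference files that
cannot be redistributed here and must be obtained once by the user. The
test suite's published-value checks in `tests/test_acceptance.py` look for
them at these exact names and fail with a pointer to this file when they are
absent.

- `cosmic_signatures_v2.tsv` — the COSMIC v2 signature matrix (30 signatures
  x 96 channels) in the original export layout ("Substitution Type",
  "Trinucleotide", "Somatic Mutation Type" columns followed by one column
  per signature). Source: the COSMIC "Signatures of Mutational Processes in
  Human Cancer" v2 download (cancer.sanger.ac.uk/cosmic/signatures_v2).
- `patient_catalogues.tsv` — published 96-channel mutational catalogues of
  13 colorectal tumor exome samples from 3 patients (a catalogue TSV, one
  column per sample; per-sample totals between 481 and 756 somatic SNVs).
- `trinucleotide_counts.tsv` — 32-row table of strand-collapsed
  trinucleotide counts with columns `Context`, `Genome` (GRCh37 whole
  genome) and `Exome` (Agilent SureSelect XT Human All Exon V4 capture
  regions). The exome column can be regenerated with
  `sigrefit context-freq --ref GRCh37.fa --bed capture_regions.bed`; the
  genome column likewise without `--bed`.

No file in this directory is required for the library itself; all other
tests run on synthetic and hand-computed fixtures.
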