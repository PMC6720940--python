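"""Deterministic toy fixtures with hand-computed expected values.

The fixture set is tiny and fully worked out by hand, so tests (and users
exploring the tool) can check every pipeline step against known numbers.

chr1 = ATCAcGGAGGCATNAC (1-based positions; position 5 is soft-masked):

    pos:  1  2  3  4  5  6  7  8  9 10 11 12 13 14 15 16
    base: A  T  C  A  c  G  G  A  G  G  C  A  T  N  A  C

The toy VCF exercises every filter path:

    pos  1  A>C    no 5' flank                -> skipped (ambiguous_context)
    pos  3  C>T    context TCA                -> T[C>T]A
    pos  3  C>T,G  multiallelic               -> skipped
    pos  5  C>A    context ACG (soft-masked)  -> A[C>A]G
    pos  5  C>CA   insertion                  -> skipped (non_snv)
    pos  9  G>T    context AGG -> revcomp CCT -> C[C>A]T (strand collapse)
    pos 11  C>G    context GCA, FILTER=q10    -> G[C>G]A (dropped if pass-only)
    pos 13  T>A    context ATN                -> skipped (ambiguous_context)

Default policy accepts 4 records; with require_pass, 3.

chr2 = ACGTACGT carries the worked trinucleotide-counting example: its six
3-mers collapse to {ACG: 4, GTA: 2}. Restricted to BED interval chr2:[1, 4),
the central bases inside the region are positions 1, 2, 3, whose 3-mers
ACG, CGT, GTA collapse to {ACG: 2, GTA: 1} (flanks may extend one base past
the region edge).
"""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["make_fixtures", "EXPECTED"]

_CHR1 = "ATCAcGGAGGCATNAC"
_CHR2 = "ACGTACGT"

_FASTA = f">chr1\n{_CHR1}\n>chr2\n{_CHR2}\n"

_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=q10,Description="Quality below 10">
##contig=<ID=chr1,length=16>
##contig=<ID=chr2,length=8>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t1\t.\tA\tC\t.\tPASS\t.
chr1\t3\t.\tC\tT\t.\tPASS\t.
chr1\t3\t.\tC\tT,G\t.\tPASS\t.
chr1\t5\t.\tC\tA\t.\tPASS\t.
chr1\t5\t.\tC\tCA\t.\tPASS\t.
chr1\t9\t.\tG\tT\t.\tPASS\t.
chr1\t11\t.\tC\tG\t.\tq10\t.
chr1\t13\t.\tT\tA\t.\tPASS\t.
"""

_BED = "chr2\t1\t4\n"

#: hand-computed expectations for the fixture set
EXPECTED = {
    "vcf_default": {
        "total": 4,
        "channels": {"T[C>T]A": 1, "A[C>A]G": 1, "C[C>A]T": 1, "G[C>G]A": 1},
        "skipped": {
            "non_snv": 1,
            "multiallelic": 1,
            "non_pass": 0,
            "ambiguous_context": 2,
        },
    },
    "vcf_pass_only": {
        "total": 3,
        "channels": {"T[C>T]A": 1, "A[C>A]G": 1, "C[C>A]T": 1},
        "skipped": {
            "non_snv": 1,
            "multiallelic": 1,
            "non_pass": 1,
            "ambiguous_context": 2,
        },
    },
    "chr2_contexts": {"ACG": 4, "GTA": 2},
    "chr2_bed_contexts": {"ACG": 2, "GTA": 1},
}


def _toy_signature_tables() -> tuple[str, str]:
    """A 2-signature toy matrix in plain and COSMIC v2 dialects.

    "Toy A" is uniform over the 16 C>A channels, "Toy B" uniform over the 16
    T>G channels: disjoint support, hence orthogonal.
    """
    from .channels import CHANNELS

    plain_lines = ["Type\tToy A\tToy B"]
    cosmic_lines = ["Substitution Type\tTrinucleotide\tSomatic Mutation Type\tToy A\tToy B"]
    for ch in CHANNELS:
        a = 1.0 / 16 if ch.substitution == "C>A" else 0.0
        b = 1.0 / 16 if ch.substitution == "T>G" else 0.0
        plain_lines.append(f"{ch.label}\t{a}\t{b}")
        cosmic_lines.append(f"{ch.substitution}\t{ch.context}\t{ch.label}\t{a}\t{b}")
    return "\n".join(plain_lines) + "\n", "\n".join(cosmic_lines) + "\n"


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture set into ``out_dir``; returns {name: path}.

    Regeneration is idempotent: contents are fixed strings. A manifest of
    the hand-computed expected values is written alongside the data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plain_sig, cosmic_sig = _toy_signature_tables()
    files = {
        "fasta": (out_dir / "toy.fa", _FASTA),
        "vcf": (out_dir / "toy.vcf", _VCF),
        "bed": (out_dir / "toy.bed", _BED),
        "signatures_plain": (out_dir / "toy_signatures.tsv", plain_sig),
        "signatures_cosmic_v2": (out_dir / "toy_signatures_cosmic_v2.tsv", cosmic_sig),
        "manifest": (
            out_dir / "manifest.json",
            json.dumps(EXPECTED, indent=2, sort_keys=True) + "\n",
        ),
    }
    out = {}
    for name, (path, content) in files.items():
        path.write_text(content)
        out[name] = path
    # drop a stale faidx index if the FASTA changed underneath it
    fai = out_dir / "toy.fa.fai"
    if fai.exists():
        fai.unlink()
    return out
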