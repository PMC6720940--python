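"""Trinucleotide context frequencies and baseline normalization.

Published signature matrices refer to the trinucleotide composition of a
particular sequence baseline (COSMIC: the GRCh37 whole genome). A catalogue
observed on a different baseline — typically exome capture regions — sees each
context in proportion to its local availability, so catalogue and signatures
must be put on a common baseline before exposures are estimated.

Expected channel counts are proportional to context availability, so to
express data observed on baseline A at baseline B each channel k with context
c(k) is multiplied by f_B(c(k)) / f_A(c(k)) and the result renormalized. The
same per-channel scaling, applied column-wise, moves a signature matrix
between baselines (the inverse ratio moves it the other way). An
``invert_ratios`` flag is provided for comparison with the opposite
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from .catalogue_io import MutationalCatalogue, SignatureMatrix
from .channels import (
    BASES,
    CHANNEL_CONTEXT_INDEX,
    CONTEXTS_32,
    N_CONTEXTS,
)

__all__ = [
    "TrinucleotideFrequencies",
    "RegionSet",
    "read_bed",
    "count_trinucleotides",
    "read_context_table",
    "write_context_table",
    "normalize_catalogue",
    "normalize_signatures",
]

_CONTEXT_POS = {ctx: i for i, ctx in enumerate(CONTEXTS_32)}

# channel -> context incidence, used to broadcast 32 context ratios onto the
# 96 channels (three substitution classes share each context)
_CHANNEL_CONTEXT = np.asarray(CHANNEL_CONTEXT_INDEX)


@dataclass
class TrinucleotideFrequencies:
    """Strand-collapsed counts of the 32 pyrimidine-centered trinucleotides.

    Counts aggregate each 3-mer with its reverse complement, so every key has
    a central C or T. ``frequencies`` are the counts divided by their total.
    """

    counts: np.ndarray
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CONTEXTS,):
            raise ValueError(
                f"expected {N_CONTEXTS} context counts, got shape {self.counts.shape}"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("context counts must be finite and >= 0")

    @classmethod
    def from_dict(
        cls, counts: dict[str, float], source_label: str = "unspecified"
    ) -> "TrinucleotideFrequencies":
        """Build from a {context: count} mapping; absent contexts count 0."""
        vec = np.zeros(N_CONTEXTS)
        for ctx, value in counts.items():
            key = ctx.upper()
            if key not in _CONTEXT_POS:
                raise KeyError(
                    f"{ctx!r} is not a pyrimidine-centered trinucleotide context"
                )
            vec[_CONTEXT_POS[key]] = value
        return cls(vec, source_label)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros(N_CONTEXTS)
        return self.counts / total

    def __getitem__(self, context: str) -> float:
        return float(self.counts[_CONTEXT_POS[context.upper()]])

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXTS_32), name="Count")


@dataclass
class RegionSet:
    """Genomic intervals in 0-based half-open coordinates.

    Overlapping or adjacent intervals on the same chromosome are merged
    before use so overlapping capture targets are not double counted.
    """

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(
                    f"invalid interval {chrom}:{start}-{end}: need 0 <= start < end"
                )

    def merged(self) -> dict[str, list[tuple[int, int]]]:
        """Per-chromosome sorted, merged interval lists."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for start, end in ivs[1:]:
                if start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            out[chrom] = [(s, e) for s, e in merged]
        return out


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED file (first three columns; 0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line: {line!r}")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    if not intervals:
        raise ValueError(f"{path}: BED file contains no intervals")
    return RegionSet(intervals)


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

# 3-mer integer code -> collapsed context position, or -1 for invalid
_COLLAPSE = np.full(64, -1, dtype=np.int64)
for _f in range(4):
    for _c in range(4):
        for _t in range(4):
            _tri = BASES[_f] + BASES[_c] + BASES[_t]
            _collapsed = _tri if _tri[1] in "CT" else _tri.translate(
                str.maketrans("ACGT", "TGCA")
            )[::-1]
            _COLLAPSE[_f * 16 + _c * 4 + _t] = _CONTEXT_POS[_collapsed]


def _count_in_sequence(seq: str, start: int | None = None, end: int | None = None) -> np.ndarray:
    """Collapsed 3-mer counts for central positions in [start, end).

    A 3-mer is attributed to its central base; flanks may extend one base
    beyond the requested window into the sequence. Windows containing a
    non-ACGT letter are ignored.
    """
    n = len(seq)
    counts = np.zeros(N_CONTEXTS)
    lo = 1 if start is None else max(start, 1)
    hi = (n - 1) if end is None else min(end, n - 1)
    if hi <= lo:
        return counts
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    window = codes[lo - 1 : hi + 1]
    five, mid, three = window[:-2], window[1:-1], window[2:]
    valid = (five < 4) & (mid < 4) & (three < 4)
    if not valid.any():
        return counts
    tri_codes = five[valid] * 16 + mid[valid] * 4 + three[valid]
    np.add.at(counts, _COLLAPSE[tri_codes], 1)
    return counts


def count_trinucleotides(
    reference: str | Path | pyfaidx.Fasta,
    regions: RegionSet | None = None,
    source_label: str | None = None,
) -> TrinucleotideFrequencies:
    """Count strand-collapsed trinucleotides in a genome or region set.

    Every position whose central base lies inside a (merged) region and whose
    two flanking bases exist and are A/C/G/T contributes one count;
    purine-centered 3-mers count toward their reverse complement. With no
    regions the whole of every sequence is counted.
    """
    if isinstance(reference, (str, Path)):
        label = source_label or str(reference)
        reference = pyfaidx.Fasta(str(reference))
    else:
        label = source_label or "FASTA"
    counts = np.zeros(N_CONTEXTS)
    if regions is None:
        for name in reference.keys():
            counts += _count_in_sequence(str(reference[name][:]))
    else:
        merged = regions.merged()
        if not merged:
            raise ValueError("empty region set")
        for chrom, ivs in merged.items():
            if chrom not in reference:
                raise ValueError(f"region chromosome {chrom!r} absent from reference")
            seq = str(reference[chrom][:])
            for start, end in ivs:
                counts += _count_in_sequence(seq, start, end)
    if counts.sum() == 0:
        warnings.warn(
            f"{label}: no valid trinucleotide contexts found", stacklevel=2
        )
    return TrinucleotideFrequencies(counts, label)


def read_context_table(path: str | Path, column: str | None = None) -> TrinucleotideFrequencies:
    """Read a 32-row trinucleotide count TSV (columns: Context, Count, ...).

    ``column`` selects a count column when several baselines share a table;
    defaults to the first non-context column.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    ctx_col = next(
        (c for c in df.columns if c.lower() in ("context", "cotext", "trinucleotide")),
        df.columns[0],
    )
    df = df.set_index(ctx_col)
    if column is None:
        column = df.columns[0]
    elif column not in df.columns:
        raise KeyError(f"{path}: no column {column!r} (have {list(df.columns)})")
    counts = {str(ctx): float(v) for ctx, v in df[column].items()}
    if len(counts) != N_CONTEXTS:
        raise ValueError(f"{path}: expected {N_CONTEXTS} context rows, got {len(counts)}")
    return TrinucleotideFrequencies.from_dict(counts, f"{path}:{column}")


def write_context_table(f: TrinucleotideFrequencies, path: str | Path) -> None:
    f.to_series().to_csv(path, sep="\t", index_label="Context")


def _channel_ratios(
    f_source: TrinucleotideFrequencies,
    f_target: TrinucleotideFrequencies,
    support: np.ndarray,
    invert_ratios: bool,
) -> np.ndarray:
    """Per-channel multipliers f_target/f_source on the 96 channels.

    ``support`` flags channels with nonzero data; a zero source frequency is
    an error only where data are present (0 * anything stays 0 elsewhere).
    """
    if f_source.total <= 0 or f_target.total <= 0:
        raise ValueError("context frequency tables must have positive totals")
    src = f_source.frequencies[_CHANNEL_CONTEXT]
    tgt = f_target.frequencies[_CHANNEL_CONTEXT]
    if invert_ratios:
        src, tgt = tgt, src
    bad = support & (src == 0)
    if bad.any():
        names = sorted({CONTEXTS_32[i] for i in _CHANNEL_CONTEXT[bad]})
        raise ValueError(
            "zero source frequency for context(s) with observed data: "
            + ", ".join(names)
        )
    ratios = np.zeros(96)
    ok = src > 0
    ratios[ok] = tgt[ok] / src[ok]
    return ratios


def normalize_catalogue(
    m: MutationalCatalogue,
    f_source: TrinucleotideFrequencies,
    f_target: TrinucleotideFrequencies,
    invert_ratios: bool = False,
) -> MutationalCatalogue:
    """Re-express a catalogue observed on baseline ``f_source`` at ``f_target``.

    Channel k is scaled by f_target(c(k)) / f_source(c(k)) and the result is
    renormalized to frequencies. Channels sharing a context share one ratio.
    """
    ratios = _channel_ratios(f_source, f_target, m.values > 0, invert_ratios)
    scaled = m.values * ratios
    total = scaled.sum()
    if total > 0:
        scaled = scaled / total
    provenance = dict(m.provenance)
    provenance["normalized"] = {
        "from": f_source.source_label,
        "to": f_target.source_label,
        "invert_ratios": invert_ratios,
    }
    return MutationalCatalogue(m.sample_id, scaled, "frequencies", provenance)


def normalize_signatures(
    P: SignatureMatrix,
    f_source: TrinucleotideFrequencies,
    f_target: TrinucleotideFrequencies,
    invert_ratios: bool = False,
) -> SignatureMatrix:
    """Re-express every signature column at baseline ``f_target``.

    The same per-channel scaling as for catalogues is applied to each column
    independently, and each column is renormalized to sum 1.
    """
    support = (P.matrix > 0).any(axis=1)
    ratios = _channel_ratios(f_source, f_target, support, invert_ratios)
    scaled = P.matrix * ratios[:, None]
    sums = scaled.sum(axis=0)
    if np.any(sums <= 0):
        bad = [n for n, s in zip(P.names, sums) if s <= 0]
        raise ValueError(f"normalization annihilated signature(s): {', '.join(bad)}")
    scaled = scaled / sums
    return SignatureMatrix(list(P.names), scaled, f_target.source_label)
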