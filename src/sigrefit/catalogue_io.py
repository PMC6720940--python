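"""Mutational catalogues and signature matrices: containers and file I/O.

A mutational catalogue is a per-sample vector of counts (or frequencies) over
the 96 pyrimidine-centered substitution channels. A signature matrix is a
96 x N column-stochastic matrix whose column n gives the probability of each
channel under mutational process n (the COSMIC convention).

Catalogue tables are plain TSV: a header row of sample ids, a first column of
channel labels such as ``A[C>A]A``, one column per sample. Signature matrices
are read in three dialects: the COSMIC v2 export ("Substitution Type" /
"Trinucleotide" / "Somatic Mutation Type" columns followed by one column per
signature), the COSMIC v3 SBS export (a "Type" or "MutationType" label column
followed by SBS columns), and a plain label-indexed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from .channels import (
    CHANNEL_LABELS,
    N_CHANNELS,
    BASES,
    channel_for_snv,
    channel_index,
)

__all__ = [
    "MutationalCatalogue",
    "SignatureMatrix",
    "VcfFilterPolicy",
    "LOW_COUNT_THRESHOLD",
    "LowCountWarning",
    "read_catalogue_table",
    "write_catalogue_table",
    "read_signature_matrix",
    "write_signature_matrix",
    "vcf_to_catalogue",
]

#: Below this catalogue total the per-channel counts are too sparse for a
#: stable exposure reconstruction; fitting and bootstrapping warn.
LOW_COUNT_THRESHOLD = 125


class LowCountWarning(UserWarning):
    """Emitted when a catalogue's mutation total is below LOW_COUNT_THRESHOLD."""


@dataclass
class MutationalCatalogue:
    """Per-sample vector of 96 channel counts or frequencies.

    Parameters
    ----------
    sample_id : str
        Sample name (catalogue table column header).
    values : array-like of shape (96,)
        Non-negative channel values in canonical channel order.
    scale : {"counts", "frequencies"}
        Frequencies must sum to 1 (all-zero allowed for an empty catalogue).
    provenance : dict
        Free-form record of source file, filters and normalizations applied.
    """

    sample_id: str
    values: np.ndarray
    scale: str = "counts"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_CHANNELS,):
            raise ValueError(
                f"catalogue {self.sample_id!r}: expected {N_CHANNELS} channel "
                f"values, got shape {self.values.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError(f"catalogue {self.sample_id!r}: values must be finite and >= 0")
        if self.scale not in ("counts", "frequencies"):
            raise ValueError(f"unknown scale {self.scale!r}")
        total = self.values.sum()
        if self.scale == "frequencies" and total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"catalogue {self.sample_id!r}: frequencies sum to {total!r}, not 1"
            )

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def as_frequencies(self) -> "MutationalCatalogue":
        """Return the catalogue rescaled to frequencies (identity if empty)."""
        if self.scale == "frequencies":
            return self
        total = self.total
        values = self.values / total if total > 0 else self.values.copy()
        return MutationalCatalogue(
            self.sample_id, values, "frequencies", dict(self.provenance)
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(CHANNEL_LABELS), name=self.sample_id)


@dataclass
class SignatureMatrix:
    """96 x N column-stochastic matrix of channel probabilities per signature.

    ``baseline`` tags the trinucleotide-frequency baseline the profiles refer
    to (e.g. "GRCh37 whole genome"); normalization updates it.
    """

    names: list[str]
    matrix: np.ndarray
    baseline: str = "unspecified"

    #: Column sums are validated to 1 within this tolerance (published files
    #: carry rounded values).
    COLUMN_SUM_TOL = 1e-4

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if n < 1:
            raise ValueError("signature matrix needs at least one signature")
        if len(set(self.names)) != n:
            raise ValueError("duplicate signature names")
        if self.matrix.shape != (N_CHANNELS, n):
            raise ValueError(
                f"expected matrix shape ({N_CHANNELS}, {n}), got {self.matrix.shape}"
            )
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("signature matrix entries must be finite and >= 0")
        sums = self.matrix.sum(axis=0)
        bad = [
            name
            for name, s in zip(self.names, sums)
            if abs(s - 1.0) > self.COLUMN_SUM_TOL
        ]
        if bad:
            raise ValueError(
                "signature columns do not sum to 1 within "
                f"{self.COLUMN_SUM_TOL}: {', '.join(bad)}"
            )

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: list[str]) -> "SignatureMatrix":
        """Sub-matrix restricted to the given signatures, renormalized check off."""
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"unknown signatures: {', '.join(missing)}")
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.matrix[:, idx], self.baseline)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(CHANNEL_LABELS), columns=list(self.names)
        )


# ---------------------------------------------------------------------------
# Catalogue tables


def _reorder_channel_rows(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Validate channel row labels and reorder to canonical channel order."""
    labels = [str(x).strip() for x in df.index]
    try:
        order = [channel_index(lab) for lab in labels]
    except ValueError as exc:
        raise ValueError(f"{source}: unrecognized channel row: {exc}") from exc
    if len(set(order)) != len(order):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise ValueError(f"{source}: duplicate channel rows: {', '.join(dupes)}")
    if len(order) != N_CHANNELS:
        raise ValueError(
            f"{source}: expected {N_CHANNELS} channel rows, found {len(order)}"
        )
    df = df.copy()
    df.index = order
    df = df.sort_index()
    df.index = list(CHANNEL_LABELS)
    return df


def read_catalogue_table(path: str | Path) -> list[MutationalCatalogue]:
    """Read a catalogue TSV (channel rows x sample columns).

    Lines starting with ``#`` (provenance headers) are ignored. Rows are
    reordered to canonical channel order; missing or duplicate channels are
    an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df = _reorder_channel_rows(df, str(path))
    out = []
    for col in df.columns:
        values = df[col].to_numpy(dtype=float)
        total = values.sum()
        scale = "frequencies" if total > 0 and abs(total - 1.0) <= 1e-9 else "counts"
        out.append(
            MutationalCatalogue(
                str(col), values, scale, {"source": str(path)}
            )
        )
    return out


def write_catalogue_table(
    catalogues: list[MutationalCatalogue] | MutationalCatalogue,
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """Write catalogues as a TSV table; ``header_lines`` become ``#`` comments."""
    if isinstance(catalogues, MutationalCatalogue):
        catalogues = [catalogues]
    if not catalogues:
        raise ValueError("no catalogues to write")
    df = pd.concat([c.to_series() for c in catalogues], axis=1)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label="Somatic Mutation Type")


# ---------------------------------------------------------------------------
# Signature matrices

_COSMIC_V2_META = {"Substitution Type", "Trinucleotide", "Somatic Mutation Type"}


def read_signature_matrix(
    path: str | Path, dialect: str = "plain_matrix", baseline: str = "unspecified"
) -> SignatureMatrix:
    """Read a signature matrix TSV in one of three dialects.

    ``cosmic_v2``: "Substitution Type", "Trinucleotide", "Somatic Mutation
    Type" columns followed by one column per signature. ``cosmic_v3_sbs``: a
    "Type"/"MutationType" label column followed by SBS columns.
    ``plain_matrix``: channel labels in the first column. Rows are reordered
    to canonical channel order; column sums are validated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if dialect == "cosmic_v2":
        missing = _COSMIC_V2_META - set(df.columns)
        if missing:
            raise ValueError(
                f"{path}: not COSMIC v2 dialect, missing columns: {sorted(missing)}"
            )
        df = df.set_index("Somatic Mutation Type")
        df = df.drop(columns=[c for c in _COSMIC_V2_META if c in df.columns])
        # trailing empty columns appear in some exports
        df = df.dropna(axis=1, how="all")
    elif dialect == "cosmic_v3_sbs":
        label_col = next(
            (c for c in ("Type", "MutationType", "MutationsType") if c in df.columns),
            None,
        )
        if label_col is None:
            raise ValueError(f"{path}: not COSMIC v3 SBS dialect (no Type column)")
        df = df.set_index(label_col)
    elif dialect == "plain_matrix":
        df = df.set_index(df.columns[0])
    else:
        raise ValueError(f"unknown signature dialect {dialect!r}")
    df = _reorder_channel_rows(df, str(path))
    return SignatureMatrix(list(df.columns), df.to_numpy(dtype=float), baseline)


def write_signature_matrix(P: SignatureMatrix, path: str | Path) -> None:
    """Write a signature matrix in the plain label-indexed dialect."""
    P.to_frame().to_csv(path, sep="\t", index_label="Type")


# ---------------------------------------------------------------------------
# VCF -> catalogue


@dataclass(frozen=True)
class VcfFilterPolicy:
    """Record filters applied when building a catalogue from a VCF.

    Non-SNV records (multi-base or symbolic alleles) are always skipped:
    only the 96 single-base-substitution channels are modelled. By default
    records are accepted regardless of FILTER (FILTER semantics vary between
    callers); ``require_pass`` restricts to PASS/unfiltered records.
    Ambiguous contexts (non-ACGT reference letters, or positions lacking a
    flank) are skipped with a warning rather than erroring: gap- and
    telomere-adjacent sites are expected in real references.
    """

    require_pass: bool = False
    skip_multiallelic: bool = True
    skip_ambiguous_context: bool = True

    #: non-SNV records can never enter a 96-channel catalogue
    skip_non_snv: bool = True

    def __post_init__(self) -> None:
        if not self.skip_non_snv:
            raise ValueError("skip_non_snv cannot be disabled")


def vcf_to_catalogue(
    vcf_path: str | Path,
    reference: str | Path | pyfaidx.Fasta,
    policy: VcfFilterPolicy | None = None,
    sample_id: str | None = None,
) -> MutationalCatalogue:
    """Build a 96-channel catalogue from the somatic SNVs of a VCF file.

    Each accepted biallelic SNV contributes one count to exactly one channel;
    purine-reference records are strand-collapsed by reverse complement.
    Soft-masked (lowercase) reference bases are uppercased before the context
    lookup. Sites are used as they appear in the file (genotypes are
    ignored); skip counts per reason are recorded in the provenance.

    Raises
    ------
    ValueError
        If the VCF REF base disagrees with the reference FASTA at that
        position (coordinate/reference mismatch).
    """
    policy = policy or VcfFilterPolicy()
    vcf_path = Path(vcf_path)
    if isinstance(reference, (str, Path)):
        reference = pyfaidx.Fasta(str(reference))
    if sample_id is None:
        sample_id = vcf_path.name.removesuffix(".gz").removesuffix(".vcf")

    counts = np.zeros(N_CHANNELS)
    skipped = {
        "non_snv": 0,
        "multiallelic": 0,
        "non_pass": 0,
        "ambiguous_context": 0,
    }
    n_ambiguous_warned = 0

    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if policy.skip_multiallelic and len(alts) > 1:
                skipped["multiallelic"] += 1
                continue
            if len(alts) != 1:
                skipped["non_snv"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            if (
                len(ref) != 1
                or len(alt) != 1
                or ref.upper() not in BASES
                or alt.upper() not in BASES
            ):
                skipped["non_snv"] += 1
                continue
            if policy.require_pass:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    skipped["non_pass"] += 1
                    continue
            if rec.chrom not in reference:
                raise ValueError(
                    f"{vcf_path}: contig {rec.chrom!r} absent from reference FASTA"
                )
            pos0 = rec.pos - 1  # VCF is 1-based
            chrom = reference[rec.chrom]
            fasta_ref = str(chrom[pos0 : pos0 + 1]).upper()
            if fasta_ref != ref.upper():
                raise ValueError(
                    f"{vcf_path}: REF mismatch at {rec.chrom}:{rec.pos}: "
                    f"VCF says {ref!r}, reference FASTA has {fasta_ref!r}"
                )
            if pos0 < 1 or pos0 + 1 >= len(chrom):
                context = None  # no flanking base inside the sequence
            else:
                tri = str(chrom[pos0 - 1 : pos0 + 2]).upper()
                context = tri if all(b in BASES for b in tri) else None
            if context is None:
                if not policy.skip_ambiguous_context:
                    raise ValueError(
                        f"{vcf_path}: ambiguous context at {rec.chrom}:{rec.pos}"
                    )
                skipped["ambiguous_context"] += 1
                n_ambiguous_warned += 1
                continue
            channel = channel_for_snv(ref, alt, context)
            counts[channel.index] += 1

    if n_ambiguous_warned:
        warnings.warn(
            f"{vcf_path}: skipped {n_ambiguous_warned} record(s) with "
            "ambiguous trinucleotide context",
            stacklevel=2,
        )
    provenance = {
        "source": str(vcf_path),
        "policy": {
            "require_pass": policy.require_pass,
            "skip_multiallelic": policy.skip_multiallelic,
            "skip_non_snv": True,
            "skip_ambiguous_context": policy.skip_ambiguous_context,
        },
        "accepted": int(counts.sum()),
        "skipped": skipped,
    }
    return MutationalCatalogue(sample_id, counts, "counts", provenance)
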