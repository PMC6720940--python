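"""The 96 single-base-substitution channels and the 32 collapsed trinucleotide contexts.

Somatic single-nucleotide variants are classified by their substitution and the
two flanking reference bases. Substitutions are reported relative to the
pyrimidine of the mutated base pair, so a G>T call observed on the reference
strand is recorded as C>A in the reverse-complemented context. This yields
6 substitution classes x 4 five-prime bases x 4 three-prime bases = 96
channels, and 32 strand-collapsed trinucleotide contexts (central base C or T).

Canonical channel order: substitution classes in the order
C>A, C>G, C>T, T>A, T>C, T>G; within a class, the 5' flank then the 3' flank,
each in A, C, G, T order. Index 0 is "A[C>A]A", index 95 is "T[T>G]T".
"""

from __future__ import annotations

import re
from dataclasses import dataclass

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

N_CHANNELS = 96
N_CONTEXTS = 32

_LABEL_RE = re.compile(r"^([A-Za-z])\[([A-Za-z])>([A-Za-z])\]([A-Za-z])$")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationChannel:
    """One of the 96 pyrimidine-centered substitution classes with flanks.

    Attributes
    ----------
    substitution : str
        One of ``C>A, C>G, C>T, T>A, T>C, T>G``.
    five_prime, three_prime : str
        The flanking reference bases (A/C/G/T).
    """

    substitution: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(
                f"invalid substitution {self.substitution!r}: the mutated "
                "reference base must be a pyrimidine (C or T)"
            )
        for name in ("five_prime", "three_prime"):
            base = getattr(self, name)
            if base not in BASES:
                raise ValueError(f"invalid {name} flank {base!r}")

    @property
    def ref(self) -> str:
        return self.substitution[0]

    @property
    def alt(self) -> str:
        return self.substitution[2]

    @property
    def context(self) -> str:
        """Trinucleotide context (5' flank + mutated base + 3' flank)."""
        return self.five_prime + self.ref + self.three_prime

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        return (
            SUBSTITUTIONS.index(self.substitution) * 16
            + BASES.index(self.five_prime) * 4
            + BASES.index(self.three_prime)
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


#: All 96 channels in canonical order; CHANNELS[i].index == i.
CHANNELS: tuple[MutationChannel, ...] = tuple(
    MutationChannel(sub, five, three)
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

#: Canonical channel labels, e.g. "A[C>A]A", in canonical order.
CHANNEL_LABELS: tuple[str, ...] = tuple(c.label for c in CHANNELS)

#: The 32 strand-collapsed trinucleotide contexts: central base C first then T,
#: flanks each in A, C, G, T order.
CONTEXTS_32: tuple[str, ...] = tuple(
    five + central + three
    for central in PYRIMIDINES
    for five in BASES
    for three in BASES
)

_CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(CONTEXTS_32)}

#: For each channel index, the index of its context in CONTEXTS_32. Three
#: substitution classes share each context.
CHANNEL_CONTEXT_INDEX: tuple[int, ...] = tuple(
    _CONTEXT_INDEX[c.context] for c in CHANNELS
)

_LABEL_INDEX = {label: i for i, label in enumerate(CHANNEL_LABELS)}


def parse_channel_label(label: str) -> MutationChannel:
    """Parse a channel label of the form ``"X[R>A]Y"``.

    Raises
    ------
    ValueError
        If the text is malformed, a base is invalid, the central reference
        base is a purine, or REF equals ALT. The message names the offending
        component.
    """
    if not isinstance(label, str):
        raise ValueError(f"channel label must be text, got {type(label).__name__}")
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed channel label {label!r}: expected form 'X[R>A]Y'")
    five, ref, alt, three = (g.upper() for g in m.groups())
    for part, name in ((five, "5' flank"), (ref, "reference base"), (alt, "alternate base"), (three, "3' flank")):
        if part not in BASES:
            raise ValueError(f"invalid {name} {part!r} in channel label {label!r}")
    if ref not in PYRIMIDINES:
        raise ValueError(
            f"central reference base {ref!r} in {label!r} is a purine: "
            "channels are pyrimidine-centered"
        )
    if alt == ref:
        raise ValueError(f"alternate base equals reference base in {label!r}")
    return MutationChannel(f"{ref}>{alt}", five, three)


def channel_index(label: str) -> int:
    """Canonical index (0-95) of a channel label; parses and validates."""
    idx = _LABEL_INDEX.get(label)
    if idx is not None:
        return idx
    return parse_channel_label(label).index


def collapse_context(trinucleotide: str) -> str | None:
    """Map a trinucleotide to its pyrimidine-centered (collapsed) form.

    Returns None when the 3-mer contains a non-ACGT letter.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in BASES for b in tri):
        return None
    if tri[1] in PYRIMIDINES:
        return tri
    return reverse_complement(tri)


def channel_for_snv(ref: str, alt: str, context: str) -> MutationChannel:
    """Channel of a biallelic SNV given its reference trinucleotide context.

    ``context`` is the reference 3-mer centered on the variant position; when
    the reference base is a purine, both the context and the substitution are
    reverse-complemented onto the pyrimidine strand.
    """
    ref = ref.upper()
    alt = alt.upper()
    context = context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on REF {ref!r}")
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"not a valid SNV: {ref!r}>{alt!r}")
    if any(b not in BASES for b in context):
        raise ValueError(f"ambiguous context {context!r}")
    if ref not in PYRIMIDINES:
        context = reverse_complement(context)
        ref = _COMPLEMENT_BASE[ref]
        alt = _COMPLEMENT_BASE[alt]
    return MutationChannel(f"{ref}>{alt}", context[0], context[2])


_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}
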