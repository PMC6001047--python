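"""96-channel single-base-substitution profiles and mutation prevalence.

Every somatic SNV is classified into one of 96 channels defined by the
substituted pyrimidine (C or T, after reverse-complementing purine-reference
records onto the pyrimidine strand), the alternate base, and the 5' and 3'
flanking bases read from the reference genome.  Channel order follows the
COSMIC display convention: six substitution blocks C>A, C>G, C>T, T>A, T>C,
T>G, and within each block the 5' flank varies slowest, both flanks in
alphabetical order (A, C, G, T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "CHANNEL_LABELS",
    "SUBSTITUTION_TYPES",
    "MutationalProfile",
    "PrevalenceResult",
    "channel_of",
    "channel_index",
    "build_profile",
    "normalize",
    "prevalence",
    "HYPERMUTATION_THRESHOLD_PER_MB",
    "DEFAULT_TERRITORY_MB",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels in canonical order, e.g. "A[C>A]A" ... "T[T>G]T".
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)

_LABEL_TO_INDEX = {label: i for i, label in enumerate(CHANNEL_LABELS)}

#: Hypermutated samples carry strictly more than this many mutations per Mb.
HYPERMUTATION_THRESHOLD_PER_MB = 12.0

#: Surveyed genomic territory, in megabases, assumed per study type.
DEFAULT_TERRITORY_MB = {"wgs": 3000.0, "wes": 30.0}


class ContextError(ValueError):
    """Raised when a trinucleotide context cannot be resolved to a channel."""


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_index(label: str) -> int:
    """Map a channel label like ``"A[C>A]A"`` to its index 0..95."""
    try:
        return _LABEL_TO_INDEX[label]
    except KeyError:
        raise KeyError(f"unknown channel label {label!r}") from None


def channel_of(ref: str, alt: str, five_prime: str, three_prime: str) -> int:
    """Return the channel index (0..95) of a substitution in context.

    If ``ref`` is a purine (A/G) the whole triplet and the alternate allele
    are reverse-complemented first, so both strand representations of a
    mutation map to the same channel.

    Raises
    ------
    ContextError
        If any base is not one of A/C/G/T (e.g. N) or ``ref == alt``.
    """
    ref, alt = ref.upper(), alt.upper()
    five_prime, three_prime = five_prime.upper(), three_prime.upper()
    for b in (ref, alt, five_prime, three_prime):
        if b not in _BASES:
            raise ContextError(f"non-canonical base {b!r} in context")
    if ref == alt:
        raise ContextError("ref and alt alleles are identical")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        five_prime, ref, three_prime = (
            _COMPLEMENT[three_prime],
            _COMPLEMENT[ref],
            _COMPLEMENT[five_prime],
        )
        alt = _COMPLEMENT[alt]
    return _LABEL_TO_INDEX[f"{five_prime}[{ref}>{alt}]{three_prime}"]


@dataclass
class MutationalProfile:
    """Per-sample counts over the 96 substitution channels."""

    sample_id: str
    counts: np.ndarray  # int vector, length 96

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"profile needs 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("channel counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def relative(self) -> np.ndarray:
        return normalize(self)


def normalize(profile: MutationalProfile) -> np.ndarray:
    """Relative profile: counts scaled to sum to 1.

    Raises ``ValueError`` for an all-zero profile, whose relative form is
    undefined.
    """
    total = profile.total
    if total == 0:
        raise ValueError(
            f"profile {profile.sample_id!r} has no mutations; relative profile undefined"
        )
    return profile.counts / total


def _fetch_triplet(reference: Fasta, chrom: str, pos: int) -> str | None:
    """1-based triplet centered at pos, or None at contig edges."""
    contig = reference[chrom]
    if pos < 2 or pos > len(contig) - 1:
        return None
    return str(contig[pos - 2 : pos + 1]).upper()


def build_profile(records, reference: Fasta, sample_id: str | None = None):
    """Accumulate SNV records of one sample into a 96-channel profile.

    Records whose flanking context falls off the contig or contains a
    non-canonical base are skipped and tallied, not imputed.

    Returns ``(MutationalProfile, n_skipped)``.
    """
    records = list(records)
    if sample_id is None:
        sample_id = records[0].sample_id if records else "sample"
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for rec in records:
        triplet = _fetch_triplet(reference, rec.chrom, rec.pos)
        if triplet is None:
            skipped += 1
            continue
        try:
            k = channel_of(rec.ref, rec.alt, triplet[0], triplet[2])
        except ContextError:
            skipped += 1
            continue
        counts[k] += 1
    return MutationalProfile(sample_id, counts), skipped


@dataclass
class PrevalenceResult:
    """Mutation burden of one sample: mutations per surveyed megabase."""

    sample_id: str
    n_mutations: int
    territory_mb: float
    per_mb: float = field(init=False)
    hypermutated: bool = field(init=False)

    def __post_init__(self) -> None:
        self.per_mb = self.n_mutations / self.territory_mb
        self.hypermutated = self.per_mb > HYPERMUTATION_THRESHOLD_PER_MB


def prevalence(
    n_mutations: int,
    study_type: str,
    territory_mb: float | None = None,
    sample_id: str = "sample",
) -> PrevalenceResult:
    """Mutations per megabase, flagging hypermutation (> 12 per Mb, strict).

    ``study_type`` is one of ``wgs``, ``wes`` or ``custom``; ``territory_mb``
    overrides the default territory and is required for ``custom``.
    """
    if study_type not in ("wgs", "wes", "custom"):
        raise ValueError(f"study_type must be wgs, wes or custom, got {study_type!r}")
    if territory_mb is None:
        if study_type == "custom":
            raise ValueError("territory_mb is required for study_type='custom'")
        territory_mb = DEFAULT_TERRITORY_MB[study_type]
    territory_mb = float(territory_mb)
    if territory_mb <= 0:
        raise ValueError(f"territory_mb must be positive, got {territory_mb}")
    return PrevalenceResult(sample_id, int(n_mutations), territory_mb)
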