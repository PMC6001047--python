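"""Synthetic references and cohorts with known signature mixtures.

Generates offline, fully deterministic test data for the pipeline: a
pseudo-random single-contig reference FASTA with controllable GC content,
and per-sample VCFs whose induced 96-channel profiles follow a chosen
non-negative mixture of catalog signatures.  The planted channel counts and
generating weights are returned as a ground-truth table, so downstream
refitting can be scored against the truth.

Planting draws channels i.i.d. from p = S @ w, then assigns each drawn
channel a genomic position whose pyrimidine-normalized trinucleotide matches
the channel's context.  A fair coin picks whether the position carries the
context on the forward-pyrimidine or forward-purine strand (the VCF REF/ALT
then fall on the purine strand in the latter case), exercising
reverse-complement normalization on read-back.  Positions are never reused
within a sample, mirroring somatic SNV uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta, Faidx

from .catalog import SignatureCatalog
from .profile import CHANNEL_LABELS

__all__ = [
    "SimulationSpec",
    "SampleSpec",
    "TruthTable",
    "make_reference",
    "simulate_sample",
    "simulate_cohort",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 32 pyrimidine-centered trinucleotide contexts.
PYRIMIDINE_CONTEXTS = tuple(
    f"{five}{center}{three}"
    for center in "CT"
    for five in "ACGT"
    for three in "ACGT"
)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    weights: tuple  # mixture weights over catalog signatures, sum to 1
    n_mutations: int


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort."""

    reference_length: int = 100_000
    gc_bias: float = 0.41  # human-genome-like GC fraction
    samples: list[SampleSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = []
        if not (0.0 < self.gc_bias < 1.0):
            raise ValueError(f"gc_bias must be in (0, 1), got {self.gc_bias}")
        for s in self.samples:
            w = np.asarray(s.weights, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-6):
                raise ValueError(
                    f"sample {s.sample_id!r}: weights must be >= 0 and sum to 1"
                )
            if s.n_mutations < 1:
                raise ValueError(f"sample {s.sample_id!r}: n_mutations must be >= 1")


@dataclass
class TruthTable:
    """Ground truth per sample: planted channel counts and mixture weights."""

    signature_names: list[str]
    weights: dict[str, np.ndarray]  # sample -> K weights
    channel_counts: dict[str, np.ndarray]  # sample -> 96 counts

    def weights_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "signature": name, "weight": w[j]}
            for s, w in self.weights.items()
            for j, name in enumerate(self.signature_names)
        ]
        return pd.DataFrame(rows)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {s: c for s, c in self.channel_counts.items()},
            index=list(CHANNEL_LABELS),
        ).rename_axis("Channel")


def make_reference(
    path, length: int, gc_bias: float = 0.41, seed: int = 0, contig: str = "chrS"
) -> Path:
    """Write a deterministic pseudo-random reference FASTA (+ .fai index).

    The sequence is i.i.d. with P(G) = P(C) = gc_bias / 2.  Build fails if
    any of the 32 pyrimidine-centered trinucleotide contexts is absent, which
    in practice requires a few kilobases; >= 10 kb is recommended.
    """
    if length < 3:
        raise ValueError("reference_length must be at least 3")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    present = set()
    for i in range(length - 2):
        tri = seq[i : i + 3]
        present.add(tri if tri[1] in "CT" else _revcomp(tri))
    missing = sorted(set(PYRIMIDINE_CONTEXTS) - present)
    if missing:
        raise ValueError(
            f"reference of length {length} is missing trinucleotide contexts "
            f"{missing[:5]}; use a longer reference"
        )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, length, 70):
            fh.write(seq[i : i + 70] + "\n")
    Faidx(str(path))  # build the .fai alongside
    return path


def _context_pools(reference: Fasta, contig: str):
    """Positions (1-based, center) per pyrimidine context, split by strand.

    Returns ``{context: [pyr_positions, pur_positions]}`` where the pyr list
    holds positions whose forward-strand center base is C/T.
    """
    seq = str(reference[contig][:]).upper()
    pools: dict[str, list[list[int]]] = {c: [[], []] for c in PYRIMIDINE_CONTEXTS}
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if "N" in tri:
            continue
        if tri[1] in "CT":
            pools[tri][0].append(i + 2)
        else:
            pools[_revcomp(tri)][1].append(i + 2)
    return pools


def _write_vcf(path, contig: str, contig_length: int, rows) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in sorted(rows):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def simulate_sample(
    reference_path,
    cat: SignatureCatalog,
    weights,
    n_mutations: int,
    seed: int,
    out_vcf,
    sample_id: str = "sample",
):
    """Plant SNVs following a signature mixture; emit a VCF and truth counts.

    Draws ``n_mutations`` channels i.i.d. from p = S @ w and places each at
    an unused genomic position matching the channel's pyrimidine-normalized
    trinucleotide context (strand chosen by fair coin, falling back to the
    other strand when one pool is exhausted).  Re-reading the emitted VCF
    through the variant_io + profile path reproduces the planted channel
    counts exactly.

    Returns ``(vcf_path, planted_counts)`` with ``planted_counts`` a
    96-vector summing to ``n_mutations``.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (cat.n_signatures,):
        raise ValueError(
            f"weights length {w.shape} does not match {cat.n_signatures} signatures"
        )
    if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must be non-negative and sum to 1")
    p = cat.matrix @ w
    p = p / p.sum()  # guard against catalog column-sum rounding
    rng = np.random.default_rng(seed)
    reference = Fasta(str(reference_path))
    contig = list(reference.keys())[0]
    contig_length = len(reference[contig])
    pools = _context_pools(reference, contig)
    for lists in pools.values():  # shuffled pop() = uniform without replacement
        for lst in lists:
            rng.shuffle(lst)
    drawn = rng.choice(96, size=n_mutations, p=p)
    coins = rng.integers(0, 2, size=n_mutations)
    planted = np.zeros(96, dtype=np.int64)
    rows = []
    for k, coin in zip(drawn, coins):
        label = CHANNEL_LABELS[k]
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        context = five + ref + three
        pyr_pool, pur_pool = pools[context]
        use_pur = bool(coin)
        pool = pur_pool if use_pur else pyr_pool
        if not pool:
            pool = pyr_pool if use_pur else pur_pool
            use_pur = not use_pur
        if not pool:
            raise RuntimeError(
                f"context {context} exhausted on the reference; "
                "use a longer reference"
            )
        pos = pool.pop()
        if use_pur:
            rows.append((pos, _COMPLEMENT[ref], _COMPLEMENT[alt]))
        else:
            rows.append((pos, ref, alt))
        planted[k] += 1
    out_vcf = Path(out_vcf)
    _write_vcf(out_vcf, contig, contig_length, rows)
    return out_vcf, planted


def _derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed below 2^31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def simulate_cohort(spec: SimulationSpec, cat: SignatureCatalog, out_dir):
    """Generate a reference, one VCF per sample, and a ground-truth table.

    Per-sample seeds are derived from ``spec.seed``; two runs with the same
    spec produce byte-identical outputs.  Writes ``reference.fa`` (+ .fai),
    ``<sample>.vcf``, ``truth_weights.tsv`` and ``truth_channel_counts.tsv``
    under ``out_dir``.  Returns ``(reference_path, {sample: vcf_path},
    TruthTable)``.
    """
    if not spec.samples:
        raise ValueError("simulation spec lists no samples")
    ids = [s.sample_id for s in spec.samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in spec: {ids}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_path = make_reference(
        out_dir / "reference.fa", spec.reference_length, spec.gc_bias, spec.seed
    )
    vcfs: dict[str, Path] = {}
    truth = TruthTable(list(cat.signature_names), {}, {})
    for i, s in enumerate(spec.samples):
        vcf_path, planted = simulate_sample(
            ref_path,
            cat,
            s.weights,
            s.n_mutations,
            seed=_derive_seed(spec.seed, i),
            out_vcf=out_dir / f"{s.sample_id}.vcf",
            sample_id=s.sample_id,
        )
        vcfs[s.sample_id] = vcf_path
        truth.weights[s.sample_id] = np.asarray(s.weights, dtype=float)
        truth.channel_counts[s.sample_id] = planted
    truth.weights_frame().to_csv(out_dir / "truth_weights.tsv", sep="\t", index=False)
    truth.counts_frame().to_csv(out_dir / "truth_channel_counts.tsv", sep="\t")
    return ref_path, vcfs, truth
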