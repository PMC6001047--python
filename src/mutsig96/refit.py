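"""Quantify known-signature contributions by non-negative least squares.

Given an observed 96-channel count vector m and a catalog matrix S
(96 x K, column-stochastic), the refit solves

    minimize ||S x - m||^2   subject to  x >= 0

with the Lawson-Hanson active-set solver.  The fit operates on raw counts,
so each contribution x_j reads as the number of mutations attributed to
signature j; relative contributions are derived afterwards.  Reconstruction
quality is scored by the residual sum of squares (RSS, count scale) and by
cosine similarity between observed and reconstructed profiles; cosine > 0.9
is flagged as a sufficiently accurate reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .catalog import SignatureCatalog
from .profile import MutationalProfile

__all__ = [
    "RefitResult",
    "refit",
    "cosine_similarity",
    "rss",
    "reconstruct",
    "ADEQUACY_COSINE_THRESHOLD",
]

#: Reconstructions with cosine similarity above this are deemed adequate.
ADEQUACY_COSINE_THRESHOLD = 0.9


@dataclass
class RefitResult:
    sample_id: str
    signature_names: list[str]
    contributions: np.ndarray  # K non-negative reals, mutation-count scale
    reconstructed: np.ndarray  # 96-vector S @ contributions
    rss: float
    cosine: float

    @property
    def relative_contributions(self) -> np.ndarray:
        total = self.contributions.sum()
        if total == 0:
            raise ValueError(f"all-zero contributions for {self.sample_id!r}")
        return self.contributions / total

    @property
    def adequate(self) -> bool:
        return self.cosine > ADEQUACY_COSINE_THRESHOLD


def cosine_similarity(a, b) -> float:
    """Cosine similarity a.b / (|a||b|), clamped to [0, 1].

    Profiles are non-negative, so the true value lies in [0, 1]; clamping
    removes floating-point excursions (identical profiles score exactly 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("profiles must be non-negative")
    aa, bb = float(a @ a), float(b @ b)
    if aa == 0 or bb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    # sqrt(aa * bb) rather than |a|*|b|: identical inputs score exactly 1
    return float(min(max(a @ b / np.sqrt(aa * bb), 0.0), 1.0))


def rss(observed, reconstructed) -> float:
    """Residual sum of squares between two equal-length vectors."""
    observed = np.asarray(observed, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if observed.shape != reconstructed.shape:
        raise ValueError(f"shape mismatch: {observed.shape} vs {reconstructed.shape}")
    diff = observed - reconstructed
    return float(diff @ diff)


def reconstruct(cat: SignatureCatalog, contributions) -> np.ndarray:
    """Profile implied by a contribution vector: S @ x."""
    x = np.asarray(contributions, dtype=float)
    if x.shape != (cat.n_signatures,):
        raise ValueError(
            f"contribution vector length {x.shape} does not match "
            f"{cat.n_signatures} catalog signatures"
        )
    return cat.matrix @ x


def refit(
    profile: MutationalProfile | np.ndarray,
    cat: SignatureCatalog,
    sample_id: str | None = None,
) -> RefitResult:
    """Non-negative least-squares fit of catalog signatures to one profile.

    Accepts a :class:`MutationalProfile` or a bare 96-vector of counts.
    Raises for an all-zero profile.
    """
    if isinstance(profile, MutationalProfile):
        m = profile.counts.astype(float)
        if sample_id is None:
            sample_id = profile.sample_id
    else:
        m = np.asarray(profile, dtype=float)
        if sample_id is None:
            sample_id = "sample"
    if m.shape != (96,):
        raise ValueError(f"profile must have 96 channels, got {m.shape}")
    if not m.any():
        raise ValueError(f"cannot refit all-zero profile {sample_id!r}")
    x, _ = scipy.optimize.nnls(cat.matrix, m)
    recon = cat.matrix @ x
    return RefitResult(
        sample_id=sample_id,
        signature_names=list(cat.signature_names),
        contributions=x,
        reconstructed=recon,
        rss=rss(m, recon),
        cosine=cosine_similarity(m, recon),
    )
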