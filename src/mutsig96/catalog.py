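"""Known-signature catalogs: loading, validation, subsetting.

A catalog is a 96 x K matrix whose column j is the probability distribution
of signature j over the 96 substitution channels.  The canonical on-disk
dialect is a TSV with a ``Channel`` column holding labels like ``A[C>A]A``
and one numeric column per signature; the historic two-column layout
(``Substitution Type`` + ``Trinucleotide``) is also accepted.  Rows are
re-ordered to canonical channel order on load, so row order on disk never
matters.

The packaged default catalog (``data/synthetic_sbs96_catalog_k30.tsv``) is a
synthetic stand-in with 30 signatures: deterministically generated sparse
column-stochastic profiles of realistic shape, not measured human data.  A
companion synthetic cancer-type association table maps cancer-type names to
signature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .profile import CHANNEL_LABELS

__all__ = [
    "SignatureCatalog",
    "CancerTypeAssociation",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "validate_catalog",
    "load_associations",
    "signatures_for_cancer_type",
    "packaged_catalog_path",
    "packaged_association_path",
]

COLUMN_SUM_TOL = 1e-3


class CatalogError(ValueError):
    """Raised for malformed signature catalogs or association tables."""


@dataclass
class SignatureCatalog:
    """96 x K matrix of known signatures plus channel and signature names."""

    signature_names: list[str]
    matrix: np.ndarray  # shape (96, K)
    channel_labels: tuple[str, ...] = field(default=CHANNEL_LABELS)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.signature_names)):
            raise CatalogError(
                f"matrix shape {self.matrix.shape} does not match "
                f"96 channels x {len(self.signature_names)} signatures"
            )
        if len(set(self.signature_names)) != len(self.signature_names):
            raise CatalogError("signature names are not unique")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)

    def subset(self, names) -> "SignatureCatalog":
        """Catalog restricted to the given signatures, in catalog order."""
        names = set(names)
        unknown = names - set(self.signature_names)
        if unknown:
            raise CatalogError(f"unknown signatures: {sorted(unknown)}")
        keep = [i for i, n in enumerate(self.signature_names) if n in names]
        return SignatureCatalog(
            [self.signature_names[i] for i in keep], self.matrix[:, keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.channel_labels), columns=self.signature_names
        ).rename_axis("Channel")


def _channel_from_two_columns(df: pd.DataFrame) -> pd.Series:
    sub = df["Substitution Type"].astype(str)
    tri = df["Trinucleotide"].astype(str)
    return tri.str[0] + "[" + sub + "]" + tri.str[2]


def load_catalog(path, strict: bool = True) -> SignatureCatalog:
    """Load a signature catalog from a delimited table.

    Accepts either a ``Channel`` label column or the two-column
    ``Substitution Type`` / ``Trinucleotide`` layout.  Rows are reindexed to
    canonical channel order.  In strict mode (default) column sums must be 1
    within ``COLUMN_SUM_TOL`` and entries non-negative; in lenient mode those
    violations are tolerated (``validate_catalog`` still reports them).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "Channel" in df.columns:
        labels = df["Channel"].astype(str)
        value_cols = [c for c in df.columns if c != "Channel"]
    elif {"Substitution Type", "Trinucleotide"} <= set(df.columns):
        labels = _channel_from_two_columns(df)
        value_cols = [
            c for c in df.columns if c not in ("Substitution Type", "Trinucleotide")
        ]
    else:
        raise CatalogError(
            f"{path}: no 'Channel' column and no "
            "'Substitution Type'/'Trinucleotide' pair found"
        )
    if labels.duplicated().any():
        dupes = sorted(labels[labels.duplicated()].unique())
        raise CatalogError(f"{path}: duplicate channels {dupes}")
    missing = set(CHANNEL_LABELS) - set(labels)
    if missing:
        raise CatalogError(
            f"{path}: missing {len(missing)} channels, e.g. {sorted(missing)[:3]}"
        )
    extra = set(labels) - set(CHANNEL_LABELS)
    if extra:
        raise CatalogError(f"{path}: unrecognized channels {sorted(extra)[:3]}")
    if not value_cols:
        raise CatalogError(f"{path}: no signature columns found")
    values = df[value_cols].copy()
    for col in value_cols:
        values[col] = pd.to_numeric(values[col], errors="coerce")
        if values[col].isna().any():
            row = int(values.index[values[col].isna()][0])
            raise CatalogError(
                f"{path}: non-numeric entry in column {col!r}, data row {row}"
            )
    values.index = labels
    values = values.reindex(list(CHANNEL_LABELS))
    cat = SignatureCatalog(list(value_cols), values.to_numpy())
    if strict:
        violations = validate_catalog(cat)
        if violations:
            raise CatalogError(f"{path}: " + "; ".join(violations))
    return cat


def write_catalog(cat: SignatureCatalog, path) -> None:
    """Write a catalog in the canonical TSV dialect (Channel + one col/sig)."""
    cat.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def validate_catalog(cat: SignatureCatalog) -> list[str]:
    """Return human-readable invariant violations; empty list iff valid."""
    violations: list[str] = []
    if tuple(cat.channel_labels) != CHANNEL_LABELS:
        violations.append("channel labels are not in canonical order")
    neg_rows, neg_cols = np.nonzero(cat.matrix < 0)
    for r, c in zip(neg_rows[:5], neg_cols[:5]):
        violations.append(
            f"negative entry for channel {cat.channel_labels[r]} "
            f"in signature {cat.signature_names[c]}"
        )
    sums = cat.matrix.sum(axis=0)
    for j, s in enumerate(sums):
        if abs(s - 1.0) > COLUMN_SUM_TOL:
            violations.append(
                f"signature {cat.signature_names[j]} sums to {s:.6g}, not 1"
            )
    return violations


@dataclass
class CancerTypeAssociation:
    """Mapping from cancer-type name to the signatures reported for it."""

    table: dict[str, list[str]]

    @property
    def cancer_types(self) -> list[str]:
        return list(self.table)


def load_associations(path, cat: SignatureCatalog) -> CancerTypeAssociation:
    """Load a cancer_type/signature TSV, checking names against the catalog.

    Signature order within each cancer type follows catalog order.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"cancer_type", "signature"}
    if not required <= set(df.columns):
        raise CatalogError(f"{path}: required columns {sorted(required)} not found")
    order = {name: i for i, name in enumerate(cat.signature_names)}
    table: dict[str, list[str]] = {}
    for ctype, group in df.groupby("cancer_type", sort=False):
        sigs = [s for s in group["signature"].astype(str) if s]
        unknown = [s for s in sigs if s not in order]
        if unknown:
            raise CatalogError(
                f"{path}: cancer type {ctype!r} references unknown signatures {unknown}"
            )
        table[str(ctype)] = sorted(set(sigs), key=order.__getitem__)
    return CancerTypeAssociation(table)


def signatures_for_cancer_type(
    assoc: CancerTypeAssociation, cancer_type: str
) -> list[str]:
    """Signatures associated with a cancer type, in catalog order."""
    if cancer_type not in assoc.table:
        raise KeyError(
            f"unknown cancer type {cancer_type!r}; available: {assoc.cancer_types}"
        )
    return list(assoc.table[cancer_type])


def packaged_catalog_path() -> Path:
    """Path of the packaged synthetic 30-signature catalog."""
    return Path(resources.files("mutsig96") / "data" / "synthetic_sbs96_catalog_k30.tsv")


def packaged_association_path() -> Path:
    """Path of the packaged synthetic cancer-type association table."""
    return Path(
        resources.files("mutsig96") / "data" / "synthetic_cancer_type_associations.tsv"
    )
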