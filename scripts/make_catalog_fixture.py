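"""Regenerate the packaged synthetic signature catalog and association table.

The packaged catalog is a synthetic stand-in for a 30-signature SBS
reference catalog: each column is an independent sparse Dirichlet draw over
the 96 channels, giving spiky, mutually distinguishable profiles of
realistic shape.  Entirely deterministic; run from the repository root:

    python scripts/make_catalog_fixture.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from mutsig96.profile import CHANNEL_LABELS  # noqa: E402

SEED = 20180614
K = 30
DIRICHLET_ALPHA = 0.1

ASSOCIATIONS = {
    "Colorectal": [1, 5, 6, 10, 15, 20],
    "Breast": [1, 2, 3, 5, 8, 13],
    "Lung": [1, 2, 4, 5, 13],
    "Melanoma": [1, 5, 7, 11],
    "Ovarian": [1, 3, 5],
    "Liver": [1, 4, 5, 6, 12, 16, 17, 22, 23, 24],
    "Stomach": [1, 2, 15, 17, 20, 21],
    "Leukemia": [1, 2, 5, 9, 13],
}


def main() -> None:
    rng = np.random.default_rng(SEED)
    cols = {}
    for j in range(1, K + 1):
        col = rng.dirichlet(np.full(96, DIRICHLET_ALPHA))
        col = np.round(col, 6)
        col[np.argmax(col)] += round(1.0 - col.sum(), 6)  # exact unit sum at 6 dp
        cols[f"Signature_{j}"] = col
    df = pd.DataFrame(cols, index=list(CHANNEL_LABELS)).rename_axis("Channel")
    data_dir = Path(__file__).resolve().parents[1] / "src" / "mutsig96" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(data_dir / "synthetic_sbs96_catalog_k30.tsv", sep="\t", float_format="%.6f")

    rows = [
        {"cancer_type": ctype, "signature": f"Signature_{j}"}
        for ctype, sigs in ASSOCIATIONS.items()
        for j in sigs
    ]
    pd.DataFrame(rows).to_csv(
        data_dir / "synthetic_cancer_type_associations.tsv", sep="\t", index=False
    )

    first5 = df.to_numpy()[:, :5]
    print("column sums:", df.sum().round(6).unique())
    print("min singular value of first 5 columns:", np.linalg.svd(first5, compute_uv=False)[-1])


if __name__ == "__main__":
    main()
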