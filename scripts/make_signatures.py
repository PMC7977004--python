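"""Regenerate the bundled synthetic AC1-AC30 signature matrix.

The 30-signature "Alexandrov COSMIC" reference set is distributed under
access conditions that preclude bundling, so the package ships a synthetic
stand-in with the same shape and structure: 30 column-stochastic signatures
over the 96 canonical channels, sparse (most mass on a minority of
channels), with the first signature biased toward C>T at NpCpG contexts the
way an ageing/deamination signature is.  Exposures fitted against this
matrix exercise the identical code paths; they are not biologically
interpretable.

Run from the repository root:  python scripts/make_signatures.py
"""

from pathlib import Path

import numpy as np

import sys
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from drdscore.catalog import SBS96_LABELS  # noqa: E402
from drdscore.signatures import SIGNATURE_NAMES, SignatureMatrix  # noqa: E402


def build_matrix(seed: int = 20_240_101) -> SignatureMatrix:
    rng = np.random.default_rng(seed)
    cols = []
    for i, name in enumerate(SIGNATURE_NAMES):
        col = rng.dirichlet(np.full(96, 0.08))
        if name == "AC1":
            # deamination-like: concentrate mass on N[C>T]G channels
            boost = np.zeros(96)
            for j, lab in enumerate(SBS96_LABELS):
                if lab[1:6] == "[C>T]" and lab[6] == "G":
                    boost[j] = 1.0
            col = 0.3 * col + 0.7 * boost / boost.sum()
        col = col / col.sum()
        # quantize to 6 decimals and repair the column sum exactly
        q = np.round(col, 6)
        q[np.argmax(q)] += round(1.0 - q.sum(), 6)
        cols.append(np.round(q, 6))
    return SignatureMatrix(np.column_stack(cols), list(SIGNATURE_NAMES),
                           list(SBS96_LABELS))


if __name__ == "__main__":
    out = (Path(__file__).resolve().parents[1] / "src" / "drdscore" / "data"
           / "ac30_signatures_synthetic.tsv")
    build_matrix().to_tsv(out)
    print(f"wrote {out}")
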