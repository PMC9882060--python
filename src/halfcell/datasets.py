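"""Small published reference counts used by the overlap analysis.

``MRNA_PROTEIN_OVERLAP`` is the cross-tabulation of genes whose message is
enriched in the anterior or posterior half of the Stentor coeruleus cell
(bulk sequencing of bisected cells) against the compartment where the
corresponding protein accumulates (anterior, posterior, or membranellar
band, from proteomics of dissected cells). Rows: RNA side; columns: protein
compartment.
"""

from __future__ import annotations

import pandas as pd

from .contingency import ContingencyTable2x2

__all__ = ["MRNA_PROTEIN_OVERLAP", "mrna_protein_table"]

MRNA_PROTEIN_OVERLAP = pd.DataFrame(
    [[23, 5, 24], [1, 0, 7]],
    index=pd.Index(["Anterior RNA", "Posterior RNA"], name="rna_side"),
    columns=["Anterior Protein", "Posterior Protein", "Membranellar Band Protein"],
)

_COLUMN_BY_CODE = {
    "A": "Anterior Protein",
    "P": "Posterior Protein",
    "MB": "Membranellar Band Protein",
}


def mrna_protein_table(columns: tuple[str, str] = ("A", "P")) -> ContingencyTable2x2:
    """A 2x2 slice of the published RNA-vs-protein cross-tabulation.

    ``columns`` selects two protein compartments by code ('A', 'P', 'MB');
    rows are always (Anterior RNA, Posterior RNA).
    """
    names = [_COLUMN_BY_CODE[c] for c in columns]
    block = MRNA_PROTEIN_OVERLAP[names]
    return ContingencyTable2x2(
        int(block.iloc[0, 0]), int(block.iloc[0, 1]),
        int(block.iloc[1, 0]), int(block.iloc[1, 1]),
        col_labels=(names[0], names[1]),
    )
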