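"""The bundled rCRS Humanin anchor.

The Humanin micro-gene occupies positions 2633-2705 (1-based inclusive) of
the revised Cambridge Reference Sequence (NC_012920): 24 codons followed by
a single thymine that serves as an incomplete stop codon (completed to UAA
by post-transcriptional polyadenylation).  Read with the standard genetic
code the region encodes MAPRGFSCLLLLTSEIDLPVKRRA.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: 1-based inclusive rCRS coordinates of the Humanin gene.
RCRS_START = 2633
RCRS_END = 2705

#: The 73-base Humanin gene as given in the rCRS (NC_012920:2633-2705).
HUMANIN_QUERY = (
    "ATGGCTCCACGAGGGTTCAGCTGTCTCTTACTTTTAACCAGTGAAATTGACCTGCCCGTGAAGAGGCGGGCAT"
)

#: Standard-code translation of the 24 complete codons.
HUMANIN_PEPTIDE = "MAPRGFSCLLLLTSEIDLPVKRRA"

assert len(HUMANIN_QUERY) == RCRS_END - RCRS_START + 1 == 73


def load_known_variants_table() -> pd.DataFrame:
    """Known haplogroup-associated Humanin variants bundled with the package.

    Columns: label, haplogroup, n_genbank, consequence.  Ships the five
    haplogroup-defining variants; users may extend it with their own table
    of the same schema.
    """
    with resources.files("humaninscan.data").joinpath("known_variants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"label": str, "haplogroup": str, "n_genbank": int, "consequence": str})
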