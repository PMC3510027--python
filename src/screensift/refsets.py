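"""Packaged reference sets.

Currently one table: the published list of 130 suppressor siRNA pools
from a genome-scale mutant-huntingtin toxicity screen (gene symbol,
Entrez id, annotation, normalized activity mean and SEM), used as a
fixture for validating the hit-calling rule against printed values.
"""

from importlib.resources import files

import pandas as pd

#: screen-wide SD of normalized means reported for the reference screen
REFERENCE_SCREEN_SD = 0.317


def suppressor_reference() -> pd.DataFrame:
    """Load the 130-row suppressor reference table.

    Returns a DataFrame with columns gene_symbol, entrez_id, gene_name,
    function_class, mean, sem — rows ranked ascending by mean normalized
    caspase activity (strongest suppression first).  A mean of 1 means no
    change relative to the negative control.
    """
    path = files("screensift.data") / "suppressor_reference.tsv"
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.astype(
        {"entrez_id": int, "mean": float, "sem": float}
    )
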