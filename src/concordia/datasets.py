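"""Small bundled reference tables."""

from importlib.resources import files

import pandas as pd


def plasma_discordant_worked_example() -> pd.DataFrame:
    """Published worked-example table for the discordance statistic.

    The 21 plasma-detectable genes among the top-100 discordantly expressed
    genes (protein up, transcript down) of a grade III vs. grade I meningioma
    transcriptome-proteome integration over 3,598 shared genes.  Columns
    carry each gene's transcript LFC with its descending-order rank, protein
    LFC with its ascending-order rank, and the published average rank — a
    ready-made oracle for the discordance average-rank arithmetic.
    """
    path = files("concordia.data").joinpath("plasma_discordant_worked_example.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
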