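"""Packaged transcriptions of the published questionnaire tables.

Two small CSVs ship with the package: the item-factor classification of the
70 retained items (the sorting study started from a pool of 85) and the
printed loading-prior table (M (SD) per item, with the reconstructed
majority vote counts). Raw study votes were never published; the companion
vote fixture in :func:`priorcfa.simulate.reconstructed_study_votes` is synthetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .agreement import ItemClassification

#: Size of the original item pool before exclusions.
INITIAL_ITEM_POOL = 85


def _read(name: str) -> pd.DataFrame:
    with resources.files("priorcfa.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_published_classification() -> ItemClassification:
    """The published item-factor classification: 70 items on 7 factors."""
    df = _read("published_classification.csv")
    return ItemClassification(
        {int(r.item_id): r.factor for r in df.itertuples()})


def load_published_loading_priors() -> pd.DataFrame:
    """The printed loading-prior table, indexed by item id.

    Columns: ``factor``, ``mean_printed``, ``sd_printed``,
    ``majority_votes`` (reconstructed as round(M * 22); 22 for the
    unanimously sorted item), ``replaced`` (1 for the item whose prior came
    from the unanimity-replacement rule).
    """
    df = _read("published_loading_priors.csv")
    return df.set_index("item_id")
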