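"""Packaged reference tables.

``class_paper_counts`` ships the published class × ecosystem paper-count
table for the four marine ecosystems (the 36 classes with at least 10
occurrences in some ecosystem), including the printed cross-ecosystem
totals.  It serves as a fixed input for matrix roll-up checks and worked
examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .community import OccurrenceMatrix

ECOSYSTEMS: tuple[str, ...] = (
    "coral_reef", "kelp_forest", "mangrove_forest", "seagrass_bed",
)


def class_paper_counts() -> pd.DataFrame:
    """The published class × ecosystem paper counts, indexed by class name.

    Columns: the four ecosystem labels, ``common_name`` and
    ``total_printed`` (the published cross-ecosystem total).
    """
    with resources.files("taxalit.data").joinpath("class_paper_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("class")


def class_paper_matrix() -> OccurrenceMatrix:
    """The same table as a class-level :class:`OccurrenceMatrix`."""
    df = class_paper_counts()
    return OccurrenceMatrix.from_wide_df(df[list(ECOSYSTEMS)], level="class")
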