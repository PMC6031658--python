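"""Packaged per-subject accuracy tables (transcribed from the study report,
comma decimals converted to dots) and their loader.

Table 1: within-subject MEG baselines (offline l1 with MI training, online
PM-trained decoding, and their average, which drives subject exclusion).
Tables 2-5: subjects x seven method columns for {MEG, EEG} x {MI, PM}
training.  The EEG tables (3 and 5) contain 17 subjects; subject 1 is
absent from the printed EEG results.

Each file carries a final ``mean`` row exactly as printed; `load_table`
separates it from the per-subject cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

TABLE_FILES = {
    1: "table1_meg_within_subject.tsv",
    2: "table2_meg_mi.tsv",
    3: "table3_eeg_mi.tsv",
    4: "table4_meg_pm.tsv",
    5: "table5_eeg_pm.tsv",
}

TABLE_META = {
    1: ("MEG", "within-subject"),
    2: ("MEG", "MI"),
    3: ("EEG", "MI"),
    4: ("MEG", "PM"),
    5: ("EEG", "PM"),
}

INTER_SUBJECT_METHODS = ("csp_lda", "csp_bagging", "regcsp",
                         "pooling", "l1_mtl", "l21_mtl")


@dataclass
class FixtureTable:
    number: int
    cells: pd.DataFrame  # subjects x columns, percent
    printed_mean: pd.Series
    modality: str
    training_condition: str

    @property
    def subject_ids(self) -> list[int]:
        return list(self.cells.index)


def load_table(number: int) -> FixtureTable:
    fname = TABLE_FILES[number]
    with resources.files("mitransfer").joinpath("data", fname).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    printed_mean = df.loc["mean"].astype(float)
    cells = df.drop(index="mean").astype(float)
    cells.index = cells.index.astype(int)
    modality, cond = TABLE_META[number]
    return FixtureTable(number=number, cells=cells, printed_mean=printed_mean,
                        modality=modality, training_condition=cond)


def load_all_tables() -> dict[int, FixtureTable]:
    return {n: load_table(n) for n in TABLE_FILES}
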