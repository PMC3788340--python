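"""Parcellation tables: the 110-region Harvard-Oxford-style ROI set.

Each network node is one parcellation region.  The bundled default divides
the whole brain (excluding the brainstem) into 110 cortical and subcortical
regions, 55 per hemisphere, each tagged with a lobe classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = ["ParcellationTable", "load_parcellation", "default_parcellation"]

REQUIRED_COLUMNS = ("roi_index", "region_name", "abbreviation", "hemisphere", "lobe")
VALID_LOBES = frozenset({"frontal", "temporal", "parietal", "occipital", "subcortical"})
VALID_HEMISPHERES = frozenset({"L", "R"})


@dataclass
class ParcellationTable:
    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"parcellation missing column(s): {missing}")
        df = df.sort_values("roi_index").reset_index(drop=True)
        idx = df["roi_index"].to_numpy()
        dup = df["roi_index"][df["roi_index"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate ROI index at row(s): {dup.tolist()}")
        if list(idx) != list(range(1, len(df) + 1)):
            raise ValueError("ROI indices must be contiguous 1..N")
        bad_lobe = df.loc[~df["lobe"].isin(VALID_LOBES)]
        if len(bad_lobe):
            raise ValueError(
                f"unknown lobe label(s): {sorted(set(bad_lobe['lobe']))} "
                f"at ROI index {bad_lobe['roi_index'].tolist()}"
            )
        bad_hemi = df.loc[~df["hemisphere"].isin(VALID_HEMISPHERES)]
        if len(bad_hemi):
            raise ValueError(f"unknown hemisphere at ROI index {bad_hemi['roi_index'].tolist()}")
        counts = df["hemisphere"].value_counts()
        if counts.get("L", 0) != counts.get("R", 0):
            raise ValueError(
                f"hemisphere counts differ: {counts.get('L', 0)} L vs {counts.get('R', 0)} R"
            )
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_rois(self) -> int:
        return len(self.table)

    def labels(self) -> list[str]:
        """Unique per-ROI labels: abbreviation plus hemisphere suffix."""
        return [
            f"{row.abbreviation}_{row.hemisphere}" for row in self.table.itertuples(index=False)
        ]

    def lookup(self, region_name: str) -> dict[str, int]:
        """ROI indices for a region name (or abbreviation) by hemisphere."""
        df = self.table
        hit = df[(df["region_name"] == region_name) | (df["abbreviation"] == region_name)]
        if hit.empty:
            raise KeyError(f"region {region_name!r} not in parcellation")
        return {row.hemisphere: int(row.roi_index) for row in hit.itertuples(index=False)}


def load_parcellation(path: Union[str, Path]) -> ParcellationTable:
    """Load and validate a parcellation TSV."""
    df = pd.read_csv(path, sep="\t")
    return ParcellationTable(df)


def default_parcellation() -> ParcellationTable:
    """The bundled 110-ROI (55 per hemisphere) parcellation."""
    ref = resources.files("connsweep").joinpath("data/parcellation_hoa110.tsv")
    with resources.as_file(ref) as path:
        return load_parcellation(path)
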