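"""Normalization of raw per-participant aesthetic ratings.

Raters differ in how they use a bounded ordinal scale (central tendency,
leniency), so raw 1..K ratings are first z-scored within each participant
and only then averaged per image.  The per-image mean z-score is the outcome
variable for every downstream association analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("participant_id", "image_id", "rating")


@dataclass
class NormalizedRatings:
    """Per-image mean of per-participant z-scores, with rater counts."""

    table: pd.DataFrame  # columns: image_id, mean_z, n_raters

    @property
    def image_ids(self) -> np.ndarray:
        return self.table["image_id"].to_numpy()

    @property
    def mean_z(self) -> np.ndarray:
        return self.table["mean_z"].to_numpy()

    def vector_for(self, image_ids) -> np.ndarray:
        """mean_z aligned to an external image-id ordering."""
        lookup = self.table.set_index("image_id")["mean_z"]
        try:
            return lookup.loc[list(image_ids)].to_numpy()
        except KeyError as err:
            raise KeyError(f"image id missing from ratings: {err}") from err

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NormalizedRatings":
        return cls(pd.read_csv(path))


def normalize_ratings(records: pd.DataFrame) -> NormalizedRatings:
    """z-score ratings within participant, then average per image.

    z uses the sample standard deviation (n-1 denominator).  Participants who
    gave the same rating to every image carry no ordinal information and have
    an undefined z-score; their records are dropped with a warning rather
    than imputed as zero.

    Raises
    ------
    ValueError
        on empty input, missing columns, duplicate (participant, image)
        pairs, or when no participant has rating variance.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"rating table missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("empty rating table")
    if records.duplicated(["participant_id", "image_id"]).any():
        raise ValueError("duplicate (participant_id, image_id) pairs")

    df = records.copy()
    grp = df.groupby("participant_id")["rating"]
    sd = grp.transform("std")  # ddof=1
    flat = sd == 0
    if flat.any():
        n_dropped = df.loc[flat, "participant_id"].nunique()
        warnings.warn(
            f"dropping {n_dropped} zero-variance participant(s) "
            f"({int(flat.sum())} records): constant raters carry no "
            "ordinal information", stacklevel=2)
        df = df[~flat]
        if len(df) == 0:
            raise ValueError("all participants have zero rating variance")
        grp = df.groupby("participant_id")["rating"]
        sd = grp.transform("std")
    df = df.assign(z=(df["rating"] - grp.transform("mean")) / sd)

    per_image = (df.groupby("image_id", sort=True)["z"]
                 .agg(mean_z="mean", n_raters="size")
                 .reset_index())
    per_image["n_raters"] = per_image["n_raters"].astype(int)
    return NormalizedRatings(per_image)
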