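"""Count matrices and sample sheets: containers, validation, TSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "CountDataError", "validate_sample_sheet",
           "load_sample_sheet", "load_counts"]

VALID_TIMES = (0, 1, 3, 5, 7)


class CountDataError(ValueError):
    pass


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Check sample metadata: unique ids, valid times, 0 hr + 5 hr per line."""
    required = {"sample_id", "cell_line", "time_hr", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise CountDataError(f"sample sheet missing columns: {sorted(missing)}")
    samples = samples.copy()
    samples["time_hr"] = samples["time_hr"].astype(int)
    samples["replicate"] = samples["replicate"].astype(int)
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
        raise CountDataError(f"duplicated sample ids: {sorted(set(dups))}")
    key = samples[["cell_line", "time_hr", "replicate"]]
    if key.duplicated().any():
        raise CountDataError("(cell_line, time_hr, replicate) not unique")
    bad_time = set(samples["time_hr"]) - set(VALID_TIMES)
    if bad_time:
        raise CountDataError(f"unsupported time points: {sorted(bad_time)}")
    for line, grp in samples.groupby("cell_line"):
        times = set(grp["time_hr"])
        if 0 not in times or 5 not in times:
            raise CountDataError(
                f"cell line {line} lacks a 0 hr and/or 5 hr sample")
    return samples.set_index("sample_id", drop=False)


@dataclass
class CountMatrix:
    """Integer read counts (features x samples) with sample metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if "sample_id" in self.samples.columns and \
                self.samples.index.name != "sample_id":
            self.samples = validate_sample_sheet(self.samples)
        extra = set(self.counts.columns) - set(self.samples.index)
        if extra:
            raise CountDataError(
                f"count columns absent from sample sheet: {sorted(extra)}")
        # align column order to the sheet; report missing samples
        present = [s for s in self.samples.index if s in self.counts.columns]
        self.missing_samples = [s for s in self.samples.index
                                if s not in self.counts.columns]
        self.counts = self.counts[present]
        self.samples = self.samples.loc[present]
        self.counts.index.name = "feature_id"
        self.counts.columns.name = None
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()]
            raise CountDataError(
                f"duplicated feature ids: {sorted(set(dups))[:10]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CountDataError("non-integer counts")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CountDataError("negative counts")

    # -- selections -------------------------------------------------------
    @property
    def lines(self) -> List[str]:
        return sorted(self.samples["cell_line"].unique())

    def select(self, cell_line: Optional[str] = None,
               times: Optional[Iterable[int]] = None) -> "CountMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if cell_line is not None:
            mask &= self.samples["cell_line"] == cell_line
        if times is not None:
            mask &= self.samples["time_hr"].isin(list(times))
        sub = self.samples.loc[mask]
        return CountMatrix(self.counts[sub.index], sub)

    def sample_ids(self, cell_line: str, time_hr: int) -> List[str]:
        m = ((self.samples["cell_line"] == cell_line)
             & (self.samples["time_hr"] == time_hr))
        return list(self.samples.index[m])

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, counts_path, samples_path=None) -> None:
        self.counts.rename_axis("feature_id").to_csv(counts_path, sep="\t")
        if samples_path is not None:
            self.samples.reset_index(drop=True).to_csv(
                samples_path, sep="\t", index=False)


def load_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))


def load_counts(tsv_path, sample_sheet: pd.DataFrame) -> CountMatrix:
    """Load a counts TSV (rows = feature id) against a validated sheet."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    return CountMatrix(df, sample_sheet)
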