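"""Paired predictor/response matrices with sample-ID alignment.

A :class:`Dataset` couples an ``n x M`` feature matrix ``X`` (e.g. gene
expression of cell lines) with an ``n x r`` response matrix ``Y`` (e.g.
area-under-curve drug sensitivities), row-aligned by sample identifier.
Alignment is always by ID, never by file position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MISSING = "NA"


@dataclass
class Dataset:
    """Row-aligned predictor matrix X (n x M) and response matrix Y (n x r)."""

    sample_ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    response_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if not self.feature_names:
            self.feature_names = [f"F{j + 1}" for j in range(self.X.shape[1])]
        if not self.response_names:
            self.response_names = [f"Y{k + 1}" for k in range(self.Y.shape[1])]
        n = len(self.sample_ids)
        if self.X.shape[0] != n or self.Y.shape[0] != n:
            raise ValueError(
                f"row mismatch: {n} sample ids, X has {self.X.shape[0]} rows, "
                f"Y has {self.Y.shape[0]} rows"
            )
        if n < 2:
            raise ValueError("a Dataset needs at least 2 samples")
        if self.X.shape[1] < 1 or self.Y.shape[1] < 1:
            raise ValueError("X and Y each need at least one column")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match X")
        if len(self.response_names) != self.Y.shape[1]:
            raise ValueError("response_names length does not match Y")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_responses(self) -> int:
        return self.Y.shape[1]

    def subset_rows(self, rows: Sequence[int]) -> "Dataset":
        rows = list(rows)
        return Dataset(
            sample_ids=[self.sample_ids[i] for i in rows],
            X=self.X[rows],
            Y=self.Y[rows],
            feature_names=list(self.feature_names),
            response_names=list(self.response_names),
        )


def _read_matrix(path: str, delimiter: str, missing: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=[missing],
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r} "
                f"(not the missing token {missing!r})"
            ) from None
    return out


def read_dataset(
    features_path: str,
    responses_path: str,
    delimiter: str = ",",
    missing: str = DEFAULT_MISSING,
    complete_case: bool = True,
) -> Dataset:
    """Read feature and response tables and align them by sample ID.

    Both files need a header row and a leading sample-ID column.  The
    returned dataset is the intersection of the two ID sets, in the
    feature file's order.  With ``complete_case=True`` rows with any
    missing response are dropped.
    """
    feats = _read_matrix(features_path, delimiter, missing)
    resps = _read_matrix(responses_path, delimiter, missing)
    common = [sid for sid in feats.index if sid in set(resps.index)]
    if not common:
        raise ValueError("no overlapping sample IDs between feature and response files")
    dropped = (len(feats) - len(common), len(resps) - len(common))
    if any(dropped):
        logger.info(
            "sample alignment dropped %d feature rows and %d response rows",
            *dropped,
        )
    feats = feats.loc[common]
    resps = resps.loc[common]
    if feats.isna().any().any():
        raise ValueError("missing values in the feature matrix are not supported")
    ds = Dataset(
        sample_ids=list(feats.index),
        X=feats.to_numpy(dtype=float),
        Y=resps.to_numpy(dtype=float),
        feature_names=list(feats.columns),
        response_names=list(resps.columns),
    )
    if complete_case:
        ds = complete_case_filter(ds)
    return ds


def complete_case_filter(ds: Dataset, response_subset: Sequence[int] | None = None) -> Dataset:
    """Restrict to samples observed for every response in ``response_subset``.

    ``response_subset`` defaults to all responses.  The input dataset is
    left untouched.
    """
    if response_subset is None:
        cols = np.arange(ds.n_responses)
    else:
        cols = np.asarray(list(response_subset), dtype=int)
        if cols.size == 0 or cols.min() < 0 or cols.max() >= ds.n_responses:
            raise IndexError(f"response_subset out of range for r={ds.n_responses}")
    keep = ~np.isnan(ds.Y[:, cols]).any(axis=1)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("complete-case filtering removed every sample")
    if n_keep < ds.n:
        logger.info("complete-case filter dropped %d of %d samples", ds.n - n_keep, ds.n)
    return ds.subset_rows(np.flatnonzero(keep))


def write_dataset(ds: Dataset, features_path: str, responses_path: str,
                  delimiter: str = ",", missing: str = DEFAULT_MISSING) -> None:
    """Write the dataset back to two delimited tables (inverse of read)."""
    fx = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.feature_names)
    fy = pd.DataFrame(ds.Y, index=ds.sample_ids, columns=ds.response_names)
    fx.index.name = "sample_id"
    fy.index.name = "sample_id"
    fx.to_csv(features_path, sep=delimiter, na_rep=missing)
    fy.to_csv(responses_path, sep=delimiter, na_rep=missing)
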