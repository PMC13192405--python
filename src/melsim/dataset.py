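"""Long-format repeated-measures container for EMA-style data.

An :class:`EmaDataset` holds one replicate of intensive longitudinal data:
many occasions nested within subjects, with an explicit ``observed`` flag so
that missingness is auditable (missing records stay in the table as rows with
``observed == 0`` rather than being dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject_id", "occasion", "value", "observed")


@dataclass(frozen=True)
class ScaleInfo:
    """Measurement scale of the outcome column.

    kind
        ``"continuous"`` or ``"ordinal"``.
    n_categories
        Number of ordinal levels K (values are integers in ``1..K``);
        ``None`` for continuous data.
    """

    kind: str = "continuous"
    n_categories: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        if self.kind == "ordinal" and (self.n_categories is None or self.n_categories < 2):
            raise ValueError("ordinal scale needs n_categories >= 2")


class EmaDataset:
    """One replicate of long-format repeated measures.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``subject_id``, ``occasion`` (1-based, unique within
        subject), ``value`` (float), ``observed`` (0/1).
    scale : ScaleInfo, optional
        Outcome scale; continuous by default.
    """

    def __init__(self, df: pd.DataFrame, scale: ScaleInfo | None = None, validate: bool = True):
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["occasion"] = df["occasion"].astype(int)
        df["value"] = df["value"].astype(float)
        df["observed"] = df["observed"].astype(bool)
        self.df = df.reset_index(drop=True)
        self.scale = scale or ScaleInfo()
        if validate:
            self._validate()

    def _validate(self) -> None:
        if len(self.df) == 0:
            raise ValueError("dataset is empty")
        dup = self.df.duplicated(subset=["subject_id", "occasion"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["subject_id", "occasion"]].tolist()
            raise ValueError(f"duplicate (subject, occasion) pair: {pair}")
        obs_per_subject = self.df.groupby("subject_id", sort=False)["observed"].sum()
        if (obs_per_subject == 0).any():
            bad = obs_per_subject.index[obs_per_subject == 0][0]
            raise ValueError(f"subject {bad!r} has no observed records")
        if not np.isfinite(self.df["value"].to_numpy()).all():
            raise ValueError("non-finite outcome values")
        if self.scale.kind == "ordinal":
            v = self.df["value"].to_numpy()
            k = self.scale.n_categories
            if not (np.all(v == np.round(v)) and v.min() >= 1 and v.max() <= k):
                raise ValueError(f"ordinal values must be integers in [1, {k}]")

    # ------------------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        """Subjects in first-appearance order."""
        return self.df["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def observed(self) -> pd.DataFrame:
        """The observed records only."""
        return self.df[self.df["observed"]]

    def observed_counts(self) -> pd.Series:
        """Number of observed records per subject (first-appearance order)."""
        return self.observed().groupby("subject_id", sort=False)["value"].size()

    def missing_rate(self) -> float:
        """Marginal fraction of records flagged missing."""
        return 1.0 - float(self.df["observed"].mean())

    def suff_stats(self) -> pd.DataFrame:
        """Per-subject sufficient statistics of the observed records.

        Returns a frame indexed like :attr:`subject_ids` with columns
        ``n`` (observed count), ``ybar`` (mean) and ``ss`` (sum of squared
        deviations from the subject mean).  These are sufficient for the
        Gaussian location-scale likelihood, which is why the model code
        never has to touch individual records.
        """
        obs = self.observed()
        g = obs.groupby("subject_id", sort=False)["value"]
        n = g.size().to_numpy(dtype=float)
        ybar = g.mean().to_numpy()
        ss = (g.var(ddof=1).fillna(0.0).to_numpy()) * np.maximum(n - 1, 0.0)
        return pd.DataFrame({"n": n, "ybar": ybar, "ss": ss}, index=g.size().index)

    def copy(self) -> "EmaDataset":
        return EmaDataset(self.df.copy(), self.scale, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EmaDataset(n_subjects={self.n_subjects}, n_records={len(self.df)}, "
            f"missing_rate={self.missing_rate():.3f}, scale={self.scale.kind})"
        )
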