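"""Standard computational formulas (SCF): per-subject means and SDs.

These are the conventional summary statistics EMA researchers feed into
stage-2 regressions: the person-level arithmetic mean (iMean) over the
observed occasions and the n-1 sample standard deviation (iSD).  The module
also provides their across-subject z-scored versions and the grouped
SCF-vs-MELS comparison workflow used on real data.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .dataset import EmaDataset

__all__ = [
    "person_mean",
    "person_sd",
    "subject_summaries",
    "zscore_across_subjects",
    "compare_methods",
]

SUMMARY_COLUMNS = ["subject_id", "n_obs", "mean_stat", "var_stat", "method_tag"]


def person_mean(values) -> float:
    """Arithmetic mean of a subject's observed values (iMean)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("person_mean needs at least one observed value")
    return float(v.mean())


def person_sd(values) -> float:
    """Sample standard deviation with the n-1 denominator (iSD)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("person_sd needs observed values")
    if v.size == 1:
        raise ValueError("sample SD is undefined for a single observation")
    return float(v.std(ddof=1))


def subject_summaries(data: EmaDataset, min_obs: int = 2) -> pd.DataFrame:
    """Per-subject iMean/iSD table (method tag ``SCF``).

    Subjects with fewer than ``min_obs`` observed records have an undefined
    sample SD; they are returned with ``var_stat = NaN`` and a warning so a
    caller can drop them explicitly rather than silently imputing zero.
    """
    stats = data.suff_stats()
    n = stats["n"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(stats["ss"].to_numpy() / (n - 1))
    sd = np.where(n >= min_obs, sd, np.nan)
    if np.isnan(sd).any():
        warnings.warn(
            f"{int(np.isnan(sd).sum())} subject(s) have < {min_obs} observations; "
            "their SD is undefined and set to NaN",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "subject_id": stats.index.to_numpy(),
            "n_obs": n.astype(int),
            "mean_stat": stats["ybar"].to_numpy(),
            "var_stat": sd,
            "method_tag": "SCF",
        }
    )


def zscore_across_subjects(stats: pd.DataFrame) -> pd.DataFrame:
    """Center/scale each statistic across subjects (tag ``SCF_Z``).

    Uses the n-1 sample SD over subjects, so the output columns have mean 0
    and sample SD exactly 1.
    """
    if len(stats) < 2:
        raise ValueError("z-scoring needs at least 2 subjects")
    out = stats.copy()
    for col in ("mean_stat", "var_stat"):
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not math.isfinite(sd) or sd == 0:
            raise ValueError(f"zero or non-finite between-subject SD for {col}")
        out[col] = (x - x.mean()) / sd
    out["method_tag"] = "SCF_Z"
    return out


def compare_methods(
    scf_z: pd.DataFrame,
    mels: pd.DataFrame,
    group_breaks: tuple[int, ...] = (10, 30),
) -> pd.DataFrame:
    """Grouped comparison of z-scored SCF statistics against MELS estimates.

    Subjects are binned by observation count at ``group_breaks`` (default
    groups: <=10, 11..30, >30).  For each group and each statistic the table
    reports the per-method means, the mean difference (MELS minus z-scored
    SCF) and the Pearson correlation between methods.
    """
    a = scf_z.set_index("subject_id").sort_index()
    b = mels.set_index("subject_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("compare_methods requires matching subject sets")

    edges = [-np.inf, *group_breaks, np.inf]
    labels = _group_labels(group_breaks)
    groups = pd.cut(a["n_obs"], bins=edges, labels=labels)

    rows = []
    for label in labels:
        mask = (groups == label).to_numpy()
        if mask.sum() == 0:
            continue
        for stat, name in (("mean_stat", "mean"), ("var_stat", "sd")):
            x = a.loc[mask, stat].to_numpy()
            y = b.loc[mask, stat].to_numpy()
            corr = np.nan
            if mask.sum() >= 2 and x.std() > 0 and y.std() > 0:
                corr = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {
                    "group": label,
                    "n_subjects": int(mask.sum()),
                    "statistic": name,
                    "scf_z_mean": float(x.mean()),
                    "mels_mean": float(y.mean()),
                    "difference": float((y - x).mean()),
                    "correlation": corr,
                }
            )
    return pd.DataFrame(rows)


def _group_labels(breaks: tuple[int, ...]) -> list[str]:
    labels = [f"Obs <= {breaks[0]}"]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        labels.append(f"Obs > {lo} and Obs <= {hi}")
    labels.append(f"Obs > {breaks[-1]}")
    return labels
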