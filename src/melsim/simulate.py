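"""Synthetic EMA data generator.

The data-generating process is a two-stage model.  Stage 2 defines a
subject-level outcome

    y_i = beta1 * Mean_i + beta2 * STD_i + Error_i,

where Mean_i (true subject mean), STD_i (true subject log within-person
scale) and Error_i are independent mean-zero normals.  Stage 1 generates
the observation-level outcomes

    y_ij = R_ij * exp(STD_i) + Mean_i,        R_ij ~ N(0, 1) i.i.d.,

so each subject's observations are Normal(Mean_i, exp(2 * STD_i)).

On top of this base process the module implements the design transforms of
the simulation study: unbalanced observation counts (10 vs 30 per subject),
MCAR and MAR missingness at 10/20/30%, and ordinal discretization to K in
5..8 categories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dataset import EmaDataset, ScaleInfo

__all__ = [
    "DgpConfig",
    "MissingnessSpec",
    "generate_subject_truth",
    "generate_observations",
    "allocate_unbalanced",
    "apply_missingness",
    "discretize_ordinal",
    "ordinal_thresholds",
    "simulate_replicate",
]

# Seed of the large one-off reference simulation from which ordinal cut
# points are frozen; deliberately independent of any run's master seed so
# the thresholds are a fixed property of the DGP configuration.
_THRESHOLD_REFERENCE_SEED = 161_803
_THRESHOLD_REFERENCE_DRAWS = 400_000


@dataclass(frozen=True)
class DgpConfig:
    """Parameters of the two-stage data-generating process.

    n_obs may be a single count (balanced design) or a per-subject integer
    array from :func:`allocate_unbalanced`.  The three SDs govern the
    spread of the true subject means, true log-scales and stage-2 errors;
    the true stage-2 coefficients default to the study's 0.5/0.5.
    """

    n_subjects: int = 300
    n_obs: int | np.ndarray = 30
    beta1: float = 0.5
    beta2: float = 0.5
    sd_location: float = 1.0
    sd_logscale: float = 0.3
    sd_error: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("sd_location", "sd_logscale", "sd_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sd_location == 0 and self.sd_logscale == 0:
            raise ValueError("at least one of sd_location/sd_logscale must be > 0")
        counts = self.obs_counts()
        if counts.min() < 2:
            raise ValueError("every subject needs >= 2 planned observations")

    def obs_counts(self) -> np.ndarray:
        """Planned observation count per subject as an int array."""
        if np.isscalar(self.n_obs):
            return np.full(self.n_subjects, int(self.n_obs))
        counts = np.asarray(self.n_obs, dtype=int)
        if counts.shape != (self.n_subjects,):
            raise ValueError("per-subject n_obs must have length n_subjects")
        return counts

    def with_(self, **kwargs) -> "DgpConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MissingnessSpec:
    """Missing-data mechanism applied to a fully observed replicate.

    mechanism
        ``"none"``, ``"MCAR"`` (record-level Bernoulli, independent of
        everything) or ``"MAR"`` (record-level logistic model on the
        subject's true log-scale, intercept calibrated so the expected
        marginal missing rate equals ``target_rate``).
    mar_slope
        Log-odds increase in missingness per unit of true log-scale; only
        used for MAR.
    """

    mechanism: str = "none"
    target_rate: float = 0.0
    mar_slope: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("none", "MCAR", "MAR"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        if not 0.0 <= self.target_rate < 1.0:
            raise ValueError("target_rate must be in [0, 1)")


def generate_subject_truth(cfg: DgpConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the subject-level truths of the two-stage DGP.

    Returns a frame with columns ``subject_id``, ``true_location``
    (Mean_i), ``true_logscale`` (STD_i), ``stage2_error`` (Error_i) and
    ``stage2_outcome`` (y_i), with the stage-2 identity
    ``y_i = beta1*Mean_i + beta2*STD_i + Error_i`` holding exactly.
    """
    rng = _resolve_rng(rng, cfg.seed)
    s = cfg.n_subjects
    loc = rng.normal(0.0, cfg.sd_location, s)
    logscale = rng.normal(0.0, cfg.sd_logscale, s)
    err = rng.normal(0.0, cfg.sd_error, s)
    return pd.DataFrame(
        {
            "subject_id": np.arange(1, s + 1),
            "true_location": loc,
            "true_logscale": logscale,
            "stage2_error": err,
            "stage2_outcome": cfg.beta1 * loc + cfg.beta2 * logscale + err,
        }
    )


def generate_observations(
    truth: pd.DataFrame, cfg: DgpConfig, rng: np.random.Generator | None = None
) -> EmaDataset:
    """Generate the observation-level outcomes y_ij for each subject."""
    if len(truth) == 0:
        raise ValueError("empty truth table")
    rng = _resolve_rng(rng, cfg.seed)
    counts = cfg.obs_counts()
    if len(counts) != len(truth):
        raise ValueError("truth table and observation allocation disagree in length")
    total = int(counts.sum())
    resid = rng.normal(0.0, 1.0, total)
    loc = np.repeat(truth["true_location"].to_numpy(), counts)
    scale = np.exp(np.repeat(truth["true_logscale"].to_numpy(), counts))
    values = resid * scale + loc
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(truth["subject_id"].to_numpy(), counts),
            "occasion": np.concatenate([np.arange(1, c + 1) for c in counts]),
            "value": values,
            "observed": True,
        }
    )
    return EmaDataset(df, validate=False)


def allocate_unbalanced(
    n_subjects: int,
    split: tuple[float, float] = (0.75, 0.25),
    sizes: tuple[int, int] = (10, 30),
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Randomly assign each subject one of two observation counts.

    Exactly ``round(split[0] * n_subjects)`` subjects receive ``sizes[0]``
    observations and the rest ``sizes[1]``; which subjects get which is
    randomized by ``seed``.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split proportions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_first = int(round(split[0] * n_subjects))
    counts = np.full(n_subjects, sizes[1], dtype=int)
    counts[:n_first] = sizes[0]
    return rng.permutation(counts)


def apply_missingness(
    data: EmaDataset,
    truth: pd.DataFrame,
    spec: MissingnessSpec,
    rng: np.random.Generator | None = None,
) -> EmaDataset:
    """Flag records missing under the requested mechanism.

    MCAR drops each record independently with probability ``target_rate``.
    MAR uses per-record probability ``expit(a0 + mar_slope * STD_i)`` with
    the intercept ``a0`` solved numerically so the expected marginal rate
    equals ``target_rate`` for this replicate's subjects.  A subject is
    never left with zero observed records (its mask is redrawn).
    """
    if not data.df["observed"].all():
        raise ValueError("apply_missingness expects fully observed data")
    if spec.mechanism == "none" or spec.target_rate == 0.0:
        return data.copy()
    rng = _resolve_rng(rng, spec.seed)

    sid = data.df["subject_id"].to_numpy()
    order = truth.set_index("subject_id").loc[pd.unique(sid)]
    counts = data.df.groupby("subject_id", sort=False)["value"].size().to_numpy()

    if spec.mechanism == "MCAR":
        p_subject = np.full(len(counts), spec.target_rate)
    else:  # MAR: probability depends on the subject's true log-scale only
        logscale = order["true_logscale"].to_numpy()
        weights = counts / counts.sum()

        def marginal(a0: float) -> float:
            return float(np.sum(weights * expit(a0 + spec.mar_slope * logscale))) - spec.target_rate

        try:
            a0 = brentq(marginal, -40.0, 40.0)
        except ValueError as exc:  # pragma: no cover - degenerate configs only
            raise RuntimeError("MAR intercept calibration failed") from exc
        p_subject = expit(a0 + spec.mar_slope * logscale)

    p_record = np.repeat(p_subject, counts)
    missing = rng.random(len(p_record)) < p_record

    # redraw any subject that lost every record
    starts = np.concatenate([[0], np.cumsum(counts)])
    for i in range(len(counts)):
        lo, hi = starts[i], starts[i + 1]
        tries = 0
        while missing[lo:hi].all():
            missing[lo:hi] = rng.random(hi - lo) < p_subject[i]
            tries += 1
            if tries > 1000:  # pragma: no cover - safety net
                missing[lo] = False
    out = data.df.copy()
    out["observed"] = ~missing
    return EmaDataset(out, data.scale, validate=False)


@lru_cache(maxsize=32)
def _frozen_thresholds(sd_location: float, sd_logscale: float, k: int) -> tuple[float, ...]:
    rng = np.random.default_rng(_THRESHOLD_REFERENCE_SEED)
    n = _THRESHOLD_REFERENCE_DRAWS
    y = rng.normal(0.0, 1.0, n) * np.exp(rng.normal(0.0, sd_logscale, n)) + rng.normal(
        0.0, sd_location, n
    )
    qs = np.arange(1, k) / k
    return tuple(np.quantile(y, qs))


def ordinal_thresholds(cfg: DgpConfig, k: int) -> np.ndarray:
    """K-1 cut points at equally spaced quantiles of the marginal of y_ij.

    Estimated once from a large frozen reference simulation of the DGP's
    marginal distribution (mixture over subjects), so every category has
    equal population mass and the mapping is a fixed property of the
    configuration, not of any particular replicate.
    """
    return np.asarray(_frozen_thresholds(cfg.sd_location, cfg.sd_logscale, int(k)))


def discretize_ordinal(
    data: EmaDataset,
    k: int,
    method: str = "round",
    cfg: DgpConfig | None = None,
    thresholds: np.ndarray | None = None,
    allow_any_k: bool = False,
) -> EmaDataset:
    """Map continuous outcomes to ordinal levels 1..k (monotone).

    ``method="round"`` (default) emulates rating a latent quantity on a
    bounded Likert scale: the value is shifted so the population mean sits
    at the scale midpoint (1+k)/2, rounded to the nearest level, and
    clamped at 1 and k.  Bins are one latent unit wide, so a larger k only
    widens the range: fewer categories mean more ceiling/floor censoring,
    which is the distortion a short rating scale inflicts on means and
    SDs.  ``method="quantile"`` instead cuts at equally spaced population
    quantiles of the marginal outcome distribution (all categories equally
    occupied, no censoring; pass ``cfg`` to derive the frozen thresholds,
    or ``thresholds`` directly).
    """
    if data.scale.kind != "continuous":
        raise ValueError("data is already ordinal")
    if not 5 <= k <= 8 and not allow_any_k:
        raise ValueError("k must be in 5..8 (pass allow_any_k=True to override)")
    out = data.df.copy()
    if method == "round" and thresholds is None:
        mid = (1 + k) / 2.0
        out["value"] = np.clip(np.round(out["value"].to_numpy() + mid), 1, k)
    elif method in ("round", "quantile"):
        if thresholds is None:
            if cfg is None:
                raise ValueError("quantile method needs either thresholds or a DgpConfig")
            thresholds = ordinal_thresholds(cfg, k)
        thresholds = np.asarray(thresholds, dtype=float)
        if len(thresholds) != k - 1 or np.any(np.diff(thresholds) <= 0):
            raise ValueError("thresholds must be k-1 strictly increasing values")
        out["value"] = (np.searchsorted(thresholds, out["value"].to_numpy()) + 1).astype(float)
    else:
        raise ValueError("method must be 'round' or 'quantile'")
    return EmaDataset(out, ScaleInfo("ordinal", k), validate=False)


def simulate_replicate(
    cfg: DgpConfig,
    missingness: MissingnessSpec | None = None,
    ordinal_k: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, EmaDataset]:
    """One full replicate: truth, observations, then design transforms."""
    rng = _resolve_rng(rng, cfg.seed)
    truth = generate_subject_truth(cfg, rng)
    data = generate_observations(truth, cfg, rng)
    if missingness is not None and missingness.mechanism != "none":
        data = apply_missingness(data, truth, missingness, rng)
    if ordinal_k is not None:
        data = discretize_ordinal(data, ordinal_k, cfg=cfg)
    return truth, data


def _resolve_rng(rng: np.random.Generator | None, seed: int | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)
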