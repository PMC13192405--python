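"""File-format plumbing, named test fixtures and run configuration.

Long-format CSV is the exchange format: columns ``subject_id``, ``occasion``,
``value``, ``observed`` (0/1), comma-separated, UTF-8, header required.
Missing records are explicit rows with ``observed = 0`` so realized
missingness rates are auditable from the files alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import EmaDataset, ScaleInfo
from .simulate import DgpConfig, MissingnessSpec, generate_observations, generate_subject_truth

__all__ = [
    "read_long_csv",
    "write_long_csv",
    "write_summary_csv",
    "make_fixture",
    "RunConfig",
]


def read_long_csv(path: str | Path, scale: ScaleInfo | None = None) -> EmaDataset:
    """Read a long-format replicate CSV into an :class:`EmaDataset`.

    The ``observed`` column is optional (defaults to all-observed).  Rows
    with ``observed = 0`` are retained but flagged.  Missing columns,
    duplicate (subject, occasion) pairs and non-numeric values raise
    descriptive errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = {"subject_id", "occasion", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {sorted(missing)}")
    if "observed" not in df.columns:
        df["observed"] = 1
    for col in ("occasion", "value", "observed"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path.name}: non-numeric values in column {col!r}") from exc
    return EmaDataset(df, scale=scale)


def write_long_csv(data: EmaDataset, path: str | Path) -> None:
    out = data.df.copy()
    out["observed"] = out["observed"].astype(int)
    out.to_csv(path, index=False)


def write_summary_csv(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write a per-subject summary table (any method tag) to CSV."""
    summaries.to_csv(path, index=False)


# ----------------------------------------------------------------------
# named fixtures
# ----------------------------------------------------------------------


def _standardize_to(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    v = (values - values.mean()) / values.std(ddof=1)
    return mean + sd * v


def make_fixture(kind: str, seed: int = 0) -> tuple[EmaDataset, pd.DataFrame]:
    """Small deterministic datasets for tests and demonstrations.

    ``"fig1_pair"``
        Two subjects engineered to share the same mean and SD exactly while
        differing sharply in observation count (5 vs 40) — the canonical
        case where summary statistics look equally precise but are not.
    ``"constant_subject"``
        Three subjects, one with zero within-person variation (the
        pathology that destabilizes random-scale estimation).
    ``"quickfit20"``
        Twenty subjects x 15 occasions from the default DGP; fits in
        seconds and converges.

    Returns (dataset, truth-like table).  For the hand-built fixtures the
    "truth" columns are the construction targets, not draws from the DGP.
    """
    rng = np.random.default_rng(seed)
    if kind == "fig1_pair":
        a = _standardize_to(rng.standard_normal(5), 3.0, 1.0)
        b = _standardize_to(rng.standard_normal(40), 3.0, 1.0)
        df = pd.DataFrame(
            {
                "subject_id": [1] * 5 + [2] * 40,
                "occasion": list(range(1, 6)) + list(range(1, 41)),
                "value": np.concatenate([a, b]),
                "observed": True,
            }
        )
        truth = pd.DataFrame(
            {
                "subject_id": [1, 2],
                "true_location": [3.0, 3.0],
                "true_logscale": [0.0, 0.0],
                "stage2_error": [0.0, 0.0],
                "stage2_outcome": [1.5, 1.5],
            }
        )
        return EmaDataset(df), truth
    if kind == "constant_subject":
        values = np.concatenate([np.full(8, 2.0), rng.normal(0, 1, 8), rng.normal(1, 2, 8)])
        df = pd.DataFrame(
            {
                "subject_id": np.repeat([1, 2, 3], 8),
                "occasion": np.tile(np.arange(1, 9), 3),
                "value": values,
                "observed": True,
            }
        )
        truth = pd.DataFrame(
            {
                "subject_id": [1, 2, 3],
                "true_location": [2.0, 0.0, 1.0],
                "true_logscale": [-np.inf, 0.0, np.log(2.0)],
                "stage2_error": [0.0] * 3,
                "stage2_outcome": [np.nan, 0.0, 0.5 + 0.5 * np.log(2.0)],
            }
        )
        return EmaDataset(df), truth
    if kind == "quickfit20":
        cfg = DgpConfig(n_subjects=20, n_obs=15, seed=seed)
        rng = np.random.default_rng(seed)
        truth = generate_subject_truth(cfg, rng)
        data = generate_observations(truth, cfg, rng)
        return data, truth
    raise ValueError(f"unknown fixture kind {kind!r}")


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one Monte-Carlo run.

    Round-trips through YAML so a run can be reconstructed byte-identically
    from its logged configuration.
    """

    scenario: str
    condition_label: str
    dgp: DgpConfig
    missingness: MissingnessSpec | None = None
    n_replicates: int = 500
    master_seed: int = 0
    n_quad: int = 15
    output_dir: str = "results"

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {
            "scenario": self.scenario,
            "condition_label": self.condition_label,
            "dgp": _dgp_to_dict(self.dgp),
            "missingness": dataclasses.asdict(self.missingness) if self.missingness else None,
            "n_replicates": self.n_replicates,
            "master_seed": self.master_seed,
            "n_quad": self.n_quad,
            "output_dir": self.output_dir,
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if "\n" not in text:
            try:
                text = Path(source).read_text()
            except OSError:
                pass
        payload = yaml.safe_load(text)
        dgp = DgpConfig(**_dgp_from_dict(payload["dgp"]))
        miss = payload.get("missingness")
        return cls(
            scenario=payload["scenario"],
            condition_label=payload["condition_label"],
            dgp=dgp,
            missingness=MissingnessSpec(**miss) if miss else None,
            n_replicates=payload["n_replicates"],
            master_seed=payload["master_seed"],
            n_quad=payload["n_quad"],
            output_dir=payload["output_dir"],
        )


def _dgp_to_dict(cfg: DgpConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if isinstance(d["n_obs"], np.ndarray):
        d["n_obs"] = [int(x) for x in d["n_obs"]]
    return d


def _dgp_from_dict(d: dict) -> dict:
    d = dict(d)
    if isinstance(d.get("n_obs"), list):
        d["n_obs"] = np.asarray(d["n_obs"], dtype=int)
    return d
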