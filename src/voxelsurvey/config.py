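"""Run configuration: one validated record of every pipeline parameter.

All randomness flows from the three named seeds recorded here (cohort,
split, survey); no stage touches a hidden global RNG.  Configs load from
YAML, CLI flags override file keys, and every violation is reported with
the offending field named.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

DEFAULT_RATIOS = (6, 2, 2)


@dataclass
class RunConfig:
    """Validated parameter record for a full pipeline run."""

    # synthetic cohort
    n_disease: int = 20
    n_control: int = 20
    dims: tuple[int, int, int] = (6, 7, 6)
    n_informative: int = 20
    effect_size: float = 0.3
    noise_sd: float = 0.05
    baseline_smoothness: float = 2.0
    informative_layout: str = "blob"
    cohort_seed: int = 0
    cohort_path: str | None = None  # load instead of simulate when set

    # voxel prep
    tol: float = 1e-12

    # similarity / bounds
    g: int = 10
    extremum_tol: float = 1e-9

    # rs-svm
    n_surveys: int = 200
    ratios: tuple[int, int, int] = DEFAULT_RATIOS
    allow_custom_split: bool = False
    split_seed: int = 1
    survey_seed: int = 2

    # comparison harness
    n_repetitions: int = 10
    baseline_columns: str = "selected"  # or "all"
    models: tuple[str, ...] = ("linear", "lasso", "pls", "svm", "rs-svm")

    # output
    out_dir: str = "run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        d["ratios"] = list(self.ratios)
        d["models"] = list(self.models)
        return d


def validate_config(raw: dict | None) -> RunConfig:
    """Fill defaults and check cross-field constraints.

    Parameters
    ----------
    raw : dict or None
        Parsed config mapping (e.g. from YAML); ``None`` or empty gives all
        defaults.

    Raises
    ------
    ValueError
        On any violation, naming the offending field.
    """
    raw = dict(raw or {})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")

    for key in ("dims", "ratios", "models"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)

    def fail(field_name, msg):
        raise ValueError(f"config field '{field_name}': {msg}")

    if len(cfg.dims) != 3 or any(int(d) < 1 for d in cfg.dims):
        fail("dims", f"must be three positive integers, got {cfg.dims}")
    if cfg.n_disease < 1:
        fail("n_disease", "must be >= 1")
    if cfg.n_control < 1:
        fail("n_control", "must be >= 1")
    n_voxels = int(cfg.dims[0]) * int(cfg.dims[1]) * int(cfg.dims[2])
    if not (0 <= cfg.n_informative <= n_voxels):
        fail("n_informative", f"must be in [0, {n_voxels}]")
    if cfg.noise_sd < 0:
        fail("noise_sd", "must be >= 0")
    if cfg.informative_layout not in ("blob", "scattered"):
        fail("informative_layout", "must be 'blob' or 'scattered'")
    if cfg.tol < 0:
        fail("tol", "must be >= 0")
    if cfg.g < 1:
        fail("g", "must be >= 1")
    if cfg.g > n_voxels:
        fail("g", f"({cfg.g}) exceeds the voxel count ({n_voxels})")
    if cfg.extremum_tol < 0:
        fail("extremum_tol", "must be >= 0")
    if cfg.n_surveys < 1:
        fail("n_surveys", "must be >= 1")
    if cfg.n_repetitions < 1:
        fail("n_repetitions", "must be >= 1")
    if tuple(cfg.ratios) != DEFAULT_RATIOS and not cfg.allow_custom_split:
        fail("ratios", f"must be {DEFAULT_RATIOS} unless allow_custom_split is set")
    for seed_field in ("cohort_seed", "split_seed", "survey_seed"):
        if getattr(cfg, seed_field) < 0:
            fail(seed_field, "must be a nonnegative integer")
    if cfg.baseline_columns not in ("selected", "all"):
        fail("baseline_columns", "must be 'selected' or 'all'")
    from .compare import ALL_MODELS
    bad = set(cfg.models) - set(ALL_MODELS)
    if bad:
        fail("models", f"unknown models {sorted(bad)}")
    if cfg.cohort_path is not None and not Path(cfg.cohort_path).exists():
        fail("cohort_path", f"path does not exist: {cfg.cohort_path}")
    return cfg


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file (optional) and apply CLI overrides."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        parsed = yaml.safe_load(text)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(parsed)
    for key, value in (overrides or {}).items():
        if value is not None:
            raw[key] = value
    return validate_config(raw)
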