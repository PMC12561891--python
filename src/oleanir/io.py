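"""CSV readers/writers, run configuration and the full pipeline driver.

One spectra dialect is the contract: a wide CSV whose header is
``sample_id`` followed by the wavenumbers in cm^-1 (descending), one
row per sample. Reference values, phenolic profiles, splits and
evaluation reports are plain long/wide CSVs. Every file written by the
pipeline carries the configuration hash on a leading ``#`` comment line
(CSV) or as a ``config_hash`` key (JSON), so outputs are traceable to
the exact run configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlate import correlation_table
from .evaluate import (DEFAULT_GRID_CODES, grid_search, reports_to_dataframe)
from .pls import fit_pls
from .preprocess import apply_pretreatment, parse_pretreatment_code
from .reference import ASSAYS, ReferenceValues
from .simulate import GeneratorConfig, generate_dataset
from .spectra import SpectraSet
from .split import SplitResult, split_sets

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "write_reference_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_kinetic_long_csv",
    "write_split_csv",
    "read_split_csv",
    "RunConfig",
    "config_hash",
    "run_pipeline",
]


def _read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _write_csv(df: pd.DataFrame, path, *, index: bool, config_hash: str | None):
    path = Path(path)
    with path.open("w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index)


def read_spectra_csv(path) -> SpectraSet:
    """Read the wide spectra CSV (sample_id; descending wavenumbers)."""
    df = _read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', "
                         f"got {df.columns[0]!r}")
    ids = df["sample_id"].astype(str).tolist()
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample_id {dupes[0]!r}")
    try:
        wavenumbers = np.asarray([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber column: {exc}") from exc
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing value at row {r + 1} "
                         f"(sample {ids[r]!r}), column {df.columns[c + 1]}")
    if wavenumbers.size >= 2 and not np.all(np.diff(wavenumbers) < 0):
        raise ValueError(
            f"{path}: wavenumber axis must be strictly descending "
            "(high to low cm^-1)"
        )
    return SpectraSet(wavenumbers=wavenumbers, absorbance=values, sample_ids=ids)


def write_spectra_csv(spectra: SpectraSet, path, config_hash: str | None = None):
    df = spectra.to_dataframe()
    df.columns = [format(w, "g") for w in spectra.wavenumbers]
    _write_csv(df, path, index=True, config_hash=config_hash)


def read_reference_csv(path, assay: str | None = None) -> ReferenceValues:
    """Read a (sample_id, value) CSV; assay from the value column name."""
    df = _read_csv(path)
    if df.columns[0] != "sample_id" or df.shape[1] != 2:
        raise ValueError(f"{path}: expected columns (sample_id, <assay>)")
    return ReferenceValues(
        assay=assay or str(df.columns[1]),
        values=df.iloc[:, 1].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def write_reference_csv(ref: ReferenceValues, path, config_hash: str | None = None):
    _write_csv(ref.to_series().to_frame(), path, index=True,
               config_hash=config_hash)


def read_profiles_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    return df.set_index("sample_id")


def write_profiles_csv(profiles: pd.DataFrame, path,
                       config_hash: str | None = None):
    _write_csv(profiles, path, index=True, config_hash=config_hash)


def read_kinetic_long_csv(path) -> dict:
    """Read long-format plate readings (well, time_s, signal) into curves."""
    from .simulate import KineticCurve

    df = _read_csv(path)
    required = {"well", "time_s", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    curves = {}
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_s")
        curves[str(well)] = KineticCurve(
            times=grp["time_s"].to_numpy(dtype=float),
            signal=grp["signal"].to_numpy(dtype=float),
        )
    return curves


def write_split_csv(split: SplitResult, path, config_hash: str | None = None):
    ids = split.sample_ids or [str(i) for i in split.all_indices]
    labels = np.full(len(ids), "prediction", dtype=object)
    labels[split.cv_indices] = "cv"
    df = pd.DataFrame({"sample_id": ids, "set": labels})
    _write_csv(df, path, index=False, config_hash=config_hash)


def read_split_csv(path) -> SplitResult:
    df = _read_csv(path)
    cv = np.nonzero((df["set"] == "cv").to_numpy())[0]
    pred = np.nonzero((df["set"] == "prediction").to_numpy())[0]
    return SplitResult(all_indices=np.arange(len(df)), cv_indices=cv,
                       prediction_indices=pred,
                       sample_ids=df["sample_id"].astype(str).tolist())


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    n_samples: int = 120
    assays: list[str] = field(default_factory=lambda: list(ASSAYS))
    pretreatments: list[str] = field(
        default_factory=lambda: list(DEFAULT_GRID_CODES))
    split_fraction: float = 0.7
    cv_scheme: str = "loo"
    max_lv: int = 20
    paper_mode: bool = False
    output_dir: str = "results/run"
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    SCHEMA = {
        "seed": int, "n_samples": int, "assays": list, "pretreatments": list,
        "split_fraction": float, "cv_scheme": str, "max_lv": int,
        "paper_mode": bool, "output_dir": str, "generator": dict,
    }

    def validate(self) -> None:
        for name, typ in self.SCHEMA.items():
            value = getattr(self, name)
            if typ is float and isinstance(value, int):
                value = float(value)
                setattr(self, name, value)
            if not isinstance(value, typ):
                raise ValueError(f"config field {name!r} must be {typ.__name__}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        for assay in self.assays:
            if assay not in ASSAYS:
                raise ValueError(f"unknown assay {assay!r}")
        for code in self.pretreatments:
            parse_pretreatment_code(code)
        if self.cv_scheme not in ("loo",) and not self.cv_scheme.startswith("kfold"):
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.SCHEMA)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def scheme(self):
        if self.cv_scheme == "loo":
            return "loo"
        # "kfold:K" -> k-fold with the run seed
        k = int(self.cv_scheme.split(":")[1])
        return ("kfold", k, self.seed)


def config_hash(config: RunConfig) -> str:
    # output_dir is excluded: the hash identifies the scientific
    # configuration, not where its outputs happen to be written.
    payload = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, pretreat, split, model, evaluate and correlate; save all.

    Returns a manifest dict (also written to ``run_log.json``) listing
    outputs, seeds and the configuration hash. Rerunning with the same
    configuration reproduces every file bit for bit.
    """
    config.validate()
    chash = config_hash(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    gen = GeneratorConfig(n_samples=config.n_samples, seed=config.seed,
                          **config.generator)
    profiles, spectra, references = generate_dataset(gen)
    write_profiles_csv(profiles, out / "profiles.csv", chash)
    write_spectra_csv(spectra, out / "spectra.csv", chash)

    outputs = ["profiles.csv", "spectra.csv"]
    best_summary = {}
    for assay in config.assays:
        ref = references[assay]
        write_reference_csv(ref, out / f"references_{assay}.csv", chash)
        reports = grid_search(
            spectra, ref, config.pretreatments,
            fraction=config.split_fraction, cv_scheme=config.scheme(),
            max_lv=config.max_lv, paper_mode=config.paper_mode,
        )
        table = reports_to_dataframe(reports)
        _write_csv(table, out / f"reports_{assay}.csv", index=False,
                   config_hash=chash)
        best = reports[0]
        # refit the winning pipeline and persist model + split
        pretreated = apply_pretreatment(spectra,
                                        parse_pretreatment_code(best.pretreatment))
        split = split_sets(pretreated, config.split_fraction)
        if config.paper_mode:
            model = fit_pls(pretreated, ref, best.selected_lv)
        else:
            model = fit_pls(pretreated.subset(split.cv_indices),
                            ref.subset(split.cv_indices), best.selected_lv)
        model.to_json(out / f"best_model_{assay}.json")
        write_split_csv(split, out / f"split_{assay}.csv", chash)
        best_report = best.to_dict()
        best_report["config_hash"] = chash
        (out / f"best_report_{assay}.json").write_text(json.dumps(best_report))
        best_summary[assay] = {
            "pretreatment": best.pretreatment,
            "selected_lv": best.selected_lv,
            "r_squared_prediction": best.prediction.r_squared,
            "rmsep": best.prediction.rmse,
            "rpd_prediction": best.prediction.rpd,
            "rpd_category": best.prediction.rpd_category,
        }
        outputs += [f"references_{assay}.csv", f"reports_{assay}.csv",
                    f"best_model_{assay}.json", f"split_{assay}.csv",
                    f"best_report_{assay}.json"]

    table = correlation_table(profiles, {a: references[a] for a in config.assays})
    table.to_csv(out / "correlations.csv")
    outputs.append("correlations.csv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "version": __version__,
        "seeds": {"generator": config.seed},
        "outputs": outputs,
        "best": best_summary,
    }
    (out / "run_log.json").write_text(json.dumps(manifest, indent=2))
    return manifest
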