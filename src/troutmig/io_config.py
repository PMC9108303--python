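"""Configuration files, yearly CSV output, checkpoints and run manifests.

Config files are flat YAML whose keys are the model's published
parameter names (hyphenated forms like ``anad-death-multiplierM`` and
``n-loci`` accepted verbatim); unknown keys are an error, never a
warning.  Yearly output is RFC-4180 CSV with a "." decimal point and an
empty field for undefined productivity.  Every output directory gets a
JSON manifest (resolved config, seed, package version, checksums) from
which a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import Population
from .experiments import ScenarioConfig
from .lifecycle import YearlyRecord


class ConfigError(ValueError):
    """A configuration file problem, naming the offending key."""


#: config-file key -> ScenarioConfig field
KEY_MAP = {
    "mortalityM": "mortalityM",
    "mortalityF": "mortalityF",
    "anad-death-multiplierM": "anad_death_multiplierM",
    "anad-death-multiplierF": "anad_death_multiplierF",
    "SurvRate": "SurvRate",
    "anad_quality": "anad_quality",
    "paras_quality": "paras_quality",
    "parasite-load": "parasite_load",
    "prop-parasites": "prop_parasites",
    "n-loci": "n_loci",
    "sneaker": "sneaker_on",
    "sneaker-threshold": "sneaker_threshold_ratio",
    "sneaker-boost": "sneaker_boost",
    "search-radius": "search_radius",
    "resident-quality": "resident_quality",
    "fecundity-alpha": "fecundity_alpha",
    "fecundity-beta": "fecundity_beta",
    "allele-frequency": "allele_frequency",
    "sigmaE-sq": "sigma_e_sq",
    "condition-variance": "condition_variance",
    "carrying-capacity": "carrying_capacity",
    "initial-population": "initial_population",
    "duration-years": "duration_years",
    "seed": "seed",
    "replicate-id": "replicate_id",
}
# underscore variants of the internal field names are accepted too
_ALL_KEYS = dict(KEY_MAP)
_ALL_KEYS.update({v: v for v in KEY_MAP.values()})


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse and validate a scenario config; empty file means all defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key: value mapping")
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> ScenarioConfig:
    resolved = {}
    for key, value in raw.items():
        if key not in _ALL_KEYS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        resolved[_ALL_KEYS[key]] = value
    try:
        config = ScenarioConfig(**resolved)
        # parameter range validation happens in the param constructors
        config.mortality_params()
        config.quality_params()
        config.architecture()
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    if not 0.0 <= config.prop_parasites <= 1.0:
        raise ConfigError(f"prop-parasites must be in [0, 1], got {config.prop_parasites}")
    if config.search_radius <= 0:
        raise ConfigError(f"search-radius must be > 0, got {config.search_radius}")
    return config


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# -- yearly CSV ---------------------------------------------------------


def write_yearly_csv(records: list[YearlyRecord], path: str | Path) -> None:
    """One header plus one row per year; undefined productivity is empty."""
    if not records:
        raise ValueError("refusing to write an empty record list")
    df = pd.DataFrame([r.to_dict() for r in records], columns=list(YearlyRecord.FIELDS))
    # %.17g guarantees binary round-trip of every float through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def read_yearly_csv(path: str | Path) -> list[YearlyRecord]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed yearly CSV {path}: {exc}") from exc
    missing = set(YearlyRecord.FIELDS) - set(df.columns)
    if missing:
        raise ValueError(f"yearly CSV {path} is missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            YearlyRecord(
                year=int(d["year"]),
                prop_anad_total=float(d["prop_anad_total"]),
                prop_anad_female=float(d["prop_anad_female"]),
                prop_anad_male=float(d["prop_anad_male"]),
                eggs_total=int(d["eggs_total"]),
                spawning_females=int(d["spawning_females"]),
                productivity=float(d["productivity"]),
                pop_size_freshwater=int(d["pop_size_freshwater"]),
                pop_size_marine=int(d["pop_size_marine"]),
                n_sneakers=int(d["n_sneakers"]),
                n_parasitised_returners=int(d["n_parasitised_returners"]),
            )
        )
    return records


# -- checkpoints --------------------------------------------------------


def write_checkpoint(pop: Population, path: str | Path) -> None:
    pop.to_dataframe().to_csv(path, index=False)


def read_checkpoint(path: str | Path) -> Population:
    return Population.from_dataframe(pd.read_csv(path))


# -- run manifest -------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path, config: ScenarioConfig, files: list[str | Path]
) -> Path:
    """Write ``manifest.json`` with the resolved config and output checksums."""
    outdir = Path(outdir)
    manifest = {
        "package": "troutmig",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.to_dict(),
        "resolved_sigma_e_sq": config.resolved_sigma_e_sq(),
        "checksums": {Path(f).name: _sha256(Path(f)) for f in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_manifest(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "manifest.json").read_text())


def config_from_manifest(outdir: str | Path) -> ScenarioConfig:
    raw = read_manifest(outdir)["config"]
    fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    return ScenarioConfig(**{k: v for k, v in raw.items() if k in fields})
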