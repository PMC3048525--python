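"""Structured-text (YAML) configuration with published defaults.

An empty file yields the complete default parameter set (every published
constant plus the documented calibration values), so runs need no
hand-typed numbers; any subset of keys may be overridden.  Unknown keys and
out-of-range values raise :class:`ConfigError` naming the offending key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__ as _pkg_version
from .networks import GeneId
from .promoters import PromoterArchitecture, ThermoConstants, \
    default_architectures
from .signaling import KineticRates, TransportParams
from .simulate import SimulationParams

__all__ = ["ConfigError", "load_config", "dump_config", "RunManifest"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration file error, naming the offending key."""


_SIM_KEYS = {"gal_out", "t_end", "burst", "gamma", "synthesis_scale",
             "det_skip_scale", "seed", "burst_fixed", "record_every",
             "scale_reference"}
_THERMO_KEYS = {"beta", "dG_bind", "dG_coop_44", "dG_coop_8080",
                "tf_ref_conc"}
_RATE_KEYS = {"k3", "k13", "k380", "k1380", "k480"}
_TRANSPORT_KEYS = {"a", "b_transport"}
_PROMOTER_KEYS = {"n_uas", "coop_pairs", "contributions", "constitutive"}
_TOP_KEYS = {"schema_version", "simulation", "thermo", "rates", "transport",
             "promoters"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}; "
                          f"allowed: {sorted(allowed)}")


def load_config(path: str | Path | None = None) -> SimulationParams:
    """Read a YAML config; omitted keys fall back to the defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version {version} unsupported "
                          f"(expected {SCHEMA_VERSION})")

    def section(name, allowed):
        sec = raw.get(name, {}) or {}
        if not isinstance(sec, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        _check_keys(sec, allowed, f"section '{name}'")
        return sec

    try:
        thermo = ThermoConstants(**section("thermo", _THERMO_KEYS))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"thermo: {e}") from e

    rates_raw = section("rates", _RATE_KEYS)
    try:
        rates = KineticRates(**{k: tuple(map(float, v))
                                for k, v in rates_raw.items()})
    except (TypeError, ValueError) as e:
        raise ConfigError(f"rates: {e}") from e

    try:
        transport = TransportParams(**section("transport", _TRANSPORT_KEYS))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"transport: {e}") from e

    archs = default_architectures()
    prom_raw = raw.get("promoters", {}) or {}
    by_name = {str(g): g for g in GeneId}
    _check_keys(prom_raw, set(by_name), "section 'promoters'")
    for name, spec in prom_raw.items():
        gene = by_name[name]
        _check_keys(spec or {}, _PROMOTER_KEYS, f"promoter '{name}'")
        base = archs[gene]
        try:
            archs[gene] = PromoterArchitecture(
                gene=gene,
                n_uas=int(spec.get("n_uas", base.n_uas)),
                coop_pairs=frozenset(
                    tuple(p) for p in spec.get(
                        "coop_pairs", [list(p) for p in base.coop_pairs])),
                contributions=tuple(spec.get("contributions",
                                             base.contributions)),
                constitutive=float(spec.get("constitutive",
                                            base.constitutive)))
        except (TypeError, ValueError) as e:
            raise ConfigError(f"promoter '{name}': {e}") from e

    sim = section("simulation", _SIM_KEYS)
    try:
        return SimulationParams(**sim, thermo=thermo, rates=rates,
                                transport=transport, architectures=archs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"simulation: {e}") from e


def dump_config(params: SimulationParams, path: str | Path | None = None
                ) -> str:
    """Serialize a full parameter set; load(dump(p)) round-trips."""
    archs = params.resolved_architectures()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "simulation": {
            "gal_out": params.gal_out, "t_end": params.t_end,
            "burst": params.burst, "gamma": params.gamma,
            "synthesis_scale": params.synthesis_scale,
            "det_skip_scale": params.det_skip_scale,
            "seed": params.seed, "burst_fixed": params.burst_fixed,
            "scale_reference": params.scale_reference,
        },
        "thermo": asdict(params.thermo),
        "rates": {k: list(getattr(params.rates, k))
                  for k in sorted(_RATE_KEYS)},
        "transport": asdict(params.transport),
        "promoters": {
            str(g): {"n_uas": a.n_uas,
                     "coop_pairs": sorted(list(p) for p in a.coop_pairs),
                     "contributions": list(a.contributions),
                     "constitutive": a.constitutive}
            for g, a in archs.items()},
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


class RunManifest:
    """Provenance of one CLI command's output files."""

    def __init__(self, command: str, seed: int | None,
                 config_path: str | Path | None = None):
        digest = None
        if config_path is not None:
            digest = hashlib.sha256(
                Path(config_path).read_bytes()).hexdigest()
        self.record = {
            "command": command,
            "seed": seed,
            "config_digest": digest,
            "galevo_version": _pkg_version,
            "created": datetime.now(timezone.utc).isoformat(),
            "outputs": [],
        }

    def add_output(self, path: str | Path, kind: str) -> None:
        self.record["outputs"].append({"path": str(path), "kind": kind})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.record, indent=1))


def write_results(obj, path: str | Path, fmt: str | None = None) -> Path:
    """Write a result object: TSV for tabular data, JSON for statistics.

    DataFrames and objects exposing ``as_frame``/``to_tsv`` (feature tables,
    equilibrium summaries) become TSV with stable column order and
    full-precision floats; mappings and sequences become JSON.  ``fmt``
    ("tsv"/"json") overrides the extension-based choice.  I/O failures
    carry the target path in the exception.
    """
    import pandas as pd

    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    try:
        if fmt == "tsv":
            if hasattr(obj, "to_tsv"):
                obj.to_tsv(path)
            else:
                frame = obj.as_frame() if hasattr(obj, "as_frame") else obj
                if not isinstance(frame, pd.DataFrame):
                    raise TypeError(f"cannot write {type(obj).__name__} "
                                    "as TSV")
                frame.to_csv(path, sep="\t", index=False)
        elif fmt == "json":
            path.write_text(json.dumps(obj, indent=1, default=float))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except OSError as e:
        raise OSError(f"failed writing results to {path}: {e}") from e
    return path
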