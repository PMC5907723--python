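"""Readers, writers and run configuration.

Internal coordinates are 0-based half-open everywhere; GFF3 output is
converted to 1-based inclusive, BED stays 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

from Bio import SeqIO

from .annotate import FlankParams, TIRParams
from .arrays import ArrayParams
from .comparative import AnchorParams, SiteParams
from .discovery import CandidateParams
from .families import ClusterParams, ProbeParams
from .ssr import SSRThresholds


class ConfigurationError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    assembly = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
    if not assembly:
        raise ConfigurationError(f"no sequences in FASTA {path}")
    return assembly


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _gff_attrs(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def write_gff3(path: str | Path, rows: list[dict]):
    """rows: dicts with scaffold, source, type, start, end (0-based
    half-open), score, strand, attrs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write("\t".join([
                r["scaffold"], r.get("source", "satarscan"), r["type"],
                str(r["start"] + 1), str(r["end"]),
                str(r.get("score", ".")), r.get("strand", "."), ".",
                _gff_attrs(r.get("attrs", {}))]) + "\n")


def write_tsv(path: str | Path, header: list[str], rows: list[list]):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults match the package-wide
    stage defaults. Round-trips losslessly through the plain-text
    key = value format."""

    assembly_a: str = ""
    assembly_b: str = ""
    out_dir: str = "satarscan_out"
    seed: int = 0
    log_level: str = "INFO"
    flank_probe_window: int = 400
    ssr: SSRThresholds = field(default_factory=SSRThresholds)
    discovery: CandidateParams = field(default_factory=CandidateParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    probing: ProbeParams = field(default_factory=ProbeParams)
    tir: TIRParams = field(default_factory=TIRParams)
    flanks: FlankParams = field(default_factory=FlankParams)
    arrays: ArrayParams = field(default_factory=ArrayParams)
    anchors: AnchorParams = field(default_factory=AnchorParams)
    sites: SiteParams = field(default_factory=SiteParams)


_BLOCKS = ("ssr", "discovery", "clustering", "probing", "tir", "flanks",
           "arrays", "anchors", "sites")


def _encode_value(value):
    if isinstance(value, frozenset):
        return ",".join(sorted(value))
    if isinstance(value, dict):
        return ",".join(f"{k}:{v}" for k, v in sorted(value.items()))
    return value


def _decode_value(text: str, template):
    if isinstance(template, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(template, int):
        return int(text)
    if isinstance(template, float):
        return float(text)
    if isinstance(template, frozenset):
        return frozenset(x for x in text.split(",") if x)
    if isinstance(template, dict):
        return {int(k): int(v) for k, v in
                (pair.split(":") for pair in text.split(",") if pair)}
    return text


def write_config(config: RunConfig, path: str | Path):
    lines = []
    for f in fields(config):
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            for sub in fields(value):
                lines.append(f"{f.name}.{sub.name} = "
                             f"{_encode_value(getattr(value, sub.name))}")
        else:
            lines.append(f"{f.name} = {_encode_value(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    config = RunConfig()
    overrides: dict[str, dict] = {b: {} for b in _BLOCKS}
    top: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"bad config line: {raw!r}")
        key, text = (p.strip() for p in line.split("=", 1))
        if "." in key:
            block, name = key.split(".", 1)
            if block not in _BLOCKS:
                raise ConfigurationError(f"unknown config block {block!r}")
            template = getattr(getattr(config, block), name)
            overrides[block][name] = _decode_value(text, template)
        else:
            if not hasattr(config, key):
                raise ConfigurationError(f"unknown config key {key!r}")
            top[key] = _decode_value(text, getattr(config, key))
    for block, kv in overrides.items():
        if kv:
            top[block] = dataclasses.replace(getattr(config, block), **kv)
    return dataclasses.replace(config, **top)


def write_manifest(path: str | Path, config: RunConfig, extra: dict):
    from . import __version__

    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, frozenset):
            return sorted(obj)
        return str(obj)

    payload = {"tool": "satarscan", "version": __version__,
               "config": dataclasses.asdict(config), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=default) + "\n")
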