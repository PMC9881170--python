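"""Readers and writers for the package's text formats.

Traces are two-column integer TSVs with comment-header metadata, results
are flat JSON records embedding the seed and a config digest, tables are
TSV. Footprints are read from BED6-like TSV or SAM; annotations, overlaps
and weights from headered TSV. All readers reject malformed files with
positioned error messages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError, InvalidInputError
from .photon_sim import ConfocalSimConfig, PhotonTrace, Species, SpeciesMix
from .riboseq import AlignedFootprint, MitoGeneModel, OverlapRegion, RpfTable

__all__ = [
    "write_trace", "read_trace",
    "load_sim_config", "config_digest", "write_result_json",
    "read_footprints_bed", "read_footprints_sam", "read_footprints",
    "read_annotation", "read_overlaps", "read_weights", "write_rpf_table",
]


def write_trace(trace: PhotonTrace, path) -> None:
    """Write a trace as TSV: header comments carry bin width and duration,
    then one (red, green) integer row per bin. Round-trips exactly."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bin_width={trace.bin_width!r}\n")
        fh.write(f"# duration={trace.duration!r}\n")
        fh.write("red\tgreen\n")
        np.savetxt(fh, np.column_stack([trace.counts_red, trace.counts_green]),
                   fmt="%d", delimiter="\t")


def read_trace(path) -> PhotonTrace:
    """Read a trace TSV written by :func:`write_trace`."""
    path = Path(path)
    meta: dict[str, float] = {}
    data_rows: list[tuple[int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError as exc:
                        raise InvalidInputError(
                            f"{path}:{lineno}: bad metadata value {val!r}"
                        ) from exc
                continue
            if line == "red\tgreen":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}")
            try:
                data_rows.append((int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-integer count in {line!r}") from exc
    if "bin_width" not in meta:
        raise InvalidInputError(f"{path}: missing '# bin_width=' header")
    if not data_rows:
        raise InvalidInputError(f"{path}: no data rows")
    arr = np.array(data_rows, dtype=np.int64)
    return PhotonTrace(meta["bin_width"], arr[:, 0], arr[:, 1])


_MIX_KEYS = ("label", "fraction", "carries_red", "carries_green")


def load_sim_config(path) -> tuple[ConfocalSimConfig, SpeciesMix]:
    """Load a flat YAML/JSON simulation config.

    Every :class:`ConfocalSimConfig` field is addressable as a top-level
    key; the species mixture is the ``species`` list of mappings with
    ``label``, ``fraction``, ``carries_red``, ``carries_green``.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InvalidConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise InvalidConfigError(f"{path}: config must be a mapping")
    species_raw = raw.pop("species", None)
    known = set(ConfocalSimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(
            f"{path}: unknown config keys {sorted(unknown)}")
    if "duration" not in raw:
        raise InvalidConfigError(f"{path}: 'duration' is required")
    config = ConfocalSimConfig(**raw)
    if species_raw is None:
        mix = SpeciesMix.positive_control()
    else:
        species = []
        for i, sp in enumerate(species_raw):
            bad = set(sp) - set(_MIX_KEYS)
            if bad:
                raise InvalidConfigError(
                    f"{path}: species[{i}]: unknown keys {sorted(bad)}")
            species.append(Species(
                label=str(sp.get("label", f"species{i}")),
                fraction=float(sp["fraction"]),
                carries_red=bool(sp.get("carries_red", False)),
                carries_green=bool(sp.get("carries_green", False)),
            ))
        mix = SpeciesMix(species)
    return config, mix


def config_digest(payload: dict) -> str:
    """Stable short digest of a parameter mapping, for provenance."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_result_json(path, result: dict, *, seed: int | None,
                      params: dict) -> None:
    """Write a flat JSON result record embedding the seed and a digest of
    the parameters that produced it."""
    record = dict(result)
    record["seed"] = seed
    record["config_digest"] = config_digest(params)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def read_footprints_bed(path) -> list[AlignedFootprint]:
    """Read footprints from BED6-like TSV (chrom, start, end, name, score,
    strand). The 5' end is ``start`` on +, ``end - 1`` on -."""
    path = Path(path)
    footprints = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise InvalidInputError(
                    f"{path}:{lineno}: BED6 needs 6 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-integer start/end") from exc
            strand = parts[5]
            if strand not in ("+", "-"):
                raise InvalidInputError(
                    f"{path}:{lineno}: bad strand {strand!r}")
            if end <= start:
                raise InvalidInputError(
                    f"{path}:{lineno}: empty interval [{start}, {end})")
            five = start if strand == "+" else end - 1
            footprints.append(AlignedFootprint(five, end - start, strand))
    return footprints


def read_footprints_sam(path) -> list[AlignedFootprint]:
    """Read footprints from SAM; the 5' end is the leftmost aligned base
    on +, the rightmost on -. Unmapped records are skipped."""
    import pysam

    footprints = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            start, end = rec.reference_start, rec.reference_end
            if end is None or end <= start:
                continue
            strand = "-" if rec.is_reverse else "+"
            five = start if strand == "+" else end - 1
            footprints.append(AlignedFootprint(five, end - start, strand))
    return footprints


def read_footprints(path) -> list[AlignedFootprint]:
    """Dispatch on extension: .sam -> SAM reader, anything else BED6."""
    if str(path).endswith(".sam"):
        return read_footprints_sam(path)
    return read_footprints_bed(path)


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise InvalidInputError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"{path}: missing required columns {sorted(missing)} "
            f"(found {list(df.columns)})")
    return df


def read_annotation(path) -> list[MitoGeneModel]:
    """Annotation TSV with columns gene, start, stop_first, strand."""
    df = _read_tsv(path, ("gene", "start", "stop_first", "strand"))
    return [MitoGeneModel(str(r.gene), int(r.start), int(r.stop_first),
                          str(r.strand)) for r in df.itertuples()]


def read_overlaps(path) -> list[OverlapRegion]:
    """Overlap TSV with columns gene_a, gene_b, start, end."""
    df = _read_tsv(path, ("gene_a", "gene_b", "start", "end"))
    return [OverlapRegion((str(r.gene_a), str(r.gene_b)), int(r.start),
                          int(r.end)) for r in df.itertuples()]


def read_weights(path) -> dict[str, float]:
    """Per-gene weight TSV with columns gene, weight."""
    df = _read_tsv(path, ("gene", "weight"))
    return {str(r.gene): float(r.weight) for r in df.itertuples()}


def write_rpf_table(table: RpfTable, path) -> None:
    """Write an RpfTable as TSV (gene, count, percent, ratio_to_reference)
    with excluded/unassigned tallies in header comments."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# excluded={table.excluded}\n")
        fh.write(f"# unassigned={table.unassigned}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)
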