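"""Readers and writers for the pipeline's plain-text formats.

Formats: TSV contact profiles (anchor_id, locus, separation_kb,
frequency[, sem]), BED4 interval tracks (TADs; epigenetic classes with
red/black/blue/green aliases for D1-D4), contact maps as COO triples with
a bin-size header or as a dense whitespace matrix, and JSON fit results /
run manifests.  Coordinates are BED-style 0-based half-open; separations
are written with 3-decimal kb precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import ContactProfile, FitResult, profile_from_arrays
from .virtual3c import CLASS_ALIASES, BinnedContactMap, IntervalAnnotation

__all__ = [
    "read_contact_profile",
    "write_contact_profile",
    "read_bed_annotation",
    "write_bed_annotation",
    "read_contact_map",
    "write_contact_map",
    "write_fit_table",
    "fit_result_to_json",
    "write_manifest",
]

PROFILE_COLUMNS = ("anchor_id", "locus", "separation_kb", "frequency")


def read_contact_profile(path, **profile_kwargs) -> ContactProfile:
    """Read a TSV contact profile; the ``sem`` column is optional.

    Rows with non-positive or unparseable separations are rejected with
    an error naming the offending line (1-based, counting the header)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("separation_kb", "frequency") + (("sem",) if "sem" in df else ()):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"{path}: unparseable {col} value on line {line}")
        df[col] = pd.to_numeric(df[col])
    nonpos = df["separation_kb"] <= 0
    if nonpos.any():
        line = int(df.index[nonpos][0]) + 2
        raise ValueError(f"{path}: non-positive separation_kb on line {line}")
    sems = df["sem"].to_numpy(dtype=float) if "sem" in df.columns else None
    profile = profile_from_arrays(
        df["separation_kb"].to_numpy(dtype=float),
        df["frequency"].to_numpy(dtype=float),
        sems, **profile_kwargs)
    obs = tuple(
        type(o)(separation=o.separation, frequency=o.frequency, sem=o.sem,
                anchor_id=str(a), locus=str(loc))
        for o, a, loc in zip(profile.observations, df["anchor_id"], df["locus"])
    )
    return ContactProfile(observations=obs, cell_type=profile.cell_type,
                          tad_class=profile.tad_class, fixed_L=profile.fixed_L)


def write_contact_profile(profile: ContactProfile, path) -> None:
    rows = []
    for o in profile.observations:
        row = {"anchor_id": o.anchor_id or "anchor", "locus": o.locus or "locus",
               "separation_kb": f"{o.separation:.3f}",
               "frequency": repr(float(o.frequency))}
        if o.sem is not None:
            row["sem"] = repr(float(o.sem))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bed_annotation(path, kind: str = "tad") -> IntervalAnnotation:
    """Read a BED4 track (0-based half-open).  kind="epigenetic"
    normalizes colour aliases (red→D1, black→D2, blue→D3, green→D4);
    overlapping intervals within the track are an error."""
    if kind not in ("tad", "epigenetic"):
        raise ValueError("kind must be 'tad' or 'epigenetic'")
    ivs = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: BED4 needs 4 columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: bad coordinates") from exc
            if start_i >= end_i:
                raise ValueError(f"{path}: line {ln}: start >= end")
            if kind == "epigenetic":
                name = CLASS_ALIASES.get(name.lower(), name)
            ivs.append((chrom, start_i, end_i, name))
    return IntervalAnnotation(tuple(ivs))


def write_bed_annotation(annotation: IntervalAnnotation, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in annotation.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_contact_map(path) -> BinnedContactMap:
    """Read a contact map: COO triples under a ``# bin_size_kb=`` header
    (columns chrom, bin_i, bin_j, value) or a dense whitespace matrix.
    Negative values are rejected."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "bin_size_kb" in first:
        bin_size = float(first.split("=", 1)[1])
        df = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
        required = {"chrom", "bin_i", "bin_j", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: COO map needs columns {sorted(required)}")
        if df.empty:
            raise ValueError(f"{path}: empty contact map")
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError(f"{path}: one chromosome per map file, got {list(chroms)}")
        if (df["value"] < 0).any():
            raise ValueError(f"{path}: negative contact values")
        n_bins = int(max(df["bin_i"].max(), df["bin_j"].max())) + 1
        return BinnedContactMap.from_coo(
            str(chroms[0]), n_bins, df["bin_i"], df["bin_j"], df["value"],
            bin_size_kb=bin_size)
    # dense whitespace matrix; chromosome name and bin size from defaults
    dense = np.loadtxt(path)
    if np.any(dense < 0):
        raise ValueError(f"{path}: negative contact values")
    return BinnedContactMap.from_dense(path.stem, dense)


def write_contact_map(cmap: BinnedContactMap, path) -> None:
    df = cmap.to_coo_frame()
    with open(path, "w") as fh:
        fh.write(f"# bin_size_kb={cmap.bin_size_kb:g}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_fit_table(fits, path) -> None:
    """Flat TSV with one row per fit (model, params, stderr, R², Sh)."""
    fits = [fits] if isinstance(fits, FitResult) else list(fits)
    pd.DataFrame([f.to_row() for f in fits]).to_csv(path, sep="\t", index=False)


def fit_result_to_json(fit: FitResult) -> str:
    payload = {
        "model_id": fit.model_id, "params": fit.params, "stderr": fit.stderr,
        "r_squared": fit.r_squared, "ssr": fit.ssr, "n_obs": fit.n_obs,
        "converged": fit.converged, "n_starts": fit.n_starts,
        "sh_kb": fit.sh_kb,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def write_manifest(config_dict: dict, path) -> None:
    """Serialize the complete run configuration (including the seed) so a
    run can be reproduced bit-for-bit."""
    import helix3c

    payload = {"helix3c_version": helix3c.__version__, "config": config_dict}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
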