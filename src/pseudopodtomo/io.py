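"""File formats: MRC volumes and TSV / STAR record tables.

Volumes are written as MRC2014 mode-2 maps with the pixel size in the
header (Angstrom, converted from the package's nm convention at the
boundary). Tables are pandas DataFrames round-tripped losslessly through
either a tab-separated file or a single-block STAR loop; each record type
has a declared schema with mandatory columns and value validators.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .volume import TomogramVolume


class FormatError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# MRC


def write_mrc(volume: TomogramVolume, path: str | Path) -> None:
    """Write a volume as an MRC2014 mode-2 (float32) map.

    The grid is stored x-fastest; the cell encodes the pixel size in
    Angstrom."""
    grid_xyz = np.ascontiguousarray(volume.grid.T.astype(np.float32))  # (nx, ny, nz)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(grid_xyz)
    nx, ny, nz = grid_xyz.shape
    a = volume.pixel_size * 10.0  # nm -> Angstrom
    m.grid.unit_cell = gemmi.UnitCell(nx * a, ny * a, nz * a, 90, 90, 90)
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path, tilt_range: float | None = None) -> TomogramVolume:
    """Read an MRC/CCP4 map into a TomogramVolume (pixel size in nm).

    Raises FormatError on unreadable or anisotropic-voxel files; no
    partial object escapes."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"not a readable MRC/CCP4 map: {path} ({exc})") from exc
    arr = np.array(m.grid, copy=True)            # (nx, ny, nz)
    spacing = np.asarray(m.grid.spacing)          # Angstrom per voxel
    if spacing[0] <= 0:
        raise FormatError(f"non-positive pixel size in {path}")
    if not np.allclose(spacing, spacing[0], rtol=1e-3):
        raise FormatError(f"anisotropic voxels not supported: {spacing}")
    return TomogramVolume(np.ascontiguousarray(arr.T), float(spacing[0]) / 10.0,
                          tilt_range=tilt_range)


# ---------------------------------------------------------------------------
# record tables

_VOTE_VALUES = {-1, 0, 1}

TABLE_SCHEMAS: dict[str, dict] = {
    "traces": {
        "required": ["filament_id", "point_index", "x", "y", "z"],
        "optional": ["true_polarity"],
    },
    "segments": {
        "required": ["filament_id", "segment_index", "x", "y", "z",
                     "tx", "ty", "tz"],
        "optional": ["inplane_angle", "class_id", "polarity_vote",
                     "vote_score", "flags"],
        "validators": {
            "polarity_vote": lambda s: set(pd.to_numeric(s).dropna().astype(int)) <= _VOTE_VALUES,
        },
    },
    "calls": {
        "required": ["filament_id", "n_votes", "n_plus", "n_minus",
                     "majority_fraction", "confidence_p", "call"],
        "optional": ["tomogram_id"],
    },
    "picks": {
        "required": ["x", "y", "z", "nx", "ny", "nz",
                     "height_above_support", "normal_tilt", "kept"],
        "optional": ["reason", "density"],
    },
    "summary": {
        "required": ["tomogram_id", "resolved_count", "tip_ward_fraction"],
        "optional": ["n_filaments", "unresolved_count", "tip_ward_count",
                     "cell_ward_count", "tip_ward_fraction_of_total"],
    },
    "fsc": {
        "required": ["frequency_inv_nm", "correlation"],
        "optional": [],
    },
}


def _validate(df: pd.DataFrame, kind: str) -> None:
    if kind not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    schema = TABLE_SCHEMAS[kind]
    for col in schema["required"]:
        if col not in df.columns:
            raise SchemaError(f"{kind} table is missing mandatory column {col!r}")
    for col, check in schema.get("validators", {}).items():
        if col in df.columns and not check(df[col]):
            raise SchemaError(f"{kind} table column {col!r} contains invalid values")


def write_table(df: pd.DataFrame, path: str | Path, kind: str,
                dialect: str = "tsv") -> None:
    """Write a validated record table as TSV or a one-block STAR loop."""
    _validate(df, kind)
    path = Path(path)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "star":
        doc = gemmi.cif.Document()
        block = doc.add_new_block(kind)
        loop = block.init_loop(f"_{kind}.", list(df.columns))
        for row in df.itertuples(index=False):
            loop.add_row([_star_cell(v) for v in row])
        doc.write_file(str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _star_cell(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "."
    s = str(v)
    return gemmi.cif.quote(s) if (s == "" or any(c.isspace() for c in s)) else s


def read_table(path: str | Path, kind: str, dialect: str | None = None
               ) -> pd.DataFrame:
    """Read a TSV or STAR record table back into a validated DataFrame.

    ``dialect=None`` sniffs from the extension (.star vs anything else).
    """
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix.lower() == ".star" else "tsv"
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "star":
        try:
            doc = gemmi.cif.read_file(str(path))
        except (RuntimeError, ValueError) as exc:
            raise FormatError(f"not a readable STAR file: {path} ({exc})") from exc
        block = doc[0]
        prefix = f"_{block.name}."
        cols: dict[str, list[str]] = {}
        for item in block:
            if item.loop is not None:
                for tag in item.loop.tags:
                    name = tag[len(prefix):] if tag.startswith(prefix) else tag.lstrip("_")
                    cols[name] = list(block.find_loop(tag))
                break
        if not cols:
            raise FormatError(f"no loop found in STAR file {path}")
        df = pd.DataFrame({k: pd.Series(v).replace(".", np.nan)
                           for k, v in cols.items()})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _coerce_numeric(df)
    _validate(df, kind)
    return df


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        s = df[col]
        if s.dtype == object:
            num = pd.to_numeric(s, errors="coerce")
            s = num if num.notna().all() and len(s) else s
        out[col] = s
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# record <-> frame converters


def traces_to_frame(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for i, p in enumerate(tr.points):
            rows.append({"filament_id": tr.filament_id, "point_index": i,
                         "x": p[0], "y": p[1], "z": p[2],
                         "true_polarity": tr.true_polarity})
    return pd.DataFrame(rows)


def frame_to_traces(df: pd.DataFrame):
    from .scene import FilamentTrace
    traces = []
    for fid, grp in df.groupby("filament_id", sort=True):
        grp = grp.sort_values("point_index")
        pol = None
        if "true_polarity" in grp.columns and grp["true_polarity"].notna().all():
            pol = int(grp["true_polarity"].iloc[0])
        traces.append(FilamentTrace(int(fid), grp[["x", "y", "z"]].to_numpy(float),
                                    None, pol))
    return traces


def segments_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "filament_id": r.filament_id, "segment_index": r.segment_index,
            "x": r.center[0], "y": r.center[1], "z": r.center[2],
            "tx": r.tangent[0], "ty": r.tangent[1], "tz": r.tangent[2],
            "inplane_angle": r.inplane_angle,
            "class_id": r.class_id if r.class_id is not None else -1,
            "polarity_vote": r.polarity_vote, "vote_score": r.vote_score,
            "flags": ";".join(r.flags) if r.flags else "",
        })
    return pd.DataFrame(rows)


def picks_to_frame(picks) -> pd.DataFrame:
    rows = []
    for p in picks:
        rows.append({
            "x": p.position[0], "y": p.position[1], "z": p.position[2],
            "nx": p.normal[0], "ny": p.normal[1], "nz": p.normal[2],
            "height_above_support": p.height_above_support,
            "normal_tilt": p.normal_tilt, "kept": int(p.kept),
            "reason": p.reason or "", "density": p.density,
        })
    return pd.DataFrame(rows)


def calls_to_frame(calls_by_tomo: dict) -> pd.DataFrame:
    rows = []
    for tomo_id, calls in calls_by_tomo.items():
        for fid, c in calls.items():
            rows.append({
                "tomogram_id": tomo_id, "filament_id": fid,
                "n_votes": c.n_votes, "n_plus": c.n_plus, "n_minus": c.n_minus,
                "majority_fraction": c.majority_fraction,
                "confidence_p": c.confidence_p, "call": c.call,
            })
    return pd.DataFrame(rows)
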