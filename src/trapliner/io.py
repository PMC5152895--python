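"""Input validation, file formats, run manifests and report assembly.

Formats are plain text throughout: telemetry and vegetation plots as CSV,
land cover as an ESRI ASCII grid (integer codes 1=forest, 2=pasture,
3=other matrix) or GeoJSON polygons with a ``class`` property (rasterized
on load), streams as GeoJSON LineString/MultiLineString.  Coordinates are
planar meters; any reprojection happens before ingest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .landscape import CLASS_CODES, FOREST, OTHER_MATRIX, PASTURE, LandCoverMap, StreamNetwork
from .pointscale import DISTANCE_CLASSES

FIX_COLUMNS = ("bird_id", "x", "y", "timestamp", "obs_dist_class", "gps_acc_m")
CLASS_NAMES = {"forest": FOREST, "pasture": PASTURE, "other": OTHER_MATRIX,
               "other_matrix": OTHER_MATRIX}


class ValidationError(ValueError):
    """Carries every violation found, not only the first."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("input validation failed:\n- " + "\n- ".join(problems))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fixes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in df.columns and c != "gps_acc_m"]
    if missing:
        raise ValidationError([f"fixes CSV missing column {c!r}" for c in missing])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_fixes_csv(fixes: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FIX_COLUMNS if c in fixes.columns]
    fixes[cols + [c for c in fixes.columns if c not in cols]].to_csv(path, index=False)


def write_ascii_grid(lcmap: LandCoverMap, path: str | Path) -> None:
    """ESRI ASCII grid; row 0 of the file is the map's top row."""
    x0, y0 = lcmap.origin
    header = (
        f"ncols {lcmap.ncols}\nnrows {lcmap.nrows}\nxllcorner {x0}\nyllcorner {y0}\n"
        f"cellsize {lcmap.resolution}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, lcmap.grid[::-1], fmt="%d")


def read_ascii_grid(path: str | Path) -> LandCoverMap:
    with open(path) as fh:
        hdr = {}
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) == 2 and not line[0].lstrip("-").replace(".", "").isdigit():
                hdr[line[0].lower()] = float(line[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        grid = np.loadtxt(fh).astype(int)
    grid = np.atleast_2d(grid)[::-1]
    return LandCoverMap(
        grid=grid,
        resolution=hdr.get("cellsize", 1.0),
        origin=(hdr.get("xllcorner", 0.0), hdr.get("yllcorner", 0.0)),
    )


def read_streams_geojson(path: str | Path) -> StreamNetwork:
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    lines: list[np.ndarray] = []
    for f in feats:
        geom = f.get("geometry", f)
        if geom["type"] == "LineString":
            lines.append(np.asarray(geom["coordinates"], float))
        elif geom["type"] == "MultiLineString":
            lines.extend(np.asarray(c, float) for c in geom["coordinates"])
        else:
            raise ValidationError([f"stream geometry must be (Multi)LineString, got {geom['type']}"])
    return StreamNetwork(tuple(lines))


def write_streams_geojson(streams: StreamNetwork, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": {"type": "LineString", "coordinates": p.tolist()},
        }
        for p in streams.polylines
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_landcover_geojson(
    path: str | Path, resolution: float = 5.0, fill: int = PASTURE
) -> LandCoverMap:
    """Rasterize GeoJSON land-cover polygons (``class`` property names the
    cover type) onto a grid at ``resolution``; unclassified cells get
    ``fill``."""
    data = json.loads(Path(path).read_text())
    feats = data["features"]
    geoms, codes = [], []
    for f in feats:
        cls = str(f["properties"].get("class", "")).lower()
        if cls not in CLASS_NAMES:
            raise ValidationError([f"unknown land-cover class {cls!r} in {path}"])
        geoms.append(shapely.geometry.shape(f["geometry"]))
        codes.append(CLASS_NAMES[cls])
    xmin, ymin, xmax, ymax = shapely.union_all(geoms).bounds
    ncols = max(1, int(np.ceil((xmax - xmin) / resolution)))
    nrows = max(1, int(np.ceil((ymax - ymin) / resolution)))
    xs = xmin + (np.arange(ncols) + 0.5) * resolution
    ys = ymin + (np.arange(nrows) + 0.5) * resolution
    X, Y = np.meshgrid(xs, ys)
    grid = np.full((nrows, ncols), fill, dtype=np.int8)
    for geom, code in zip(geoms, codes):
        inside = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(nrows, ncols)
        grid[inside] = code
    return LandCoverMap(grid=grid, resolution=resolution, origin=(xmin, ymin))


def read_landcover(path: str | Path, resolution: float = 5.0) -> LandCoverMap:
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return read_landcover_geojson(path, resolution=resolution)
    return read_ascii_grid(path)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(
    fixes: pd.DataFrame, lcmap: LandCoverMap, streams: StreamNetwork | None = None
) -> list[str]:
    """Schema and consistency checks; raises ValidationError listing every
    violation at once, returns the (empty) problem list when clean."""
    problems: list[str] = []
    for c in ("bird_id", "x", "y", "timestamp", "obs_dist_class"):
        if c not in fixes.columns:
            problems.append(f"fixes missing column {c!r}")
    if not problems:
        bad_cls = set(fixes["obs_dist_class"]) - set(DISTANCE_CLASSES)
        if bad_cls:
            problems.append(f"unknown observer-distance classes: {sorted(bad_cls)}")
        if not np.isfinite(fixes[["x", "y"]].to_numpy(float)).all():
            problems.append("non-finite coordinates in fixes")
        ts = pd.to_datetime(fixes["timestamp"])
        for bird, sub in fixes.assign(_ts=ts).groupby("bird_id"):
            t = sub["_ts"].to_numpy()
            srt = sub["_ts"].sort_values().to_numpy()
            dup = pd.Series(srt).duplicated()
            if dup.any():
                problems.append(f"bird {bird}: duplicate timestamp at sorted row {int(dup.idxmax())}")
            if not (t[:-1] <= t[1:]).all():
                row = int(np.flatnonzero(t[:-1] > t[1:])[0]) + 1
                problems.append(f"bird {bird}: non-monotone timestamp at row {row}")
        on_map = lcmap.contains(fixes["x"].to_numpy(float), fixes["y"].to_numpy(float))
        n_off = int((~on_map).sum())
        if n_off:
            problems.append(f"{n_off} fixes outside the land-cover map extent")
    bad_codes = sorted(set(np.unique(lcmap.grid)) - set(CLASS_CODES))
    if bad_codes:
        problems.append(f"unknown land-cover class codes: {bad_codes}")
    if streams is not None:
        bx0, by0, bx1, by1 = lcmap.bounds
        for i, p in enumerate(streams.polylines):
            if (p[:, 0] < bx0 - 1e-6).any() or (p[:, 0] > bx1 + 1e-6).any() \
               or (p[:, 1] < by0 - 1e-6).any() or (p[:, 1] > by1 + 1e-6).any():
                problems.append(f"stream {i} has vertices outside the map extent")
    if problems:
        raise ValidationError(problems)
    return problems


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record: config hash, seeds, input checksums, and
    per-stage record counts."""

    config_hash: str = ""
    seeds: dict = dc_field(default_factory=dict)
    input_checksums: dict = dc_field(default_factory=dict)
    counts: dict = dc_field(default_factory=dict)
    versions: dict = dc_field(default_factory=dict)

    @staticmethod
    def hash_config(config: dict) -> str:
        return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def add_input(self, name: str, path: str | Path) -> None:
        self.input_checksums[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def to_json(self) -> str:
        from . import __version__

        self.versions.setdefault("trapliner", __version__)
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def build_report(
    ssf_fits: list | None = None,
    ssf_ranking: pd.DataFrame | None = None,
    second_stage_tables: dict | None = None,
    point_gls: object | None = None,
    paired_fit: object | None = None,
    homerange_summary: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble tidy output tables from whatever stages ran.

    The SSF table carries the columns Model, Variable, Coeff., SE, CI low,
    CI high, OR, AICc, dAICc; the second-stage table SSF variable,
    Variable, Coefficient, SE, P.  Stages that did not run are omitted
    (with a note key).
    """
    report: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    if ssf_fits:
        delta = {}
        if ssf_ranking is not None:
            delta = dict(zip(ssf_ranking["model"], ssf_ranking["delta_aicc"]))
        rows = []
        for f in ssf_fits:
            for var, r in f.params.iterrows():
                rows.append(
                    {
                        "Model": f.model,
                        "Variable": var,
                        "Coeff.": r["coef"],
                        "SE": r["se"],
                        "CI low": r["ci_low"],
                        "CI high": r["ci_high"],
                        "OR": r["or"],
                        "AICc": f.aicc,
                        "dAICc": delta.get(f.model, np.nan),
                    }
                )
        report["ssf"] = pd.DataFrame(rows)
    else:
        notes.append("SSF stage absent")
    if second_stage_tables:
        rows = []
        for ssf_var, tab in second_stage_tables.items():
            for var, r in tab.iterrows():
                rows.append(
                    {"SSF variable": ssf_var, "Variable": var,
                     "Coefficient": r["coef"], "SE": r["se"], "P": r["p"]}
                )
        report["second_stage"] = pd.DataFrame(rows)
    if point_gls is not None:
        tab = point_gls.params.reset_index(names="Variable")
        tab.insert(0, "Structure", point_gls.structure)
        report["point_gls"] = tab
    if paired_fit is not None:
        report["paired_logistic"] = paired_fit.params.reset_index(names="Variable")
    if homerange_summary is not None and len(homerange_summary):
        report["homerange"] = homerange_summary
    else:
        notes.append("home-range stage absent")
    if notes:
        report["notes"] = pd.DataFrame({"note": notes})
    return report


def write_report(report: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, tab in report.items():
        tab.to_csv(outdir / f"{name}.csv", index=False)
        summary[name] = len(tab)
    (outdir / "report.json").write_text(json.dumps(
        {k: v.to_dict(orient="records") for k, v in report.items()}, indent=2, default=str
    ))
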