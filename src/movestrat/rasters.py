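"""Plain-text raster persistence (ESRI ASCII grid) for covariate stacks and ODs.

Layers are written as ``<covariate>_<year>.asc`` (static covariates as
``<covariate>.asc``) alongside a ``manifest.json`` recording the grid, years
and covariate kinds, so a stack round-trips without external metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .occurrence import GridSpec, OccurrenceDistribution
from .simulate import CovariateStack


def write_ascii_grid(path, array: np.ndarray, grid: GridSpec) -> None:
    """Write one layer; rows are flipped so the file reads north-up."""
    array = np.asarray(array)
    header = (f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
              f"xllcorner {grid.x0:.6f}\nyllcorner {grid.y0:.6f}\n"
              f"cellsize {grid.cell_size:.6f}\nNODATA_value -9999\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array[::-1], fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        array = np.loadtxt(fh)
    grid = GridSpec(x0=hdr["xllcorner"], y0=hdr["yllcorner"],
                    cell_size=hdr["cellsize"],
                    n_cols=int(hdr["ncols"]), n_rows=int(hdr["nrows"]))
    return np.atleast_2d(array)[::-1].copy(), grid


def write_stack(stack: CovariateStack, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cell_size": stack.grid.cell_size,
        "years": stack.years,
        "covariates": {},
    }
    for name in stack.covariates:
        if stack.is_static(name):
            fname = f"{name}.asc"
            write_ascii_grid(directory / fname, stack.layers[name], stack.grid)
            manifest["covariates"][name] = {"kind": "static", "files": [fname]}
        else:
            files = []
            for i, year in enumerate(stack.years):
                fname = f"{name}_{year}.asc"
                write_ascii_grid(directory / fname, stack.layers[name][i],
                                 stack.grid)
                files.append(fname)
            manifest["covariates"][name] = {"kind": "annual", "files": files}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_stack(directory) -> CovariateStack:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    layers: dict[str, np.ndarray] = {}
    grid = None
    for name, meta in manifest["covariates"].items():
        arrays = []
        for fname in meta["files"]:
            arr, grid = read_ascii_grid(directory / fname)
            arrays.append(arr)
        layers[name] = arrays[0] if meta["kind"] == "static" \
            else np.stack(arrays)
    return CovariateStack(grid=grid, layers=layers,
                          years=list(manifest["years"]))


def write_od(od: OccurrenceDistribution, path) -> None:
    """Persist an OD as an ASCII grid; the window id rides in a sidecar line."""
    write_ascii_grid(path, od.mass, od.grid)
    with open(path, "a") as fh:
        fh.write(f"# window_id {od.window_id}\n")


def read_od(path) -> OccurrenceDistribution:
    window_id = ""
    with open(path) as fh:
        lines = fh.readlines()
    if lines and lines[-1].startswith("# window_id"):
        window_id = lines[-1].split(maxsplit=2)[-1].strip()
        if window_id == "window_id":
            window_id = ""
        lines = lines[:-1]
    hdr = {}
    for line in lines[:6]:
        key, val = line.split()
        hdr[key.lower()] = float(val)
    array = np.loadtxt(lines[6:])
    grid = GridSpec(x0=hdr["xllcorner"], y0=hdr["yllcorner"],
                    cell_size=hdr["cellsize"],
                    n_cols=int(hdr["ncols"]), n_rows=int(hdr["nrows"]))
    return OccurrenceDistribution(grid=grid,
                                  mass=np.atleast_2d(array)[::-1].copy(),
                                  window_id=window_id)
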