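"""CSV/JSON readers and writers for cohort tables and analysis reports.

Conventions: traits and RGB triplets travel as plain CSV with a
``sample_id`` column; spectra travel as wide CSV (one row per sample, one
column per wavelength in integer nm); correlogram grids are matrix CSV
with wavelength axis headers plus a JSON sidecar of the ranked best pairs.

Every file written here starts with a comment line embedding the
config hash and seed of the run that produced it, so outputs are
traceable; readers skip ``#`` comment lines, making the round trip exact
to full float precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "write_traits",
    "read_traits",
    "write_spectra",
    "read_spectra",
    "write_correlogram",
    "write_best_pairs",
    "write_manifest",
    "load_config",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_line(meta: dict | None) -> str:
    meta = meta or {}
    parts = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# ripescan {parts}".rstrip() + "\n"


def write_csv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    """Write a DataFrame as CSV with a traceability comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_line(meta))
        # default float formatting is the shortest exact round-trip repr
        df.to_csv(fh, index=index, lineterminator="\n")


def read_csv(path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (comment lines skipped)."""
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, comment="#", **kwargs)


def write_traits(traits: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_csv(traits, path, meta=meta)


def read_traits(path) -> pd.DataFrame:
    return read_csv(path)


def write_spectra(spectra: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Wide spectra CSV: header = wavelengths (nm), plus a sample_id column."""
    out = spectra.copy()
    if "sample_id" not in out.columns:
        out.insert(0, "sample_id", [f"s{i:03d}" for i in range(len(out))])
    write_csv(out, path, meta=meta)


def read_spectra(path) -> pd.DataFrame:
    """Read wide spectra CSV; wavelength columns become integers."""
    df = read_csv(path)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.columns = [int(float(c)) for c in df.columns]
    return df


def write_correlogram(result, path_prefix, meta: dict | None = None) -> None:
    """Export a correlogram: matrix CSV plus JSON of ranked best pairs."""
    grid = result.to_frame()
    write_csv(grid, Path(str(path_prefix) + "_grid.csv"), meta=meta, index=True)
    write_best_pairs(result, Path(str(path_prefix) + "_best.json"), meta=meta)


def write_best_pairs(result, path, meta: dict | None = None) -> None:
    payload = {
        "trait": result.trait,
        "n_samples": result.n_samples,
        "meta": meta or {},
        "best_pairs": [
            {"lambda1": l1, "lambda2": l2, "r2": r2} for l1, l2, r2 in result.best_pairs
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(path, config: dict, outputs: list[str]) -> None:
    """Record the run configuration, its hash and the produced files."""
    payload = {
        "config": config,
        "config_hash": config_hash(config),
        "outputs": sorted(outputs),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def plot_correlogram(result, path, cmap: str = "viridis") -> None:
    """Optional convenience: render the R2 grid as a contour-style map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    wl = result.wavelengths
    im = ax.pcolormesh(wl, wl, result.r2_grid.T, cmap=cmap, vmin=0, vmax=1)
    ax.set_xlabel("numerator wavelength (nm)")
    ax.set_ylabel("denominator wavelength (nm)")
    ax.set_title(f"R$^2$ of {result.trait} ~ R$_{{\\lambda_1}}$/R$_{{\\lambda_2}}$")
    fig.colorbar(im, ax=ax, label="R$^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
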