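"""Dataset I/O, run configuration and fixture generation.

Datasets are delimited text files (CSV/TSV) with a header containing the
study and auxiliary columns (``y`` and ``x`` by default).  Every run writes
its result table as CSV plus a JSON metadata sidecar recording the seed,
mode, estimator variants, theory path, quantile rule and package version,
so outputs are traceable and byte-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .moments import summarize_population

__all__ = ["load_dataset", "RunConfig", "write_outputs", "make_fixture"]

log = logging.getLogger("auxmean")


def load_dataset(
    path: str | Path,
    *,
    y_col: str = "y",
    x_col: str = "x",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Load paired (y, x) vectors from a delimited text file with a header.

    Rows with a missing value in either column are dropped pairwise and the
    drop count is logged and recorded in the returned provenance dict.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (y_col, x_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} "
                             f"(available: {list(df.columns)})")
    sub = df[[y_col, x_col]].apply(pd.to_numeric, errors="coerce")
    n_raw = len(sub)
    sub = sub.dropna()
    n_dropped = n_raw - len(sub)
    if n_dropped:
        log.info("%s: dropped %d incomplete rows of %d", path, n_dropped, n_raw)
    if len(sub) < 2:
        raise ValueError(f"{path}: fewer than 2 complete rows")
    prov = {
        "path": str(path), "y_col": y_col, "x_col": x_col,
        "rows": len(sub), "rows_dropped": n_dropped,
        "loaded_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    return sub[y_col].to_numpy(float), sub[x_col].to_numpy(float), prov


@dataclass
class RunConfig:
    """One reproducible run: mode, inputs, scenario and output location."""

    mode: str                       # {estimate|theory|simulate|tune}
    out_dir: Path
    seed: int = 0
    input_path: Path | None = None
    summary_overrides: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("estimate", "theory", "simulate", "tune"):
            raise ValueError(f"invalid mode {self.mode!r}")
        self.out_dir = Path(self.out_dir)


def write_outputs(
    config: RunConfig,
    table: pd.DataFrame,
    metadata: dict,
    *,
    stem: str | None = None,
) -> tuple[Path, Path]:
    """Write a result table (CSV, full precision) and its JSON metadata."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or config.mode
    csv_path = config.out_dir / f"{stem}.csv"
    json_path = config.out_dir / f"{stem}.meta.json"
    table.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "package": "auxmean",
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        **metadata,
    }
    json_path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    log.info("wrote %s and %s", csv_path, json_path)
    return csv_path, json_path


def make_fixture(
    kind: str,
    stream: np.random.Generator,
    out_dir: str | Path,
    *,
    n_rows: int = 60,
) -> tuple[Path, Path]:
    """Write a small paired CSV fixture plus a JSON file of its true summary.

    ``linear``: exact line (rho = 1); ``skewed``: lognormal pair; and
    ``degenerate``: constant auxiliary column for exercising error paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "linear":
        x = np.linspace(1.0, 10.0, n_rows)
        y = 2.0 * x + 3.0
    elif kind == "skewed":
        z = stream.standard_normal(n_rows)
        x = np.exp(1.0 + 0.5 * z)
        y = np.exp(0.5 + 0.4 * z + 0.2 * stream.standard_normal(n_rows))
    elif kind == "degenerate":
        x = np.full(n_rows, 5.0)
        y = stream.normal(10.0, 1.0, n_rows)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    df = pd.DataFrame({"y": y, "x": x})
    csv_path = out_dir / f"fixture_{kind}.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    s = summarize_population(y, x)
    truth = {f: getattr(s, f) for f in
             ("N", "mu_y", "mu_x", "S2_y", "S2_x", "S_yx",
              "C_y", "C_x", "C_yx", "rho", "median_x")}
    json_path = out_dir / f"fixture_{kind}.truth.json"
    json_path.write_text(json.dumps(truth, indent=2, default=float,
                                    allow_nan=True) + "\n")
    return csv_path, json_path
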